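"""Putative-enhancer calling and group-level consensus catalogs.

A sample's putative enhancers are its H3K27ac peaks that overlap an H3K4me1
peak and lie at least a minimum distance (default 2.5 kb) from every
annotated TSS.  Per-group consensus catalogs merge the per-sample sets and
keep regions reproducibly supported by a minimum number of samples
(default 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import (
    IntervalSet,
    distances_to_points,
    filter_overlapping,
    merge,
    overlap_bp,
)

__all__ = ["SamplePeaks", "EnhancerCatalog", "call_sample_enhancers", "build_consensus"]


@dataclass
class SamplePeaks:
    """Peak calls for the two enhancer histone marks of one sample."""

    sample_id: str
    group: str  # "tumor" | "normal"
    patient_id: str
    k4me1: IntervalSet
    k27ac: IntervalSet

    def __post_init__(self) -> None:
        if self.group not in ("tumor", "normal"):
            raise ValueError(f"group must be tumor|normal, got {self.group!r}")


@dataclass
class EnhancerCatalog:
    """Merged consensus enhancer regions for one group with sample support."""

    group: str
    regions: IntervalSet  # disjoint, named group_####
    support: np.ndarray  # contributing samples per region
    n_samples: int
    min_support: int = 1

    @property
    def region_ids(self) -> list[str]:
        return [str(n) for n in self.regions.names]


def _geometric_intersection(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Clip ``a`` to its per-base intersection with the union of ``b``."""
    merged = merge(b).by_chrom()
    rows = []
    for chrom, (starts, ends) in a.by_chrom().items():
        if chrom not in merged:
            continue
        ms, me = merged[chrom]
        for s, e in zip(starts, ends):
            i = np.searchsorted(me, s, side="right")
            j = np.searchsorted(ms, e, side="left")
            for k in range(i, j):
                rows.append((chrom, max(int(s), int(ms[k])), min(int(e), int(me[k]))))
    return IntervalSet(rows)


def call_sample_enhancers(
    sample: SamplePeaks,
    tss_points,
    tss_min_dist_bp: int = 2500,
    anchor: str = "k27ac",
) -> IntervalSet:
    """Call one sample's putative enhancers.

    Keeps H3K27ac peaks overlapping (>= 1 bp) any H3K4me1 peak, then removes
    those closer than ``tss_min_dist_bp`` to any TSS; a peak at exactly the
    minimum distance is retained ("at least" semantics).  With
    ``anchor="geometric"`` the common region is clipped to the per-base
    intersection of the two marks instead of keeping H3K27ac coordinates.
    """
    if tss_min_dist_bp < 0:
        raise ValueError("tss_min_dist_bp must be >= 0")
    if anchor == "k27ac":
        common = filter_overlapping(sample.k27ac, sample.k4me1, 1)
    elif anchor == "geometric":
        common = _geometric_intersection(sample.k27ac, sample.k4me1)
    else:
        raise ValueError(f"anchor must be k27ac|geometric, got {anchor!r}")
    if len(common) == 0:
        return common
    dist = distances_to_points(common, tss_points)
    return common.subset(dist >= tss_min_dist_bp)


def build_consensus(
    per_sample: list[IntervalSet], group: str, min_support: int = 2
) -> EnhancerCatalog:
    """Merge per-sample enhancer sets into a reproducibility-filtered catalog.

    The union of all per-sample sets is merged first; support of a merged
    region is the number of samples contributing >= 1 bp of overlap to it
    (a region bridging two samples' peaks via a third counts each sample
    once).  Regions with support below ``min_support`` are dropped and ids
    ``<group>_####`` are assigned in genome order.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not per_sample:
        raise ValueError("per_sample must be a non-empty list")
    all_rows = [
        (iv.chrom, iv.start, iv.end) for s in per_sample for iv in s
    ]
    merged = merge(IntervalSet(all_rows)) if all_rows else IntervalSet()
    support = np.zeros(len(merged), dtype=np.int64)
    for s in per_sample:
        if len(s):
            support += (overlap_bp(merged, s) > 0).astype(np.int64)
    keep = support >= min_support
    kept = merged.subset(keep)
    kept_support = support[keep]
    named = IntervalSet(
        [(iv.chrom, iv.start, iv.end) for iv in kept],
        names=[f"{group}_{i:04d}" for i in range(len(kept))],
        scores=kept_support.astype(float),
    )
    return EnhancerCatalog(
        group=group,
        regions=named,
        support=kept_support,
        n_samples=len(per_sample),
        min_support=min_support,
    )
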