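"""Genomic interval algebra: parsing, merging, overlap and windowed gene linking.

All coordinates follow the BED convention — 0-based, half-open ``[start, end)``.
GTF input (1-based, inclusive) is converted at the reader boundary.  Abutting
half-open intervals (``a.end == b.start``) share no base and are therefore
never merged, matching bedtools semantics.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GeneAnnotation",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_gtf",
    "read_gene_table",
    "merge",
    "filter_overlapping",
    "overlap_bp",
    "distance_to_points",
    "link_genes_within",
]


class GenomicInterval(NamedTuple):
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __len__(self) -> int:  # bases covered
        return self.end - self.start


class BedParseError(ValueError):
    """Raised for malformed BED records; message names the offending line."""


def _validate_interval(chrom: str, start: int, end: int, context: str = "") -> None:
    if not chrom:
        raise ValueError(f"empty chromosome name{context}")
    if not (0 <= start < end):
        raise BedParseError(
            f"invalid interval {chrom}:{start}-{end} (need 0 <= start < end){context}"
        )


class IntervalSet:
    """An ordered collection of genomic intervals with optional ids and scores.

    Iteration order is (chrom lexicographic, start, end).  Disjointness is not
    required unless the set was produced by :func:`merge`.
    """

    __slots__ = ("chroms", "starts", "ends", "names", "scores")

    def __init__(
        self,
        intervals: Iterable[tuple] = (),
        names: Sequence[str] | None = None,
        scores: Sequence[float] | None = None,
    ) -> None:
        ivs = [GenomicInterval(str(c), int(s), int(e)) for c, s, e in intervals]
        for iv in ivs:
            _validate_interval(*iv)
        n = len(ivs)
        names_arr = np.asarray(
            list(names) if names is not None else [""] * n, dtype=object
        )
        scores_arr = np.asarray(
            list(scores) if scores is not None else [math.nan] * n, dtype=float
        )
        if len(names_arr) != n or len(scores_arr) != n:
            raise ValueError("names/scores length mismatch")
        order = sorted(range(n), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
        self.chroms = np.asarray([ivs[i].chrom for i in order], dtype=object)
        self.starts = np.asarray([ivs[i].start for i in order], dtype=np.int64)
        self.ends = np.asarray([ivs[i].end for i in order], dtype=np.int64)
        self.names = names_arr[order] if n else names_arr
        self.scores = scores_arr[order] if n else scores_arr

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for c, s, e in zip(self.chroms, self.starts, self.ends):
            yield GenomicInterval(c, int(s), int(e))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            len(self) == len(other)
            and bool(np.all(self.chroms == other.chroms))
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
        )

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    def interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(self.chroms[i], int(self.starts[i]), int(self.ends[i]))

    def total_bases(self) -> int:
        """Sum of interval lengths (bases counted with multiplicity)."""
        return int(np.sum(self.ends - self.starts))

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, in sorted order."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if len(self) == 0:
            return out
        chroms = self.chroms
        bounds = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        pieces = np.split(np.arange(len(self)), bounds)
        for idx in pieces:
            out[chroms[idx[0]]] = (self.starts[idx], self.ends[idx])
        return out

    def subset(self, mask: np.ndarray) -> "IntervalSet":
        mask = np.asarray(mask, dtype=bool)
        out = IntervalSet.__new__(IntervalSet)
        out.chroms = self.chroms[mask]
        out.starts = self.starts[mask]
        out.ends = self.ends[mask]
        out.names = self.names[mask]
        out.scores = self.scores[mask]
        return out


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its strand-correct transcription start site (0-based)."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    biotype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SKIP = ("track", "browser", "#")


def read_bed(path) -> IntervalSet:
    """Read a BED3+ file into a sorted :class:`IntervalSet`.

    Columns 4 and 5 populate names and scores when present; further columns
    are ignored.  ``track``/``browser``/comment lines are skipped.  Malformed
    records raise :class:`BedParseError` naming the line number.
    """
    rows, names, scores = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r},{fields[2]!r}"
                ) from None
            try:
                _validate_interval(chrom, start, end)
            except (BedParseError, ValueError) as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from None
            rows.append((chrom, start, end))
            names.append(fields[3] if len(fields) > 3 else "")
            try:
                scores.append(float(fields[4]) if len(fields) > 4 else math.nan)
            except ValueError:
                scores.append(math.nan)
    return IntervalSet(rows, names=names, scores=scores)


def write_bed(ivset: IntervalSet, path, header_lines: Sequence[str] = ()) -> None:
    """Write BED3/4/5; name and score columns are emitted only when non-trivial."""
    has_names = any(n for n in ivset.names)
    has_scores = bool(len(ivset)) and not np.all(np.isnan(ivset.scores))
    with open(path, "w") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        for i in range(len(ivset)):
            cols = [ivset.chroms[i], str(int(ivset.starts[i])), str(int(ivset.ends[i]))]
            if has_names or has_scores:
                cols.append(str(ivset.names[i]) or ".")
            if has_scores:
                sc = ivset.scores[i]
                cols.append("." if math.isnan(sc) else f"{sc:g}")
            fh.write("\t".join(cols) + "\n")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path, feature: str = "gene") -> list[GeneAnnotation]:
    """Extract gene annotations from a GTF file (1-based inclusive → 0-based).

    The TSS is the 5' end of the gene: 0-based ``start-1`` on ``+``, and the
    last covered base ``end-1`` (0-based) on ``-``.
    """
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: not a 9-column GTF record")
            if fields[2] != feature:
                continue
            chrom, start1, end1, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            tss = (start1 - 1) if strand == "+" else (end1 - 1)
            genes.append(
                GeneAnnotation(
                    gene_id=attrs.get("gene_id", ""),
                    gene_name=attrs.get("gene_name", attrs.get("gene_id", "")),
                    chrom=chrom,
                    strand=strand,
                    tss=tss,
                    biotype=attrs.get("gene_biotype", attrs.get("gene_type", "")),
                )
            )
    return genes


def read_gene_table(path) -> list[GeneAnnotation]:
    """Read a TSV gene table: gene_id, gene_name, chrom, strand, tss, biotype."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"gene_id", "gene_name", "chrom", "strand", "tss", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneAnnotation(
            gene_id=str(r.gene_id),
            gene_name=str(r.gene_name),
            chrom=str(r.chrom),
            strand=str(r.strand),
            tss=int(r.tss),
            biotype=str(r.biotype),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def merge(ivset: IntervalSet) -> IntervalSet:
    """Coalesce overlapping intervals per chromosome.

    Output intervals are disjoint and non-adjacent except that abutting
    half-open intervals (``end == start``) are preserved as distinct: they
    share no base.  The union of covered bases is exactly preserved.
    """
    rows: list[tuple[str, int, int]] = []
    for chrom, (starts, ends) in ivset.by_chrom().items():
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            s, e = int(s), int(e)
            if s < cur_e:  # strict: abutting (s == cur_e) does not merge
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return IntervalSet(rows)


def _overlap_with_merged(
    starts: np.ndarray, ends: np.ndarray, ms: np.ndarray, me: np.ndarray
) -> np.ndarray:
    """Per-query overlap (bp) against a merged, disjoint, sorted interval list."""
    cum = np.concatenate(([0], np.cumsum(me - ms)))
    i = np.searchsorted(me, starts, side="right")
    j = np.searchsorted(ms, ends, side="left")
    out = np.zeros(len(starts), dtype=np.int64)
    hit = i < j
    if np.any(hit):
        ih, jh = i[hit], j[hit]
        total = cum[jh] - cum[ih]
        left_trim = np.maximum(starts[hit] - ms[ih], 0)
        right_trim = np.maximum(me[jh - 1] - ends[hit], 0)
        out[hit] = total - left_trim - right_trim
    return out


def overlap_bp(anchor: IntervalSet, other: IntervalSet) -> np.ndarray:
    """Bases of each anchor interval covered by the union of ``other``.

    Returned in anchor's sorted iteration order.
    """
    merged = merge(other).by_chrom()
    out = np.zeros(len(anchor), dtype=np.int64)
    pos = 0
    for chrom, (starts, ends) in anchor.by_chrom().items():
        n = len(starts)
        if chrom in merged:
            ms, me = merged[chrom]
            out[pos : pos + n] = _overlap_with_merged(starts, ends, ms, me)
        pos += n
    return out


def filter_overlapping(
    anchor: IntervalSet, other: IntervalSet, min_overlap_bp: int = 1
) -> IntervalSet:
    """Anchor intervals sharing >= ``min_overlap_bp`` bases with the union of
    ``other``; anchor coordinates are preserved (no clipping)."""
    if min_overlap_bp < 1:
        raise ValueError(f"min_overlap_bp must be >= 1, got {min_overlap_bp}")
    return anchor.subset(overlap_bp(anchor, other) >= min_overlap_bp)


def _points_by_chrom(points: Iterable[tuple[str, int]]) -> dict[str, np.ndarray]:
    if isinstance(points, dict):
        return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in points.items()}
    acc: dict[str, list[int]] = {}
    for chrom, bp in points:
        acc.setdefault(chrom, []).append(int(bp))
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in acc.items()}


def distance_to_points(iv: GenomicInterval, points) -> float:
    """Minimum distance (bp) from the interval's occupied bases to any point.

    Points inside ``[start, end)`` give 0; the half-open end is not a base, so
    exterior distance is measured from ``start`` and ``end - 1``.  Returns
    ``math.inf`` when no point lies on the interval's chromosome.
    """
    pts = _points_by_chrom(points)
    arr = pts.get(iv.chrom)
    if arr is None or len(arr) == 0:
        return math.inf
    inside = (arr >= iv.start) & (arr < iv.end)
    if np.any(inside):
        return 0.0
    d = np.minimum(np.abs(arr - iv.start), np.abs(arr - (iv.end - 1)))
    return float(np.min(d))


def distances_to_points(ivset: IntervalSet, points) -> np.ndarray:
    """Vectorised :func:`distance_to_points` over a whole set (sorted order)."""
    pts = _points_by_chrom(points)
    out = np.full(len(ivset), math.inf)
    pos = 0
    for chrom, (starts, ends) in ivset.by_chrom().items():
        n = len(starts)
        arr = pts.get(chrom)
        if arr is not None and len(arr):
            # nearest point to each of start and end-1; containment -> 0
            last = ends - 1
            for k, (s, e1) in enumerate(zip(starts, last)):
                lo = np.searchsorted(arr, s, side="left")
                hi = np.searchsorted(arr, e1, side="right")
                if hi > lo:  # a point within [start, end-1] == inside [start,end)
                    out[pos + k] = 0.0
                    continue
                cand = []
                if lo > 0:
                    cand.append(s - arr[lo - 1])
                if lo < len(arr):
                    cand.append(arr[lo] - e1)
                out[pos + k] = float(min(cand))
        pos += n
    return out


def link_genes_within(
    loci: IntervalSet,
    genes: Sequence[GeneAnnotation],
    window_bp: int,
    biotype_filter: str | None = None,
) -> dict[str, list[str]]:
    """Link genes to loci when the TSS lies in ``[start - window, end + window)``.

    A TSS exactly ``window_bp`` upstream of ``start`` links (left edge is
    closed); one exactly ``window_bp`` past ``end`` does not (right edge open).
    Keys are locus names when set, else ``chrom:start-end``.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    pool = [g for g in genes if biotype_filter is None or g.biotype == biotype_filter]
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom in {g.chrom for g in pool}:
        sub = sorted((g.tss, g.gene_id) for g in pool if g.chrom == chrom)
        by_chrom[chrom] = (np.asarray([t for t, _ in sub], dtype=np.int64), [i for _, i in sub])
    out: dict[str, list[str]] = {}
    for i in range(len(loci)):
        iv = loci.interval(i)
        key = str(loci.names[i]) or f"{iv.chrom}:{iv.start}-{iv.end}"
        hits: list[str] = []
        entry = by_chrom.get(iv.chrom)
        if entry is not None:
            tss_arr, ids = entry
            lo = np.searchsorted(tss_arr, iv.start - window_bp, side="left")
            hi = np.searchsorted(tss_arr, iv.end + window_bp, side="left")
            hits = ids[lo:hi]
        out[key] = list(hits)
    return out
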