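"""End-to-end orchestration: catalog -> differential -> saturation -> funnel.

Reads the fixture/file layout the generator emits (or equivalent real data
exported to the same plain-text formats), runs every stage with one resolved
threshold configuration, and writes per-stage BED/TSV outputs plus a
machine-readable JSON summary.  Every output file carries a header block
with the package version, the resolved thresholds and the seed, so a run can
be reproduced from its own outputs.

Also hosts the immunohistochemistry scoring utility: the product of a
positive-cell-proportion score (1-4, by quartile bins of the percentage of
positive cells) and a staining-intensity score (0-3), giving 0-12.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import SamplePeaks, build_consensus, call_sample_enhancers
from .differential import (
    CountMatrix,
    PairedDesign,
    ThresholdConfig,
    call_differential_enhancers,
    records_to_frame,
    saturation_analysis,
)
from .intervals import IntervalSet, merge, overlap_bp, read_bed, read_gene_table, write_bed
from .prioritize import ExpressionMatrix, run_funnel

__all__ = ["RunConfig", "IHCScore", "ihc_score", "validate_inputs", "run_all"]


@dataclass
class RunConfig:
    """Paths and settings for a full pipeline run over one fixture directory."""

    fixture_dir: str
    out_dir: str
    seed: int = 0
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    run_saturation: bool = False
    saturation_k: list[int] | None = None
    saturation_replicates: int = 10
    target_cluster: str | None = None  # default: manifest value
    tf_ids: list[str] | None = None    # default: manifest value
    stop_after: str | None = None      # catalog | differential | saturation

    def resolved(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


@dataclass(frozen=True)
class IHCScore:
    """Immunohistochemistry composite score: proportion bin x intensity."""

    proportion_pct: float
    intensity: int
    proportion_score: int
    score: int


def ihc_score(proportion_pct: float, intensity: int) -> IHCScore:
    """Score a stained section: proportion bin (<=25 -> 1, <=50 -> 2,
    <=75 -> 3, else 4) times intensity (0-3); range 0-12.

    The printed bin edges leave 25-26% formally unassigned; the closed upper
    bound at each edge used here is a documented convention.
    """
    if not (0 <= proportion_pct <= 100):
        raise ValueError(f"proportion_pct must be in [0, 100], got {proportion_pct}")
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity must be one of 0,1,2,3, got {intensity}")
    if proportion_pct <= 25:
        pscore = 1
    elif proportion_pct <= 50:
        pscore = 2
    elif proportion_pct <= 75:
        pscore = 3
    else:
        pscore = 4
    return IHCScore(
        proportion_pct=float(proportion_pct),
        intensity=int(intensity),
        proportion_score=pscore,
        score=pscore * int(intensity),
    )


# ---------------------------------------------------------------------------
# input loading / validation
# ---------------------------------------------------------------------------


def _load_manifest(fixture_dir: Path) -> dict:
    path = fixture_dir / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {fixture_dir}")
    return json.loads(path.read_text())


def load_samples(fixture_dir: Path, manifest: dict) -> list[SamplePeaks]:
    samples = []
    for entry in manifest["samples"]:
        samples.append(
            SamplePeaks(
                sample_id=entry["sample_id"],
                group=entry["group"],
                patient_id=entry["patient_id"],
                k4me1=read_bed(fixture_dir / entry["k4me1_path"]),
                k27ac=read_bed(fixture_dir / entry["k27ac_path"]),
            )
        )
    return samples


def validate_inputs(config: RunConfig) -> dict:
    """Check file existence, schemas and id cross-references.

    Returns ``{"errors": [...], "warnings": [...]}``; never raises for
    findings (only for an unreadable manifest).
    """
    errors: list[str] = []
    warnings: list[str] = []
    fdir = Path(config.fixture_dir)
    try:
        manifest = _load_manifest(fdir)
    except FileNotFoundError as exc:
        return {"errors": [str(exc)], "warnings": []}

    for entry in manifest.get("samples", []):
        for key in ("k4me1_path", "k27ac_path"):
            p = fdir / entry[key]
            if not p.exists():
                errors.append(f"missing peak file {entry[key]}")
                continue
            try:
                read_bed(p)
            except Exception as exc:
                errors.append(str(exc))
    for name, rel in {**manifest.get("tables", {}), **manifest.get("beds", {})}.items():
        if not (fdir / rel).exists():
            errors.append(f"missing {name} file {rel}")
    if errors:
        return {"errors": errors, "warnings": warnings}

    counts = CountMatrix.from_tsv(
        fdir / manifest["tables"]["counts"],
        fdir / manifest["tables"]["region_lengths"],
        fdir / manifest["tables"]["library_sizes"],
    )
    for dname in ("design_chip", "design_rna"):
        design = PairedDesign.from_tsv(fdir / manifest["tables"][dname])
        universe = (
            counts.sample_ids
            if dname == "design_chip"
            else ExpressionMatrix.from_tsv(fdir / manifest["tables"]["expression"]).sample_ids
        )
        try:
            design.validate_against(universe)
        except ValueError as exc:
            errors.append(f"{dname}: {exc}")
    regions = read_bed(fdir / manifest["beds"]["regions"])
    region_names = {str(n) for n in regions.names}
    missing = [r for r in counts.region_ids if r not in region_names]
    if missing:
        errors.append(f"count regions missing from regions.bed: {missing[:5]}")
    if not set(TF_DEFAULT(manifest, config)) <= set(
        ExpressionMatrix.from_tsv(fdir / manifest["tables"]["expression"]).gene_ids
    ):
        errors.append("TF ids absent from expression matrix")
    return {"errors": errors, "warnings": warnings}


def TF_DEFAULT(manifest: dict, config: RunConfig) -> list[str]:
    return list(config.tf_ids or manifest.get("tf_ids", []))


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------


def _header(config: RunConfig, stage: str) -> list[str]:
    cfg = config.thresholds
    pairs = ", ".join(f"{k}={v}" for k, v in asdict(cfg).items())
    return [
        f"oncoenh {__version__} | stage={stage} | seed={config.seed}",
        f"thresholds: {pairs}",
    ]


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig, stage: str) -> None:
    with open(path, "w") as fh:
        for h in _header(config, stage):
            fh.write(f"# {h}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run_all(config: RunConfig) -> dict:
    """Execute catalog -> differential -> (saturation) -> funnel.

    Returns the run summary (also written to ``summary.json``); raises
    ``RuntimeError`` naming the failing stage on any stage error.
    """
    fdir = Path(config.fixture_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    findings = validate_inputs(config)
    if findings["errors"]:
        raise RuntimeError(f"stage validate: {findings['errors']}")
    manifest = _load_manifest(fdir)
    cfg = config.thresholds
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(cfg),
        "stages": {},
    }

    def guarded(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name}: {exc}") from exc

    # ---- catalog --------------------------------------------------------
    def catalog_stage():
        samples = load_samples(fdir, manifest)
        genes = read_gene_table(fdir / manifest["tables"]["genes"])
        tss: dict[str, list[int]] = {}
        for g in genes:
            tss.setdefault(g.chrom, []).append(g.tss)
        tss = {c: np.sort(np.asarray(v)) for c, v in tss.items()}
        out_catalogs = {}
        for group in ("tumor", "normal"):
            per_sample = [
                call_sample_enhancers(s, tss, cfg.tss_min_dist_bp, anchor=cfg.anchor)
                for s in samples
                if s.group == group
            ]
            cat = build_consensus(per_sample, group, cfg.min_support)
            write_bed(cat.regions, out / f"catalog_{group}.bed",
                      header_lines=_header(config, f"catalog:{group}"))
            out_catalogs[group] = cat
            summary["stages"][f"catalog_{group}"] = {
                "n_samples": cat.n_samples, "n_regions": len(cat.regions),
            }
        return out_catalogs, genes

    def finish() -> dict:
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
        return summary

    catalogs_by_group, genes = guarded("catalog", catalog_stage)
    if config.stop_after == "catalog":
        return finish()

    # ---- differential ---------------------------------------------------
    def differential_stage():
        counts = CountMatrix.from_tsv(
            fdir / manifest["tables"]["counts"],
            fdir / manifest["tables"]["region_lengths"],
            fdir / manifest["tables"]["library_sizes"],
        )
        design = PairedDesign.from_tsv(fdir / manifest["tables"]["design_chip"])
        regions = read_bed(fdir / manifest["beds"]["regions"])
        union = merge(IntervalSet(
            [(iv.chrom, iv.start, iv.end)
             for grp in catalogs_by_group.values() for iv in grp.regions]
        ))
        # tested universe: count-matrix regions overlapping the merged
        # tumor+normal consensus (counting happened on the fixed region grid)
        in_universe = overlap_bp(regions, union) > 0
        by_name = dict(zip([str(n) for n in regions.names], in_universe))
        universe = [rid for rid in counts.region_ids if by_name.get(rid, False)]
        records = call_differential_enhancers(counts, design, universe, cfg)
        table = records_to_frame(records)
        _write_table(table, out / "differential.tsv", config, "differential")
        name_to_iv = {str(regions.names[i]): regions.interval(i)
                      for i in range(len(regions))}
        for klass in ("SOE", "CDE"):
            ids = [r.region_id for r in records if r.klass == klass]
            ivs = IntervalSet(
                [(name_to_iv[i].chrom, name_to_iv[i].start, name_to_iv[i].end)
                 for i in ids],
                names=ids,
            )
            write_bed(ivs, out / f"{klass.lower()}.bed",
                      header_lines=_header(config, f"differential:{klass}"))
        summary["stages"]["differential"] = {
            "universe": len(universe),
            "n_soe": int((table["klass"] == "SOE").sum()),
            "n_cde": int((table["klass"] == "CDE").sum()),
        }
        return counts, design, records, universe, name_to_iv

    counts, design_chip, records, universe, name_to_iv = guarded(
        "differential", differential_stage
    )
    if config.stop_after == "differential":
        return finish()

    # ---- saturation (optional) -----------------------------------------
    def saturation_stage():
        results = saturation_analysis(
            counts, design_chip, cfg,
            k_values=config.saturation_k,
            n_replicates=config.saturation_replicates,
            seed=config.seed, universe=universe,
        )
        rows = [
            {"k": r.k, "replicate": i, "recovery": rec}
            for r in results for i, rec in enumerate(r.recoveries)
        ]
        _write_table(pd.DataFrame(rows), out / "saturation.tsv", config, "saturation")
        _write_table(
            pd.DataFrame([
                {"k": r.k, "mean": r.mean, "sd": r.sd,
                 "n_replicates": r.n_replicates,
                 "reference_empty": r.reference_empty}
                for r in results
            ]),
            out / "saturation_summary.tsv", config, "saturation",
        )
        summary["stages"]["saturation"] = {
            "k_values": [r.k for r in results],
            "mean_recovery": {str(r.k): r.mean for r in results},
        }

    if config.run_saturation or config.stop_after == "saturation":
        guarded("saturation", saturation_stage)
    if config.stop_after == "saturation":
        return finish()

    # ---- funnel ---------------------------------------------------------
    def funnel_stage():
        soe_list = [r.region_id for r in records if r.klass == "SOE"]
        soes = IntervalSet(
            [(name_to_iv[i].chrom, name_to_iv[i].start, name_to_iv[i].end)
             for i in soe_list],
            names=soe_list,
        )
        cluster_peaks = read_bed(fdir / manifest["beds"]["cluster_peaks"])
        expr = ExpressionMatrix.from_tsv(fdir / manifest["tables"]["expression"])
        design_rna = PairedDesign.from_tsv(fdir / manifest["tables"]["design_rna"])
        cells = pd.read_csv(fdir / manifest["tables"]["cluster_cells"],
                            sep="\t", index_col=0, comment="#")
        labels = cells.pop("cluster")
        target = config.target_cluster or manifest.get("target_cluster", "squamous")
        tf_ids = TF_DEFAULT(manifest, config)
        result = run_funnel(
            soes=soes, cluster_peaks=cluster_peaks, genes=genes, expr=expr,
            design=design_rna, cluster_de=cells, tf_ids=tf_ids, cfg=cfg,
            cluster_kwargs={"labels": labels, "target_cluster": target},
        )
        write_bed(result.stage1_loci, out / "funnel_loci.bed",
                  header_lines=_header(config, "funnel:loci"))
        _write_table(result.audit, out / "funnel_audit.tsv", config, "funnel")
        _write_table(
            pd.DataFrame({"candidate": result.stage4_candidates}),
            out / "funnel_candidates.tsv", config, "funnel",
        )
        summary["stages"]["funnel"] = {
            **result.stage_counts, "metadata": result.metadata,
            "candidates": result.stage4_candidates,
        }

    guarded("funnel", funnel_stage)
    return finish()
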