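"""Four-stage integrative funnel for enhancer-driven oncogene candidates.

Stage 1 intersects cancer-gained enhancers (SOEs) with cell-type-cluster-
specific accessibility peaks; stage 2 links protein-coding genes whose TSS
lies within a genomic window (default 200 kb) of the surviving loci; stage 3
keeps genes upregulated both in bulk paired tumor/normal expression and in
the target single-cell cluster; stage 4 keeps genes co-expressed (Pearson
r above threshold, BH-adjusted p below threshold) with ALL of the master
transcription factors across tumor samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import PairedDesign, ThresholdConfig
from .intervals import GeneAnnotation, IntervalSet, filter_overlapping, link_genes_within
from .stats import (
    bh_adjust,
    bonferroni_adjust,
    pearson_with_p,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

__all__ = [
    "ExpressionMatrix",
    "ClusterDE",
    "FunnelResult",
    "celltype_overlap_stage",
    "bulk_de_filter",
    "cluster_de_filter",
    "coexpression_filter",
    "run_funnel",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample normalized expression (RPKM or equivalent, >= 0)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape mismatch")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    def gene_row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self.gene_ids.index(gene_id)]
        except ValueError:
            raise KeyError(f"unknown gene {gene_id!r}") from None

    def sample_cols(self, sample_ids) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return self.values[:, idx]

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(
            gene_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )


@dataclass
class ClusterDE:
    """Per-gene target-cluster-vs-rest differential expression statistics."""

    table: pd.DataFrame  # columns: gene_id, log2fc_cluster, p, p_adjusted
    adjust_method: str = "bonferroni"

    def __post_init__(self) -> None:
        need = {"gene_id", "log2fc_cluster", "p", "p_adjusted"}
        if not need <= set(self.table.columns):
            raise ValueError(f"cluster DE table needs columns {sorted(need)}")


@dataclass
class FunnelResult:
    """Per-stage survivors and the audit trail of the prioritisation funnel."""

    stage0_soe_count: int
    stage1_loci: IntervalSet
    stage2_genes: list[str]
    stage3_genes: list[str]
    stage4_candidates: list[str]
    audit: pd.DataFrame  # per stage-2 gene: filter outcomes and per-TF r
    metadata: dict

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "stage0_soes": self.stage0_soe_count,
            "stage1_loci": len(self.stage1_loci),
            "stage2_linked_genes": len(self.stage2_genes),
            "stage3_de_genes": len(self.stage3_genes),
            "stage4_candidates": len(self.stage4_candidates),
        }

    def failing_stage(self, gene_id: str) -> str | None:
        """First funnel stage the gene failed, or None if it is a candidate."""
        if gene_id in self.stage4_candidates:
            return None
        if gene_id not in self.stage2_genes:
            return "overlap_linking"
        row = self.audit.set_index("gene_id").loc[gene_id]
        if not row["bulk_de_pass"]:
            return "bulk_de"
        if not row["cluster_de_pass"]:
            return "cluster_de"
        return "coexpression"


def celltype_overlap_stage(soes: IntervalSet, cluster_peaks: IntervalSet) -> IntervalSet:
    """SOEs sharing >= 1 bp with any cluster-specific peak (no clipping)."""
    if len(soes) == 0 or len(cluster_peaks) == 0:
        return soes.subset(np.zeros(len(soes), dtype=bool))
    return filter_overlapping(soes, cluster_peaks, 1)


def _bulk_de_table(
    expr: ExpressionMatrix, design: PairedDesign, cfg: ThresholdConfig
) -> pd.DataFrame:
    if len(design) < 2:
        raise ValueError("need >= 2 pairs")
    tum = expr.sample_cols(design.tumor_samples())
    nor = expr.sample_cols(design.normal_samples())
    stats_p = np.empty(len(expr.gene_ids))
    for i in range(len(expr.gene_ids)):
        _, stats_p[i] = wilcoxon_signed_rank(tum[i], nor[i])
    padj = bh_adjust(stats_p)
    log2fc = np.log2(
        (tum.mean(axis=1) + cfg.pseudocount) / (nor.mean(axis=1) + cfg.pseudocount)
    )
    return pd.DataFrame(
        {"gene_id": expr.gene_ids, "log2fc": log2fc, "p": stats_p, "padj": padj}
    )


def bulk_de_filter(
    expr: ExpressionMatrix, design: PairedDesign, cfg: ThresholdConfig | None = None
) -> list[str]:
    """Genes upregulated in paired bulk tumors: Wilcoxon signed-rank across
    patient pairs, BH over all genes, log2FC of group means; keep
    log2FC > deg_log2fc and padj < deg_padj (strict)."""
    cfg = cfg or ThresholdConfig()
    tab = _bulk_de_table(expr, design, cfg)
    keep = (tab["log2fc"] > cfg.deg_log2fc) & (tab["padj"] < cfg.deg_padj)
    return tab.loc[keep, "gene_id"].tolist()


def cluster_de_from_matrix(
    cells: pd.DataFrame,
    labels: pd.Series,
    target_cluster: str,
    cfg: ThresholdConfig | None = None,
) -> ClusterDE:
    """Compute target-cluster-vs-rest DE from a cells x genes matrix.

    Per gene: Mann-Whitney rank-sum between cells in the target cluster and
    all other cells; log2FC of cluster means with pseudocount; adjusted per
    ``cfg.cluster_adjust`` (Bonferroni by default for this stage).
    """
    cfg = cfg or ThresholdConfig()
    labels = labels.loc[cells.index]
    if target_cluster not in set(labels):
        raise ValueError(f"unknown cluster label {target_cluster!r}")
    in_mask = (labels == target_cluster).to_numpy()
    vals = cells.to_numpy(dtype=float)
    pvals = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        _, pvals[j] = wilcoxon_rank_sum(vals[in_mask, j], vals[~in_mask, j])
    adjust = bonferroni_adjust if cfg.cluster_adjust == "bonferroni" else bh_adjust
    padj = adjust(pvals)
    eps = cfg.pseudocount
    log2fc = np.log2(
        (vals[in_mask].mean(axis=0) + eps) / (vals[~in_mask].mean(axis=0) + eps)
    )
    return ClusterDE(
        table=pd.DataFrame(
            {
                "gene_id": list(cells.columns),
                "log2fc_cluster": log2fc,
                "p": pvals,
                "p_adjusted": padj,
            }
        ),
        adjust_method=cfg.cluster_adjust,
    )


def cluster_de_filter(
    cluster_de, cfg: ThresholdConfig | None = None, **matrix_kwargs
) -> list[str]:
    """Genes upregulated in the target cluster versus the rest.

    Accepts a precomputed :class:`ClusterDE` table, or a cells x genes
    DataFrame plus ``labels=``/``target_cluster=`` keywords to compute one.
    Keeps log2FC > cluster_log2fc and adjusted p < deg_padj (strict).
    """
    cfg = cfg or ThresholdConfig()
    if isinstance(cluster_de, pd.DataFrame):
        cluster_de = cluster_de_from_matrix(cluster_de, cfg=cfg, **matrix_kwargs)
    tab = cluster_de.table
    keep = (tab["log2fc_cluster"] > cfg.cluster_log2fc) & (
        tab["p_adjusted"] < cfg.deg_padj
    )
    return tab.loc[keep, "gene_id"].tolist()


def coexpression_filter(
    expr: ExpressionMatrix,
    tf_ids: list[str],
    candidates: list[str],
    cfg: ThresholdConfig | None = None,
    sample_ids: list[str] | None = None,
    method: str = "pearson",
) -> tuple[list[str], pd.DataFrame]:
    """Keep candidates co-expressed with every master TF.

    Pearson r (or Spearman with ``method="spearman"``) between each candidate
    and each TF across the given samples (tumor samples by convention), with
    BH adjustment within each TF's candidate list.  A candidate survives only
    if r > coexpr_r and padj < coexpr_padj for ALL TFs; zero-variance vectors
    make r undefined and the pair fails with a flag rather than raising.
    Returns (kept gene ids, per-pair audit table).
    """
    cfg = cfg or ThresholdConfig()
    for tf in tf_ids:
        if tf not in expr.gene_ids:
            raise KeyError(f"TF {tf!r} absent from expression matrix")
    cols = (
        [expr.sample_ids.index(s) for s in sample_ids]
        if sample_ids is not None
        else list(range(len(expr.sample_ids)))
    )
    if len(cols) < 3:
        raise ValueError("need >= 3 samples for correlation")
    from scipy.stats import rankdata

    def vec(gid: str) -> np.ndarray:
        v = expr.gene_row(gid)[cols]
        return rankdata(v) if method == "spearman" else v

    rows = []
    pass_by_tf: dict[str, np.ndarray] = {}
    for tf in tf_ids:
        tf_vec = vec(tf)
        r_arr = np.full(len(candidates), np.nan)
        p_arr = np.full(len(candidates), np.nan)
        for i, gid in enumerate(candidates):
            r_arr[i], p_arr[i] = pearson_with_p(vec(gid), tf_vec)
        defined = ~np.isnan(p_arr)
        padj = np.full(len(candidates), np.nan)
        if defined.any():
            padj[defined] = bh_adjust(p_arr[defined])
        passed = defined & (r_arr > cfg.coexpr_r) & (padj < cfg.coexpr_padj)
        pass_by_tf[tf] = passed
        for i, gid in enumerate(candidates):
            rows.append(
                {
                    "gene_id": gid,
                    "tf": tf,
                    "r": r_arr[i],
                    "p": p_arr[i],
                    "padj": padj[i],
                    "undefined": not defined[i],
                    "pass": bool(passed[i]),
                }
            )
    audit = pd.DataFrame(rows)
    all_pass = np.logical_and.reduce([pass_by_tf[tf] for tf in tf_ids]) if tf_ids else \
        np.zeros(len(candidates), dtype=bool)
    kept = [g for g, ok in zip(candidates, all_pass) if ok]
    return kept, audit


def run_funnel(
    soes: IntervalSet,
    cluster_peaks: IntervalSet,
    genes: list[GeneAnnotation],
    expr: ExpressionMatrix,
    design: PairedDesign,
    cluster_de,
    tf_ids: list[str],
    cfg: ThresholdConfig | None = None,
    biotype_filter: str | None = "protein_coding",
    cluster_kwargs: dict | None = None,
) -> FunnelResult:
    """Run the four-stage funnel and return survivors plus an audit table."""
    cfg = cfg or ThresholdConfig()
    try:
        loci = celltype_overlap_stage(soes, cluster_peaks)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage celltype_overlap failed: {exc}") from exc
    links = link_genes_within(loci, genes, cfg.link_window_bp, biotype_filter)
    stage2 = sorted({g for ids in links.values() for g in ids})

    measured = set(expr.gene_ids)
    bulk_pass = set(bulk_de_filter(expr, design, cfg)) if stage2 else set()
    cluster_pass = (
        set(cluster_de_filter(cluster_de, cfg, **(cluster_kwargs or {})))
        if stage2
        else set()
    )
    stage3 = [g for g in stage2 if g in bulk_pass and g in cluster_pass]
    # the master TFs anchor the co-expression test; they are not candidate
    # targets themselves (self-correlation is trivially 1)
    coexpr_pool = [g for g in stage3 if g not in set(tf_ids)]
    stage4, coexpr_audit = (
        coexpression_filter(
            expr, tf_ids, coexpr_pool, cfg, sample_ids=design.tumor_samples()
        )
        if coexpr_pool
        else ([], pd.DataFrame(columns=["gene_id", "tf", "r", "p", "padj", "undefined", "pass"]))
    )

    r_by_gene = (
        coexpr_audit.pivot_table(index="gene_id", columns="tf", values="r")
        if len(coexpr_audit)
        else pd.DataFrame()
    )
    audit_rows = []
    for g in stage2:
        row = {
            "gene_id": g,
            "measured": g in measured,
            "bulk_de_pass": g in bulk_pass,
            "cluster_de_pass": g in cluster_pass,
            "coexpr_pass": g in stage4,
        }
        for tf in tf_ids:
            row[f"r_{tf}"] = (
                float(r_by_gene.loc[g, tf])
                if g in r_by_gene.index and tf in r_by_gene.columns
                else np.nan
            )
        audit_rows.append(row)
    audit = pd.DataFrame(audit_rows)

    return FunnelResult(
        stage0_soe_count=len(soes),
        stage1_loci=loci,
        stage2_genes=stage2,
        stage3_genes=stage3,
        stage4_candidates=sorted(stage4),
        audit=audit,
        metadata={
            "link_window_bp": cfg.link_window_bp,
            "link_mode": cfg.link_mode,
            "biotype_filter": biotype_filter,
            "cluster_log2fc": cfg.cluster_log2fc,
            "cluster_adjust": cfg.cluster_adjust,
            "coexpr_r": cfg.coexpr_r,
            "coexpr_padj": cfg.coexpr_padj,
            "coexpr_samples": "tumor",
            "tf_ids": list(tf_ids),
        },
    )
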