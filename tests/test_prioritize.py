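"""The four-stage candidate funnel: overlap, linking, dual DE, co-expression."""

import numpy as np
import pandas as pd
import pytest

from oncoenh.differential import PairedDesign, ThresholdConfig
from oncoenh.intervals import IntervalSet
from oncoenh.prioritize import (
    ExpressionMatrix,
    bulk_de_filter,
    celltype_overlap_stage,
    cluster_de_filter,
    cluster_de_from_matrix,
    coexpression_filter,
    run_funnel,
)

from conftest import base_union, random_intervals


def iv(*rows):
    return IntervalSet([("chr1", s, e) for s, e in rows])


class TestOverlapStage:
    def test_empty_soes(self):
        assert len(celltype_overlap_stage(iv(), iv((0, 10)))) == 0

    def test_single_base_overlap_kept_unclipped(self):
        out = celltype_overlap_stage(iv((100, 200)), iv((150, 250)))
        assert [(x.start, x.end) for x in out] == [(100, 200)]

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            soe_rows = random_intervals(rng, 40, 10_000)
            peak_rows = random_intervals(rng, 40, 10_000)
            occ = base_union(peak_rows, 10_000)
            out = celltype_overlap_stage(iv(*soe_rows), iv(*peak_rows))
            expected = sorted(
                (s, e) for s, e in soe_rows if occ[s:e].any()
            )
            assert sorted((x.start, x.end) for x in out) == expected


def paired_expr(n_pairs=8, genes=("up", "flat"), folds=(4.0, 1.0), seed=0):
    rng = np.random.default_rng(seed)
    base = rng.uniform(5, 10, size=(len(genes), n_pairs))
    values = np.hstack([base * np.asarray(folds)[:, None], base])
    samples = [f"T{j}" for j in range(n_pairs)] + [f"N{j}" for j in range(n_pairs)]
    design = PairedDesign({f"P{j}": (f"T{j}", f"N{j}") for j in range(n_pairs)})
    return ExpressionMatrix(list(genes), samples, values), design


class TestBulkDE:
    def test_upregulated_gene_passes_flat_fails(self):
        expr, design = paired_expr()
        assert bulk_de_filter(expr, design) == ["up"]

    def test_exact_twofold_fails_strict_threshold(self):
        expr, design = paired_expr(genes=("edge",), folds=(2.0,))
        # group-mean log2fc == 1.0 exactly: strict > excludes it
        assert bulk_de_filter(expr, design) == []

    def test_all_zero_gene_fails_with_p_one(self):
        expr, design = paired_expr(genes=("zero",), folds=(1.0,))
        expr.values[:] = 0.0
        assert bulk_de_filter(expr, design) == []


class TestClusterDE:
    @staticmethod
    def cells(seed=0, n=60):
        rng = np.random.default_rng(seed)
        idx = [f"c{i}" for i in range(3 * n)]
        labels = pd.Series(["squamous"] * n + ["immune"] * n + ["stromal"] * n,
                           index=idx)
        marker = np.concatenate([rng.uniform(20, 40, n), rng.uniform(1, 3, 2 * n)])
        uniform = rng.uniform(5, 10, 3 * n)
        df = pd.DataFrame({"marker": marker, "uniform": uniform}, index=idx)
        return df, labels

    def test_cluster_specific_gene_passes(self):
        df, labels = self.cells()
        kept = cluster_de_filter(df, labels=labels, target_cluster="squamous")
        assert kept == ["marker"]

    def test_unknown_cluster_rejected(self):
        df, labels = self.cells()
        with pytest.raises(ValueError, match="basal"):
            cluster_de_filter(df, labels=labels, target_cluster="basal")

    def test_matrix_route_matches_independent_recomputation(self):
        from scipy.stats import mannwhitneyu

        df, labels = self.cells(seed=4, n=40)
        de = cluster_de_from_matrix(df, labels, "squamous")
        in_mask = (labels == "squamous").to_numpy()
        for _, row in de.table.iterrows():
            ref = mannwhitneyu(
                df[row.gene_id].to_numpy()[in_mask],
                df[row.gene_id].to_numpy()[~in_mask],
                alternative="two-sided", method="asymptotic",
            )
            assert row.p == pytest.approx(ref.pvalue, rel=1e-9)
            assert row.p_adjusted == pytest.approx(min(1.0, ref.pvalue * 2), rel=1e-9)

    def test_alternative_marker_threshold(self):
        df, labels = self.cells(seed=5)
        df["mild"] = np.concatenate([
            np.random.default_rng(6).uniform(9, 11, 60),
            np.random.default_rng(7).uniform(5, 7, 120),
        ])
        cfg = ThresholdConfig(cluster_log2fc=0.25)
        kept = cluster_de_filter(df, cfg, labels=labels, target_cluster="squamous")
        assert "mild" in kept  # log2fc ~0.7 passes the marker-style 0.25 cut


class TestCoexpression:
    @staticmethod
    def expr_with_tfs(seed=0, n=20):
        rng = np.random.default_rng(seed)
        tf = rng.uniform(1, 10, n)
        rows = {f"TF{k}": tf for k in range(4)}
        rows["same"] = tf.copy()
        rows["anti"] = tf.max() + 1 - tf
        rows["noise"] = rng.uniform(1, 10, n)
        rows["const"] = np.full(n, 3.0)
        gene_ids = list(rows)
        return ExpressionMatrix(
            gene_ids, [f"T{j}" for j in range(n)], np.vstack(list(rows.values()))
        )

    def test_identical_vector_kept_anticorrelated_excluded(self):
        expr = self.expr_with_tfs()
        tfs = ["TF0", "TF1", "TF2", "TF3"]
        kept, audit = coexpression_filter(expr, tfs, ["same", "anti", "noise"])
        assert kept == ["same"]
        anti_r = audit[audit.gene_id == "anti"]["r"]
        assert np.allclose(anti_r, -1.0)

    def test_zero_variance_candidate_flagged_not_raised(self):
        expr = self.expr_with_tfs()
        kept, audit = coexpression_filter(expr, ["TF0"], ["const"])
        assert kept == []
        assert audit.loc[audit.gene_id == "const", "undefined"].all()

    def test_missing_tf_rejected(self):
        expr = self.expr_with_tfs()
        with pytest.raises(KeyError):
            coexpression_filter(expr, ["ABSENT"], ["same"])


class TestFunnel:
    def test_all_empty_inputs_give_zero_counts(self):
        expr, design = paired_expr()
        result = run_funnel(
            soes=iv(), cluster_peaks=iv(), genes=[], expr=expr, design=design,
            cluster_de=pd.DataFrame({"x": []}, index=pd.Index([], name="cell")),
            tf_ids=[],
            cluster_kwargs={"labels": pd.Series(dtype=object), "target_cluster": "sq"},
        )
        assert all(v == 0 for v in result.stage_counts.values())

    def test_recovers_planted_oncogene_only(self, default_cohort):
        cohort, truth = default_cohort
        soe_names = set(truth.planted_soe_ids)
        mask = np.array([str(n) in soe_names for n in cohort.regions.names])
        soes = cohort.regions.subset(mask)
        result = run_funnel(
            soes=soes, cluster_peaks=cohort.cluster_peaks, genes=cohort.genes,
            expr=cohort.expression, design=cohort.design_rna,
            cluster_de=cohort.cluster_cells,
            tf_ids=["TP63", "SOX2", "GRHL2", "KLF5"],
            cluster_kwargs={"labels": cohort.cluster_labels,
                            "target_cluster": "squamous"},
        )
        assert result.stage4_candidates == [truth.oncogene_id]
        # nested gene sets
        assert set(result.stage4_candidates) <= set(result.stage3_genes)
        assert set(result.stage3_genes) <= set(result.stage2_genes)

    def test_each_decoy_fails_exactly_its_stage(self, default_cohort):
        cohort, truth = default_cohort
        soe_names = set(truth.planted_soe_ids)
        mask = np.array([str(n) in soe_names for n in cohort.regions.names])
        result = run_funnel(
            soes=cohort.regions.subset(mask), cluster_peaks=cohort.cluster_peaks,
            genes=cohort.genes, expr=cohort.expression, design=cohort.design_rna,
            cluster_de=cohort.cluster_cells,
            tf_ids=["TP63", "SOX2", "GRHL2", "KLF5"],
            cluster_kwargs={"labels": cohort.cluster_labels,
                            "target_cluster": "squamous"},
        )
        expected = {
            "gene_decoy_overlap": "overlap_linking",
            "gene_decoy_bulk": "bulk_de",
            "gene_decoy_cluster": "cluster_de",
            "gene_decoy_coexpr": "coexpression",
        }
        for gene, stage in expected.items():
            assert result.failing_stage(gene) == stage, gene
        assert result.failing_stage(truth.oncogene_id) is None

    def test_ablating_cluster_peak_overlap_removes_candidate(self, default_cohort):
        cohort, truth = default_cohort
        onco_region = truth.special_gene_regions[truth.oncogene_id]
        soe_names = set(truth.planted_soe_ids)
        mask = np.array([str(n) in soe_names for n in cohort.regions.names])
        soes = cohort.regions.subset(mask)
        region_iv = {
            str(cohort.regions.names[i]): cohort.regions.interval(i)
            for i in range(len(cohort.regions))
        }[onco_region]
        # drop cluster peaks overlapping the oncogene's enhancer
        keep = np.array([
            not (x.start < region_iv.end and region_iv.start < x.end)
            for x in cohort.cluster_peaks
        ])
        result = run_funnel(
            soes=soes, cluster_peaks=cohort.cluster_peaks.subset(keep),
            genes=cohort.genes, expr=cohort.expression, design=cohort.design_rna,
            cluster_de=cohort.cluster_cells,
            tf_ids=["TP63", "SOX2", "GRHL2", "KLF5"],
            cluster_kwargs={"labels": cohort.cluster_labels,
                            "target_cluster": "squamous"},
        )
        assert result.stage4_candidates == []

    def test_relaxed_thresholds_collapse_stage3_to_stage2(self, default_cohort):
        cohort, truth = default_cohort
        soe_names = set(truth.planted_soe_ids)
        mask = np.array([str(n) in soe_names for n in cohort.regions.names])
        cfg = ThresholdConfig(deg_log2fc=0.0, deg_padj=1 - 1e-9,
                              cluster_log2fc=0.0, coexpr_r=0.0,
                              coexpr_padj=1 - 1e-9)
        # thresholds relaxed to the 0/1 extremes: DE filters pass every
        # measured gene with log2fc > 0, so only direction and definedness bind
        result = run_funnel(
            soes=cohort.regions.subset(mask), cluster_peaks=cohort.cluster_peaks,
            genes=cohort.genes, expr=cohort.expression, design=cohort.design_rna,
            cluster_de=cohort.cluster_cells, cfg=cfg,
            tf_ids=["TP63", "SOX2", "GRHL2", "KLF5"],
            cluster_kwargs={"labels": cohort.cluster_labels,
                            "target_cluster": "squamous"},
        )
        assert set(result.stage3_genes) <= set(result.stage2_genes)
        assert set(result.stage4_candidates) <= set(result.stage3_genes)

    def test_permutation_invariance_of_expression_rows(self, default_cohort):
        cohort, truth = default_cohort
        soe_names = set(truth.planted_soe_ids)
        mask = np.array([str(n) in soe_names for n in cohort.regions.names])
        rng = np.random.default_rng(13)
        perm = rng.permutation(len(cohort.expression.gene_ids))
        shuffled = ExpressionMatrix(
            gene_ids=[cohort.expression.gene_ids[i] for i in perm],
            sample_ids=cohort.expression.sample_ids,
            values=cohort.expression.values[perm],
        )
        kwargs = dict(
            soes=cohort.regions.subset(mask), cluster_peaks=cohort.cluster_peaks,
            genes=cohort.genes, design=cohort.design_rna,
            cluster_de=cohort.cluster_cells,
            tf_ids=["TP63", "SOX2", "GRHL2", "KLF5"],
            cluster_kwargs={"labels": cohort.cluster_labels,
                            "target_cluster": "squamous"},
        )
        a = run_funnel(expr=cohort.expression, **kwargs)
        b = run_funnel(expr=shuffled, **kwargs)
        assert a.stage4_candidates == b.stage4_candidates
        assert a.stage3_genes == b.stage3_genes
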