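"""Synthetic paired tumor/normal cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a paired patient design (a shared lognormal patient factor multiplies the
  tumor and normal signal of the same patient — the structure that makes the
  paired test the right analysis);
* per-sample stochastic peak detection of a fixed true-region grid, with
  boundary jitter, for both histone marks;
* negative-binomial read counts whose tumor means carry planted log2
  fold-changes for the cancer-gained (SOE) and cancer-depleted (CDE)
  region classes;
* a bulk expression matrix in which four "master TF" vectors and designated
  target genes share a latent per-tumor activity (pairwise correlation set
  by ``tf_target_corr``), normal samples carrying independent noise;
* cluster-specific accessibility peaks overlapping a subset of planted SOEs;
* a cells x genes matrix with cluster labels in which designated genes are
  upregulated in the target ("squamous") cluster.

One planted oncogene satisfies all four funnel criteria; four decoy genes
each violate exactly one (no SOE/cluster-peak overlap near the gene, not
bulk-upregulated, not cluster-upregulated, not TF-co-expressed), so the
funnel audit can be tested exhaustively.  A truth manifest records every
planted identity.

The ChIP cohort (``n_patients`` pairs, default 18) is a subset of a larger
expression cohort (``n_rna_pairs`` pairs, default 59), mirroring the typical
situation where histone-mark profiling covers fewer patients than RNA-seq.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import SamplePeaks
from .differential import CountMatrix, PairedDesign
from .intervals import GeneAnnotation, IntervalSet, write_bed
from .prioritize import ExpressionMatrix

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticCohort", "simulate_cohort", "write_fixtures"]

TF_NAMES = ["TP63", "SOX2", "GRHL2", "KLF5"]
DECOY_KINDS = ["no_overlap", "not_bulk_de", "not_cluster_de", "not_coexpressed"]


@dataclass
class SimConfig:
    """Cohort-generator settings (defaults are the study conditions)."""

    seed: int = 0
    n_patients: int = 18          # matched ChIP-seq pairs
    n_rna_pairs: int = 59         # matched expression pairs (superset cohort)
    n_regions: int = 500
    frac_soe: float = 0.10
    frac_cde: float = 0.10
    frac_tss_inside: float = 0.05  # stable regions planted inside the TSS exclusion zone
    soe_log2fc_mean: float = 1.5
    soe_log2fc_sd: float = 0.3
    nb_dispersion: float = 10.0   # NB size parameter; var = mu + mu^2/size
    detection_prob: float = 0.9
    peak_jitter_bp: int = 50
    noise_peaks: int = 3          # spurious peaks per sample per mark
    chrom: str = "chr1"
    genome_length: int = 10_000_000
    n_genes: int = 300
    n_cells_per_cluster: int = 100
    tf_target_corr: float = 0.8
    library_size_log10_mean: float = math.log10(2e7)
    library_size_log10_sd: float = 0.1
    patient_effect_sd: float = 0.3     # lognormal sigma of the shared patient factor
    baseline_log2_rpkm_mean: float = 3.0
    baseline_log2_rpkm_sd: float = 1.0
    cluster_peak_frac: float = 0.4     # fraction of eligible SOEs given a cluster peak

    def __post_init__(self) -> None:
        if self.frac_soe + self.frac_cde + self.frac_tss_inside > 1:
            raise ValueError("region class fractions must sum to <= 1")
        for name in ("detection_prob", "frac_soe", "frac_cde", "frac_tss_inside",
                     "tf_target_corr", "cluster_peak_frac"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_rna_pairs < self.n_patients:
            raise ValueError("n_rna_pairs must be >= n_patients")


@dataclass
class SyntheticTruth:
    """Ground-truth manifest for a simulated cohort."""

    planted_soe_ids: list[str]
    planted_cde_ids: list[str]
    stable_ids: list[str]
    tss_excluded_ids: list[str]
    oncogene_id: str
    decoy_ids: dict[str, str]  # gene_id -> violated criterion
    true_log2fc: dict[str, float]
    cluster_peak_soe_ids: list[str]
    special_gene_regions: dict[str, str]  # gene_id -> region_id

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    """In-memory cohort: everything the pipeline consumes."""

    config: SimConfig
    regions: IntervalSet              # true region grid, named region_####
    samples: list[SamplePeaks]        # ChIP peak sets, tumor + normal
    counts: CountMatrix
    design_chip: PairedDesign
    design_rna: PairedDesign
    genes: list[GeneAnnotation]
    expression: ExpressionMatrix
    cluster_peaks: IntervalSet
    cluster_cells: pd.DataFrame       # cells x genes
    cluster_labels: pd.Series         # cell -> cluster
    target_cluster: str = "squamous"

    @property
    def tss_points(self) -> dict[str, np.ndarray]:
        pts: dict[str, list[int]] = {}
        for g in self.genes:
            pts.setdefault(g.chrom, []).append(g.tss)
        return {c: np.sort(np.asarray(v)) for c, v in pts.items()}


def _special_indices(n_regions: int) -> dict[str, int]:
    """Deterministic slots for the oncogene SOE and the four decoy SOEs."""
    fracs = {
        "oncogene": 0.10,
        "not_bulk_de": 0.20,
        "not_cluster_de": 0.30,
        "not_coexpressed": 0.40,
        "no_overlap": 0.80,
    }
    idx = {k: int(round(f * n_regions)) for k, f in fracs.items()}
    if len(set(idx.values())) < len(idx) or max(idx.values()) >= n_regions - 1:
        raise ValueError("n_regions too small to place planted funnel genes")
    return idx


def simulate_cohort(cfg: SimConfig) -> tuple[SyntheticCohort, SyntheticTruth]:
    """Generate a full synthetic cohort and its ground-truth manifest.

    Identical configs (including seed) produce identical cohorts.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_regions
    spacing = cfg.genome_length // n
    if spacing < 4 * 2500:
        raise ValueError("genome too small for the region grid and TSS exclusion bands")

    # -- region grid -------------------------------------------------------
    lengths = rng.integers(800, 1201, size=n)
    starts = np.arange(n) * spacing + (spacing // 2 - lengths // 2)
    ends = starts + lengths
    region_ids = [f"region_{i:04d}" for i in range(n)]
    regions = IntervalSet(
        [(cfg.chrom, int(s), int(e)) for s, e in zip(starts, ends)], names=region_ids
    )

    # inter-region bands where a TSS can sit without excluding any region
    margin = 2500 + cfg.peak_jitter_bp + 150
    band_lo = ends[:-1] + margin
    band_hi = starts[1:] - margin
    if np.any(band_hi <= band_lo):
        raise ValueError("infeasible geometry: no TSS band between regions")

    def tss_in_band(i: int) -> int:
        return int(rng.integers(band_lo[i], band_hi[i]))

    # -- region classes ----------------------------------------------------
    special = _special_indices(n)
    zone_radius = int(math.ceil(200_000 / spacing)) + 1
    # two isolation zones: around the no-overlap decoy (its gene must have NO
    # cluster-accessible locus in linking range) and around the oncogene (so
    # ablating its enhancer's cluster-peak overlap unlinks the gene entirely)
    no_ovl_idx = special["no_overlap"]
    onco_idx = special["oncogene"]
    exclusion_zone = set(range(no_ovl_idx - zone_radius, no_ovl_idx + zone_radius + 1))
    exclusion_zone |= set(range(onco_idx - zone_radius, onco_idx + zone_radius + 1))

    n_soe = int(round(cfg.frac_soe * n))
    n_cde = int(round(cfg.frac_cde * n))
    n_viol = int(round(cfg.frac_tss_inside * n))
    if n_soe:
        # the oncogene/decoy slots are always cancer-gained when any are planted
        forced_soe = sorted(special.values())
        pool = [i for i in range(n) if i not in special.values()]
    else:
        forced_soe = []
        pool = list(range(n))
    rng.shuffle(pool)
    extra_soe = max(0, n_soe - len(forced_soe))
    soe_idx = sorted(forced_soe + pool[:extra_soe])
    rest = pool[extra_soe:]
    cde_idx = sorted(rest[:n_cde])
    rest = rest[n_cde:]
    viol_idx = sorted(rest[:n_viol])
    stable_idx = sorted(rest[n_viol:])

    true_lfc = np.zeros(n)
    if soe_idx:
        true_lfc[soe_idx] = rng.normal(cfg.soe_log2fc_mean, cfg.soe_log2fc_sd, len(soe_idx))
    if cde_idx:
        true_lfc[cde_idx] = -rng.normal(cfg.soe_log2fc_mean, cfg.soe_log2fc_sd, len(cde_idx))

    # -- designs and samples ----------------------------------------------
    rna_patients = [f"P{i + 1:03d}" for i in range(cfg.n_rna_pairs)]
    design_rna = PairedDesign(
        {p: (f"T{i + 1:03d}", f"N{i + 1:03d}") for i, p in enumerate(rna_patients)}
    )
    chip_patients = rna_patients[: cfg.n_patients]
    design_chip = design_rna.subset(chip_patients)
    chip_samples = design_chip.tumor_samples() + design_chip.normal_samples()

    # -- ChIP peaks --------------------------------------------------------
    j = cfg.peak_jitter_bp
    samples: list[SamplePeaks] = []
    for pi, pid in enumerate(chip_patients):
        for group, sid in zip(("tumor", "normal"), design_chip.pairs[pid]):
            marks = {}
            for mark in ("k4me1", "k27ac"):
                detected = rng.random(n) < cfg.detection_prob
                s_jit = starts + (rng.integers(-j, j + 1, size=n) if j else 0)
                e_jit = ends + (rng.integers(-j, j + 1, size=n) if j else 0)
                s_jit = np.maximum(s_jit, 0)
                e_jit = np.maximum(e_jit, s_jit + 1)
                rows = [
                    (cfg.chrom, int(s), int(e))
                    for s, e in zip(s_jit[detected], e_jit[detected])
                ]
                for _ in range(cfg.noise_peaks):
                    b = int(rng.integers(0, n - 1))
                    ns = int(rng.integers(band_lo[b], band_hi[b] - 300))
                    rows.append((cfg.chrom, ns, ns + int(rng.integers(200, 301))))
                marks[mark] = IntervalSet(rows)
            samples.append(
                SamplePeaks(sample_id=sid, group=group, patient_id=pid,
                            k4me1=marks["k4me1"], k27ac=marks["k27ac"])
            )

    # -- counts ------------------------------------------------------------
    lib = np.power(
        10.0,
        rng.normal(cfg.library_size_log10_mean, cfg.library_size_log10_sd, len(chip_samples)),
    ).round().astype(np.int64)
    baseline = np.power(2.0, rng.normal(cfg.baseline_log2_rpkm_mean,
                                        cfg.baseline_log2_rpkm_sd, n))
    patient_factor = np.exp(rng.normal(0.0, cfg.patient_effect_sd, cfg.n_patients))
    counts = np.zeros((n, len(chip_samples)), dtype=np.int64)
    for si, sid in enumerate(chip_samples):
        pi = si % cfg.n_patients
        is_tumor = si < cfg.n_patients
        mu = (
            baseline
            * patient_factor[pi]
            * np.power(2.0, true_lfc if is_tumor else 0.0)
            * (lengths / 1e3)
            * (lib[si] / 1e6)
        )
        size = cfg.nb_dispersion
        counts[:, si] = rng.negative_binomial(size, size / (size + mu))
    count_matrix = CountMatrix(
        region_ids=region_ids,
        sample_ids=list(chip_samples),
        counts=counts,
        region_lengths=lengths.astype(float),
        library_sizes=lib.astype(float),
    )

    # -- genes -------------------------------------------------------------
    genes: list[GeneAnnotation] = []
    gene_roles: dict[str, str] = {}

    def add_gene(gid: str, band: int, role: str, biotype: str = "protein_coding") -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(gid, gid, cfg.chrom, strand, tss_in_band(band), biotype))
        gene_roles[gid] = role

    for tf in TF_NAMES:
        add_gene(tf, int(rng.integers(0, n - 1)), "tf")
    add_gene("gene_onco", special["oncogene"], "oncogene")
    add_gene("gene_decoy_overlap", special["no_overlap"], "decoy:no_overlap")
    add_gene("gene_decoy_bulk", special["not_bulk_de"], "decoy:not_bulk_de")
    add_gene("gene_decoy_cluster", special["not_cluster_de"], "decoy:not_cluster_de")
    add_gene("gene_decoy_coexpr", special["not_coexpressed"], "decoy:not_coexpressed")
    for k, ridx in enumerate(viol_idx):
        # promoter-proximal gene planted inside the region: exercises the TSS filter
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_prox_{k:03d}"
        genes.append(GeneAnnotation(
            gid, gid, cfg.chrom, strand,
            int((starts[ridx] + ends[ridx]) // 2), "protein_coding"))
        gene_roles[gid] = "promoter_proximal"
    n_up_bg = 20
    for k in range(n_up_bg):
        add_gene(f"gene_up_{k:03d}", int(rng.integers(0, n - 1)), "bulk_up_background")
    n_marker = 15
    for k in range(n_marker):
        add_gene(f"gene_sq_{k:03d}", int(rng.integers(0, n - 1)), "squamous_marker")
    n_null = cfg.n_genes - len(genes)
    if n_null < 0:
        raise ValueError("n_genes too small for the planted gene roles")
    for k in range(n_null):
        biotype = "lincRNA" if rng.random() < 0.1 else "protein_coding"
        add_gene(f"gene_null_{k:03d}", int(rng.integers(0, n - 1)), "null", biotype)

    # -- bulk expression ---------------------------------------------------
    gene_ids = [g.gene_id for g in genes]
    expr_samples = design_rna.tumor_samples() + design_rna.normal_samples()
    n_rna = cfg.n_rna_pairs
    rho = cfg.tf_target_corr
    latent = rng.normal(0.0, 1.0, n_rna)  # per-tumor squamous activity
    coexpr_genes = {
        "gene_onco", "gene_decoy_overlap", "gene_decoy_bulk", "gene_decoy_cluster",
        *TF_NAMES,
    }
    tumor_up = {
        "gene_onco", "gene_decoy_overlap", "gene_decoy_cluster", "gene_decoy_coexpr",
        *TF_NAMES,
        *(g for g, r in gene_roles.items() if r == "bulk_up_background"),
    }
    base = rng.normal(4.0, 1.0, len(genes))
    log2expr = np.empty((len(genes), 2 * n_rna))
    for gi, gid in enumerate(gene_ids):
        delta = 2.0 if gid in tumor_up else 0.0
        if gid in coexpr_genes:
            tum = base[gi] + delta + math.sqrt(rho) * latent \
                + math.sqrt(1 - rho) * rng.normal(0, 1, n_rna)
        else:
            tum = base[gi] + delta + rng.normal(0, 1, n_rna)
        nor = base[gi] + rng.normal(0, 1, n_rna)
        log2expr[gi, :n_rna] = tum
        log2expr[gi, n_rna:] = nor
    expression = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=list(expr_samples),
        values=np.power(2.0, log2expr),
    )

    # -- cluster-specific accessibility peaks ------------------------------
    forced_peak_idx = {
        special["oncogene"], special["not_bulk_de"],
        special["not_cluster_de"], special["not_coexpressed"],
    }
    eligible = [i for i in soe_idx if i not in exclusion_zone and i not in forced_peak_idx]
    chosen = sorted(forced_peak_idx | {
        i for i in eligible if rng.random() < cfg.cluster_peak_frac
    }) if soe_idx else []
    peak_rows = []
    for i in chosen:
        js, je = int(rng.integers(-100, 101)), int(rng.integers(-100, 101))
        peak_rows.append((cfg.chrom, max(0, int(starts[i]) + js), int(ends[i]) + je))
    for _ in range(10):  # background accessible sites away from the decoy zone
        b = int(rng.integers(0, n - 1))
        if b in exclusion_zone:
            continue
        ps = int(rng.integers(band_lo[b], band_hi[b] - 400))
        peak_rows.append((cfg.chrom, ps, ps + int(rng.integers(300, 401))))
    cluster_peaks = IntervalSet(peak_rows)

    # -- cluster cell matrix ----------------------------------------------
    clusters = ["squamous", "immune", "stromal"]
    ncell = cfg.n_cells_per_cluster
    cell_ids = [f"{c[:2]}_{k:04d}" for c in clusters for k in range(ncell)]
    labels = pd.Series(
        [c for c in clusters for _ in range(ncell)], index=cell_ids, name="cluster"
    )
    cluster_up = {
        "gene_onco", "gene_decoy_overlap", "gene_decoy_bulk", "gene_decoy_coexpr",
        *TF_NAMES,
        *(g for g, r in gene_roles.items() if r == "squamous_marker"),
    }
    cell_base = rng.normal(2.0, 1.0, len(genes))
    cell_log2 = np.empty((len(cell_ids), len(genes)))
    for gi, gid in enumerate(gene_ids):
        mean = np.full(len(cell_ids), cell_base[gi])
        if gid in cluster_up:
            mean[:ncell] += 2.5  # squamous cells first
        cell_log2[:, gi] = mean + rng.normal(0, 1, len(cell_ids))
    cluster_cells = pd.DataFrame(
        np.power(2.0, cell_log2), index=cell_ids, columns=gene_ids
    )

    truth = SyntheticTruth(
        planted_soe_ids=[region_ids[i] for i in soe_idx],
        planted_cde_ids=[region_ids[i] for i in cde_idx],
        stable_ids=[region_ids[i] for i in stable_idx],
        tss_excluded_ids=[region_ids[i] for i in viol_idx],
        oncogene_id="gene_onco",
        decoy_ids={
            "gene_decoy_overlap": "no_overlap",
            "gene_decoy_bulk": "not_bulk_de",
            "gene_decoy_cluster": "not_cluster_de",
            "gene_decoy_coexpr": "not_coexpressed",
        },
        true_log2fc={region_ids[i]: float(true_lfc[i]) for i in range(n)},
        cluster_peak_soe_ids=[region_ids[i] for i in chosen],
        special_gene_regions={
            "gene_onco": region_ids[special["oncogene"]],
            "gene_decoy_overlap": region_ids[special["no_overlap"]],
            "gene_decoy_bulk": region_ids[special["not_bulk_de"]],
            "gene_decoy_cluster": region_ids[special["not_cluster_de"]],
            "gene_decoy_coexpr": region_ids[special["not_coexpressed"]],
        },
    )
    cohort = SyntheticCohort(
        config=cfg,
        regions=regions,
        samples=samples,
        counts=count_matrix,
        design_chip=design_chip,
        design_rna=design_rna,
        genes=genes,
        expression=expression,
        cluster_peaks=cluster_peaks,
        cluster_cells=cluster_cells,
        cluster_labels=labels,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, float_cols: tuple[str, ...] = ()) -> None:
    df = df.copy()
    for c in float_cols:
        df[c] = df[c].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_fixtures(cohort: SyntheticCohort, truth: SyntheticTruth, out_dir) -> dict:
    """Write the cohort to disk in the exact formats the pipeline reads.

    Emits one BED per sample per mark, the count/length/library-size TSVs,
    both designs, the gene table, the expression and cluster-cell matrices,
    the cluster-peak and region BEDs, the truth JSON and a manifest.  Output
    is byte-identical for identical cohorts (counts as integers, reals at
    fixed 6-decimal formatting, LF newlines).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)

    manifest: dict = {"samples": [], "tables": {}, "n_patients": cohort.config.n_patients}
    for sp in cohort.samples:
        entry = {"sample_id": sp.sample_id, "patient_id": sp.patient_id, "group": sp.group}
        for mark in ("k4me1", "k27ac"):
            rel = f"peaks/{sp.sample_id}_{mark}.bed"
            write_bed(getattr(sp, mark), out / rel)
            entry[f"{mark}_path"] = rel
        manifest["samples"].append(entry)
    samples_df = pd.DataFrame(manifest["samples"])[
        ["sample_id", "patient_id", "group", "k4me1_path", "k27ac_path"]
    ]
    _write_tsv(samples_df, out / "samples.tsv")
    manifest["tables"]["samples"] = "samples.tsv"

    cm = cohort.counts
    counts_df = pd.DataFrame(cm.counts, index=cm.region_ids, columns=cm.sample_ids)
    counts_df.index.name = "region_id"
    counts_df.to_csv(out / "counts.tsv", sep="\t", lineterminator="\n")
    _write_tsv(
        pd.DataFrame({"region_id": cm.region_ids,
                      "length": cm.region_lengths.astype(int)}),
        out / "region_lengths.tsv",
    )
    _write_tsv(
        pd.DataFrame({"sample_id": cm.sample_ids,
                      "library_size": cm.library_sizes.astype(int)}),
        out / "library_sizes.tsv",
    )
    for name, design in (("design_chip", cohort.design_chip), ("design_rna", cohort.design_rna)):
        _write_tsv(
            pd.DataFrame(
                [(p, t, nn) for p, (t, nn) in design.pairs.items()],
                columns=["patient_id", "tumor_sample", "normal_sample"],
            ),
            out / f"{name}.tsv",
        )
    _write_tsv(
        pd.DataFrame(
            [(g.gene_id, g.gene_name, g.chrom, g.strand, g.tss, g.biotype)
             for g in cohort.genes],
            columns=["gene_id", "gene_name", "chrom", "strand", "tss", "biotype"],
        ),
        out / "genes.tsv",
    )
    expr_df = pd.DataFrame(
        cohort.expression.values,
        index=cohort.expression.gene_ids,
        columns=cohort.expression.sample_ids,
    )
    expr_df.index.name = "gene_id"
    expr_df.to_csv(out / "expression.tsv", sep="\t",
                   float_format="%.6f", lineterminator="\n")
    cells_df = cohort.cluster_cells.copy()
    cells_df.insert(0, "cluster", cohort.cluster_labels)
    cells_df.index.name = "cell_id"
    cells_df.to_csv(out / "cluster_cells.tsv", sep="\t",
                    float_format="%.6f", lineterminator="\n")
    write_bed(cohort.cluster_peaks, out / "cluster_peaks.bed")
    write_bed(cohort.regions, out / "regions.bed")
    (out / "truth.json").write_text(truth.to_json() + "\n")

    manifest["tables"].update(
        counts="counts.tsv", region_lengths="region_lengths.tsv",
        library_sizes="library_sizes.tsv", design_chip="design_chip.tsv",
        design_rna="design_rna.tsv", genes="genes.tsv",
        expression="expression.tsv", cluster_cells="cluster_cells.tsv",
    )
    manifest["beds"] = {"cluster_peaks": "cluster_peaks.bed", "regions": "regions.bed"}
    manifest["truth"] = "truth.json"
    manifest["target_cluster"] = cohort.target_cluster
    manifest["tf_ids"] = TF_NAMES
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
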