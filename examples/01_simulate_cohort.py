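"""Generate a synthetic paired tumor/normal cohort and inspect its truth.

The generator plants cancer-gained (SOE) and cancer-depleted (CDE) enhancer
regions with log2 fold-changes ~ N(1.5, 0.3), a shared per-patient factor
that makes the design genuinely paired, and one oncogene plus four decoy
genes wired into the downstream prioritisation funnel.
"""

from oncoenh import SimConfig, simulate_cohort, write_fixtures

cohort, truth = simulate_cohort(SimConfig(seed=42))

print(f"patients (ChIP pairs):   {cohort.config.n_patients}")
print(f"patients (RNA pairs):    {cohort.config.n_rna_pairs}")
print(f"regions on the grid:     {len(cohort.regions)}")
print(f"planted SOEs:            {len(truth.planted_soe_ids)}")
print(f"planted CDEs:            {len(truth.planted_cde_ids)}")
print(f"TSS-proximal (excluded): {len(truth.tss_excluded_ids)}")
print(f"planted oncogene:        {truth.oncogene_id}")
print(f"decoys:                  {truth.decoy_ids}")

# write_fixtures emits the exact plain-text layout the pipeline consumes
manifest = write_fixtures(cohort, truth, "scratch/example_cohort")
print(f"\nwrote {len(manifest['samples']) * 2} peak BEDs and "
      f"{len(manifest['tables'])} tables under scratch/example_cohort/")
# Each planted SOE should be recoverable by the differential stage; the
# truth manifest is what the tests compare recovered calls against.
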