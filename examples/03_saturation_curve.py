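"""How many patient pairs does SOE discovery need?

Subsample k pairs without replacement, re-run the differential call, and
measure the fraction of full-cohort SOEs recovered.  The curve saturates
well before the full cohort: most discoveries need only a handful of pairs.
"""

from oncoenh import SimConfig, simulate_cohort
from oncoenh.differential import saturation_analysis

cohort, truth = simulate_cohort(SimConfig(seed=42))
universe = [r for r in cohort.counts.region_ids
            if r not in set(truth.tss_excluded_ids)]

results = saturation_analysis(
    cohort.counts, cohort.design_chip,
    k_values=[2, 4, 6, 9, 12, 15, 18], n_replicates=25, seed=7,
    universe=universe,
)

print("k pairs   mean recovery   sd")
for r in results:
    print(f"{r.k:7d}   {r.mean:13.3f}   {r.sd:.3f}")
# recovery is exactly 1.0 at k = 18 (the subsample is the cohort) and the
# mean is non-decreasing in k: the discovery curve flattens as the planted
# effects are large relative to the paired noise.
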