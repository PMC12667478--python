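"""Composite immunohistochemistry scoring.

The score is the product of a positive-cell-proportion score (1-4 by
quartile bins of the stained-cell percentage) and a staining-intensity
score (0 none .. 3 strong), giving a 0-12 scale.
"""

from oncoenh import ihc_score

for pct, intensity in [(80, 3), (40, 2), (10, 0), (60, 1), (25, 2)]:
    s = ihc_score(pct, intensity)
    print(f"{pct:5.1f}% positive, intensity {intensity} -> "
          f"proportion score {s.proportion_score}, IHC score {s.score}")
# 80%/3 gives the maximum 12; zero intensity always gives 0.
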