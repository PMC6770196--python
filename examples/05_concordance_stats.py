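"""Prediction-vs-experiment concordance on the packaged affinity table.

Recomputes the log affinity ratios, the two Pearson correlations, the
energy-band concordance count, and the categorical predictor
concordance for the gain candidates.
"""
from pts1scan.stats import (
    affinity_correlations,
    foldx_concordance,
    gof_category_fixture,
    log_ka_ratio,
    predictor_concordance,
    table3_fixture,
)

records = table3_fixture()

print("log10(Ka_WT / Ka_MT) per tested variant:")
for r in records:
    print(f"  {r.label:12s} {log_ka_ratio(r.ka_wt, r.ka_mt):+.3f} "
          f"(observed: {r.experimental_outcome})")

cors = affinity_correlations(records)
for name, c in cors.items():
    print(f"\n{name} vs log Ka ratio: r = {c.r:.2f}, p = {c.p_value:.3g}, "
          f"95% CI [{c.ci_low:.2f}, {c.ci_high:.2f}], n = {c.n}")

count, _ = foldx_concordance(records, significance=0.5)
print(f"\nenergy-change concordance (+/-0.5 kcal/mol band): {count}/{len(records)}")

count, verdicts = predictor_concordance(gof_category_fixture())
print(f"categorical predictor concordance (gain candidates): {count}/{len(verdicts)}")

# Positive log ratios mean the mutant binds the receptor more weakly
# (signal loss); negative means more strongly (signal gain). Both
# predictors track the measured ratio: the energy change positively
# (r ~ 0.68), the score difference negatively (r ~ -0.93).
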