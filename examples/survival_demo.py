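"""Stratified survival analysis of a simulated cohort.

Splits patients at the median RBM25 expression after excluding
follow-up longer than 60 months, estimates Kaplan-Meier curves per
group and tests the difference with the log-rank test.
"""

from splicescreen import CohortSimConfig, simulate_cohort, stratified_survival

cfg = CohortSimConfig(seed=1)  # log-HR 0.7 per sd of (low) RBM25
_, genes, clinical, _ = simulate_cohort(cfg)

res = stratified_survival(clinical, genes.loc["RBM25"], "median", max_months=60)
print(f"{len(res.low_ids)} low vs {len(res.high_ids)} high RBM25 patients")
print(f"log-rank chi2 = {res.chi2:.2f}, p = {res.p_value:.2e}")
for name, curve in (("low", res.low_curve), ("high", res.high_curve)):
    print(f"{name} RBM25: S(12 months) = {curve.survival_at(12):.2f}, "
          f"S(36 months) = {curve.survival_at(36):.2f}")
# Low RBM25 carries the higher hazard, so its curve sits below the high
# group's at every time point and the log-rank test is significant.
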