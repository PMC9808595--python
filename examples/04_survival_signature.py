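"""The four-gene disease-free-survival signature on a simulated cohort.

Simulates an expression + DFS cohort under a proportional-hazards model
with the signature coefficients planted, then: Kaplan-Meier curves on a
median expression split, the multivariate Cox fit (Efron ties) with hazard
ratios and AIC, the linear risk score with high/low stratification,
time-dependent ROC at 3 years, and the five-group stratification.
"""

import numpy as np

from pbscreen import survival, synthetic

GENES = ["ZNF720", "REEP3", "CNNM2", "CGREF1"]
TRUE_BETA = [0.4193, 0.1222, 0.1394, 0.291]

cohort = synthetic.simulate_survival_cohort(
    95, 4, TRUE_BETA, censor_frac=0.4, rng_seed=12, gene_ids=GENES
)

# Median split per gene, as a single-gene prognosis check
for gene in GENES:
    groups = survival.dichotomize_median(cohort.expression.loc[gene])
    hi = (groups == "high").to_numpy()
    chi2, p = survival.logrank_test(
        cohort.time_years[hi], cohort.event[hi],
        cohort.time_years[~hi], cohort.event[~hi],
    )
    print(f"{gene:>7} median split: log-rank p = {p:.4f}")

model = survival.fit_cox(cohort.time_years, cohort.event,
                         cohort.expression.loc[GENES].T)
print("\nmultivariate Cox fit (planted beta in parentheses):")
for gene, beta, truth, (lo, hi_ci) in zip(GENES, model.beta, TRUE_BETA,
                                          model.ci95):
    print(f"  {gene:>7}: beta = {beta:+.3f} ({truth:+.3f}), "
          f"HR = {np.exp(beta):.2f} [{lo:.2f}, {hi_ci:.2f}]")
print(f"  logPL = {model.log_partial_likelihood:.4f}, AIC = {model.aic:.4f}")

scores, groups = survival.risk_score(model, cohort.expression)
hi = (groups == "high").to_numpy()
chi2, p = survival.logrank_test(
    cohort.time_years[hi], cohort.event[hi],
    cohort.time_years[~hi], cohort.event[~hi],
)
auc = survival.td_roc_auc(cohort.time_years, cohort.event, scores, 3.0)
print(f"\nrisk-score high vs low: log-rank p = {p:.2e}; "
      f"3-year cumulative/dynamic AUC = {auc:.3f}")

five = survival.five_group_assign(cohort.expression, GENES)
print("five-group sizes:", dict(five.value_counts().sort_index()))
# The high-risk half relapses faster (small log-rank p) and the risk score
# discriminates 3-year relapse (AUC > 0.5); group sizes partition the cohort.
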