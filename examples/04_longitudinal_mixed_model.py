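"""Group-by-time mixed model and brain-behaviour correlations on LI change.

Simulates the two patient arms, forms within-subject LI_he changes at
week 7 and month 6, fits the covariate-adjusted random-intercept mixed
model with Satterthwaite degrees of freedom, and correlates week-7 LI
change with behaviour change in the training arm.
"""

from hemilat.pipeline import li_deltas
from hemilat.stats import fit_group_time_lmm, partial_correlation, fdr_bh
from hemilat.synthetic import simulate_cohort
from hemilat.validation import LMM_COVARIATES, patients_only_spec

cohort = simulate_cohort(patients_only_spec(seed=7)).table
deltas = li_deltas(cohort, score_cols=("memory", "executive"))

model = fit_group_time_lmm(deltas, "d_li_he", LMM_COVARIATES)
print("fixed-effect F tests on the LI_he change (Satterthwaite df):")
for term, res in model.tests.items():
    print(
        f"  {term:11s} F({res.df[0]:.0f}, {res.df[1]:.2f}) = {res.statistic:6.3f}, "
        f"p = {res.p:.4f}"
    )
print(f"variance components: subject tau2 = {model.tau2:.5f}, residual = {model.sigma2:.5f}")

tg_w7 = deltas[(deltas.group == "TG") & (deltas.time == "W7")]
print(f"\npartial correlations in the training arm at week 7 (n = {len(tg_w7)}):")
results = []
for score in ("memory", "executive"):
    res = partial_correlation(
        tg_w7["d_li_he"].to_numpy(),
        tg_w7[f"d_{score}"].to_numpy(),
        tg_w7[LMM_COVARIATES].to_numpy(),
    )
    results.append((score, res))
adjusted = fdr_bh([r.p for _, r in results])
for (score, res), p_fdr in zip(results, adjusted):
    print(f"  d_li_he ~ d_{score}: r = {res.effect_size:+.3f}, p = {res.p:.4f}, p_fdr = {p_fdr:.4f}")
# A significant interaction reflects the training-specific week-7 shift
# that reverts at month 6; the partial correlations recover the coupling
# between lateralization change and behaviour change built into the
# generator.
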