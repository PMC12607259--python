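"""Monte-Carlo design-validation experiments for the synthetic cohort.

These experiments characterize the operating behaviour of the full
pipeline under the emulated trial design: the false-positive rate and
power of the group-by-time mixed model at the design's arm sizes, and the
recovery of a known brain-behaviour partial correlation at the week-7
sample size. They are what a trialist would run to check that the
analysis plan behaves as advertised before touching real data.
"""

from __future__ import annotations

import numpy as np

from hemilat.pipeline import li_deltas
from hemilat.stats import fit_group_time_lmm, partial_correlation
from hemilat.synthetic import (
    CohortSpec,
    _default_asymmetry,
    noise_sd_for_partial_r,
    simulate_behaviour,
    simulate_cohort,
)

__all__ = [
    "patients_only_spec",
    "interaction_rejection_rate",
    "partial_r_recovery",
]

#: LMM covariates used throughout the longitudinal analyses
LMM_COVARIATES = ["age", "sex", "education", "mFD", "mFC"]


def patients_only_spec(seed: int, null: bool = False) -> CohortSpec:
    """The trial's two patient arms (28/28 -> 25/24 -> 21/14), no healthy arm.

    With ``null=True`` the training arm keeps its rightward asymmetry at
    week 7, so the group-by-time interaction on LI change is exactly null.
    """
    asymmetry = {k: v for k, v in _default_asymmetry().items() if k[0] != "HG"}
    if null:
        asymmetry[("TG", "W7")] = asymmetry[("TG", "B0")]
    return CohortSpec(
        n_baseline={"CG": 28, "TG": 28},
        asymmetry=asymmetry,
        seed=seed,
    )


def interaction_rejection_rate(
    n_replicates: int,
    seed: int,
    null: bool,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the group-by-time interaction over replicate trials.

    Each replicate simulates a complete two-arm cohort (time series, LIs,
    covariates), forms within-subject LI_he changes at week 7 and month 6,
    and fits the covariate-adjusted mixed model. Under ``null=True`` this
    estimates the type-I error; otherwise the power at the design's
    calibrated training effect.
    """
    rejections = 0
    for rep in range(n_replicates):
        spec = patients_only_spec(seed=seed + rep, null=null)
        cohort = simulate_cohort(spec).table
        deltas = li_deltas(cohort)
        model = fit_group_time_lmm(deltas, "d_li_he", LMM_COVARIATES)
        rejections += model.tests["group:time"].p < alpha
    return rejections / n_replicates


def partial_r_recovery(
    n_replicates: int,
    seed: int,
    n: int = 24,
    target_r: float = 0.5,
    li_sd: float = 0.08,
    slope: float = 20.0,
) -> float:
    """Mean estimated partial correlation over replicate samples of size n.

    Scores are generated as intercept + slope*li + gamma*confounder +
    noise, with the noise calibrated so the population partial correlation
    between score and LI given the confounder equals ``target_r``; the
    estimator is the covariate-residualized Pearson r at the week-7
    training-arm sample size.
    """
    noise_sd = noise_sd_for_partial_r(target_r, slope, li_sd)
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_replicates)
    for rep in range(n_replicates):
        li = rng.normal(0.0, li_sd, n)
        confounder = rng.normal(0.0, 1.0, n)
        scores = simulate_behaviour(
            li, slope=slope, intercept=10.0, noise_sd=noise_sd,
            seed=rng.integers(2**31),
        )
        scores = scores + 3.0 * confounder
        estimates[rep] = partial_correlation(li, scores, confounder).effect_size
    return float(estimates.mean())
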