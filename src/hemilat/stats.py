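"""Inference battery for baseline comparisons and longitudinal models.

Covers the statistics a lateralization trial needs: pooled two-sample t
(raw vectors or printed n/mean/sd summaries), Pearson chi-square without
continuity correction with Cramer's V, one-way ANOVA (raw or summaries)
with partial eta squared, ANCOVA with optional HC3 robust Wald F,
one-sample t with Cohen's d, covariate-residualized partial correlation,
Benjamini-Hochberg FDR over an explicitly declared comparison family,
Games-Howell post hocs, and a group-by-time linear mixed model with a
random intercept per participant and Satterthwaite denominator df.

Every result carries a ``method`` tag so reports are auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "StatTestResult",
    "MixedModelResult",
    "pooled_t",
    "chi_square",
    "one_way_anova",
    "ancova",
    "one_sample_t",
    "partial_correlation",
    "fdr_bh",
    "games_howell",
    "fit_group_time_lmm",
]


@dataclass(frozen=True)
class SummaryStats:
    """n / mean / sample-sd (n-1 denominator) summary of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary requires n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_values(cls, values: np.ndarray) -> "SummaryStats":
        values = np.asarray(values, dtype=float)
        return cls(len(values), float(values.mean()), float(values.std(ddof=1)))


@dataclass(frozen=True)
class StatTestResult:
    """Statistic, df, p, effect size and an auditable method tag."""

    statistic: float
    df: float | tuple[float, float]
    p: float
    effect_size: float
    effect_kind: str
    method: str
    extra: dict = field(default_factory=dict)


def _as_summary(g) -> SummaryStats:
    if isinstance(g, SummaryStats):
        return g
    return SummaryStats.from_values(g)


def pooled_t(a, b) -> StatTestResult:
    """Student (pooled-variance) two-sample t with Cohen's d.

    Accepts raw vectors or :class:`SummaryStats`; both routes give exactly
    the same answer. Cohen's d uses the pooled sd with n-1 weights. When
    both groups are constant and equal the statistic is defined as 0
    (p = 1) rather than 0/0.
    """
    a, b = _as_summary(a), _as_summary(b)
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    diff = a.mean - b.mean
    if pooled_var == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        d = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        sp = math.sqrt(pooled_var)
        t = diff / (sp * math.sqrt(1 / a.n + 1 / b.n))
        d = diff / sp
    p = float(2 * sps.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    if t == 0.0:
        p = 1.0
    return StatTestResult(t, df, p, d, "cohen_d", "pooled two-sample t")


def chi_square(counts) -> StatTestResult:
    """Pearson chi-square (no continuity correction) with Cramer's V."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal")
    chi2, p, df, _ = sps.chi2_contingency(counts, correction=False)
    n = counts.sum()
    v = math.sqrt(chi2 / (n * (min(counts.shape) - 1)))
    return StatTestResult(float(chi2), int(df), float(p), v, "cramers_v", "pearson chi-square")


def one_way_anova(groups) -> StatTestResult:
    """One-way ANOVA from raw vectors or summaries, with partial eta squared.

    Sums of squares are reconstructed from n/mean/sd, so printed summary
    rows reproduce the F exactly up to their rounding.
    """
    summaries = [_as_summary(g) for g in groups]
    if len(summaries) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    n_total = ns.sum()
    grand = (ns * means).sum() / n_total
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df1 = len(summaries) - 1
    df2 = int(n_total) - len(summaries)
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else math.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    eta_p = ss_between / (ss_between + ss_within) if ss_between + ss_within else 0.0
    return StatTestResult(f, (df1, df2), p, eta_p, "partial_eta_sq", "one-way ANOVA")


def ancova(
    outcome: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    hc3: bool = False,
) -> StatTestResult:
    """Group F adjusted for covariates, optionally with HC3 robust errors.

    Fits outcome ~ group + covariates by OLS. The default F is the
    classical partial (type-II) F for the group factor; with ``hc3=True``
    it is the Wald F from an HC3 heteroskedasticity-consistent covariance.
    Partial eta squared is always reported from the classical sums of
    squares.
    """
    import statsmodels.api as sm

    outcome = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValueError("group factor needs at least two levels")
    dummies = pd.get_dummies(pd.Categorical(group, categories=levels), drop_first=True)
    x_parts = [np.ones((len(outcome), 1)), dummies.to_numpy(dtype=float)]
    k_group = dummies.shape[1]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        x_parts.append(cov)
    x = np.hstack(x_parts)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")
    if len(outcome) <= x.shape[1]:
        raise ValueError("too few observations for the requested adjustment")
    full = sm.OLS(outcome, x).fit()
    # classical partial SS via the restricted model without the group dummies
    x_restricted = np.hstack([x[:, :1], x[:, 1 + k_group :]])
    restricted = sm.OLS(outcome, x_restricted).fit()
    ss_group = restricted.ssr - full.ssr
    ss_resid = full.ssr
    df1, df2 = k_group, int(full.df_resid)
    eta_p = ss_group / (ss_group + ss_resid) if ss_group + ss_resid else 0.0
    if hc3:
        contrast = np.zeros((k_group, x.shape[1]))
        contrast[:, 1 : 1 + k_group] = np.eye(k_group)
        wald = full.get_robustcov_results(cov_type="HC3").wald_test(
            contrast, use_f=True, scalar=True
        )
        f, p = float(wald.statistic), float(wald.pvalue)
        method = "ANCOVA, HC3 robust Wald F"
    else:
        f = (ss_group / df1) / (ss_resid / df2)
        p = float(sps.f.sf(f, df1, df2))
        method = "ANCOVA, classical F"
    return StatTestResult(f, (df1, df2), p, eta_p, "partial_eta_sq", method)


def one_sample_t(values: np.ndarray, mu: float = 0.0) -> StatTestResult:
    """One-sample t against ``mu`` with Cohen's d = (mean - mu)/sd."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two observations")
    sd = values.std(ddof=1)
    if sd == 0:
        t, p = (0.0, 1.0) if values[0] == mu else (math.inf, 0.0)
        d = 0.0 if values[0] == mu else math.inf
    else:
        res = sps.ttest_1samp(values, mu)
        t, p = float(res.statistic), float(res.pvalue)
        d = float((values.mean() - mu) / sd)
    return StatTestResult(t, len(values) - 1, p, d, "cohen_d", "one-sample t")


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> StatTestResult:
    """Pearson correlation of x and y after residualizing both on covariates.

    Both variables are regressed (with intercept) on the covariate matrix
    by least squares; the correlation of the residuals is tested on
    n - 2 - k df. With no covariates this reduces to the plain Pearson r.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.hstack([np.ones((n, 1)), cov])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    # a variable fully explained by the covariates leaves only rounding
    # noise in its residual; its partial correlation is zero by definition
    if np.dot(rx, rx) <= (1e-10 * np.linalg.norm(x - x.mean())) ** 2 or np.dot(
        ry, ry
    ) <= (1e-10 * np.linalg.norm(y - y.mean())) ** 2:
        r = 0.0
    else:
        r = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = max(-1.0, min(1.0, r))
    df = n - 2 - k
    if abs(r) == 1.0:
        t, p = math.copysign(math.inf, r), 0.0
    else:
        t = r * math.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return StatTestResult(
        t, df, p, r, "partial_r", "partial correlation", extra={"n": n, "k": k}
    )


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def games_howell(groups, labels=None) -> list[StatTestResult]:
    """Games-Howell pairwise comparisons (Welch df + studentized range).

    Robust to unequal variances; appropriate when the homogeneity
    assumption of classical post hocs fails.
    """
    import pingouin as pg

    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    dv = np.concatenate(groups)
    between = np.concatenate([[lab] * len(g) for lab, g in zip(labels, groups)])
    table = pg.pairwise_gameshowell(
        data=pd.DataFrame({"dv": dv, "between": between}), dv="dv", between="between"
    )
    results = []
    for _, row in table.iterrows():
        results.append(
            StatTestResult(
                float(row["T"]),
                float(row["df"]),
                float(row["pval"]),
                float(row["hedges"]),
                "hedges_g",
                "Games-Howell pairwise",
                extra={"A": row["A"], "B": row["B"]},
            )
        )
    return results


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model with Satterthwaite df
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixedModelResult:
    """Fixed-effect F tests and variance components of the group-time LMM."""

    tests: dict
    fe_params: pd.Series
    tau2: float
    sigma2: float
    n_obs: int
    n_subjects: int
    df_method: str
    converged: bool


class _RandomInterceptREML:
    """REML machinery for y = X b + u_subject + e, u ~ N(0, tau2), e ~ N(0, sigma2).

    The per-subject covariance sigma2*I + tau2*J is inverted in closed form
    (Sherman-Morrison), so all quantities are exact and cheap; the REML
    criterion is profiled over the variance ratio for a robust 1-D fit.
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, groups: np.ndarray):
        self.y = y
        self.x = x
        order = np.argsort(groups, kind="stable")
        self.y = y[order]
        self.x = x[order]
        g = np.asarray(groups)[order]
        _, starts = np.unique(g, return_index=True)
        bounds = np.append(np.sort(starts), len(g))
        self.slices = [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
        self.n, self.p = self.x.shape

    def _gls(self, tau2: float, sigma2: float):
        """X'V^-1 X, X'V^-1 y, y'V^-1 y, log|V| for V = sigma2 I + tau2 J."""
        xtvx = np.zeros((self.p, self.p))
        xtvy = np.zeros(self.p)
        ytvy = 0.0
        logdet = 0.0
        for sl in self.slices:
            xi, yi = self.x[sl], self.y[sl]
            ni = xi.shape[0]
            a = tau2 / (sigma2 * (sigma2 + ni * tau2))
            xs, ys = xi.sum(axis=0), yi.sum()
            xtvx += xi.T @ xi / sigma2 - a * np.outer(xs, xs)
            xtvy += xi.T @ yi / sigma2 - a * xs * ys
            ytvy += yi @ yi / sigma2 - a * ys * ys
            logdet += (ni - 1) * math.log(sigma2) + math.log(sigma2 + ni * tau2)
        return xtvx, xtvy, ytvy, logdet

    def reml_neg2loglik(self, tau2: float, sigma2: float) -> float:
        xtvx, xtvy, ytvy, logdet = self._gls(tau2, sigma2)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return math.inf
        beta = np.linalg.solve(xtvx, xtvy)
        rss = ytvy - xtvy @ beta
        return logdet + logdet_x + rss

    def fit(self):
        from scipy.optimize import minimize_scalar

        # profile: V = sigma2 (I + lam J); REML-optimal sigma2 has closed form
        def profiled(log_lam: float) -> float:
            lam = math.exp(log_lam)
            xtvx, xtvy, ytvy, logdet = self._gls(lam, 1.0)
            sign, logdet_x = np.linalg.slogdet(xtvx)
            if sign <= 0:
                return math.inf
            beta = np.linalg.solve(xtvx, xtvy)
            rss = ytvy - xtvy @ beta
            if rss <= 0:
                return math.inf
            sigma2 = rss / (self.n - self.p)
            return logdet + logdet_x + (self.n - self.p) * math.log(sigma2)

        res = minimize_scalar(
            profiled, bounds=(-12.0, 12.0), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = math.exp(res.x)
        xtvx, xtvy, ytvy, _ = self._gls(lam, 1.0)
        beta = np.linalg.solve(xtvx, xtvy)
        sigma2 = (ytvy - xtvy @ beta) / (self.n - self.p)
        tau2 = lam * sigma2
        # boundary handling: treat a tiny ratio as tau2 = 0
        if lam < 1e-8:
            tau2 = 0.0
        return beta, tau2, sigma2, res.success

    def beta_cov(self, tau2: float, sigma2: float) -> np.ndarray:
        xtvx, _, _, _ = self._gls(tau2, sigma2)
        return np.linalg.inv(xtvx)

    def theta_cov(self, tau2: float, sigma2: float) -> np.ndarray:
        """Asymptotic covariance of (tau2, sigma2): inverse REML information.

        The Hessian of the -2 REML log-likelihood is evaluated by central
        finite differences; cov(theta) = 2 H^-1.
        """
        theta = np.array([max(tau2, 1e-10), sigma2])
        h = np.maximum(1e-6, 1e-4 * theta)

        def f(t):
            return self.reml_neg2loglik(max(t[0], 0.0), max(t[1], 1e-12))

        hess = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2)
                ej = np.zeros(2)
                ei[i] = h[i]
                ej[j] = h[j]
                hess[i, j] = hess[j, i] = (
                    f(theta + ei + ej)
                    - f(theta + ei - ej)
                    - f(theta - ei + ej)
                    + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
        try:
            return 2.0 * np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return np.full((2, 2), np.nan)


def _satterthwaite_f(
    model: _RandomInterceptREML,
    beta: np.ndarray,
    tau2: float,
    sigma2: float,
    contrast: np.ndarray,
) -> tuple[float, float, float]:
    """Wald F for C beta = 0 with Satterthwaite denominator df.

    Follows the multi-df recipe used by lmerTest: eigendecompose the
    contrast covariance, compute a 1-D Satterthwaite df per component via
    the delta method over the variance parameters, and pool them.
    """
    q = contrast.shape[0]
    cov_beta = model.beta_cov(tau2, sigma2)
    m = contrast @ cov_beta @ contrast.T
    f_stat = float(beta @ contrast.T @ np.linalg.solve(m, contrast @ beta)) / q

    a = model.theta_cov(tau2, sigma2)
    eigval, eigvec = np.linalg.eigh(m)
    theta = np.array([tau2, sigma2])
    h = np.maximum(1e-6, 1e-4 * np.maximum(theta, 1e-8))
    nus = []
    for comp in range(q):
        c_row = eigvec[:, comp] @ contrast

        def vfun(t):
            cb = model.beta_cov(max(t[0], 0.0), max(t[1], 1e-12))
            return float(c_row @ cb @ c_row)

        grad = np.zeros(2)
        for i in range(2):
            e = np.zeros(2)
            e[i] = h[i]
            grad[i] = (vfun(theta + e) - vfun(theta - e)) / (2 * h[i])
        denom = float(grad @ a @ grad)
        v = float(eigval[comp])
        nu = 2 * v**2 / denom if denom > 0 else math.inf
        nus.append(max(nu, 1.0 + 1e-8))
    if q == 1:
        df2 = nus[0]
    else:
        e_sum = sum(nu / (nu - 2) for nu in nus if nu > 2)
        df2 = 2 * e_sum / (e_sum - q) if e_sum > q else math.inf
    p = float(sps.f.sf(f_stat, q, df2)) if math.isfinite(df2) else float(
        sps.chi2.sf(f_stat * q, q)
    )
    return f_stat, df2, p


def _effects_code(values: pd.Series, levels) -> np.ndarray:
    """Sum-to-zero coding: k-1 columns, last level coded -1 everywhere."""
    arr = np.asarray(values)
    out = np.zeros((len(arr), len(levels) - 1))
    for j, level in enumerate(levels[:-1]):
        out[arr == level, j] = 1.0
    out[arr == levels[-1], :] = -1.0
    return out


def fit_group_time_lmm(
    data: pd.DataFrame,
    outcome: str,
    covariates: list[str] | None = None,
    group_col: str = "group",
    time_col: str = "time",
    subject_col: str = "subject",
) -> MixedModelResult:
    """Group-by-time linear mixed model on a long-format cohort table.

    Fixed effects: group, time, group x time, plus the listed covariates;
    random intercept per participant, fitted by REML. F tests use
    Satterthwaite-approximate denominator df (tagged in the result);
    partial eta squared is approximated as F*df1/(F*df1 + df2). Missing
    sessions (attrition) are simply absent rows and are tolerated.
    """
    covariates = list(covariates or [])
    cols = [outcome, group_col, time_col, subject_col] + covariates
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    d = data[cols].dropna().copy()
    y = d[outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("outcome is constant")
    cells = d.groupby([group_col, time_col], observed=True).size()
    g_levels = pd.unique(d[group_col])
    t_levels = pd.unique(d[time_col])
    for g in g_levels:
        for t in t_levels:
            if (g, t) not in cells.index:
                raise ValueError(f"empty group-by-time cell: ({g}, {t})")

    # sum-to-zero (effects) coding so the factor tests are Type-III style
    # marginal tests, matching standard mixed-ANOVA reporting
    g_dum = _effects_code(d[group_col], g_levels)
    t_dum = _effects_code(d[time_col], t_levels)
    inter = np.einsum("ij,ik->ijk", g_dum, t_dum).reshape(len(d), -1)
    cov_mat = d[covariates].to_numpy(dtype=float) if covariates else np.empty((len(d), 0))
    x = np.hstack([np.ones((len(d), 1)), g_dum, t_dum, inter, cov_mat])
    names = (
        ["Intercept"]
        + [f"{group_col}[{g}]" for g in g_levels[:-1]]
        + [f"{time_col}[{t}]" for t in t_levels[:-1]]
        + [
            f"{group_col}[{g}]:{time_col}[{t}]"
            for g in g_levels[:-1]
            for t in t_levels[:-1]
        ]
        + covariates
    )
    slices = {
        "group": slice(1, 1 + g_dum.shape[1]),
        "time": slice(1 + g_dum.shape[1], 1 + g_dum.shape[1] + t_dum.shape[1]),
        "group:time": slice(
            1 + g_dum.shape[1] + t_dum.shape[1],
            1 + g_dum.shape[1] + t_dum.shape[1] + inter.shape[1],
        ),
    }

    model = _RandomInterceptREML(y, x, d[subject_col].to_numpy())
    beta, tau2, sigma2, converged = model.fit()

    tests = {}
    for term, sl in slices.items():
        q = sl.stop - sl.start
        contrast = np.zeros((q, x.shape[1]))
        contrast[np.arange(q), np.arange(sl.start, sl.stop)] = 1.0
        f_stat, df2, p = _satterthwaite_f(model, beta, tau2, sigma2, contrast)
        eta_p = f_stat * q / (f_stat * q + df2) if math.isfinite(df2) else float("nan")
        tests[term] = StatTestResult(
            f_stat, (q, df2), p, eta_p, "partial_eta_sq",
            "LMM Wald F, Satterthwaite df",
        )
    return MixedModelResult(
        tests=tests,
        fe_params=pd.Series(beta, index=names),
        tau2=float(tau2),
        sigma2=float(sigma2),
        n_obs=len(d),
        n_subjects=int(d[subject_col].nunique()),
        df_method="satterthwaite",
        converged=bool(converged),
    )
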