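"""Reliability and group-comparison statistics.

The layer mirrors the analysis plan of a typical biomechanics study:

* ICC(C,1) — two-way random-effects intraclass correlation, single
  measures, consistency definition (McGraw & Wong), with the exact
  F-based confidence interval, for pre- versus postoperative agreement;
* one-way ANOVA with step-down Holm-Sidak pairwise adjustment and
  noncentral-F observed power;
* distributional gating with Shapiro-Wilk (normality per group) and
  Brown-Forsythe (equality of variances), routing failures to
* Kruskal-Wallis with Dunn's pairwise z tests under Bonferroni correction;
* the Pearson product-moment correlation.

ICC categories follow the conventional bands: > 0.75 excellent,
0.40-0.75 moderate, < 0.40 poor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    category: str
    df1: int
    df2: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.icc + 1e-12
                and self.icc <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must bracket the estimate")


@dataclass
class PairwiseComparison:
    groups: tuple
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class TestResult:
    name: str
    statistic: float
    df: tuple
    p_value: float
    pairwise: list = field(default_factory=list)
    observed_power: float | None = None


def icc_category(icc: float) -> str:
    if icc > 0.75:
        return "excellent"
    if icc >= 0.40:
        return "moderate"
    return "poor"


def icc_consistency(ratings: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(C,1): two-way random effects, single measures, consistency.

    ``ratings`` is an (n subjects x k raters) array with no missing cells.
    The estimate comes from the two-way ANOVA mean squares,
    (MS_rows - MS_error) / (MS_rows + (k-1) MS_error); the confidence
    interval is the exact F interval and the p-value tests ICC = 0 via
    F = MS_rows / MS_error on (n-1, (n-1)(k-1)) df.
    """
    y = np.asarray(ratings, dtype=float)
    if y.ndim != 2 or y.shape[1] < 2:
        raise ValueError("ratings must be (n subjects, k >= 2 raters)")
    n, k = y.shape
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if np.isnan(y).any():
        raise ValueError("missing cells are not supported")

    grand = y.mean()
    ss_rows = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    df1, df2 = n - 1, (n - 1) * (k - 1)
    ms_rows = ss_rows / df1
    ms_err = ss_err / df2
    if ms_rows + ms_err <= 0 or not np.isfinite(ms_rows / max(ms_err, 1e-300)):
        raise ValueError("degenerate mean squares (constant data?)")
    if ms_err == 0:
        # perfect consistency: mean squares collapse, ICC = 1 exactly
        return ICCResult(1.0, 1.0, 1.0, 0.0, "excellent", df1, df2)

    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    f_obs = ms_rows / ms_err
    p = float(sps.f.sf(f_obs, df1, df2))
    f_crit = sps.f.ppf(1 - alpha / 2, df1, df2)
    f_crit_rev = sps.f.ppf(1 - alpha / 2, df2, df1)
    fl = f_obs / f_crit
    fu = f_obs * f_crit_rev
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(float(icc), float(ci_low), float(ci_high), p,
                     icc_category(float(icc)), df1, df2)


def simulate_icc_pairs(population_icc: float, n: int,
                       rng: np.random.Generator,
                       rater_sd: float = 0.1) -> np.ndarray:
    """Two-way random-effects generator y_ij = a_i + b_j + e_ij whose
    population consistency ICC equals ``population_icc`` (subject variance
    rho, residual variance 1 - rho; the rater effect b_j shifts columns and
    is invisible to the consistency definition)."""
    if not 0.0 <= population_icc < 1.0:
        raise ValueError("population ICC must lie in [0, 1)")
    a = rng.normal(0.0, np.sqrt(population_icc), size=(n, 1))
    b = rng.normal(0.0, rater_sd, size=(1, 2))
    e = rng.normal(0.0, np.sqrt(1.0 - population_icc), size=(n, 2))
    return a + b + e


# ---------------------------------------------------------------------------
# ANOVA + Holm-Sidak
# ---------------------------------------------------------------------------


def holm_sidak(p_raw: np.ndarray) -> np.ndarray:
    """Step-down Sidak adjustment: the i-th smallest of m raw p-values
    becomes 1 - (1 - p)^(m - i + 1), with monotonicity enforced and a cap
    at 1.  Adjusted values are never below the raw values."""
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def anova_observed_power(groups: list[np.ndarray],
                         alpha: float = 0.05) -> float:
    """Post hoc power of the one-way F test at the sample effect size:
    noncentrality lambda = sum n_j (mean_j - grand)^2 / MSE."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([np.mean(g) for g in groups])
    n_tot = ns.sum()
    grand = np.concatenate(groups).mean()
    ss_within = sum(np.sum((g - m) ** 2) for g, m in zip(groups, means))
    df1, df2 = k - 1, n_tot - k
    mse = ss_within / df2
    if mse == 0:
        return 1.0
    lam = float(np.sum(ns * (means - grand) ** 2) / mse)
    f_crit = sps.f.ppf(1 - alpha, df1, df2)
    return float(sps.ncf.sf(f_crit, df1, df2, lam))


def anova_holm_sidak(groups: list[np.ndarray],
                     labels: list[str] | None = None,
                     alpha: float = 0.05) -> TestResult:
    """One-way ANOVA with Holm-Sidak-adjusted pairwise pooled t tests and
    noncentral-F observed power."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere; the F "
                         "statistic is undefined")
    labels = labels or [f"g{i}" for i in range(len(groups))]
    f_stat, p = sps.f_oneway(*groups)
    k = len(groups)
    n_tot = sum(len(g) for g in groups)

    pairs = list(itertools.combinations(range(k), 2))
    t_stats, p_raw = [], []
    for i, j in pairs:
        t, pr = sps.ttest_ind(groups[i], groups[j])
        t_stats.append(float(t))
        p_raw.append(float(pr))
    p_adj = holm_sidak(np.array(p_raw))
    pairwise = [PairwiseComparison((labels[i], labels[j]), t_stats[m],
                                   p_raw[m], float(p_adj[m]))
                for m, (i, j) in enumerate(pairs)]
    power = anova_observed_power(groups, alpha)
    return TestResult("one-way ANOVA (Holm-Sidak post hoc)", float(f_stat),
                      (k - 1, n_tot - k), float(p), pairwise, power)


# ---------------------------------------------------------------------------
# Distributional gate
# ---------------------------------------------------------------------------


@dataclass
class GateDecision:
    parametric: bool
    shapiro_p: list
    brown_forsythe_p: float


def distribution_gate(groups: list[np.ndarray],
                      alpha: float = 0.05) -> GateDecision:
    """Shapiro-Wilk per group plus Brown-Forsythe (Levene on deviations
    from group medians); any rejection at ``alpha`` routes the comparison
    to the non-parametric branch."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    shapiro_p = [float(sps.shapiro(g).pvalue) for g in groups]
    bf_p = float(sps.levene(*groups, center="median").pvalue)
    parametric = all(p > alpha for p in shapiro_p) and bf_p > alpha
    return GateDecision(parametric, shapiro_p, bf_p)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn/Bonferroni
# ---------------------------------------------------------------------------


def kruskal_dunn(groups: list[np.ndarray],
                 labels: list[str] | None = None) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise z tests and
    Bonferroni multiplication capped at 1."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels = labels or [f"g{i}" for i in range(len(groups))]
    h_stat, p = sps.kruskal(*groups)

    pooled = np.concatenate(groups)
    n_tot = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for n_g in sizes:
        mean_ranks.append(ranks[start:start + n_g].mean())
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12 * (n_tot - 1))

    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        se = np.sqrt((n_tot * (n_tot + 1) / 12 - tie_term)
                     * (1 / sizes[i] + 1 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2 * float(sps.norm.sf(abs(z)))
        pairwise.append(PairwiseComparison(
            (labels[i], labels[j]), float(z), p_raw,
            min(1.0, p_raw * m)))
    return TestResult("Kruskal-Wallis (Dunn/Bonferroni post hoc)",
                      float(h_stat), (len(groups) - 1,), float(p), pairwise)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with its t-distributed p-value."""
    res = sps.pearsonr(np.asarray(x, dtype=float),
                       np.asarray(y, dtype=float))
    return float(res.statistic), float(res.pvalue)


def simulate_bivariate_pairs(rho: float, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """(n, 2) draws from a standard bivariate normal with correlation rho."""
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal(np.zeros(2), cov, size=n)
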