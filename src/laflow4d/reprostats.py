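"""Reproducibility statistics for repeated biomarker measurements.

The central quantity is the within-subject coefficient of variation computed
by the root-mean-square method on paired sessions:

    CV = sqrt( (1/n) * sum_i [ (x_i1 - x_i2)^2 / 2 ] / mbar_i^2 )

with ``mbar_i`` the pair mean — a proportional repeatability measure.
Non-parametric inference is by subject-level bootstrap: percentile 95% CIs
(1000 resamples by default), and comparisons of CVs between independent
groups or between dependent (same-subject) measurement pairs via the
bootstrap distribution of the CV difference (add-one corrected, two-tailed
p-values). The module also provides Bland-Altman limits of agreement and the
agreement-based power/sample-size calculation, ICC(A,1) from two-way ANOVA
mean squares, McNemar's test for paired pattern calls, stratified-bootstrap
Pearson correlation, Spearman correlation, and Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

#: switch from the exact binomial to the continuity-corrected chi-square
#: McNemar test at this many discordant pairs
MCNEMAR_EXACT_MAX = 25


@dataclass
class CVEstimate:
    cv: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_boot: int


@dataclass
class AgreementStats:
    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class CVComparison:
    delta_cv: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    paired: bool


# --------------------------------------------------------------------------
# Within-subject CV
# --------------------------------------------------------------------------


def _pair_ratios(pairs: np.ndarray) -> np.ndarray:
    """Per-subject squared proportional deviation (d_i^2/2) / mbar_i^2."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must have shape (n, 2)")
    if np.any(pairs <= 0):
        raise ValueError("within-subject CV requires strictly positive values")
    d = pairs[:, 0] - pairs[:, 1]
    m = pairs.mean(axis=1)
    return (d**2 / 2.0) / m**2


def rms_cv(pairs: np.ndarray) -> float:
    """Point estimate of the RMS within-subject CV (proportion)."""
    return float(np.sqrt(_pair_ratios(pairs).mean()))


def within_subject_cv(
    pairs: np.ndarray, n_boot: int = 1000, seed: int | None = None
) -> CVEstimate:
    """RMS within-subject CV with a percentile bootstrap 95% CI.

    Subjects (pairs) are resampled with replacement ``n_boot`` times; the CI
    is the 2.5/97.5 percentile of the resampled CVs.
    """
    r = _pair_ratios(pairs)
    n = r.size
    if n < 2:
        raise ValueError("need at least 2 pairs for a bootstrap CI")
    cv = float(np.sqrt(r.mean()))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.sqrt(r[idx].mean(axis=1))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return CVEstimate(cv, float(lo), float(hi), n, n_boot)


def _boot_p_two_tailed(deltas: np.ndarray) -> float:
    """Add-one corrected two-tailed bootstrap p for H0: delta = 0."""
    b = deltas.size
    n_le = int(np.count_nonzero(deltas <= 0))
    n_ge = int(np.count_nonzero(deltas >= 0))
    p = 2.0 * min(n_le + 1, n_ge + 1) / (b + 1)
    return min(p, 1.0)


def compare_cv_independent(
    pairs_a: np.ndarray,
    pairs_b: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> CVComparison:
    """Bootstrap comparison of CVs between two independent groups.

    Subjects are resampled within each group independently; the CI is the
    percentile interval of ``CV_A* - CV_B*`` and the p-value is the add-one
    corrected two-tailed bootstrap tail probability.
    """
    ra, rb = _pair_ratios(pairs_a), _pair_ratios(pairs_b)
    if ra.size < 2 or rb.size < 2:
        raise ValueError("each group needs at least 2 pairs")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, ra.size, size=(n_boot, ra.size))
    ib = rng.integers(0, rb.size, size=(n_boot, rb.size))
    deltas = np.sqrt(ra[ia].mean(axis=1)) - np.sqrt(rb[ib].mean(axis=1))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    delta = float(np.sqrt(ra.mean()) - np.sqrt(rb.mean()))
    return CVComparison(delta, float(lo), float(hi), _boot_p_two_tailed(deltas), n_boot, False)


def compare_cv_dependent(
    pairs_a: np.ndarray,
    pairs_b: np.ndarray,
    n_boot: int = 10000,
    seed: int | None = None,
) -> CVComparison:
    """Bootstrap comparison of two CVs measured on the same subjects.

    Each resample draws subjects jointly — a drawn subject carries both its
    pair from A and its pair from B — preserving the dependence between the
    two measures. Rows of ``pairs_a`` and ``pairs_b`` must be aligned
    subject-for-subject.
    """
    ra, rb = _pair_ratios(pairs_a), _pair_ratios(pairs_b)
    if ra.size != rb.size:
        raise ValueError(
            f"dependent comparison needs aligned subjects: {ra.size} pairs in A "
            f"vs {rb.size} in B"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ra.size, size=(n_boot, ra.size))
    deltas = np.sqrt(ra[idx].mean(axis=1)) - np.sqrt(rb[idx].mean(axis=1))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    delta = float(np.sqrt(ra.mean()) - np.sqrt(rb.mean()))
    return CVComparison(delta, float(lo), float(hi), _boot_p_two_tailed(deltas), n_boot, True)


# --------------------------------------------------------------------------
# Agreement
# --------------------------------------------------------------------------


def bland_altman(pairs: np.ndarray) -> AgreementStats:
    """Mean bias and 95% limits of agreement (bias +/- 1.96 * SD of diffs)."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least 2 pairs of measurements")
    d = pairs[:, 0] - pairs[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementStats(bias, bias - 1.96 * sd, bias + 1.96 * sd, d.size)


def ba_agreement_power(
    n: int,
    mean_diff: float,
    sd_diff: float,
    max_allowed_diff: float,
    alpha: float = 0.05,
) -> float:
    """Power that both 95% limits of agreement fall within +/- max_allowed_diff.

    Normal-approximation formulation of the Bland-Altman agreement
    sample-size framework (Lu et al. 2016): the estimated limit
    ``dbar +/- 1.96 s`` has standard error ``sd * sqrt(1/n + z^2/(2(n-1)))``
    with z = 1.96; agreement is declared when the ``1 - alpha/2`` confidence
    bound of each limit lies inside the allowed difference, and the power of
    that joint event is ``Phi(tau1) + Phi(tau2) - 1`` with

        tau_{1,2} = (delta -/+ mean_diff - z * sd) / SE  -  z_{1-alpha/2}.

    Degenerate inputs (allowed difference not exceeding the expected limit)
    give power near 0 rather than an error.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    if max_allowed_diff <= abs(mean_diff):
        raise ValueError("max_allowed_diff must exceed |mean_diff|")
    z = stats.norm.ppf(0.975)  # LoA multiplier, fixed at the 95% limits
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    se = sd_diff * np.sqrt(1.0 / n + z**2 / (2.0 * (n - 1)))
    tau1 = (max_allowed_diff - mean_diff - z * sd_diff) / se - z_alpha
    tau2 = (max_allowed_diff + mean_diff - z * sd_diff) / se - z_alpha
    power = stats.norm.cdf(tau1) + stats.norm.cdf(tau2) - 1.0
    return float(np.clip(power, 0.0, 1.0))


def ba_sample_size(
    mean_diff: float,
    sd_diff: float,
    max_allowed_diff: float,
    target_power: float = 0.9,
    alpha: float = 0.05,
    n_max: int = 100000,
) -> int:
    """Smallest n whose agreement power reaches ``target_power``."""
    for n in range(2, n_max + 1):
        if ba_agreement_power(n, mean_diff, sd_diff, max_allowed_diff, alpha) >= target_power:
            return n
    raise ValueError(f"target power {target_power} not reached by n = {n_max}")


# --------------------------------------------------------------------------
# ICC, McNemar, correlations
# --------------------------------------------------------------------------


def icc_two_way_mixed(table: np.ndarray) -> tuple[float, float]:
    """ICC(A,1): two-way mixed model, absolute agreement, single measures.

    ``table`` is subjects x raters (complete). Mean squares come from the
    two-way ANOVA decomposition; ICC(A,1) =
    (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)), with the p-value
    from the F test of the subject effect (MSR / MSE).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] < 2:
        raise ValueError("table must be subjects x raters with >= 2 raters")
    if t.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(t)):
        raise ValueError("table must be complete (no missing cells)")
    n, k = t.shape
    grand = t.mean()
    row_means = t.mean(axis=1)
    col_means = t.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((t - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    if mse == 0:
        p = 0.0 if msr > 0 else 1.0
    else:
        f = msr / mse
        p = float(stats.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return float(icc), p


def mcnemar_test(b: int, c: int) -> float:
    """McNemar's test on the discordant counts of a paired 2x2 table.

    Exact two-tailed binomial test when b + c < MCNEMAR_EXACT_MAX, otherwise
    the chi-square statistic with continuity correction.
    """
    if b < 0 or c < 0 or b != int(b) or c != int(c):
        raise ValueError("discordant counts must be non-negative integers")
    if b + c == 0:
        return 1.0
    table = [[0, b], [c, 0]]
    exact = (b + c) < MCNEMAR_EXACT_MAX
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(min(res.pvalue, 1.0))


def pearson_bootstrap(
    x: np.ndarray,
    y: np.ndarray,
    strata: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Pearson r on pooled data with a stratified percentile bootstrap CI.

    Each resample draws subjects within each stratum (e.g. cardiac rhythm)
    with replacement, preserving stratum sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    if x.shape != y.shape or x.shape != strata.shape:
        raise ValueError("x, y, strata must have identical shapes")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for g in groups:
        if g.size < 3:
            raise ValueError("each stratum needs at least 3 observations")
    r = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = np.concatenate([g[rng.integers(0, g.size, g.size)] for g in groups])
        xb, yb = x[idx], y[idx]
        if np.std(xb) == 0 or np.std(yb) == 0:
            boot[i] = r
        else:
            boot[i] = np.corrcoef(xb, yb)[0, 1]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return r, (float(lo), float(hi))


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with t-approximate p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def bonferroni_adjust(p_values) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) for m comparisons."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(1.0, p.size * p)
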