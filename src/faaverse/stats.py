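"""Scalar statistics used throughout the multiverse.

Group contrasts use the Welch t-test (no equal-variance assumption) with
Cohen's d (pooled SD) as effect size; linear contrasts use OLS regression with
the t of the predictor of interest and Pearson r (or partial r when confounds
are controlled) as effect size.  Interval estimates are bias-corrected
accelerated (BCa) bootstrap CIs.  Evidence for the null is quantified with
default-prior Bayes factors: the Jeffreys-Zellner-Siow (JZS) t-test Bayes
factor with a Cauchy(0, 0.707) prior on the standardized effect, and the
stretched-beta (kappa = 1, i.e. uniform) prior correlation Bayes factor, both
inverted to favour the null (BF01).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

__all__ = [
    "TestResult",
    "welch_t",
    "cohen_d",
    "regression_t",
    "residualize",
    "bca_ci",
    "bf01_ttest",
    "bf01_correlation",
    "binomial_meta",
    "chi2_two_proportions",
    "levene",
]


@dataclass
class TestResult:
    """Outcome of one statistical test.

    ``effect_kind`` tags the scale of ``effect_size``: 'cohen_d', 'pearson_r'
    or 'partial_r'.  ``n`` is the per-group tuple for two-sample tests and the
    total for regressions.  ``bf01`` > 1 favours the null.
    """

    __test__ = False  # not a pytest class despite the Test* name

    statistic: float
    p: float
    df: float | tuple[float, float]
    effect_size: float | None = None
    effect_kind: str | None = None
    ci: tuple[float, float] | None = None
    n: int | tuple[int, ...] | None = None
    bf01: float | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p must be in [0, 1]")
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise ValueError("ci low must be <= high")
        if self.bf01 is not None and self.bf01 <= 0:
            raise ValueError("bf01 must be positive")


def cohen_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference (x minus y) with the pooled-SD denominator."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sample Welch t-test (x vs y) with Welch-Satterthwaite df.

    Effect size is Cohen's d with the pooled SD — the conventional pairing
    even though the test itself does not pool variances.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        df=float(res.df),
        effect_size=cohen_d(x, y),
        effect_kind="cohen_d",
        n=(len(x), len(y)),
    )


def _design_matrix(
    n: int, x: np.ndarray | None, confounds: np.ndarray | pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if x is not None:
        cols.append(np.asarray(x, float))
        names.append("x")
    if confounds is not None:
        conf = pd.DataFrame(confounds)
        for c in conf.columns:
            cols.append(conf[c].to_numpy(dtype=float))
            names.append(str(c))
    return np.column_stack(cols), names


def regression_t(
    y: Sequence[float],
    x: Sequence[float],
    confounds: pd.DataFrame | np.ndarray | None = None,
) -> TestResult:
    """OLS of y on x (plus optional confound columns), t of the x coefficient.

    Rows with a missing value in y, x or any confound are dropped listwise and
    counted in ``n_dropped``.  Effect size is Pearson r without confounds and
    the partial correlation r = t / sqrt(t^2 + df) with confounds.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    x = np.asarray(x, float)
    X, _ = _design_matrix(len(y), x, confounds)
    keep = np.isfinite(y) & np.isfinite(X).all(axis=1)
    n_dropped = int((~keep).sum())
    y, X = y[keep], X[keep]
    n, k = X.shape
    if n <= k:
        raise ValueError(f"too few rows (n={n}) for {k} parameters")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    t = float(fit.tvalues[1])
    df = float(fit.df_resid)
    if confounds is None:
        r = float(np.corrcoef(X[:, 1], y)[0, 1])
        kind = "pearson_r"
    else:
        r = float(t / np.sqrt(t * t + df))
        kind = "partial_r"
    return TestResult(
        statistic=t,
        p=float(fit.pvalues[1]),
        df=df,
        effect_size=r,
        effect_kind=kind,
        n=int(n),
        n_dropped=n_dropped,
    )


def residualize(
    y: np.ndarray, confounds: pd.DataFrame | np.ndarray
) -> np.ndarray:
    """OLS residuals of y on the confound columns (intercept always included).

    y may be 1-D (n,) or 2-D (n, features); residuals are orthogonal to every
    confound column.  Rows with missing confounds yield NaN residuals so the
    caller can apply its own drop rule.
    """
    y = np.asarray(y, float)
    y2 = y[:, None] if y.ndim == 1 else y
    X, _ = _design_matrix(y2.shape[0], None, confounds)
    keep = np.isfinite(X).all(axis=1) & np.isfinite(y2).all(axis=1)
    if keep.sum() <= X.shape[1]:
        raise ValueError("too few complete rows to residualize")
    Xk = X[keep]
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise ValueError("rank-deficient confound design")
    beta, *_ = np.linalg.lstsq(Xk, y2[keep], rcond=None)
    out = np.full_like(y2, np.nan)
    out[keep] = y2[keep] - Xk @ beta
    return out[:, 0] if y.ndim == 1 else out


def bca_ci(
    data: np.ndarray | tuple[np.ndarray, ...],
    stat_fn: Callable[..., float],
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    paired: bool = False,
) -> tuple[float, float]:
    """Bias-corrected accelerated bootstrap CI for ``stat_fn(*data)``.

    ``data`` is one sample or a tuple of samples, resampled independently by
    default; ``paired=True`` resamples whole rows jointly (for correlations
    and regression effect sizes).  Deterministic given ``seed``.  A
    degenerate bootstrap distribution (all resample statistics equal)
    collapses to a point interval with a warning.
    """
    samples = (data,) if isinstance(data, np.ndarray) else tuple(data)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def _stat(*args, axis=-1):  # scipy passes resamples stacked on `axis`
        args = tuple(np.asarray(a) for a in args)
        if args[0].ndim == 1:
            return stat_fn(*args)
        try:  # axis-aware statistics (np.mean, ...) vectorize directly
            return np.asarray(stat_fn(*args, axis=axis))
        except TypeError:
            return np.array([
                stat_fn(*(np.take(a, i, axis=0) for a in args))
                for i in range(args[0].shape[0])
            ])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on degenerate BCa input
        try:
            res = sps.bootstrap(
                samples,
                _stat,
                n_resamples=n_boot,
                confidence_level=level,
                method="BCa",
                vectorized=True,
                paired=paired,
                rng=rng,
            )
        except Exception:
            point = float(stat_fn(*samples))
            warnings.warn("degenerate bootstrap distribution; point interval")
            return (point, point)
    low, high = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if np.isnan(low) or np.isnan(high):
        point = float(stat_fn(*samples))
        warnings.warn("degenerate bootstrap distribution; point interval")
        return (point, point)
    return (low, high)


# ---------------------------------------------------------------------------
# Bayes factors


def jzs_bf10_from_t(t: float, nx: int, ny: int | None = None, r_scale: float = 0.707) -> float:
    """JZS Bayes factor BF10 from a t statistic (Cauchy prior scale r_scale).

    One-sample when ``ny`` is None; otherwise independent two-sample.  The
    alternative places a Cauchy(0, r_scale) prior on the standardized effect,
    integrated out via the equivalent inverse-gamma mixture over the g-prior.
    """
    if ny is None:
        neff, df = float(nx), nx - 1.0
    else:
        neff, df = nx * ny / (nx + ny), nx + ny - 2.0
    t2 = t * t
    r2 = r_scale * r_scale

    def integrand(g: float) -> float:
        m = 1.0 + neff * g
        like = m ** -0.5 * (1.0 + t2 / (m * df)) ** (-(df + 1.0) / 2.0)
        prior = np.sqrt(r2 / (2.0 * np.pi)) * g ** -1.5 * np.exp(-r2 / (2.0 * g))
        return like * prior

    num, _ = integrate.quad(integrand, 0, np.inf, epsabs=0, epsrel=1e-10, limit=400)
    den = (1.0 + t2 / df) ** (-(df + 1.0) / 2.0)
    return float(num / den)


def bf01_ttest(
    x: Sequence[float], y: Sequence[float] | None = None, r_scale: float = 0.707
) -> float:
    """BF01 (evidence for the null) for a one- or two-sample t-test."""
    x = np.asarray(x, float)
    if y is None:
        if len(x) < 2 or x.var(ddof=1) == 0:
            raise ValueError("need n >= 2 and nonzero variance")
        t = float(sps.ttest_1samp(x, 0.0).statistic)
        bf10 = jzs_bf10_from_t(t, len(x), None, r_scale)
    else:
        y = np.asarray(y, float)
        res = welch_t(x, y)  # validates inputs
        # BF uses the pooled-variance t, the statistic the JZS model assumes.
        t = float(sps.ttest_ind(x, y, equal_var=True).statistic)
        bf10 = jzs_bf10_from_t(t, len(x), len(y), r_scale)
    return 1.0 / bf10


def _log_corr_density_kernel(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """log of the rho-dependent part of the sampling density of Pearson r."""
    rho = np.asarray(rho, float)
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    return (
        (n - 1.0) / 2.0 * np.log1p(-rho * rho)
        + (1.5 - n) * np.log1p(-rho * r)
        + np.log(hyp)
    )


def bf01_correlation(x: Sequence[float], y: Sequence[float], kappa: float = 1.0) -> float:
    """BF01 for a Pearson correlation under a stretched-beta(1/kappa) prior.

    kappa = 1 is the default uniform prior on rho in (-1, 1).  Computed by
    numerically integrating Hotelling's exact sampling density of r over the
    prior; constants independent of rho cancel against the null density.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need n >= 4")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    a = 1.0 / kappa  # stretched-beta shape

    def integrand(rho: float) -> float:
        prior = sps.beta.pdf((rho + 1.0) / 2.0, a, a) / 2.0
        return np.exp(_log_corr_density_kernel(rho, r, n)) * prior

    num, _ = integrate.quad(integrand, -1, 1, epsabs=0, epsrel=1e-10, limit=400)
    den = np.exp(_log_corr_density_kernel(np.array(0.0), r, n))
    return float(den / num)


# ---------------------------------------------------------------------------
# Counts and variances


def binomial_meta(k: int, n: int, p0: float = 0.05) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0).

    The meta-test over the multiverse: is the number of significant analyses
    larger than expected by chance at the row-level alpha?
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return float(sps.binom.sf(k - 1, n, p0))


def chi2_two_proportions(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Pearson chi-square (df = 1, no continuity correction) for two proportions.

    Compares k1/n1 vs k2/n2 via the 2x2 table of counts.  Used as the
    follow-up asymmetry check on significant clusters (left vs right share of
    cluster membership).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("each margin needs n >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], float)
    if (table.sum(axis=0) == 0).any():
        raise ValueError("empty margin in 2x2 table")
    p1, p2 = k1 / n1, k2 / n2
    if p1 == p2:
        chi2 = 0.0  # exact zero, avoids float fuzz in the general formula
    else:
        chi2, _, _, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(
        statistic=float(chi2),
        p=float(sps.chi2.sf(chi2, 1)),
        df=1.0,
        n=(int(n1), int(n2)),
    )


def levene(groups: Sequence[Sequence[float]]) -> TestResult:
    """Levene test on absolute deviations from group means.

    Gate for pooling studies: rejects when the scale of the values differs
    across studies.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    w, p = sps.levene(*groups, center="mean")
    k = len(groups)
    n = sum(len(g) for g in groups)
    return TestResult(statistic=float(w), p=float(p), df=(k - 1.0, float(n - k)), n=int(n))
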