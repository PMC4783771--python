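"""Log-linear growth fits and first-principles statistical comparisons.

The test statistics here (Pearson chi-square on a 2x2 table, Welch t,
normal slope contrast) are computed by this module from their defining
formulas; only the tail probabilities of the reference distributions come
from scipy.  All p-values are two-sided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _stats

from .errors import BootstrapError, ComparisonError, FitError, StatTestError


@dataclass(frozen=True)
class LogLinearFit:
    """OLS fit of ln(count) on time (hours); slope is a net rate per hour."""

    slope: float
    intercept: float
    slope_se: Optional[float]
    n_points: int
    r2: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise FitError("a log-linear fit needs at least 2 points")
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise FitError(f"r2 out of [0, 1]: {self.r2}")
        if self.slope_se is not None and self.slope_se < 0:
            raise FitError("slope_se must be >= 0")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test.

    ``df`` is ``inf`` for the normal (z) slope contrast, which has no
    finite degrees of freedom.
    """

    statistic: float
    df: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise StatTestError(f"p-value out of [0, 1]: {self.p_value}")
        if self.df < 1:
            raise StatTestError(f"df must be >= 1, got {self.df}")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df if math.isfinite(self.df) else None,
            "p_value": self.p_value,
        }


# ---------------------------------------------------------------------------
# Growth-curve fitting
# ---------------------------------------------------------------------------


def loglinear_fit(times: Sequence[float], counts: Sequence[float]) -> LogLinearFit:
    """Fit ln(count) = intercept + slope * time by ordinary least squares.

    Non-positive counts are dropped (with their times) before fitting; at
    least two positive counts are required.  ``slope_se`` is the usual OLS
    standard error and is missing (None) for a two-point fit, which has no
    residual degrees of freedom.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(counts, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise FitError("times and counts must be 1-D vectors of equal length")
    keep = y > 0
    t, y = t[keep], np.log(y[keep])
    n = int(t.size)
    if n < 2:
        raise FitError(f"need >= 2 positive counts to fit, got {n}")
    t_bar, y_bar = t.mean(), y.mean()
    sxx = float(np.sum((t - t_bar) ** 2))
    if sxx == 0.0:
        raise FitError("all usable points share one time value; slope undefined")
    sxy = float(np.sum((t - t_bar) * (y - y_bar)))
    slope = sxy / sxx
    intercept = y_bar - slope * t_bar
    resid = y - (intercept + slope * t)
    ssr = float(np.sum(resid**2))
    syy = float(np.sum((y - y_bar) ** 2))
    r2 = 1.0 if syy == 0.0 else max(0.0, min(1.0, 1.0 - ssr / syy))
    slope_se = None if n == 2 else math.sqrt(max(ssr, 0.0) / (n - 2) / sxx)
    return LogLinearFit(slope=slope, intercept=intercept, slope_se=slope_se,
                        n_points=n, r2=r2)


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------


def compare_slopes(fit_a: LogLinearFit, fit_b: LogLinearFit) -> TestResult:
    """Normal contrast of two independent slopes: z = (a - b)/sqrt(se_a^2 + se_b^2)."""
    if fit_a.slope_se is None or fit_b.slope_se is None:
        raise ComparisonError(
            "both fits need a slope standard error; for two-point fits use a "
            "replicate-level bootstrap instead"
        )
    denom = math.hypot(fit_a.slope_se, fit_b.slope_se)
    if denom == 0.0:
        if fit_a.slope == fit_b.slope:
            return TestResult(0.0, math.inf, 1.0, "slope-contrast-z")
        raise ComparisonError("zero standard errors with unequal slopes")
    z = (fit_a.slope - fit_b.slope) / denom
    p = 2.0 * float(_stats.norm.sf(abs(z)))
    return TestResult(z, math.inf, min(p, 1.0), "slope-contrast-z")


def compare_replicate_slopes(slopes_a: Sequence[float],
                             slopes_b: Sequence[float]) -> TestResult:
    """Slope contrast built from per-replicate slopes (mean +/- s.e.m. per group)."""
    a = np.asarray(list(slopes_a), float)
    b = np.asarray(list(slopes_b), float)
    if a.size < 2 or b.size < 2:
        raise ComparisonError("need >= 2 replicate slopes per group")
    fit_a = LogLinearFit(float(a.mean()), 0.0, float(a.std(ddof=1) / math.sqrt(a.size)),
                         int(a.size), 1.0)
    fit_b = LogLinearFit(float(b.mean()), 0.0, float(b.std(ddof=1) / math.sqrt(b.size)),
                         int(b.size), 1.0)
    return compare_slopes(fit_a, fit_b)


def endpoint_welch_t(reps_a: Sequence[float], reps_b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test on end-point counts, two-sided."""
    a = np.asarray(list(reps_a), float)
    b = np.asarray(list(reps_b), float)
    if a.size < 2 or b.size < 2:
        raise StatTestError("each group needs >= 2 end-point values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        warnings.warn("both groups are constant and equal; t = 0 by convention",
                      UserWarning, stacklevel=2)
        return TestResult(0.0, float(na + nb - 2), 1.0, "welch-t")
    t = float((a.mean() - b.mean()) / math.sqrt(se2))
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(_stats.t.sf(abs(t), df))
    return TestResult(t, float(df), min(p, 1.0), "welch-t")


def chi2_2x2(k1: int, n1: int, k2: int, n2: int, *, yates: bool = False) -> TestResult:
    """Pearson chi-square on the 2x2 table [[k1, n1-k1], [k2, n2-k2]], df = 1.

    No continuity correction by default (the scored denominators this is
    meant for are >= 1000, where it is negligible); pass ``yates=True`` for
    the corrected statistic.  A zero column margin yields statistic 0 and
    p = 1 with a warning.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise StatTestError("each group must have n >= 1")
        if not (0 <= k <= n):
            raise StatTestError(f"need 0 <= k <= n, got k={k}, n={n}")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    col = obs.sum(axis=0)
    if np.any(col == 0):
        warnings.warn("a column margin is zero; chi-square is degenerate",
                      UserWarning, stacklevel=2)
        return TestResult(0.0, 1.0, 1.0, "chi2-2x2")
    row = obs.sum(axis=1)
    total = obs.sum()
    expected = np.outer(row, col) / total
    dev = np.abs(obs - expected)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float(np.sum(dev**2 / expected))
    p = float(_stats.chi2.sf(stat, df=1))
    return TestResult(stat, 1.0, min(p, 1.0), "chi2-2x2" + ("-yates" if yates else ""))


# ---------------------------------------------------------------------------
# Bootstrap support
# ---------------------------------------------------------------------------


def bootstrap_percentile_ci(
    values_fn: Callable[[np.random.Generator], float],
    B: int,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Percentile bootstrap interval from B seeded calls to ``values_fn``.

    ``values_fn`` receives the shared Generator and must return one
    resampled statistic per call; the (alpha/2, 1 - alpha/2) empirical
    quantiles of the B values are returned.  Deterministic given ``seed``.
    """
    if B < 1:
        raise BootstrapError("B must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise BootstrapError("alpha must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.empty(B, dtype=float)
    for i in range(B):
        try:
            values[i] = values_fn(rng)
        except Exception as exc:  # noqa: BLE001 - context added, then re-raised
            raise BootstrapError(f"resampler failed at iteration {i}: {exc}") from exc
    low, high = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)
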