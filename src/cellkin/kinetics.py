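"""Deterministic birth-death kinetics and growth-curve reconciliation.

The model is continuous-time exponential birth-death, dN/dt = (b - d) N.
Per-hour rates are obtained from occupancy indices (fraction of scored
cells inside a phase of known duration):

* ``flux`` convention: index = rate x window, exact for a stationary age
  profile over a short window.  Always used for death, because apoptotic
  cells are terminal.
* ``age_structured`` convention (mitosis only): for an exponentially
  growing age-structured population with cycle time T_c = ln2 / b, the
  fraction of cells inside a terminal phase of duration T_M is
  2^(T_M / T_c) - 1; both conventions agree to first order for small
  indices.

Reconciliation compares the net rate predicted from indices, k_pred =
b - d_detected, with the net rate observed in growth curves, k_obs (mean
per-replicate log-linear slope).  The gap d_excess = k_pred - k_obs is the
death rate the index assay failed to see; its uncertainty comes from a
percentile bootstrap that resamples replicates and re-draws the binomial
index counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .assay_model import GrowthCurve, IndexMeasurement, KineticConstants
from .errors import DataValidationError, PairingError, ReconciliationError
from .growth_stats import bootstrap_percentile_ci, loglinear_fit

LN2 = math.log(2.0)

CONVENTIONS = ("flux", "age_structured")


def _check_convention(convention: str) -> None:
    if convention not in CONVENTIONS:
        raise DataValidationError(
            f"unknown convention {convention!r}; expected one of {CONVENTIONS}"
        )


@dataclass(frozen=True)
class KineticRates:
    """Per-hour birth and detected-death rates; k_pred = b - d_detected."""

    b: float
    d_detected: float
    convention: str = "flux"

    def __post_init__(self) -> None:
        _check_convention(self.convention)
        if self.b < 0 or self.d_detected < 0:
            raise DataValidationError("rates must be >= 0 per hour")

    @property
    def k_pred(self) -> float:
        return self.b - self.d_detected


@dataclass(frozen=True)
class ReconciliationReport:
    """Predicted vs observed net growth rate for one (cell_line, condition)."""

    cell_line: str
    condition: str
    k_obs: float
    k_pred: float
    ci_low: float
    ci_high: float
    B: int
    seed: Optional[int]
    convention: str
    T_M_h: float
    T_A_h: float

    @property
    def d_excess(self) -> float:
        """Death rate unaccounted for by the detected-death assay, per hour."""
        return self.k_pred - self.k_obs

    @property
    def hidden_death_flag(self) -> bool:
        """True iff the bootstrap CI on d_excess excludes zero from below."""
        return self.ci_low > 0.0

    def to_dict(self) -> dict:
        return {
            "cell_line": self.cell_line,
            "condition": self.condition,
            "k_obs_per_h": self.k_obs,
            "k_pred_per_h": self.k_pred,
            "d_excess_per_h": self.d_excess,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "B": self.B,
            "seed": self.seed,
            "hidden_death_flag": self.hidden_death_flag,
            "convention": self.convention,
            "T_M_h": self.T_M_h,
            "T_A_h": self.T_A_h,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReconciliationReport":
        return cls(
            cell_line=d["cell_line"],
            condition=d["condition"],
            k_obs=d["k_obs_per_h"],
            k_pred=d["k_pred_per_h"],
            ci_low=d["ci_low"],
            ci_high=d["ci_high"],
            B=d["B"],
            seed=d["seed"],
            convention=d["convention"],
            T_M_h=d["T_M_h"],
            T_A_h=d["T_A_h"],
        )


# ---------------------------------------------------------------------------
# Index <-> rate conversions
# ---------------------------------------------------------------------------


def index_from_rate(rate: float, window: float, convention: str = "flux") -> float:
    """Expected index fraction for a per-hour rate and phase window (hours)."""
    _check_convention(convention)
    if rate < 0:
        raise DataValidationError("rate must be >= 0 per hour")
    if window <= 0:
        raise DataValidationError("window must be > 0 hours")
    if convention == "flux":
        index = rate * window
        if index >= 1.0:
            warnings.warn(
                f"flux index {index:.3g} >= 1; capped at 1 (rate x window too large)",
                UserWarning,
                stacklevel=2,
            )
            return 1.0
        return index
    # age_structured: 2^(T_M / T_c) - 1 with T_c = ln2 / rate
    return float(2.0 ** (window * rate / LN2) - 1.0)


def rate_from_index(index: float, window: float, convention: str = "flux") -> float:
    """Per-hour rate implied by an observed index fraction; inverse of
    :func:`index_from_rate` (exact roundtrip in both conventions)."""
    _check_convention(convention)
    if index < 0:
        raise DataValidationError("index must be >= 0")
    if window <= 0:
        raise DataValidationError("window must be > 0 hours")
    if convention == "flux":
        if index >= 1.0:
            warnings.warn(
                f"flux index {index:.3g} >= 1 implies phase occupancy beyond the "
                "whole window; rate computed anyway",
                UserWarning,
                stacklevel=2,
            )
        return index / window
    return math.log1p(index) / window


def predicted_rates(
    mi: IndexMeasurement,
    ai: IndexMeasurement,
    constants: KineticConstants,
    convention: str = "flux",
) -> KineticRates:
    """Convert paired mitotic and apoptotic indices into kinetic rates.

    The mitotic index uses the requested convention; the apoptotic index is
    always converted with the flux rule (death is terminal, so there is no
    age-structured enrichment of dying cells).
    """
    if mi.kind != "mitotic" or ai.kind != "apoptotic":
        raise PairingError(
            f"expected (mitotic, apoptotic) measurements, got ({mi.kind}, {ai.kind})"
        )
    if mi.group != ai.group:
        raise PairingError(
            f"group labels differ: {mi.group} vs {ai.group}"
        )
    b = rate_from_index(mi.fraction, constants.T_M_h, convention)
    d = rate_from_index(ai.fraction, constants.T_A_h, "flux")
    return KineticRates(b=b, d_detected=d, convention=convention)


# ---------------------------------------------------------------------------
# Deterministic growth model
# ---------------------------------------------------------------------------


def predict_curve(N0: float, k: float, times) -> np.ndarray:
    """Closed-form exponential growth N(t) = N0 * exp(k t) at the given hours."""
    if N0 < 0:
        raise DataValidationError("N0 must be >= 0")
    t = np.asarray(times, dtype=float)
    if t.ndim == 1 and t.size > 1 and np.any(np.diff(t) < 0):
        raise DataValidationError("times must be ascending")
    return N0 * np.exp(k * t)


def doubling_time(k: float) -> float:
    """ln2 / k hours; +inf at k = 0, negative ("halving time") for k < 0."""
    if k == 0.0:
        return math.inf
    return LN2 / k


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------


def replicate_slopes(curve: GrowthCurve) -> np.ndarray:
    """Per-replicate log-linear slopes, replicate-id order, zero counts dropped.

    Replicates with fewer than two positive counts are excluded with a
    warning; an empty result raises :class:`ReconciliationError`.
    """
    slopes = []
    for rep in sorted(curve.counts):
        counts = curve.counts[rep]
        if int(np.sum(counts > 0)) < 2:
            warnings.warn(
                f"replicate {rep!r} of {curve.cell_line}/{curve.condition} has "
                "< 2 positive counts and is excluded from the slope fit",
                UserWarning,
                stacklevel=2,
            )
            continue
        slopes.append(loglinear_fit(curve.times, counts).slope)
    if not slopes:
        raise ReconciliationError(
            f"no usable replicate in {curve.cell_line}/{curve.condition}"
        )
    return np.asarray(slopes, dtype=float)


def reconcile_growth(
    curve: GrowthCurve,
    mi: IndexMeasurement,
    ai: IndexMeasurement,
    constants: KineticConstants,
    convention: str = "flux",
    B: int = 2000,
    seed: Optional[int] = None,
    alpha: float = 0.05,
) -> ReconciliationReport:
    """Quantify the death rate needed to reconcile indices with observed growth.

    k_obs is the mean of per-replicate OLS slopes of ln(count) on time;
    k_pred comes from :func:`predicted_rates`.  Each of the B bootstrap
    iterations resamples replicates with replacement and re-draws the index
    counts k* ~ Binomial(n, k/n), then recomputes the full chain, giving a
    percentile CI on d_excess = k_pred - k_obs.
    """
    if B < 1:
        raise ReconciliationError("B must be >= 1")
    if curve.group != mi.group or curve.group != ai.group:
        raise PairingError(
            f"curve group {curve.group} does not match index groups "
            f"{mi.group} / {ai.group}"
        )
    slopes = replicate_slopes(curve)
    k_obs = float(slopes.mean())
    rates = predicted_rates(mi, ai, constants, convention)

    p_mi = mi.fraction
    p_ai = ai.fraction
    n_reps = slopes.size

    def _resample(rng: np.random.Generator) -> float:
        idx = rng.integers(0, n_reps, size=n_reps)
        k_obs_star = float(slopes[idx].mean())
        mi_star = rng.binomial(mi.total, p_mi) / mi.total
        ai_star = rng.binomial(ai.total, p_ai) / ai.total
        b_star = rate_from_index(mi_star, constants.T_M_h, convention)
        d_star = ai_star / constants.T_A_h  # flux rule for death, inlined
        return (b_star - d_star) - k_obs_star

    with warnings.catch_warnings():
        # index >= 1 warnings inside the hot loop would repeat B times
        warnings.simplefilter("ignore", UserWarning)
        ci_low, ci_high = bootstrap_percentile_ci(_resample, B=B, alpha=alpha, seed=seed)

    return ReconciliationReport(
        cell_line=curve.cell_line,
        condition=curve.condition,
        k_obs=k_obs,
        k_pred=rates.k_pred,
        ci_low=ci_low,
        ci_high=ci_high,
        B=B,
        seed=seed if seed is None or isinstance(seed, int) else None,
        convention=convention,
        T_M_h=constants.T_M_h,
        T_A_h=constants.T_A_h,
    )
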