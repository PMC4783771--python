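"""Synthetic datasets with the measurement structure the pipeline assumes.

Ground truth is a linear birth-death process per (cell_line, condition):
division at rate b, detectable death at rate d_detected, plus a second,
assay-invisible removal channel d_hidden (detached / necrotic cells that
leave the well without acquiring the apoptosis marker).  The population is
observed through the study's instruments:

* hemocytometer counting -- Poisson counts in a small sampled fraction of
  the well, averaged over several chambers;
* index scoring -- Binomial(n_scored, expected index) draws for the
  mitotic and apoptotic indices; the hidden channel contributes nothing to
  the apoptotic index, which is the point of the recovery experiment;
* daily observation over a configurable span (default days 0-6).

Small populations are simulated with an exact Gillespie algorithm; large
ones (default N0 > 5000) use the deterministic expectation N0*exp((b-d)t),
whose per-cell fluctuations are negligible next to counting noise at that
scale.  Each (group, replicate, instrument) tuple gets its own RNG stream
derived from the scenario seed, so adding a replicate or group never
perturbs existing draws.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assay_model import (
    GROWTH_COLUMNS,
    INDEX_COLUMNS,
    IndexMeasurement,
    KineticConstants,
)
from .errors import GenerationError
from .kinetics import index_from_rate

GroupKey = Tuple[str, str]

#: Above this initial population the generator defaults to the
#: deterministic-expectation fast path instead of event-level Gillespie.
GILLESPIE_N0_LIMIT = 5000


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParams:
    """Ground-truth kinetics for one (cell_line, condition)."""

    b: float
    d_detected: float
    d_hidden: float
    N0: float
    T_M_h: float = 1.0
    T_A_h: float = 3.0

    def __post_init__(self) -> None:
        if min(self.b, self.d_detected, self.d_hidden) < 0:
            raise GenerationError("rates must all be >= 0 per hour")
        if self.N0 <= 0:
            raise GenerationError("N0 must be > 0")
        if self.T_M_h <= 0 or self.T_A_h <= 0:
            raise GenerationError("T_M_h and T_A_h must be > 0 hours")

    @property
    def d_total(self) -> float:
        return self.d_detected + self.d_hidden

    @property
    def k_true(self) -> float:
        """Net growth rate actually experienced by the population."""
        return self.b - self.d_total

    def constants(self) -> KineticConstants:
        return KineticConstants(T_M_h=self.T_M_h, T_A_h=self.T_A_h)


@dataclass(frozen=True)
class SamplingConfig:
    """Observation-process parameters shared by all groups."""

    n_scored: int = 1000
    n_chambers: int = 4
    chamber_fraction: float = 1e-4
    days: Tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    replicates: int = 3
    index_time_h: float = 24.0
    mi_convention: str = "flux"
    growth_model: str = "auto"  # auto | gillespie | deterministic

    def __post_init__(self) -> None:
        if self.n_scored < 1:
            raise GenerationError("n_scored must be >= 1")
        if self.n_chambers < 1:
            raise GenerationError("n_chambers must be >= 1")
        if not (0.0 < self.chamber_fraction <= 1.0):
            raise GenerationError("chamber_fraction must lie in (0, 1]")
        if self.replicates < 1:
            raise GenerationError("replicates must be >= 1")
        if len(self.days) == 0 or any(d < 0 for d in self.days):
            raise GenerationError("days must be a non-empty list of ints >= 0")
        if self.growth_model not in ("auto", "gillespie", "deterministic"):
            raise GenerationError(
                f"growth_model must be auto|gillespie|deterministic, "
                f"got {self.growth_model!r}"
            )
        if self.mi_convention not in ("flux", "age_structured"):
            raise GenerationError("mi_convention must be flux or age_structured")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full ground truth for one synthetic dataset."""

    groups: Dict[GroupKey, GroupParams]
    seed: int
    sampling: SamplingConfig = field(default_factory=SamplingConfig)

    def __post_init__(self) -> None:
        if not self.groups:
            raise GenerationError("scenario needs at least one (cell_line, condition)")

    @classmethod
    def from_dict(cls, cfg: dict) -> "ScenarioConfig":
        """Build from the config-file layout (``groups`` list + ``sampling``)."""
        try:
            seed = int(cfg["seed"])
        except (KeyError, TypeError, ValueError) as exc:
            raise GenerationError("scenario config requires an integer 'seed'") from exc
        sampling_cfg = dict(cfg.get("sampling") or {})
        if "days" in sampling_cfg:
            sampling_cfg["days"] = tuple(int(d) for d in sampling_cfg["days"])
        sampling = SamplingConfig(**sampling_cfg)
        groups: Dict[GroupKey, GroupParams] = {}
        for entry in cfg.get("groups", []):
            key = (str(entry["cell_line"]), str(entry["condition"]))
            if key in groups:
                raise GenerationError(f"duplicate scenario group {key}")
            groups[key] = GroupParams(
                b=float(entry["b"]),
                d_detected=float(entry.get("d_detected", 0.0)),
                d_hidden=float(entry.get("d_hidden", 0.0)),
                N0=float(entry["N0"]),
                T_M_h=float(entry.get("T_M_h", 1.0)),
                T_A_h=float(entry.get("T_A_h", 3.0)),
            )
        return cls(groups=groups, seed=seed, sampling=sampling)

    def truth_dict(self) -> dict:
        """Ground truth as a JSON-serializable document."""
        return {
            "seed": self.seed,
            "sampling": {
                "n_scored": self.sampling.n_scored,
                "n_chambers": self.sampling.n_chambers,
                "chamber_fraction": self.sampling.chamber_fraction,
                "days": list(self.sampling.days),
                "replicates": self.sampling.replicates,
                "index_time_h": self.sampling.index_time_h,
                "mi_convention": self.sampling.mi_convention,
                "growth_model": self.sampling.growth_model,
            },
            "groups": [
                {
                    "cell_line": line,
                    "condition": cond,
                    "b": gp.b,
                    "d_detected": gp.d_detected,
                    "d_hidden": gp.d_hidden,
                    "N0": gp.N0,
                    "T_M_h": gp.T_M_h,
                    "T_A_h": gp.T_A_h,
                }
                for (line, cond), gp in sorted(self.groups.items())
            ],
        }


# ---------------------------------------------------------------------------
# Seed-stream derivation
# ---------------------------------------------------------------------------


def stream_rng(seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator for a named stream.

    Keys (labels, replicate indices, stream names) are hashed individually,
    so streams are independent of enumeration order: adding a replicate or
    group leaves every existing stream untouched.
    """
    entropy = [int(seed) & 0xFFFFFFFF] + [
        zlib.crc32(str(k).encode("utf-8")) for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Stochastic growth
# ---------------------------------------------------------------------------


def simulate_birth_death(
    N0: int,
    b: float,
    d_total: float,
    t_end: float,
    seed=None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Exact Gillespie simulation of a linear birth-death process.

    Each of N cells independently divides at rate b and dies at rate
    d_total, so the next event time is Exponential(N (b + d)) and the event
    is a birth with probability b / (b + d).  Returns event times (starting
    at 0) and population sizes after each event; the trajectory is a step
    function.  Extinction simply ends the event sequence at 0.
    """
    if N0 < 0:
        raise GenerationError("N0 must be >= 0")
    if b < 0 or d_total < 0:
        raise GenerationError("rates must be >= 0")
    if t_end < 0:
        raise GenerationError("t_end must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    times = [0.0]
    sizes = [int(N0)]
    n = int(N0)
    total_rate_per_cell = b + d_total
    if n == 0 or total_rate_per_cell == 0.0 or t_end == 0.0:
        return np.asarray(times), np.asarray(sizes)

    p_birth = b / total_rate_per_cell
    t = 0.0
    block = 8192
    exp_draws = rng.exponential(size=block)
    uni_draws = rng.random(size=block)
    i = 0
    while n > 0:
        if i == block:
            exp_draws = rng.exponential(size=block)
            uni_draws = rng.random(size=block)
            i = 0
        t += exp_draws[i] / (n * total_rate_per_cell)
        if t > t_end:
            break
        n += 1 if uni_draws[i] < p_birth else -1
        i += 1
        times.append(t)
        sizes.append(n)
    return np.asarray(times), np.asarray(sizes)


def population_at(times: np.ndarray, sizes: np.ndarray, t: float) -> int:
    """Population size of a step-function trajectory at time t (>= 0)."""
    idx = int(np.searchsorted(times, t, side="right")) - 1
    return int(sizes[max(idx, 0)])


# ---------------------------------------------------------------------------
# Observation layer
# ---------------------------------------------------------------------------


def sample_hemocytometer(
    true_count: float,
    chamber_fraction: float = 1e-4,
    n_chambers: int = 4,
    seed=None,
) -> float:
    """Estimate cells/well from Poisson chamber counts averaged over chambers.

    Each chamber sees an independent Poisson(true_count * chamber_fraction)
    number of cells; the chamber mean divided by the sampled fraction is an
    unbiased estimate of the well count, with variance shrinking as
    1/n_chambers.
    """
    if true_count < 0:
        raise GenerationError("true_count must be >= 0")
    if not (0.0 < chamber_fraction <= 1.0):
        raise GenerationError("chamber_fraction must lie in (0, 1]")
    if n_chambers < 1:
        raise GenerationError("n_chambers must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.poisson(true_count * chamber_fraction, size=n_chambers)
    return float(counts.mean() / chamber_fraction)


def sample_index(
    rate: float,
    window: float,
    n_scored: int,
    convention: str = "flux",
    seed=None,
    *,
    kind: str = "mitotic",
    cell_line: str = "synthetic",
    condition: str = "standard",
) -> IndexMeasurement:
    """Draw a scored index: positives ~ Binomial(n_scored, expected index)."""
    if n_scored < 1:
        raise GenerationError("n_scored must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = index_from_rate(rate, window, convention)  # warns + caps at 1 under flux
    p = min(p, 1.0)
    positives = int(rng.binomial(n_scored, p))
    return IndexMeasurement(
        kind=kind,
        positives=positives,
        total=n_scored,
        cell_line=cell_line,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _true_count_fn(gp: GroupParams, sampling: SamplingConfig, rng: np.random.Generator):
    """Return a callable t -> true well population for one replicate."""
    use_gillespie = sampling.growth_model == "gillespie" or (
        sampling.growth_model == "auto" and gp.N0 <= GILLESPIE_N0_LIMIT
    )
    t_end = 24.0 * max(max(sampling.days), 0) + 1e-9
    if use_gillespie:
        times, sizes = simulate_birth_death(int(round(gp.N0)), gp.b, gp.d_total, t_end, rng)
        return lambda t: float(population_at(times, sizes, t))
    return lambda t: float(gp.N0 * np.exp(gp.k_true * t))


def generate_dataset(
    config: ScenarioConfig,
    out_dir: Optional[str] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a full synthetic dataset in the pipeline's CSV schemas.

    For every (cell_line, condition, replicate): simulate growth with
    d_total = d_detected + d_hidden, observe it daily through the
    hemocytometer sampler, and draw one mitotic and one apoptotic index at
    ``index_time_h``.  The apoptotic sampler sees only d_detected -- the
    hidden channel removes cells without leaving an assay signature.

    Returns (growth table, index table, truth document); if ``out_dir`` is
    given, also writes ``growth.csv``, ``index.csv`` and ``truth.json``.
    """
    sampling = config.sampling
    growth_rows = []
    index_rows = []
    for (line, cond), gp in sorted(config.groups.items()):
        for r in range(1, sampling.replicates + 1):
            rep = f"r{r}"
            growth_rng = stream_rng(config.seed, line, cond, rep, "growth")
            hemo_rng = stream_rng(config.seed, line, cond, rep, "hemocytometer")
            mi_rng = stream_rng(config.seed, line, cond, rep, "mitotic")
            ai_rng = stream_rng(config.seed, line, cond, rep, "apoptotic")

            true_count = _true_count_fn(gp, sampling, growth_rng)
            for day in sampling.days:
                t = 24.0 * day
                observed = sample_hemocytometer(
                    true_count(t), sampling.chamber_fraction, sampling.n_chambers, hemo_rng
                )
                growth_rows.append((line, cond, rep, t, observed))

            mi = sample_index(
                gp.b, gp.T_M_h, sampling.n_scored, sampling.mi_convention, mi_rng,
                kind="mitotic", cell_line=line, condition=cond,
            )
            ai = sample_index(
                gp.d_detected, gp.T_A_h, sampling.n_scored, "flux", ai_rng,
                kind="apoptotic", cell_line=line, condition=cond,
            )
            index_rows.append((line, cond, rep, "mitotic", mi.positives, mi.total))
            index_rows.append((line, cond, rep, "apoptotic", ai.positives, ai.total))

    growth_df = pd.DataFrame(growth_rows, columns=GROWTH_COLUMNS)
    index_df = pd.DataFrame(index_rows, columns=INDEX_COLUMNS)
    truth = config.truth_dict()

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        growth_df.to_csv(os.path.join(out_dir, "growth.csv"), index=False)
        index_df.to_csv(os.path.join(out_dir, "index.csv"), index=False)
        with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
            fh.write(json.dumps(truth, indent=2, sort_keys=True) + "\n")

    return growth_df, index_df, truth
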