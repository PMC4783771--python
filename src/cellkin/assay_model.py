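"""Domain types, tidy-CSV input, JSON report output, and assay quantification.

This module owns the validated in-memory representation of the four assay
families the pipeline consumes:

* timed cell counts per well (growth curves),
* scored index measurements (mitotic / apoptotic: k positives of n cells),
* soft-agar colony size sets and matrigel invasion field counts,
* per-group kinetic constants (mitotic duration, death-detection window).

It also implements the quantification rules applied to raw assay output:
colony size filtering at a lower size limit, field-of-view summaries
(mean / s.e.m.), and conversion of nuclei-per-cm2 imaging densities to
cells per well.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    DataValidationError,
    DuplicateRecordError,
    SchemaError,
)

#: Closed set of recognised culture-condition labels.  Extra labels may be
#: admitted through the ``extra_conditions`` config key (a deliberate hook:
#: unknown labels are rejected rather than silently fragmenting groups).
DEFAULT_CONDITIONS: Tuple[str, ...] = ("standard", "serum_free", "fu5", "hypoxia")

#: Well area of a standard 6-well plate, cm^2; used to scale nuclei densities.
WELL_AREA_CM2: float = 9.6

#: Minimum number of cells that should be scored per index measurement.
MIN_SCORED_CELLS: int = 1000

#: Default lower size limit (um) for a structure to count as a colony.
DEFAULT_MIN_COLONY_SIZE_UM: float = 15.0

#: Expected number of imaged fields in an invasion record.
EXPECTED_INVASION_FIELDS: int = 6

GROWTH_COLUMNS: Tuple[str, ...] = ("cell_line", "condition", "replicate", "time_h", "count")
INDEX_COLUMNS: Tuple[str, ...] = ("cell_line", "condition", "replicate", "kind", "positives", "total")

GroupKey = Tuple[str, str]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GrowthCurve:
    """Timed cell counts for one cell line under one culture condition.

    ``counts`` maps a replicate id to a vector of cell counts per well,
    aligned with ``times`` (hours since the start of treatment).  Counts are
    stored as reals: hemocytometer values averaged over chambers are
    generally non-integer.
    """

    cell_line: str
    condition: str
    times: np.ndarray
    counts: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise DataValidationError("times must be a non-empty 1-D vector")
        if np.any(np.diff(self.times) <= 0):
            raise DataValidationError(
                f"times must be strictly ascending for {self.cell_line}/{self.condition}"
            )
        if not self.counts:
            raise DataValidationError(
                f"growth curve {self.cell_line}/{self.condition} has no replicates"
            )
        coerced: Dict[str, np.ndarray] = {}
        for rep, values in self.counts.items():
            arr = np.asarray(values, dtype=float)
            if arr.shape != self.times.shape:
                raise DataValidationError(
                    f"replicate {rep!r} of {self.cell_line}/{self.condition} has "
                    f"{arr.size} counts for {self.times.size} time points"
                )
            if np.any(arr < 0) or np.any(~np.isfinite(arr)):
                raise DataValidationError(
                    f"replicate {rep!r} of {self.cell_line}/{self.condition} "
                    "contains negative or non-finite counts"
                )
            coerced[rep] = arr
        self.counts = coerced

    @property
    def n_replicates(self) -> int:
        return len(self.counts)

    @property
    def group(self) -> GroupKey:
        return (self.cell_line, self.condition)

    def final_counts(self) -> np.ndarray:
        """Per-replicate counts at the last time point, in replicate-id order."""
        return np.array([self.counts[r][-1] for r in sorted(self.counts)])


@dataclass(frozen=True)
class IndexMeasurement:
    """k positives among n scored cells (mitotic or apoptotic index)."""

    kind: str
    positives: int
    total: int
    cell_line: str
    condition: str

    def __post_init__(self) -> None:
        if self.kind not in ("mitotic", "apoptotic"):
            raise DataValidationError(f"unknown index kind {self.kind!r}")
        if self.total < 1:
            raise DataValidationError("total scored cells must be >= 1")
        if not (0 <= self.positives <= self.total):
            raise DataValidationError(
                f"positives must lie in [0, total]; got {self.positives}/{self.total}"
            )
        if self.total < MIN_SCORED_CELLS:
            warnings.warn(
                f"{self.kind} index for {self.cell_line}/{self.condition} scored "
                f"only {self.total} cells (< {MIN_SCORED_CELLS})",
                UserWarning,
                stacklevel=2,
            )

    @property
    def fraction(self) -> float:
        """The index: positives / total."""
        return self.positives / self.total

    @property
    def group(self) -> GroupKey:
        return (self.cell_line, self.condition)


def pool_indices(measurements: Sequence[IndexMeasurement]) -> IndexMeasurement:
    """Pool replicate index measurements of one kind and group by summing counts."""
    if not measurements:
        raise DataValidationError("cannot pool an empty list of index measurements")
    first = measurements[0]
    for m in measurements[1:]:
        if m.kind != first.kind or m.group != first.group:
            raise DataValidationError(
                "pooled index measurements must share kind and (cell_line, condition)"
            )
    return IndexMeasurement(
        kind=first.kind,
        positives=sum(m.positives for m in measurements),
        total=sum(m.total for m in measurements),
        cell_line=first.cell_line,
        condition=first.condition,
    )


@dataclass(frozen=True)
class ColonySet:
    """Longest-axis colony sizes (um) from a soft-agar assay."""

    sizes: Tuple[float, ...]
    n_fields: int
    cell_line: str
    condition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(float(s) for s in self.sizes))
        if any(s <= 0 for s in self.sizes):
            raise DataValidationError("colony sizes must be > 0 um")
        if self.n_fields < 1:
            raise DataValidationError("n_fields must be >= 1")


@dataclass(frozen=True)
class InvasionRecord:
    """Per-field invasive cell counts from a matrigel assay."""

    field_counts: Tuple[int, ...]
    cell_line: str
    condition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "field_counts", tuple(int(c) for c in self.field_counts))
        if any(c < 0 for c in self.field_counts):
            raise DataValidationError("invasion field counts must be >= 0")
        if len(self.field_counts) != EXPECTED_INVASION_FIELDS:
            warnings.warn(
                f"invasion record for {self.cell_line}/{self.condition} has "
                f"{len(self.field_counts)} fields (expected {EXPECTED_INVASION_FIELDS})",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class KineticConstants:
    """Phase-duration constants: mitotic duration and death-detection window."""

    T_M_h: float = 1.0
    T_A_h: float = 3.0

    def __post_init__(self) -> None:
        if not (self.T_M_h > 0 and self.T_A_h > 0):
            raise DataValidationError("T_M_h and T_A_h must both be > 0 hours")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_GLOBAL_DEFAULTS = {
    "mi_convention": "flux",
    "min_colony_size_um": DEFAULT_MIN_COLONY_SIZE_UM,
    "bootstrap_B": 2000,
    "alpha": 0.05,
    "seed": None,
    "reference_line": None,
}


def load_config(path: str) -> dict:
    """Load a YAML or JSON config file and merge in global defaults.

    The returned dict always carries ``globals`` (defaults merged),
    ``groups`` (possibly empty list) and ``extra_conditions``.
    """
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        try:
            cfg = yaml.safe_load(fh)  # YAML is a superset of JSON
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse config {path}: {exc}") from exc
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping at top level")
    merged_globals = dict(_GLOBAL_DEFAULTS)
    merged_globals.update(cfg.get("globals") or {})
    cfg["globals"] = merged_globals
    cfg.setdefault("groups", [])
    cfg.setdefault("extra_conditions", [])
    if merged_globals["mi_convention"] not in ("flux", "age_structured"):
        raise ConfigError(
            f"mi_convention must be 'flux' or 'age_structured', "
            f"got {merged_globals['mi_convention']!r}"
        )
    return cfg


def allowed_conditions(config: Optional[Mapping] = None) -> Tuple[str, ...]:
    extra = tuple((config or {}).get("extra_conditions", ()))
    return DEFAULT_CONDITIONS + tuple(e for e in extra if e not in DEFAULT_CONDITIONS)


def constants_from_config(config: Mapping) -> Dict[GroupKey, KineticConstants]:
    """Per-(cell_line, condition) kinetic constants from the config's groups."""
    out: Dict[GroupKey, KineticConstants] = {}
    for entry in config.get("groups", []):
        try:
            key = (str(entry["cell_line"]), str(entry["condition"]))
        except KeyError as exc:
            raise ConfigError(f"group entry missing key {exc}") from exc
        out[key] = KineticConstants(
            T_M_h=float(entry.get("T_M_h", KineticConstants.T_M_h)),
            T_A_h=float(entry.get("T_A_h", KineticConstants.T_A_h)),
        )
    return out


# ---------------------------------------------------------------------------
# Tidy-CSV input
# ---------------------------------------------------------------------------


def _read_csv(path: str, required: Sequence[str], label: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise SchemaError(f"{label} CSV not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{label} CSV {path} is missing column(s): {', '.join(missing)}"
        )
    return df


def _check_condition(value: str, allowed: Sequence[str], row: int, path: str) -> None:
    if value not in allowed:
        raise DataValidationError(
            f"unknown condition {value!r} at row {row} of {path}; "
            f"allowed: {', '.join(allowed)}"
        )


def load_growth_csv(path: str, allowed: Sequence[str] = DEFAULT_CONDITIONS) -> List[GrowthCurve]:
    """Parse a tidy growth CSV (one row per observed count) into GrowthCurves."""
    df = _read_csv(path, GROWTH_COLUMNS, "growth")
    counts = pd.to_numeric(df["count"], errors="coerce")
    for idx in df.index[counts.isna()]:
        raise DataValidationError(f"non-numeric count at row {int(idx)} of {path}")
    for idx in df.index[counts < 0]:
        raise DataValidationError(f"negative count at row {int(idx)} of {path}")
    dup_key = ["cell_line", "condition", "replicate", "time_h"]
    dups = df.duplicated(subset=dup_key)
    if dups.any():
        row = int(df.index[dups][0])
        raise DuplicateRecordError(
            f"duplicate (cell_line, condition, replicate, time_h) at row {row} of {path}"
        )
    for idx, cond in df["condition"].items():
        _check_condition(str(cond), allowed, int(idx), path)

    curves: List[GrowthCurve] = []
    for (line, cond), grp in df.groupby(["cell_line", "condition"], sort=True):
        rep_series: Dict[str, pd.Series] = {}
        for rep, sub in grp.groupby("replicate", sort=True):
            sub = sub.sort_values("time_h")
            rep_series[str(rep)] = pd.Series(
                sub["count"].to_numpy(float), index=sub["time_h"].to_numpy(float)
            )
        time_grids = {tuple(s.index) for s in rep_series.values()}
        if len(time_grids) != 1:
            raise DataValidationError(
                f"replicates of {line}/{cond} in {path} do not share one time grid"
            )
        times = np.array(next(iter(time_grids)), dtype=float)
        curves.append(
            GrowthCurve(
                cell_line=str(line),
                condition=str(cond),
                times=times,
                counts={r: s.to_numpy() for r, s in rep_series.items()},
            )
        )
    return curves


def load_index_csv(path: str, allowed: Sequence[str] = DEFAULT_CONDITIONS) -> List[IndexMeasurement]:
    """Parse a tidy index CSV into per-row IndexMeasurements."""
    df = _read_csv(path, INDEX_COLUMNS, "index")
    out: List[IndexMeasurement] = []
    for idx, row in df.iterrows():
        _check_condition(str(row["condition"]), allowed, int(idx), path)
        try:
            positives = int(row["positives"])
            total = int(row["total"])
        except (TypeError, ValueError) as exc:
            raise DataValidationError(
                f"non-integer positives/total at row {int(idx)} of {path}"
            ) from exc
        try:
            out.append(
                IndexMeasurement(
                    kind=str(row["kind"]),
                    positives=positives,
                    total=total,
                    cell_line=str(row["cell_line"]),
                    condition=str(row["condition"]),
                )
            )
        except DataValidationError as exc:
            raise DataValidationError(f"row {int(idx)} of {path}: {exc}") from exc
    return out


def load_dataset(
    growth_csv_path: str,
    index_csv_path: str,
    config_path: str,
) -> Tuple[List[GrowthCurve], List[IndexMeasurement], Dict[GroupKey, KineticConstants]]:
    """Load and validate a full dataset.

    Returns validated growth curves, per-row index measurements, and the
    per-group kinetic constants declared in the config.  Groups present in
    the data but absent from the config fall back to default constants.
    """
    config = load_config(config_path)
    allowed = allowed_conditions(config)
    curves = load_growth_csv(growth_csv_path, allowed)
    indices = load_index_csv(index_csv_path, allowed)
    constants = constants_from_config(config)
    for curve in curves:
        constants.setdefault(curve.group, KineticConstants())
    return curves, indices, constants


def write_growth_csv(curves: Sequence[GrowthCurve], path: str) -> None:
    rows = []
    for c in curves:
        for rep in sorted(c.counts):
            for t, n in zip(c.times, c.counts[rep]):
                rows.append((c.cell_line, c.condition, rep, t, n))
    pd.DataFrame(rows, columns=GROWTH_COLUMNS).to_csv(path, index=False)


def write_index_csv(indices: Sequence[IndexMeasurement], path: str) -> None:
    # replicate ids are not carried by IndexMeasurement; emit positional ids
    rows = [
        (m.cell_line, m.condition, f"r{i + 1}", m.kind, m.positives, m.total)
        for i, m in enumerate(indices)
    ]
    pd.DataFrame(rows, columns=INDEX_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Assay quantification
# ---------------------------------------------------------------------------


def filter_colonies(
    colonies: ColonySet, min_size: float = DEFAULT_MIN_COLONY_SIZE_UM
) -> Tuple[ColonySet, int]:
    """Keep colonies whose longest axis is >= ``min_size`` um (inclusive).

    The threshold is inclusive so that structures exactly at the measured
    baseline size stay on the boundary.  Order is preserved; an empty input
    yields an empty output, not an error.
    """
    if min_size <= 0:
        raise DataValidationError("min_size must be > 0 um")
    kept_sizes = tuple(s for s in colonies.sizes if s >= min_size)
    kept = replace(colonies, sizes=kept_sizes)
    return kept, len(kept_sizes)


def summarize_fields(values: Sequence[float]) -> Tuple[float, Optional[float], int]:
    """Mean, s.e.m. and n of a list of per-field (or per-replicate) values.

    The s.e.m. uses the sample (n-1) standard deviation; it is reported as
    ``None`` (missing) when n = 1.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DataValidationError("no observations")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, None, 1
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size))
    return mean, sem, int(arr.size)


def nuclei_count_from_density(density: float, well_area: float = WELL_AREA_CM2) -> float:
    """Scale an imaged nuclei density (nuclei/cm^2) to whole-well cell count."""
    if density < 0:
        raise DataValidationError("nuclei density must be >= 0")
    if well_area <= 0:
        raise DataValidationError("well area must be > 0 cm^2")
    return density * well_area


# ---------------------------------------------------------------------------
# Report serialization (schema owned by kinetics.ReconciliationReport)
# ---------------------------------------------------------------------------


def write_report(reports: Sequence, path: str, tests: Optional[List[dict]] = None,
                 meta: Optional[dict] = None) -> None:
    """Serialize reconciliation reports (plus optional tests block) as JSON.

    Floats are written with full ``repr`` precision so the file round-trips
    losslessly through :func:`read_report`.
    """
    doc = {"records": [r.to_dict() for r in reports]}
    if tests is not None:
        doc["tests"] = tests
    if meta is not None:
        doc["meta"] = meta
    text = json.dumps(doc, indent=2, sort_keys=True, allow_nan=False) + "\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


def read_report(path: str) -> List:
    """Read back a report written by :func:`write_report`."""
    from .kinetics import ReconciliationReport  # local import: avoid cycle

    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    return [ReconciliationReport.from_dict(rec) for rec in doc.get("records", [])]
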