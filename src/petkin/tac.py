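"""Core containers and delimited-text I/O for time-activity data.

A time-activity curve (TAC) is the sampled radioactivity concentration in a
region of interest (or in arterial plasma) versus time after tracer
injection.  Canonical units throughout the package are minutes for time,
kBq/ml for activity concentration, MBq for injected dose, grams for body
weight, and units of 10^6 for cell counts.  Decay correction is assumed to
have been applied upstream; no half-life handling happens here.

Times are frame midpoints.  When a frame is described by its start and end,
the midpoint is (start + end) / 2.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeActivityCurve",
    "CohortRecord",
    "read_tac",
    "write_tac",
    "read_cohort",
    "write_cohort",
    "convert_time",
    "convert_activity",
    "TIME_FACTORS_TO_MIN",
    "ACTIVITY_FACTORS_TO_KBQ_ML",
]

#: multiply a time in ``unit`` by this factor to obtain minutes
TIME_FACTORS_TO_MIN = {"s": 1.0 / 60.0, "min": 1.0, "h": 60.0}

#: multiply an activity concentration in ``unit`` by this to obtain kBq/ml
ACTIVITY_FACTORS_TO_KBQ_ML = {"Bq_ml": 1e-3, "kBq_ml": 1.0, "MBq_ml": 1e3}


def convert_time(values, from_unit: str, to_unit: str):
    """Convert times between s/min/h.  Involutive: applying the inverse
    conversion returns the input."""
    if from_unit not in TIME_FACTORS_TO_MIN or to_unit not in TIME_FACTORS_TO_MIN:
        raise ValueError(f"unknown time unit: {from_unit!r} or {to_unit!r}")
    factor = TIME_FACTORS_TO_MIN[from_unit] / TIME_FACTORS_TO_MIN[to_unit]
    return np.asarray(values, dtype=float) * factor


def convert_activity(values, from_unit: str, to_unit: str):
    """Convert activity concentrations between Bq/ml, kBq/ml and MBq/ml."""
    if (
        from_unit not in ACTIVITY_FACTORS_TO_KBQ_ML
        or to_unit not in ACTIVITY_FACTORS_TO_KBQ_ML
    ):
        raise ValueError(f"unknown activity unit: {from_unit!r} or {to_unit!r}")
    factor = ACTIVITY_FACTORS_TO_KBQ_ML[from_unit] / ACTIVITY_FACTORS_TO_KBQ_ML[to_unit]
    return np.asarray(values, dtype=float) * factor


@dataclass(frozen=True)
class TimeActivityCurve:
    """Sampled activity concentration over time for one region or plasma.

    Parameters
    ----------
    times : array-like
        Sample midpoint times in minutes; strictly increasing and >= 0.
    values : array-like
        Activity concentration in kBq/ml; nonnegative.
    frame_durations : array-like, optional
        Per-sample frame durations in minutes; all positive when given.
    label : str
        Region name (e.g. ``"plasma"``, ``"lesion"``).
    """

    times: np.ndarray
    values: np.ndarray
    frame_durations: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if times.size == 0:
            raise ValueError("empty time-activity curve")
        if times.shape != values.shape:
            raise ValueError(
                f"times and values must have equal length "
                f"({times.size} != {values.size})"
            )
        if np.any(times < 0):
            row = int(np.flatnonzero(times < 0)[0])
            raise ValueError(f"negative time at row {row}")
        diffs = np.diff(times)
        if np.any(diffs <= 0):
            row = int(np.flatnonzero(diffs <= 0)[0]) + 1
            raise ValueError(f"times not strictly increasing at row {row}")
        if np.any(values < 0):
            row = int(np.flatnonzero(values < 0)[0])
            raise ValueError(f"negative activity concentration at row {row}")
        durations = self.frame_durations
        if durations is not None:
            durations = np.atleast_1d(np.asarray(durations, dtype=float))
            if durations.shape != times.shape:
                raise ValueError("frame_durations length mismatch")
            if np.any(durations <= 0):
                row = int(np.flatnonzero(durations <= 0)[0])
                raise ValueError(f"nonpositive frame duration at row {row}")
            durations.setflags(write=False)
        times.setflags(write=False)
        values.setflags(write=False)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "frame_durations", durations)

    def __len__(self) -> int:
        return self.times.size

    def with_values(self, values) -> "TimeActivityCurve":
        """Return a copy of this curve with new values on the same grid."""
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))


@dataclass
class CohortRecord:
    """One animal of the xenograft cohort.

    ``cd25_cells`` is the number of CD25-positive (IL-2 receptor bearing)
    cells in the lesion, in units of 10^6 cells; 0 denotes a control region
    with no implanted cells.
    """

    animal_id: str
    cd25_cells: float
    injected_dose: float  # MBq
    body_weight: float  # g
    plasma: TimeActivityCurve
    lesion: TimeActivityCurve
    control: TimeActivityCurve | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.injected_dose <= 0:
            raise ValueError("injected_dose must be > 0")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")
        if self.cd25_cells < 0:
            raise ValueError("cd25_cells must be >= 0")


_TAC_COLUMNS = ("time_min", "activity_kBq_ml", "duration_min")


def read_tac(path, label: str | None = None) -> TimeActivityCurve:
    """Read a TAC from a delimited text table.

    The file must have a header row ``time_min,activity_kBq_ml`` with an
    optional third column ``duration_min``; ``#`` starts a comment line.
    Columns ``time_s`` / ``activity_MBq_ml`` etc. are converted to the
    canonical minutes / kBq/ml.  Malformed rows are rejected with their row
    index.
    """
    with open(path) as fh:
        header = ""
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                header = line
                break
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, comment="#", sep=sep, float_precision="round_trip")
    cols = {c.strip(): c for c in df.columns}

    def _find(prefix, factors):
        for name, col in cols.items():
            for unit in factors:
                if name == f"{prefix}_{unit}":
                    return col, unit
        return None, None

    tcol, tunit = _find("time", TIME_FACTORS_TO_MIN)
    acol, aunit = _find("activity", ACTIVITY_FACTORS_TO_KBQ_ML)
    if tcol is None or acol is None:
        raise ValueError(
            f"{path}: header must contain time_<unit> and activity_<unit> "
            f"columns (e.g. {_TAC_COLUMNS[0]},{_TAC_COLUMNS[1]})"
        )
    bad = df[tcol].isna() | df[acol].isna()
    if bad.any():
        raise ValueError(f"{path}: malformed row {int(np.flatnonzero(bad)[0])}")
    times = convert_time(df[tcol].to_numpy(), tunit, "min")
    values = convert_activity(df[acol].to_numpy(), aunit, "kBq_ml")
    dcol, dunit = _find("duration", TIME_FACTORS_TO_MIN)
    durations = None
    if dcol is not None and not df[dcol].isna().all():
        durations = convert_time(df[dcol].to_numpy(), dunit, "min")
    if label is None:
        label = os.path.splitext(os.path.basename(str(path)))[0]
    return TimeActivityCurve(times, values, durations, label=label)


def write_tac(curve: TimeActivityCurve, path) -> None:
    """Write a TAC as CSV with the canonical header, re-readable
    bit-compatibly at 17 significant digits."""
    data = {"time_min": curve.times, "activity_kBq_ml": curve.values}
    if curve.frame_durations is not None:
        data["duration_min"] = curve.frame_durations
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        if curve.label:
            fh.write(f"# label: {curve.label}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def write_cohort(records: list[CohortRecord], directory) -> str:
    """Write a cohort as ``cohort.csv`` plus per-animal TAC files.

    Returns the path of the cohort index file.  When ground-truth
    generating parameters are attached to the records, a ``truth.csv``
    sidecar is written as well.
    """
    os.makedirs(directory, exist_ok=True)
    rows, truth_rows = [], []
    for rec in records:
        paths = {}
        for kind in ("plasma", "lesion", "control"):
            tac = getattr(rec, kind)
            if tac is None:
                paths[kind] = ""
                continue
            fname = f"{rec.animal_id}_{kind}.csv"
            write_tac(tac, os.path.join(directory, fname))
            paths[kind] = fname
        rows.append(
            {
                "animal_id": rec.animal_id,
                "cd25_cells_1e6": rec.cd25_cells,
                "dose_MBq": rec.injected_dose,
                "weight_g": rec.body_weight,
                "plasma_tac": paths["plasma"],
                "lesion_tac": paths["lesion"],
                "control_tac": paths["control"],
            }
        )
        if rec.truth:
            truth_rows.append({"animal_id": rec.animal_id, **rec.truth})
    index = os.path.join(directory, "cohort.csv")
    pd.DataFrame(rows).to_csv(index, index=False, float_format="%.17g")
    if truth_rows:
        pd.DataFrame(truth_rows).to_csv(
            os.path.join(directory, "truth.csv"), index=False, float_format="%.17g"
        )
    return index


def read_cohort(index_path) -> list[CohortRecord]:
    """Read a cohort index CSV; TAC paths are resolved relative to it."""
    base = os.path.dirname(os.path.abspath(str(index_path)))
    df = pd.read_csv(index_path, comment="#")
    required = {"animal_id", "cd25_cells_1e6", "dose_MBq", "weight_g",
                "plasma_tac", "lesion_tac"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        control = None
        ctrl = row.get("control_tac", "")
        if isinstance(ctrl, str) and ctrl:
            control = read_tac(os.path.join(base, ctrl), label="control")
        records.append(
            CohortRecord(
                animal_id=str(row["animal_id"]),
                cd25_cells=float(row["cd25_cells_1e6"]),
                injected_dose=float(row["dose_MBq"]),
                body_weight=float(row["weight_g"]),
                plasma=read_tac(os.path.join(base, row["plasma_tac"]), label="plasma"),
                lesion=read_tac(os.path.join(base, row["lesion_tac"]), label="lesion"),
                control=control,
            )
        )
    return records
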