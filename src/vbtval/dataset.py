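"""Per-repetition observations, criterion/practical pairing and bookkeeping.

A *missed* repetition was performed and recorded but not identified by the
practical device; a *ghost* repetition was registered by the device without a
lift taking place (typically unracking artefacts).  Ghosts are excluded from
the paired analysis and counted separately; missed repetitions reduce the
paired sample and feed the missed-repetition rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXERCISES",
    "RepObservation",
    "PairedDataset",
    "VelocitySummary",
    "match_reps",
    "missed_rate",
    "summarize_velocities",
    "observations_to_frame",
    "frame_to_observations",
    "write_rep_table",
    "read_rep_table",
    "read_wide_rep_table",
]

EXERCISES = ("squat", "bench", "deadlift")

_STATUSES = ("ok", "missed", "ghost")

_REP_COLUMNS = ["subject_id", "exercise", "load_pct", "set_index", "rep_index",
                "device_id", "mean_velocity_mps", "status"]


@dataclass(frozen=True)
class RepObservation:
    """One device's record (or lack thereof) of one repetition."""

    subject_id: str
    exercise: str
    load_pct: float
    set_index: int
    rep_index: int
    device_id: str
    mean_velocity: float | None
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"status must be one of {_STATUSES}, got {self.status!r}")
        if self.status == "missed":
            if self.mean_velocity is not None:
                raise ValueError("missed repetitions carry no velocity")
        else:
            if self.mean_velocity is None:
                raise ValueError(f"status={self.status!r} requires a velocity")
            if not self.mean_velocity > 0:
                raise ValueError(
                    f"mean velocity must be positive, got {self.mean_velocity}")

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.exercise, self.load_pct,
                self.set_index, self.rep_index, self.device_id)

    @property
    def set_key(self) -> tuple:
        return (self.subject_id, self.exercise, self.load_pct, self.set_index)


@dataclass(frozen=True)
class PairedDataset:
    """Criterion/practical velocity pairs for one practical device.

    ``frame`` holds one row per paired repetition with both velocities
    present; ``n_paired + n_missed`` equals the number of criterion
    repetitions the device was exposed to.
    """

    frame: pd.DataFrame = field(repr=False)
    device_id: str
    n_paired: int
    n_missed: int
    n_ghost: int

    def __post_init__(self) -> None:
        if len(self.frame) != self.n_paired:
            raise ValueError("n_paired does not match the number of rows")
        if self.n_paired and (self.frame[["criterion_mv", "practical_mv"]].isna().any().any()):
            raise ValueError("paired rows must have both velocities present")

    @property
    def n_criterion(self) -> int:
        return self.n_paired + self.n_missed

    def for_exercise(self, exercise: str) -> "PairedDataset":
        sub = self.frame[self.frame.exercise == exercise].reset_index(drop=True)
        missed = int(self._missed_by_exercise.get(exercise, 0))
        ghost = int(self._ghost_by_exercise.get(exercise, 0))
        obj = PairedDataset(sub, self.device_id, len(sub), missed, ghost)
        object.__setattr__(obj, "_missed_by_ex", {exercise: missed})
        object.__setattr__(obj, "_ghost_by_ex", {exercise: ghost})
        return obj

    # populated by match_reps; defaults keep hand-built datasets working
    @property
    def _missed_by_exercise(self) -> dict:
        return getattr(self, "_missed_by_ex", {})

    @property
    def _ghost_by_exercise(self) -> dict:
        return getattr(self, "_ghost_by_ex", {})


def match_reps(criterion: Sequence[RepObservation],
               practical: Sequence[RepObservation]) -> PairedDataset:
    """Pair criterion and practical repetitions within each set, in order.

    Within each (subject, exercise, load, set) the k-th criterion ok-rep is
    paired with the k-th practical ok-rep.  Criterion reps without a partner
    count as missed; practical ghost rows — explicit ``status=ghost`` or
    ok-reps in excess of the criterion count — are excluded from pairing and
    counted separately.
    """
    for obs_list, label in ((criterion, "criterion"), (practical, "practical")):
        keys = [o.key for o in obs_list]
        if len(keys) != len(set(keys)):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValueError(f"duplicate {label} observation key: {dup}")
    device_ids = {o.device_id for o in practical}
    if len(device_ids) > 1:
        raise ValueError(f"practical observations span several devices: {sorted(device_ids)}")
    device_id = device_ids.pop() if device_ids else "practical"

    crit_sets: dict[tuple, list[RepObservation]] = {}
    for o in sorted(criterion, key=lambda o: (o.key)):
        crit_sets.setdefault(o.set_key, []).append(o)
    prac_sets: dict[tuple, list[RepObservation]] = {}
    for o in sorted(practical, key=lambda o: (o.key)):
        prac_sets.setdefault(o.set_key, []).append(o)

    rows = []
    n_missed = 0
    n_ghost = 0
    missed_by_ex: dict[str, int] = {}
    ghost_by_ex: dict[str, int] = {}
    for set_key in sorted(crit_sets):
        crit_ok = [o for o in crit_sets[set_key] if o.status == "ok"]
        prac_all = prac_sets.get(set_key, [])
        explicit_ghosts = [o for o in prac_all if o.status == "ghost"]
        prac_ok = [o for o in prac_all if o.status == "ok"]
        exercise = set_key[1]
        n_ghost += len(explicit_ghosts)
        ghost_by_ex[exercise] = ghost_by_ex.get(exercise, 0) + len(explicit_ghosts)
        # surplus practical ok-reps are unracking artefacts: label as ghosts
        surplus = max(len(prac_ok) - len(crit_ok), 0)
        if surplus:
            n_ghost += surplus
            ghost_by_ex[exercise] = ghost_by_ex.get(exercise, 0) + surplus
            prac_ok = prac_ok[: len(crit_ok)]
        for k, c in enumerate(crit_ok):
            if k < len(prac_ok):
                rows.append({
                    "subject_id": c.subject_id, "exercise": c.exercise,
                    "load_pct": c.load_pct, "set_index": c.set_index,
                    "rep_index": c.rep_index,
                    "criterion_mv": c.mean_velocity,
                    "practical_mv": prac_ok[k].mean_velocity,
                })
            else:
                n_missed += 1
                missed_by_ex[exercise] = missed_by_ex.get(exercise, 0) + 1
    frame = pd.DataFrame(rows, columns=["subject_id", "exercise", "load_pct",
                                        "set_index", "rep_index",
                                        "criterion_mv", "practical_mv"])
    ds = PairedDataset(frame, device_id, len(frame), n_missed, n_ghost)
    object.__setattr__(ds, "_missed_by_ex", missed_by_ex)
    object.__setattr__(ds, "_ghost_by_ex", ghost_by_ex)
    return ds


def missed_rate(paired: PairedDataset) -> float:
    """Fraction of criterion repetitions the practical device failed to record."""
    total = paired.n_paired + paired.n_missed
    if total == 0:
        raise ValueError("cannot compute a missed rate on an empty dataset")
    return paired.n_missed / total


@dataclass(frozen=True)
class VelocitySummary:
    n: int
    mean: float
    sd: float
    min: float
    max: float
    sd_defined: bool = True


def summarize_velocities(observations: Iterable[RepObservation]) -> VelocitySummary:
    """Descriptive statistics of ok-status mean velocities (SD uses n-1)."""
    vals = np.array([o.mean_velocity for o in observations if o.status == "ok"],
                    dtype=float)
    if vals.size == 0:
        raise ValueError("no ok observations to summarize")
    sd_defined = vals.size > 1
    sd = float(vals.std(ddof=1)) if sd_defined else 0.0
    return VelocitySummary(int(vals.size), float(vals.mean()), sd,
                           float(vals.min()), float(vals.max()), sd_defined)


# ---------------------------------------------------------------------------
# delimited-text IO
# ---------------------------------------------------------------------------


def observations_to_frame(observations: Iterable[RepObservation]) -> pd.DataFrame:
    rows = [{
        "subject_id": o.subject_id, "exercise": o.exercise, "load_pct": o.load_pct,
        "set_index": o.set_index, "rep_index": o.rep_index, "device_id": o.device_id,
        "mean_velocity_mps": o.mean_velocity if o.mean_velocity is not None else np.nan,
        "status": o.status,
    } for o in observations]
    return pd.DataFrame(rows, columns=_REP_COLUMNS)


def frame_to_observations(frame: pd.DataFrame) -> list[RepObservation]:
    obs = []
    for i, row in enumerate(frame.itertuples(index=False)):
        mv = row.mean_velocity_mps
        mv = None if (mv is None or (isinstance(mv, float) and math.isnan(mv))) else float(mv)
        try:
            obs.append(RepObservation(
                subject_id=str(row.subject_id), exercise=str(row.exercise),
                load_pct=float(row.load_pct), set_index=int(row.set_index),
                rep_index=int(row.rep_index), device_id=str(row.device_id),
                mean_velocity=mv, status=str(row.status)))
        except ValueError as exc:
            raise ValueError(f"invalid repetition record at row {i + 2}: {exc}") from exc
    return obs


def write_rep_table(observations: Iterable[RepObservation], path: str | Path) -> None:
    # %.17g guarantees exact float64 round-trips
    observations_to_frame(observations).to_csv(path, index=False, float_format="%.17g")


def read_rep_table(path: str | Path) -> list[RepObservation]:
    frame = pd.read_csv(path, dtype={"subject_id": str, "exercise": str,
                                     "device_id": str, "status": str},
                        float_precision="round_trip")
    missing = set(_REP_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"rep table {path} lacks columns: {sorted(missing)}")
    return frame_to_observations(frame)


def read_wide_rep_table(path: str | Path, criterion_id: str,
                        device_ids: Sequence[str] | None = None) -> list[RepObservation]:
    """Read a wide per-rep table (one velocity column per device) as long form.

    Expected columns: subject_id, exercise, load_pct, set_index, rep_index and
    one column per device.  Empty device cells become missed repetitions.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str, "exercise": str})
    id_cols = ["subject_id", "exercise", "load_pct", "set_index", "rep_index"]
    missing = set(id_cols) - set(frame.columns)
    if missing:
        raise ValueError(f"wide rep table {path} lacks columns: {sorted(missing)}")
    devices = device_ids or [c for c in frame.columns if c not in id_cols]
    if criterion_id not in devices:
        raise ValueError(f"criterion column {criterion_id!r} not found in {list(devices)}")
    obs: list[RepObservation] = []
    for dev in devices:
        for i, row in frame.iterrows():
            mv = row[dev]
            if pd.isna(mv):
                status, mv = "missed", None
            else:
                status, mv = "ok", float(mv)
            obs.append(RepObservation(
                subject_id=str(row.subject_id), exercise=str(row.exercise),
                load_pct=float(row.load_pct), set_index=int(row.set_index),
                rep_index=int(row.rep_index), device_id=dev,
                mean_velocity=mv, status=status))
    return obs
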