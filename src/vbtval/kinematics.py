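"""Criterion trajectory processing: filtering, differentiation, rep detection.

The processing chain mirrors how a motion-capture reference signal is turned
into per-repetition mean velocities: a zero-phase fourth-order Butterworth
low-pass at 10 Hz on the marker position, numerical differentiation, and
threshold-based segmentation of the vertical velocity.  A repetition is a
contiguous region of upward movement whose net vertical displacement reaches
10 cm; its mean velocity is vertical displacement divided by duration.

"Distance" is vertical displacement throughout: the 10 cm rule and the
concentric definition refer to lifting height, not 3D path length, and only
upward (positive vertical velocity) segments are candidate repetitions.

Segment boundaries are refined beyond the raw 0.02 m/s threshold crossings:
interpolated crossing times of several levels relative to the segment's peak
velocity are extrapolated to level zero (a two-parameter arcsine flank model,
which reduces to linear extrapolation at small levels).  This removes the
duration bias a pure threshold rule would introduce — low-velocity tails of
the concentric phase would otherwise be clipped — and keeps the mean velocity
within a few tenths of a percent of the true displacement/duration ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .dataset import RepObservation

__all__ = [
    "Trajectory",
    "RepSegment",
    "lowpass_filter",
    "differentiate",
    "detect_reps",
    "resolve_multiple_detections",
    "process_attempt",
    "read_trajectory",
    "write_trajectory",
]

logger = logging.getLogger(__name__)

V_THRESH = 0.02   # m/s, instantaneous velocity threshold for rep detection
D_THRESH = 0.10   # m, minimum vertical displacement of a counted rep

# relative velocity levels used for boundary refinement
_EDGE_LEVELS = np.arange(0.10, 0.72, 0.05)


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 3D marker positions for one lift attempt (z vertical)."""

    time: np.ndarray
    position: np.ndarray            # (n, 3) in metres
    subject_id: str = ""
    exercise: str = ""
    load_pct: float = float("nan")
    set_index: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "position", p)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if p.shape != (t.size, 3):
            raise ValueError(f"position must be (n, 3), got {p.shape}")
        if not (np.isfinite(t).all() and np.isfinite(p).all()):
            raise ValueError("trajectory contains non-finite values")
        dt = np.diff(t)
        if (dt <= 0).any():
            raise ValueError("time must be strictly increasing")
        if np.ptp(dt) > 1e-6:
            raise ValueError("sampling intervals must be uniform within 1e-6 s")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    @property
    def vertical(self) -> np.ndarray:
        return self.position[:, 2]


@dataclass(frozen=True)
class RepSegment:
    """One detected concentric (upward) phase."""

    start_time: float
    end_time: float
    displacement: float
    duration: float
    mean_velocity: float
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if abs(self.mean_velocity * self.duration - self.displacement) > 1e-9:
            raise ValueError("mean_velocity * duration must equal displacement")


def lowpass_filter(traj: Trajectory, order: int = 4, cutoff: float = 10.0) -> Trajectory:
    """Zero-phase (forward-backward) Butterworth low-pass on each coordinate.

    The two-pass magnitude response at frequency f is 1 / (1 + (f/cutoff)^(2*order)).
    """
    if order < 2 or order % 2:
        raise ValueError(f"order must be an even integer >= 2, got {order}")
    nyq = traj.sampling_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({nyq:.1f} Hz)")
    padlen = 6 * order
    if traj.time.size <= padlen:
        raise ValueError(
            f"trajectory too short for filter warm-up: {traj.time.size} samples, "
            f"need more than {padlen}")
    b, a = butter(order, cutoff / nyq)
    filtered = filtfilt(b, a, traj.position, axis=0, padtype="even", padlen=padlen)
    return replace(traj, position=filtered)


def differentiate(traj: Trajectory) -> np.ndarray:
    """Vertical velocity: central differences inside, one-sided at the ends."""
    return np.gradient(traj.vertical, traj.time)


def _edge_time(time: np.ndarray, v: np.ndarray, s: int, e: int, edge: str) -> float:
    """Extrapolated zero-velocity time for one boundary of a run [s, e].

    Crossing times of levels a * v_peak are fit as t(a) = t0 + c * arcsin(a)
    and read off at a = 0.  Crossings require two consecutive samples at or
    above the level, which keeps isolated noise blips from triggering early.
    """
    n = v.size
    if edge == "start":
        vv, ss, ee = v, s, e
    else:
        vv, ss, ee = v[::-1], n - 1 - e, n - 1 - s
    vpk = vv[ss:ee + 1].max()
    idx_cross, levels = [], []
    seg = vv[ss:ee + 1]
    persist = np.r_[seg[1:], seg[-1:]]
    for a in _EDGE_LEVELS:
        lvl = a * vpk
        ok = (seg >= lvl) & (persist >= lvl)
        if not ok.any():
            continue
        k = ss + int(np.argmax(ok))
        if k == 0 or vv[k - 1] >= lvl:
            continue
        idx_cross.append((k - 1) + (lvl - vv[k - 1]) / (vv[k] - vv[k - 1]))
        levels.append(a)
    if len(idx_cross) < 3:
        return float(time[s] if edge == "start" else time[e])
    al = np.asarray(levels)
    design = np.column_stack([np.ones_like(al), np.arcsin(al)])
    coef, *_ = np.linalg.lstsq(design, np.asarray(idx_cross), rcond=None)
    idx0 = float(coef[0])
    dt = float(time[1] - time[0])
    if edge == "start":
        return float(time[0] + idx0 * dt)
    return float(time[0] + (n - 1 - idx0) * dt)


def detect_reps(time: np.ndarray, position: np.ndarray, velocity: np.ndarray,
                v_thresh: float = V_THRESH, d_thresh: float = D_THRESH,
                refine: bool = True) -> list[RepSegment]:
    """Segment upward movement phases and keep those travelling >= ``d_thresh``.

    Candidate segments are maximal contiguous runs with velocity strictly above
    ``v_thresh``; boundaries are then refined to the extrapolated zero-velocity
    instants (see module docstring).  Displacement is the vertical position
    difference between the two boundaries.
    """
    time = np.asarray(time, dtype=float)
    position = np.asarray(position, dtype=float)
    velocity = np.asarray(velocity, dtype=float)
    if not (time.shape == position.shape == velocity.shape):
        raise ValueError("time, position and velocity must be aligned 1D series")
    above = velocity > v_thresh
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0])
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)
    segments = []
    for s, e in zip(starts, ends):
        if refine:
            t0 = _edge_time(time, velocity, s, e, "start")
            t1 = _edge_time(time, velocity, s, e, "end")
        else:
            t0, t1 = float(time[s]), float(time[e])
        if not t1 > t0:
            continue
        z0 = float(np.interp(t0, time, position))
        z1 = float(np.interp(t1, time, position))
        disp = z1 - z0
        dur = t1 - t0
        if disp >= d_thresh:
            segments.append(RepSegment(t0, t1, disp, dur, disp / dur))
    return segments


def resolve_multiple_detections(segments: list[RepSegment],
                                expected_reps: int) -> list[RepSegment]:
    """Keep the ``expected_reps`` largest-displacement segments, in time order.

    Ties prefer the earlier segment.  If fewer segments than expected survive,
    they are returned as-is and a warning is logged.
    """
    if expected_reps < 1:
        raise ValueError("expected_reps must be >= 1")
    if len(segments) < expected_reps:
        logger.warning("only %d segment(s) detected where %d expected",
                       len(segments), expected_reps)
        return list(segments)
    if len(segments) > expected_reps:
        ranked = sorted(segments, key=lambda r: (-r.displacement, r.start_time))
        kept = set(id(r) for r in ranked[:expected_reps])
        logger.info("resolved %d detections to the %d largest-displacement segment(s)",
                    len(segments), expected_reps)
        return [r for r in segments if id(r) in kept]
    return list(segments)


def process_attempt(traj: Trajectory, expected_reps: int = 1,
                    v_thresh: float = V_THRESH, d_thresh: float = D_THRESH,
                    order: int = 4, cutoff: float = 10.0,
                    device_id: str = "vicon") -> list[RepObservation]:
    """Full criterion pipeline: filter, differentiate, detect, resolve.

    Emits one criterion :class:`RepObservation` per kept segment.
    """
    filtered = lowpass_filter(traj, order=order, cutoff=cutoff)
    velocity = differentiate(filtered)
    segments = detect_reps(filtered.time, filtered.vertical, velocity,
                           v_thresh=v_thresh, d_thresh=d_thresh)
    kept = resolve_multiple_detections(segments, expected_reps)
    return [RepObservation(
        subject_id=traj.subject_id, exercise=traj.exercise,
        load_pct=traj.load_pct, set_index=traj.set_index, rep_index=i + 1,
        device_id=device_id, mean_velocity=seg.mean_velocity, status="ok")
        for i, seg in enumerate(kept)]


# ---------------------------------------------------------------------------
# delimited-text IO (time_s, x_m, y_m, z_m)
# ---------------------------------------------------------------------------


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    frame = pd.DataFrame({
        "time_s": traj.time,
        "x_m": traj.position[:, 0],
        "y_m": traj.position[:, 1],
        "z_m": traj.position[:, 2],
    })
    frame.to_csv(path, index=False, float_format="%.6f")


def read_trajectory(path: str | Path, subject_id: str = "", exercise: str = "",
                    load_pct: float = float("nan"), set_index: int = 1) -> Trajectory:
    """Read a trajectory file; accepts the minimal (time_s, z_m) form too."""
    frame = pd.read_csv(path)
    if "time_s" not in frame.columns or "z_m" not in frame.columns:
        raise ValueError(f"{path}: expected columns time_s and z_m")
    n = len(frame)
    pos = np.zeros((n, 3))
    for i, col in enumerate(("x_m", "y_m", "z_m")):
        if col in frame.columns:
            pos[:, i] = frame[col].to_numpy(dtype=float)
    name = Path(path).stem
    if not subject_id and name.count("_") >= 2:
        parts = name.split("_")
        subject_id, exercise = parts[0], parts[1]
        try:
            load_pct = float(parts[2])
        except ValueError:
            pass
    return Trajectory(frame.time_s.to_numpy(dtype=float), pos,
                      subject_id=subject_id, exercise=exercise,
                      load_pct=load_pct, set_index=set_index)
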