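"""Synthetic cohorts, barbell trajectories and device observation models.

The generator emulates a laboratory concurrent-validity study of barbell
velocity measurement in the powerlifting lifts:

* a cohort of competitive powerlifters whose body mass and relative strength
  (1RM per kg body mass) are drawn from truncated normal distributions with
  published sample characteristics;
* a progressive single-repetition loading ladder from 45% to 90% of each
  lifter's 1RM in 5% steps, loads rounded to the nearest 2.5 kg;
* exercise-specific vertical barbell trajectories sampled at 200 Hz — squat
  (eccentric then concentric), bench press (eccentric, pause, concentric) and
  deadlift (concentric first, then lowering) — with an optional mid-concentric
  "sticking region" velocity dip;
* phenomenological device observation models at the mean-velocity level:
  fixed plus proportional bias, correlated subject-level random effects,
  residual noise, and missed/ghost repetition generation.

Movement phases use half-cosine position segments (half-sine velocity), so
phase boundaries have exactly zero velocity and displacement, duration and
mean velocity are available in closed form.  Mean concentric velocity falls
linearly with load fraction between configurable anchor points, spanning
roughly 0.1-1.0 m/s over the 45-90% ladder with the defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erf

from .dataset import EXERCISES, RepObservation
from .kinematics import Trajectory

__all__ = [
    "TruncatedNormal",
    "Table1Params",
    "Subject",
    "ProtocolSpec",
    "TrajectoryConfig",
    "DeviceProfile",
    "TrueRep",
    "DEFAULT_TABLE1",
    "DEFAULT_PROTOCOL",
    "DEFAULT_TRAJECTORIES",
    "simulate_cohort",
    "protocol_loads",
    "simulate_trajectory",
    "simulate_device",
    "trajectory_filename",
]


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) truncated to [low, high], sampled by rejection."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be non-negative, got {self.sd}")
        if not self.low <= self.high:
            raise ValueError(f"empty support [{self.low}, {self.high}]")
        if self.sd == 0 and not self.low <= self.mean <= self.high:
            raise ValueError("degenerate distribution with mean outside support")

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        for _ in range(10000):
            x = rng.normal(self.mean, self.sd)
            if self.low <= x <= self.high:
                return float(x)
        raise RuntimeError("truncated-normal rejection sampling did not terminate")


@dataclass(frozen=True)
class Table1Params:
    """Cohort distributions: body mass (kg) and relative 1RM (kg per kg BM)."""

    body_mass: TruncatedNormal
    relative_one_rm: Mapping[str, TruncatedNormal]

    def __post_init__(self) -> None:
        missing = set(EXERCISES) - set(self.relative_one_rm)
        if missing:
            raise ValueError(f"relative 1RM spec missing exercises: {sorted(missing)}")


DEFAULT_TABLE1 = Table1Params(
    body_mass=TruncatedNormal(83.4, 19.8, 55.8, 147.7),
    relative_one_rm={
        "squat": TruncatedNormal(2.32, 0.43, 1.68, 3.46),
        "bench": TruncatedNormal(1.46, 0.36, 0.88, 2.28),
        "deadlift": TruncatedNormal(2.71, 0.48, 2.07, 3.88),
    },
)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    body_mass: float
    one_rm: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValueError("body mass must be positive")
        for ex, rm in self.one_rm.items():
            if rm <= 0:
                raise ValueError(f"1RM for {ex} must be positive")


def simulate_cohort(n_subjects: int, seed: int,
                    table1_params: Table1Params | None = None) -> list[Subject]:
    """Draw a cohort; absolute 1RM = relative 1RM x body mass."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = table1_params or DEFAULT_TABLE1
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        bm = params.body_mass.sample(rng)
        one_rm = {ex: params.relative_one_rm[ex].sample(rng) * bm
                  for ex in EXERCISES}
        cohort.append(Subject(subject_id=f"S{i + 1:02d}", body_mass=bm, one_rm=one_rm))
    return cohort


@dataclass(frozen=True)
class ProtocolSpec:
    """Progressive loading ladder as fractions of 1RM."""

    load_fractions: tuple[float, ...] = tuple(
        round(0.45 + 0.05 * k, 2) for k in range(10))
    reps_per_load: int = 1
    load_rounding: float = 2.5

    def __post_init__(self) -> None:
        fr = self.load_fractions
        if not fr:
            raise ValueError("load_fractions must be non-empty")
        if any(not 0 < f <= 1 for f in fr):
            raise ValueError("load fractions must lie in (0, 1]")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise ValueError("load fractions must be strictly increasing")
        if self.load_rounding <= 0:
            raise ValueError("load_rounding must be positive")
        if self.reps_per_load < 1:
            raise ValueError("reps_per_load must be >= 1")


DEFAULT_PROTOCOL = ProtocolSpec()


def protocol_loads(subject: Subject, exercise: str,
                   protocol: ProtocolSpec = DEFAULT_PROTOCOL) -> list[float]:
    """Absolute loads (kg), each rounded to the nearest increment, ties up."""
    if exercise not in subject.one_rm:
        raise KeyError(f"subject {subject.subject_id} has no 1RM for {exercise!r}")
    one_rm = subject.one_rm[exercise]
    inc = protocol.load_rounding
    loads = []
    for f in protocol.load_fractions:
        raw = f * one_rm
        loads.append(math.floor(raw / inc + 0.5 + 1e-9) * inc)
    return loads


@dataclass(frozen=True)
class TrajectoryConfig:
    """Shape parameters of the simulated barbell path for one exercise.

    ``mv_at_min_load`` / ``mv_at_max_load`` anchor the linear load-velocity
    relationship at the ends of ``fraction_range`` (default 45% and 90% 1RM).
    ``sticking_dip_depth`` carves a mid-concentric velocity dip of that depth
    (fraction of the local peak) with displacement conserved.
    """

    exercise: str
    rom: float                             # m, concentric range of motion
    mv_at_min_load: float                  # m/s at the lightest ladder load
    mv_at_max_load: float                  # m/s at the heaviest ladder load
    sampling_rate: float = 200.0
    pause_duration: float = 0.0            # s, bench only
    sticking_dip_depth: float = 0.0
    noise_sd: float = 0.0                  # m, additive white position noise
    eccentric_velocity: float = 0.5        # m/s, mean lowering speed
    lead_in: float = 0.7                   # s of quiet standing before movement
    lead_out: float = 0.7
    top_hold: float = 0.5                  # s, deadlift lockout hold
    fraction_range: tuple[float, float] = (0.45, 0.90)

    def __post_init__(self) -> None:
        if self.exercise not in EXERCISES:
            raise ValueError(f"exercise must be one of {EXERCISES}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.rom <= 0.10:
            raise ValueError("rom must exceed the 0.10 m detection threshold")
        if not 0 <= self.sticking_dip_depth < 1:
            raise ValueError("sticking_dip_depth must lie in [0, 1)")
        if not self.mv_at_max_load < self.mv_at_min_load:
            raise ValueError("mean velocity must decrease with load")
        if min(self.mv_at_max_load, self.mv_at_min_load) <= 0:
            raise ValueError("anchor velocities must be positive")
        if self.noise_sd < 0 or self.pause_duration < 0:
            raise ValueError("noise_sd and pause_duration must be non-negative")
        if self.lead_in < 0.5 or self.lead_out < 0.5:
            raise ValueError("need at least 0.5 s of quiet standing on both sides")


# noise_sd emulates residual marker noise after 3D reconstruction (~0.5 mm)
DEFAULT_TRAJECTORIES: dict[str, TrajectoryConfig] = {
    "squat": TrajectoryConfig("squat", rom=0.60, mv_at_min_load=0.90,
                              mv_at_max_load=0.30, noise_sd=0.0005),
    "bench": TrajectoryConfig("bench", rom=0.40, mv_at_min_load=0.75,
                              mv_at_max_load=0.17, pause_duration=0.8,
                              noise_sd=0.0005),
    "deadlift": TrajectoryConfig("deadlift", rom=0.50, mv_at_min_load=0.80,
                                 mv_at_max_load=0.25, noise_sd=0.0005),
}


def _flat(duration: float, z: float, fs: float) -> np.ndarray:
    return np.full(int(round(duration * fs)), float(z))


def _halfcos_segment(duration: float, z0: float, disp: float, fs: float) -> np.ndarray:
    """Half-cosine position ramp: velocity is a half-sine pulse, 0 at both ends."""
    n = int(round(duration * fs))
    tau = np.arange(n) / fs
    return z0 + disp * (1.0 - np.cos(np.pi * tau / duration)) / 2.0


def _dip_coefficient(dip_depth: float, w_over_t: float = 0.125) -> float:
    """Subtraction coefficient c such that min/peak of sin - c*gauss = 1 - depth.

    The subtracted Gaussian also lowers the two flanking peaks, so the
    coefficient is found by bisection on the analytic velocity shape.
    """
    x = np.linspace(0.0, 1.0, 2001)
    sin = np.sin(np.pi * x)
    g = np.exp(-((x - 0.5) ** 2) / (2 * w_over_t ** 2))
    target = 1.0 - dip_depth

    def ratio(c: float) -> float:
        v = sin - c * g
        mid = v.size // 2
        i1 = int(np.argmax(v[:mid]))
        i2 = mid + int(np.argmax(v[mid:]))
        return v[i1:i2 + 1].min() / v.max()

    lo, hi = 0.0, 1.0 - 1e-9
    for _ in range(60):
        c = 0.5 * (lo + hi)
        if ratio(c) > target:
            lo = c
        else:
            hi = c
    return 0.5 * (lo + hi)


def _concentric_segment(duration: float, z0: float, disp: float, fs: float,
                        dip_depth: float) -> np.ndarray:
    """Concentric ramp, optionally with a sticking-region velocity dip.

    The velocity profile is A * [sin(pi tau/T) - c * g(tau)] with g a Gaussian
    bump centred mid-phase (width T/8); c is calibrated so the dip bottom sits
    at (1 - dip_depth) of the realized peak velocity, and A is chosen so the
    displacement stays ``disp``.  The position is the closed-form integral
    (erf terms).
    """
    if dip_depth == 0.0:
        return _halfcos_segment(duration, z0, disp, fs)
    T = duration
    w = T / 8.0
    c = _dip_coefficient(dip_depth)
    n = int(round(T * fs))
    tau = np.arange(n) / fs
    gauss_area = w * math.sqrt(2 * math.pi) * erf(T / (2 * math.sqrt(2) * w))
    amp = disp / (2 * T / np.pi - c * gauss_area)
    base = (T / np.pi) * (1.0 - np.cos(np.pi * tau / T))
    dip = w * math.sqrt(math.pi / 2) * (
        erf((tau - T / 2) / (math.sqrt(2) * w)) + erf(T / (2 * math.sqrt(2) * w)))
    return z0 + amp * (base - c * dip)


def target_mean_velocity(load_fraction: float, config: TrajectoryConfig) -> float:
    """Linear load-velocity relationship between the ladder anchor fractions."""
    f_lo, f_hi = config.fraction_range
    slope = (config.mv_at_max_load - config.mv_at_min_load) / (f_hi - f_lo)
    return config.mv_at_min_load + slope * (load_fraction - f_lo)


def simulate_trajectory(exercise: str, load_fraction: float,
                        config: TrajectoryConfig | None = None,
                        seed: int = 0, subject_id: str = "",
                        load_pct: float | None = None,
                        set_index: int = 1) -> tuple[Trajectory, float]:
    """Build one attempt's trajectory; returns it with the noiseless mean velocity.

    Durations are quantized to the sample grid so the returned true mean
    velocity (rom / concentric duration) is exact for the generated samples.
    """
    if config is None:
        config = DEFAULT_TRAJECTORIES[exercise]
    if config.exercise != exercise:
        raise ValueError(f"config is for {config.exercise!r}, not {exercise!r}")
    if not 0 < load_fraction <= 1:
        raise ValueError("load_fraction must lie in (0, 1]")
    fs = config.sampling_rate
    mv = target_mean_velocity(load_fraction, config)
    if mv <= 0:
        raise ValueError("configured load-velocity profile gives non-positive velocity")
    n_con = max(int(round(config.rom / mv * fs)), 2)
    t_con = n_con / fs
    true_mv = config.rom / t_con
    t_ecc = int(round(config.rom / config.eccentric_velocity * fs)) / fs

    rom = config.rom
    if exercise == "squat":
        z_top = 1.0
        parts = [_flat(config.lead_in, z_top, fs),
                 _halfcos_segment(t_ecc, z_top, -rom, fs),
                 _concentric_segment(t_con, z_top - rom, rom, fs, config.sticking_dip_depth),
                 _flat(config.lead_out, z_top, fs)]
    elif exercise == "bench":
        z_top = 1.0
        parts = [_flat(config.lead_in, z_top, fs),
                 _halfcos_segment(t_ecc, z_top, -rom, fs),
                 _flat(config.pause_duration, z_top - rom, fs),
                 _concentric_segment(t_con, z_top - rom, rom, fs, config.sticking_dip_depth),
                 _flat(config.lead_out, z_top, fs)]
    else:  # deadlift: concentric first, brief lockout, lowering
        z_floor = 0.2
        parts = [_flat(config.lead_in, z_floor, fs),
                 _concentric_segment(t_con, z_floor, rom, fs, config.sticking_dip_depth),
                 _flat(config.top_hold, z_floor + rom, fs),
                 _halfcos_segment(t_ecc, z_floor + rom, -rom, fs),
                 _flat(config.lead_out, z_floor, fs)]
    z = np.concatenate(parts)
    n = z.size
    pos = np.zeros((n, 3))
    pos[:, 2] = z
    if config.noise_sd > 0:
        rng = np.random.default_rng(seed)
        pos += rng.normal(0.0, config.noise_sd, size=pos.shape)
    traj = Trajectory(np.arange(n) / fs, pos, subject_id=subject_id,
                      exercise=exercise,
                      load_pct=load_pct if load_pct is not None else round(100 * load_fraction, 1),
                      set_index=set_index)
    return traj, true_mv


# ---------------------------------------------------------------------------
# device observation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeviceProfile:
    """Phenomenological error model of one practical device.

    Observed MV = (alpha + u0_i) + (beta + u1_i) * true MV + N(0, sigma^2),
    with (u0_i, u1_i) drawn once per subject from MVN(0, re_cov).  Each rep is
    independently missed with ``miss_prob``; each set spawns a ghost
    repetition with ``ghost_prob``.
    """

    device_id: str
    alpha: float = 0.0
    beta: float = 1.0
    sigma: float = 0.0
    re_cov: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 0.0), (0.0, 0.0))
    miss_prob: float = 0.0
    ghost_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        cov = np.asarray(self.re_cov, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("re_cov must be 2x2")
        if abs(cov[0, 1] - cov[1, 0]) > 1e-12:
            raise ValueError("re_cov must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError("re_cov must be positive semi-definite")
        for p in (self.miss_prob, self.ghost_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def re_cholesky(self) -> np.ndarray:
        cov = np.asarray(self.re_cov, dtype=float)
        vals, vecs = np.linalg.eigh(cov)
        return vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))


@dataclass(frozen=True)
class TrueRep:
    """Ground truth for one performed repetition."""

    subject_id: str
    exercise: str
    load_pct: float
    set_index: int
    rep_index: int
    mean_velocity: float


_MIN_OBSERVED_MV = 0.005  # m/s floor; devices never report non-positive velocity


def simulate_device(true_reps: Sequence[TrueRep], profile: DeviceProfile,
                    seed: int) -> list[RepObservation]:
    """Apply a device's observation model to ground-truth repetitions."""
    rng = np.random.default_rng(seed)
    chol = profile.re_cholesky()
    effects: dict[str, np.ndarray] = {}
    for sid in sorted({r.subject_id for r in true_reps}):
        effects[sid] = chol @ rng.standard_normal(2)
    obs: list[RepObservation] = []
    for rep in true_reps:
        if rng.random() < profile.miss_prob:
            obs.append(RepObservation(
                rep.subject_id, rep.exercise, rep.load_pct, rep.set_index,
                rep.rep_index, profile.device_id, None, "missed"))
            continue
        u0, u1 = effects[rep.subject_id]
        mv = ((profile.alpha + u0) + (profile.beta + u1) * rep.mean_velocity
              + rng.normal(0.0, profile.sigma))
        obs.append(RepObservation(
            rep.subject_id, rep.exercise, rep.load_pct, rep.set_index,
            rep.rep_index, profile.device_id,
            max(float(mv), _MIN_OBSERVED_MV), "ok"))
    # ghost repetitions: unracking artefacts with small, displacement-free velocity
    if profile.ghost_prob > 0:
        sets: dict[tuple, int] = {}
        for rep in true_reps:
            key = (rep.subject_id, rep.exercise, rep.load_pct, rep.set_index)
            sets[key] = max(sets.get(key, 0), rep.rep_index)
        for key in sorted(sets):
            if rng.random() < profile.ghost_prob:
                obs.append(RepObservation(
                    key[0], key[1], key[2], key[3], sets[key] + 1,
                    profile.device_id,
                    float(rng.uniform(0.02, 0.10)), "ghost"))
    return obs


def trajectory_filename(subject_id: str, exercise: str, load_pct: float) -> str:
    return f"{subject_id}_{exercise}_{load_pct:g}.csv"
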