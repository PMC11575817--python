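"""Run configuration: nested dataclasses with YAML round-tripping."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dataset import EXERCISES
from .models import PriorSpec, SamplerSpec
from .synthetic import (DEFAULT_PROTOCOL, DEFAULT_TABLE1, DEFAULT_TRAJECTORIES,
                        DeviceProfile, ProtocolSpec, Table1Params, TrajectoryConfig,
                        TruncatedNormal)

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


def _default_devices() -> tuple[DeviceProfile, ...]:
    """Study-like device set: a faithful tethered reference and a noisier app."""
    return (
        DeviceProfile("reference_lt", alpha=0.0, beta=1.0, sigma=0.02,
                      re_cov=((0.005 ** 2, 0.0), (0.0, 0.01 ** 2))),
        DeviceProfile("app_degraded", alpha=0.05, beta=0.85, sigma=0.08,
                      re_cov=((0.01 ** 2, 0.0), (0.0, 0.02 ** 2)),
                      miss_prob=0.08, ghost_prob=0.02),
    )


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full simulated validity study."""

    seed: int = 0
    n_subjects: int = 20
    criterion_id: str = "vicon"
    reference_id: str = "reference_lt"
    rope_mass: float = 0.95
    # between-subject SD (m/s) of each lifter's load-velocity profile offset
    mv_subject_sd: float = 0.03
    protocol: ProtocolSpec = field(default_factory=lambda: DEFAULT_PROTOCOL)
    table1: Table1Params = field(default_factory=lambda: DEFAULT_TABLE1)
    trajectories: dict = field(default_factory=lambda: dict(DEFAULT_TRAJECTORIES))
    devices: tuple = field(default_factory=_default_devices)
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerSpec = field(default_factory=SamplerSpec)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.5 < self.rope_mass < 1:
            raise ValueError("rope_mass must lie in (0.5, 1)")
        ids = [d.device_id for d in self.devices]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate device ids: {ids}")
        if self.reference_id not in ids:
            raise ValueError(
                f"reference device {self.reference_id!r} not among devices {ids}")
        if self.criterion_id in ids:
            raise ValueError("criterion_id must not collide with a practical device id")
        missing = set(EXERCISES) - set(self.trajectories)
        if missing:
            raise ValueError(f"trajectory config missing exercises: {sorted(missing)}")

    def device(self, device_id: str) -> DeviceProfile:
        for d in self.devices:
            if d.device_id == device_id:
                return d
        raise KeyError(device_id)


# ---------------------------------------------------------------------------
# YAML (de)serialization
# ---------------------------------------------------------------------------


def _tn_to_dict(tn: TruncatedNormal) -> dict:
    return {"mean": tn.mean, "sd": tn.sd, "low": tn.low, "high": tn.high}


def _config_to_dict(cfg: RunConfig) -> dict:
    return {
        "seed": cfg.seed,
        "n_subjects": cfg.n_subjects,
        "criterion_id": cfg.criterion_id,
        "reference_id": cfg.reference_id,
        "rope_mass": cfg.rope_mass,
        "mv_subject_sd": cfg.mv_subject_sd,
        "protocol": {
            "load_fractions": [float(f) for f in cfg.protocol.load_fractions],
            "reps_per_load": cfg.protocol.reps_per_load,
            "load_rounding": cfg.protocol.load_rounding,
        },
        "table1": {
            "body_mass": _tn_to_dict(cfg.table1.body_mass),
            "relative_one_rm": {ex: _tn_to_dict(tn)
                                for ex, tn in cfg.table1.relative_one_rm.items()},
        },
        "trajectories": {
            ex: {
                "rom": tc.rom, "mv_at_min_load": tc.mv_at_min_load,
                "mv_at_max_load": tc.mv_at_max_load,
                "sampling_rate": tc.sampling_rate,
                "pause_duration": tc.pause_duration,
                "sticking_dip_depth": tc.sticking_dip_depth,
                "noise_sd": tc.noise_sd,
                "eccentric_velocity": tc.eccentric_velocity,
                "lead_in": tc.lead_in, "lead_out": tc.lead_out,
                "top_hold": tc.top_hold,
                "fraction_range": list(tc.fraction_range),
            } for ex, tc in cfg.trajectories.items()
        },
        "devices": [
            {
                "device_id": d.device_id, "alpha": d.alpha, "beta": d.beta,
                "sigma": d.sigma,
                "re_cov": [list(map(float, row)) for row in d.re_cov],
                "miss_prob": d.miss_prob, "ghost_prob": d.ghost_prob,
            } for d in cfg.devices
        ],
        "priors": {
            "beta_scale": cfg.priors.beta_scale,
            "sigma_scale": cfg.priors.sigma_scale,
            "tau_scale": cfg.priors.tau_scale,
            "lkj_eta": cfg.priors.lkj_eta,
        },
        "sampler": {
            "n_walkers": cfg.sampler.n_walkers, "n_warmup": cfg.sampler.n_warmup,
            "n_keep": cfg.sampler.n_keep, "thin": cfg.sampler.thin,
            "seed": cfg.sampler.seed,
        },
    }


def _config_from_dict(d: dict) -> RunConfig:
    kwargs: dict = {}
    for key in ("seed", "n_subjects", "criterion_id", "reference_id", "rope_mass",
                "mv_subject_sd"):
        if key in d:
            kwargs[key] = d[key]
    if "protocol" in d:
        p = d["protocol"]
        kwargs["protocol"] = ProtocolSpec(
            load_fractions=tuple(p.get("load_fractions", DEFAULT_PROTOCOL.load_fractions)),
            reps_per_load=p.get("reps_per_load", 1),
            load_rounding=p.get("load_rounding", 2.5))
    if "table1" in d:
        t = d["table1"]
        kwargs["table1"] = Table1Params(
            body_mass=TruncatedNormal(**t["body_mass"]),
            relative_one_rm={ex: TruncatedNormal(**tn)
                             for ex, tn in t["relative_one_rm"].items()})
    if "trajectories" in d:
        kwargs["trajectories"] = {
            ex: TrajectoryConfig(
                exercise=ex,
                **{k: (tuple(v) if k == "fraction_range" else v)
                   for k, v in spec.items()})
            for ex, spec in d["trajectories"].items()}
    if "devices" in d:
        kwargs["devices"] = tuple(
            DeviceProfile(
                device_id=spec["device_id"], alpha=spec.get("alpha", 0.0),
                beta=spec.get("beta", 1.0), sigma=spec.get("sigma", 0.0),
                re_cov=tuple(tuple(row) for row in spec.get("re_cov", ((0, 0), (0, 0)))),
                miss_prob=spec.get("miss_prob", 0.0),
                ghost_prob=spec.get("ghost_prob", 0.0))
            for spec in d["devices"])
    if "priors" in d:
        kwargs["priors"] = PriorSpec(**d["priors"])
    if "sampler" in d:
        kwargs["sampler"] = SamplerSpec(**d["sampler"])
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return _config_from_dict(yaml.safe_load(fh))


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest identifying a configuration."""
    canon = yaml.safe_dump(_config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
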