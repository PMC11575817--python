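"""End-to-end study orchestration: simulate, detect, pair, fit, judge.

``run_full_study`` reproduces the whole simulated validity study from a
single :class:`~vbtval.config.RunConfig`: cohort and loading ladder, one
criterion trajectory per attempt processed through the kinematics chain,
device observations from the ground-truth velocities, criterion/practical
pairing with missed/ghost bookkeeping, the two Bayesian mixed models per
device and exercise, and reference-anchored ROPE classification of the five
validity statistics.  ``run_external`` runs the same analysis on an existing
per-repetition table.  Analyses are per exercise and per device; nothing is
pooled across exercises.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataset as ds
from . import kinematics as kin
from . import models, rope, synthetic
from .config import RunConfig, config_hash, save_config

__all__ = ["StudyReport", "DeviceExerciseResult", "run_full_study",
           "run_external", "simulate_rep_tables"]

logger = logging.getLogger(__name__)

STATISTICS = ("intercept", "slope", "r2", "rmse", "smb")

_MIN_SUBJECTS = 2
_MIN_PAIRED = 10


@dataclass
class DeviceExerciseResult:
    """Posterior summaries and draws for one device in one exercise."""

    device_id: str
    exercise: str
    n_paired: int
    n_missed: int
    n_ghost: int
    summaries: dict[str, models.PosteriorSummary] = field(default_factory=dict)
    estimable: bool = True
    reason: str = ""

    @property
    def missed_rate(self) -> float:
        total = self.n_paired + self.n_missed
        return self.n_missed / total if total else float("nan")


@dataclass
class StudyReport:
    seed: int
    config_digest: str
    missed_rates: pd.DataFrame
    summaries: pd.DataFrame
    equivalence: pd.DataFrame
    results: dict[tuple[str, str], DeviceExerciseResult]
    criterion_summary: ds.VelocitySummary
    ropes: dict[tuple[str, str], rope.RopeRegion]

    def label(self, device_id: str, exercise: str, statistic: str) -> str:
        m = self.equivalence
        row = m[(m.device_id == device_id) & (m.exercise == exercise)
                & (m.statistic == statistic)]
        if row.empty:
            return "not_estimable"
        return row.label.iloc[0]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# seed={self.seed} config={self.config_digest}\n"
        for name, frame in (("missed_rates.csv", self.missed_rates),
                            ("validity_summaries.csv", self.summaries),
                            ("equivalence.csv", self.equivalence)):
            with open(out / name, "w") as fh:
                fh.write(header)
                frame.to_csv(fh, index=False)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.format_summary())

    def format_summary(self) -> str:
        lines = [f"Validity study report (seed={self.seed}, config={self.config_digest})",
                 "",
                 f"Criterion repetitions: n={self.criterion_summary.n}, "
                 f"MV {self.criterion_summary.mean:.2f} +/- {self.criterion_summary.sd:.2f} "
                 f"[{self.criterion_summary.min:.2f}-{self.criterion_summary.max:.2f}] m/s",
                 ""]
        for (dev, ex), res in sorted(self.results.items()):
            lines.append(f"== {dev} / {ex} ==")
            if not res.estimable:
                lines.append(f"  not estimable: {res.reason}")
                continue
            lines.append(f"  paired={res.n_paired} missed={res.n_missed} "
                         f"ghost={res.n_ghost} missed_rate={res.missed_rate:.1%}")
            for stat in STATISTICS:
                s = res.summaries[stat]
                lbl = self.label(dev, ex, stat)
                lines.append(f"  {stat:<9} {s.mean:8.4f} [{s.hdi_low:8.4f}, "
                             f"{s.hdi_high:8.4f}]  {lbl}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# simulation stages
# ---------------------------------------------------------------------------


def _child_seed(root: int, *salt: int) -> int:
    """Stable per-task seed below 2^31 (LCG-style mixing on Python ints)."""
    mask = (1 << 64) - 1
    h = root & mask
    for s in salt:
        h = (h * 6364136223846793005 + s + 1442695040888963407) & mask
    return h % (2 ** 31 - 1)


def simulate_rep_tables(config: RunConfig, out_dir: str | Path | None = None,
                        ) -> tuple[list[ds.RepObservation], dict[str, list[ds.RepObservation]], list[synthetic.TrueRep]]:
    """Simulate the measurement part of the study.

    Returns criterion observations (from the kinematics chain), practical
    observations per device (from the device error models applied to the
    ground-truth velocities), and the ground-truth repetitions.
    """
    cohort = synthetic.simulate_cohort(config.n_subjects, _child_seed(config.seed, 1),
                                       config.table1)
    true_reps: list[synthetic.TrueRep] = []
    criterion: list[ds.RepObservation] = []
    traj_dir = None
    if out_dir is not None:
        traj_dir = Path(out_dir) / "trajectories"
        traj_dir.mkdir(parents=True, exist_ok=True)
    shift_rng = np.random.default_rng(_child_seed(config.seed, 5))
    for si, subject in enumerate(cohort):
        for ei, exercise in enumerate(ds.EXERCISES):
            tcfg = config.trajectories[exercise]
            if config.mv_subject_sd > 0:
                # each lifter's load-velocity profile sits a bit above or
                # below the group line; keep the heaviest load liftable
                shift = float(shift_rng.normal(0.0, config.mv_subject_sd))
                shift = max(shift, 0.10 - tcfg.mv_at_max_load)
                tcfg = replace(tcfg,
                               mv_at_min_load=tcfg.mv_at_min_load + shift,
                               mv_at_max_load=tcfg.mv_at_max_load + shift)
            for li, frac in enumerate(config.protocol.load_fractions):
                load_pct = round(100 * frac, 1)
                seed = _child_seed(config.seed, 2, si, ei, li)
                traj, true_mv = synthetic.simulate_trajectory(
                    exercise, frac, tcfg, seed=seed,
                    subject_id=subject.subject_id, load_pct=load_pct,
                    set_index=li + 1)
                if traj_dir is not None:
                    kin.write_trajectory(traj, traj_dir / synthetic.trajectory_filename(
                        subject.subject_id, exercise, load_pct))
                true_reps.append(synthetic.TrueRep(
                    subject.subject_id, exercise, load_pct, li + 1, 1, true_mv))
                criterion.extend(kin.process_attempt(
                    traj, expected_reps=config.protocol.reps_per_load,
                    device_id=config.criterion_id))
    practical = {
        dev.device_id: synthetic.simulate_device(
            true_reps, dev, _child_seed(config.seed, 3, di))
        for di, dev in enumerate(config.devices)}
    return criterion, practical, true_reps


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------


def _analyze_device_exercise(paired: ds.PairedDataset, exercise: str,
                             config: RunConfig, fit_seed: int) -> DeviceExerciseResult:
    sub = paired.for_exercise(exercise)
    res = DeviceExerciseResult(paired.device_id, exercise, sub.n_paired,
                               sub.n_missed, sub.n_ghost)
    n_subj = sub.frame.subject_id.nunique() if sub.n_paired else 0
    if sub.n_paired < _MIN_PAIRED or n_subj < _MIN_SUBJECTS:
        res.estimable = False
        res.reason = (f"insufficient data: {sub.n_paired} paired reps from "
                      f"{n_subj} subject(s)")
        return res
    sampler1 = type(config.sampler)(**{**config.sampler.__dict__, "seed": fit_seed})
    sampler2 = type(config.sampler)(**{**config.sampler.__dict__, "seed": fit_seed + 1})
    fit1 = models.fit_model1(sub, config.priors, sampler1)
    fit2 = models.fit_model2(sub, config.priors, sampler2)
    scale_sd = float(sub.frame.criterion_mv.std(ddof=1))
    res.summaries = {
        "intercept": fit1.summary("intercept"),
        "slope": fit1.summary("slope"),
        "r2": models.compute_r2(fit1),
        "rmse": models.compute_rmse(fit1),
        "smb": models.compute_smb(fit2, scale_sd),
    }
    return res


def _analyze(criterion: list[ds.RepObservation],
             practical: dict[str, list[ds.RepObservation]],
             config: RunConfig) -> StudyReport:
    if not practical:
        raise ValueError("no practical devices to analyze")
    if config.reference_id not in practical:
        raise ValueError(
            f"reference device {config.reference_id!r} not among devices "
            f"{sorted(practical)}")
    paired = {dev: ds.match_reps(criterion, obs) for dev, obs in practical.items()}

    results: dict[tuple[str, str], DeviceExerciseResult] = {}
    missed_rows = []
    for di, (dev, pset) in enumerate(sorted(paired.items())):
        for ei, exercise in enumerate(ds.EXERCISES):
            fit_seed = _child_seed(config.seed, 4, di, ei)
            res = _analyze_device_exercise(pset, exercise, config, fit_seed)
            results[(dev, exercise)] = res
            missed_rows.append({
                "device_id": dev, "exercise": exercise,
                "n_paired": res.n_paired, "n_missed": res.n_missed,
                "n_ghost": res.n_ghost, "missed_rate": res.missed_rate})
            logger.info("%s/%s: paired=%d missed=%d ghost=%d estimable=%s",
                        dev, exercise, res.n_paired, res.n_missed, res.n_ghost,
                        res.estimable)

    # reference-anchored ROPEs, then classification of every device
    ropes: dict[tuple[str, str], rope.RopeRegion] = {}
    for exercise in ds.EXERCISES:
        ref = results[(config.reference_id, exercise)]
        if not ref.estimable:
            continue
        for stat in STATISTICS:
            ropes[(exercise, stat)] = rope.build_rope(
                ref.summaries[stat].draws, rope.PERFECT_VALUES[stat], stat,
                mass=config.rope_mass, reference_device=config.reference_id)

    sum_rows, eq_rows = [], []
    for (dev, exercise), res in sorted(results.items()):
        if not res.estimable:
            sum_rows.append({"device_id": dev, "exercise": exercise,
                             "statistic": "", "mean": np.nan, "hdi_low": np.nan,
                             "hdi_high": np.nan, "rhat_max": np.nan,
                             "ess_min": np.nan, "note": res.reason})
            continue
        for stat in STATISTICS:
            s = res.summaries[stat]
            sum_rows.append({"device_id": dev, "exercise": exercise,
                             "statistic": stat, "mean": s.mean,
                             "hdi_low": s.hdi_low, "hdi_high": s.hdi_high,
                             "rhat_max": s.rhat_max, "ess_min": s.ess_min,
                             "note": "flagged" if s.flagged else ""})
            key = (exercise, stat)
            if key not in ropes:
                continue
            ev = rope.evaluate_device(dev, stat, s.draws, ropes[key],
                                      rule_mass=config.rope_mass)
            eq_rows.append({"device_id": dev, "exercise": exercise,
                            "statistic": stat, "p_in_rope": ev.p_in_rope,
                            "p_below_rope": ev.direction_probs["below_low"],
                            "p_above_rope": ev.direction_probs["above_high"],
                            "rope_low": ropes[key].low, "rope_high": ropes[key].high,
                            "label": ev.label})

    crit_summary = ds.summarize_velocities(criterion)
    return StudyReport(
        seed=config.seed, config_digest=config_hash(config),
        missed_rates=pd.DataFrame(missed_rows),
        summaries=pd.DataFrame(sum_rows),
        equivalence=pd.DataFrame(eq_rows),
        results=results, criterion_summary=crit_summary, ropes=ropes)


def run_full_study(config: RunConfig, out_dir: str | Path | None = None,
                   write_trajectories: bool = False) -> StudyReport:
    """Simulate and analyze a complete study; optionally write all artifacts."""
    criterion, practical, true_reps = simulate_rep_tables(
        config, out_dir if write_trajectories else None)
    n_true = len(true_reps)
    n_crit = sum(1 for o in criterion if o.status == "ok")
    if n_crit != n_true:
        logger.warning("criterion chain recovered %d of %d simulated reps",
                       n_crit, n_true)
    report = _analyze(criterion, practical, config)
    # reconciliation: paired + missed must equal criterion reps for every device
    for dev in practical:
        sub = report.missed_rates[report.missed_rates.device_id == dev]
        if int(sub.n_paired.sum() + sub.n_missed.sum()) != n_crit:
            raise AssertionError(f"rep bookkeeping broken for {dev}")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out)
        save_config(config, out / "config.yaml")
        ds.write_rep_table(criterion
                           + [o for obs in practical.values() for o in obs],
                           out / "rep_observations.csv")
    return report


def run_external(rep_table: str | Path, criterion_id: str, reference_id: str,
                 config: RunConfig | None = None,
                 out_dir: str | Path | None = None) -> StudyReport:
    """Analyze an existing per-repetition table (skips simulation/kinematics)."""
    obs = ds.read_rep_table(rep_table)
    found = sorted({o.device_id for o in obs})
    if criterion_id not in found:
        raise ValueError(f"criterion {criterion_id!r} not in table; found {found}")
    if reference_id not in found:
        raise ValueError(f"reference {reference_id!r} not in table; found {found}")
    criterion = [o for o in obs if o.device_id == criterion_id]
    practical = {dev: [o for o in obs if o.device_id == dev]
                 for dev in found if dev != criterion_id}
    if config is None:
        config = RunConfig()
    if config.reference_id != reference_id or config.criterion_id != criterion_id:
        from dataclasses import replace
        # device profiles in the config are irrelevant here; keep ids consistent
        config = replace(config, criterion_id=criterion_id, reference_id=reference_id,
                         devices=tuple(synthetic.DeviceProfile(dev) for dev in practical))
    report = _analyze(criterion, practical, config)
    if out_dir is not None:
        report.write(out_dir)
    return report
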