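"""Reference-anchored regions of practical equivalence (ROPE).

The practical relevance of a device's error is judged against a reference
device rather than an absolute cut-off: for each validity statistic the
reference posterior's 95% HDI limit farther from the perfect value (intercept
0, slope 1, R^2 1, RMSE 0, SMB 0) defines the region boundary.  Unbounded
statistics get a symmetric region around the perfect value; R^2 (<= 1) and
RMSE (>= 0) get one-sided regions ending at their boundary-perfect value.

A posterior claim is labelled "likely" only when at least 95% of posterior
mass supports it; otherwise the comparison is reported as unclear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .models import hdi

__all__ = [
    "PERFECT_VALUES",
    "ONE_SIDED_UPPER",
    "ONE_SIDED_LOWER",
    "RopeRegion",
    "EquivalenceResult",
    "build_rope",
    "equivalence_probability",
    "direction_probability",
    "classify",
]

PERFECT_VALUES = {"intercept": 0.0, "slope": 1.0, "r2": 1.0, "rmse": 0.0, "smb": 0.0}
ONE_SIDED_UPPER = {"r2"}    # statistic bounded above by its perfect value
ONE_SIDED_LOWER = {"rmse"}  # statistic bounded below by its perfect value

LIKELY_EQUIVALENT = "likely_equivalent"
LIKELY_DIFFERENT = "likely_different"
UNCLEAR = "unclear"


@dataclass(frozen=True)
class RopeRegion:
    statistic: str
    perfect_value: float
    low: float
    high: float
    reference_device: str = ""

    def __post_init__(self) -> None:
        if not self.low <= self.perfect_value <= self.high:
            raise ValueError(
                f"ROPE [{self.low}, {self.high}] must contain the perfect value "
                f"{self.perfect_value}")

    @property
    def half_width(self) -> float:
        return max(self.high - self.perfect_value, self.perfect_value - self.low)


@dataclass(frozen=True)
class EquivalenceResult:
    statistic: str
    device: str
    p_in_rope: float
    direction_probs: Mapping[str, float]
    label: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_in_rope <= 1:
            raise ValueError("p_in_rope must lie in [0, 1]")


def build_rope(reference_draws: np.ndarray, perfect_value: float, statistic: str,
               mass: float = 0.95, reference_device: str = "") -> RopeRegion:
    """ROPE from the reference posterior's more extreme HDI limit.

    For two-sided statistics the region is symmetric about the perfect value
    with half-width |extreme limit - perfect value|; for R^2 it is
    [extreme lower limit, 1] and for RMSE it is [0, extreme upper limit].
    """
    lo, hi = hdi(np.asarray(reference_draws, dtype=float), mass)
    if statistic in ONE_SIDED_UPPER:
        if lo > perfect_value:
            raise ValueError(
                f"reference HDI [{lo:.4g}, {hi:.4g}] lies above the perfect value")
        return RopeRegion(statistic, perfect_value, lo, perfect_value, reference_device)
    if statistic in ONE_SIDED_LOWER:
        if hi < perfect_value:
            raise ValueError(
                f"reference HDI [{lo:.4g}, {hi:.4g}] lies below the perfect value")
        return RopeRegion(statistic, perfect_value, perfect_value, hi, reference_device)
    half = max(abs(lo - perfect_value), abs(hi - perfect_value))
    return RopeRegion(statistic, perfect_value, perfect_value - half,
                      perfect_value + half, reference_device)


def equivalence_probability(device_draws: np.ndarray, rope: RopeRegion) -> float:
    """Posterior probability of the statistic falling inside the ROPE (inclusive)."""
    d = np.asarray(device_draws, dtype=float)
    if d.size < 100:
        raise ValueError(f"need at least 100 draws, got {d.size}")
    return float(np.mean((d >= rope.low) & (d <= rope.high)))


def direction_probability(device_draws: np.ndarray, threshold: float,
                          side: str) -> float:
    """Posterior probability of the statistic lying strictly on one side."""
    d = np.asarray(device_draws, dtype=float)
    if d.size < 100:
        raise ValueError(f"need at least 100 draws, got {d.size}")
    if side == "below":
        return float(np.mean(d < threshold))
    if side == "above":
        return float(np.mean(d > threshold))
    raise ValueError(f"side must be 'below' or 'above', got {side!r}")


def classify(p_in_rope: float, direction_probs: Mapping[str, float] | None = None,
             rule_mass: float = 0.95) -> str:
    """Label a posterior as likely equivalent, likely different, or unclear.

    ``direction_probs`` holds probabilities of the statistic lying beyond each
    ROPE edge (e.g. {"below_low": ..., "above_high": ...}); a directional
    claim at or above ``rule_mass`` also yields "likely different" when the
    equivalence probability misses its threshold.
    """
    if not 0 <= p_in_rope <= 1:
        raise ValueError("p_in_rope must lie in [0, 1]")
    if p_in_rope >= rule_mass:
        return LIKELY_EQUIVALENT
    if p_in_rope <= 1 - rule_mass:
        return LIKELY_DIFFERENT
    if direction_probs:
        if any(p >= rule_mass for p in direction_probs.values()):
            return LIKELY_DIFFERENT
    return UNCLEAR


def evaluate_device(device: str, statistic: str, device_draws: np.ndarray,
                    rope: RopeRegion, rule_mass: float = 0.95) -> EquivalenceResult:
    """Convenience wrapper: probabilities plus label for one device/statistic."""
    p_in = equivalence_probability(device_draws, rope)
    dirs = {
        "below_low": direction_probability(device_draws, rope.low, "below"),
        "above_high": direction_probability(device_draws, rope.high, "above"),
    }
    return EquivalenceResult(statistic, device, p_in, dirs,
                             classify(p_in, dirs, rule_mass))
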