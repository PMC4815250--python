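"""Block- and day-level performance metrics.

TPR is the fraction of attempted trials in a block whose intent was detected;
FPR the fraction of catch trials with a (falsely) accepted intent.  The
responsiveness metric is intents per minute, 60 / (seconds from trial start
to accepted detection), computed over correctly detected attempted trials
only, with its within-block coefficient of variation (sample SD / mean).
Detection latency is accepted-detection time minus the kinematic movement
onset (velocity-threshold crossing); negative values mean the intent preceded
physical movement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .online_sim import TrialOutcome

__all__ = [
    "BlockMetrics",
    "block_metrics",
    "movement_onset_from_kinematics",
    "velocity_threshold_from_practice",
    "compare_days",
    "trend_slope",
]


@dataclass
class BlockMetrics:
    tpr_pct: float
    fpr_pct: float
    intents_per_min: list[float]
    cov: float | None
    latencies_s: list[float]
    n_attempted: int
    n_catch: int
    n_detected: int
    n_false_positive: int

    def as_dict(self) -> dict:
        return {
            "tpr_pct": self.tpr_pct,
            "fpr_pct": self.fpr_pct,
            "intents_per_min_mean": float(np.mean(self.intents_per_min))
            if self.intents_per_min else None,
            "cov": self.cov,
            "latency_mean_s": float(np.mean(self.latencies_s)) if self.latencies_s else None,
            "n_attempted": self.n_attempted,
            "n_catch": self.n_catch,
        }


def block_metrics(outcomes: list[TrialOutcome]) -> BlockMetrics:
    """Metrics for one block of trial outcomes."""
    attempted = [o for o in outcomes if not o.is_catch]
    catch = [o for o in outcomes if o.is_catch]
    detected = [o for o in attempted if o.detected]
    false_pos = [o for o in catch if o.detected]
    tpr = 100.0 * len(detected) / len(attempted) if attempted else float("nan")
    fpr = 100.0 * len(false_pos) / len(catch) if catch else float("nan")
    ipm = [60.0 / o.time_to_detect_s for o in detected if o.time_to_detect_s and o.time_to_detect_s > 0]
    cov = None
    if len(ipm) >= 2 and np.mean(ipm) > 0:
        cov = float(np.std(ipm, ddof=1) / np.mean(ipm))
    lat = [o.latency_s for o in detected if o.latency_s is not None]
    return BlockMetrics(
        tpr_pct=tpr, fpr_pct=fpr, intents_per_min=ipm, cov=cov, latencies_s=lat,
        n_attempted=len(attempted), n_catch=len(catch),
        n_detected=len(detected), n_false_positive=len(false_pos),
    )


def movement_onset_from_kinematics(velocity: np.ndarray, fs: float,
                                   threshold_dps: float) -> float | None:
    """Time of the first |velocity| crossing of the threshold, or None."""
    if threshold_dps <= 0:
        raise ValueError("threshold must be positive")
    idx = np.flatnonzero(np.abs(np.asarray(velocity)) > threshold_dps)
    return float(idx[0] / fs) if idx.size else None


def velocity_threshold_from_practice(peak_velocities_dps) -> float:
    """5% of the mean peak velocity over practice trials."""
    peaks = np.asarray(peak_velocities_dps, dtype=float)
    if peaks.size == 0:
        raise ValueError("no practice peaks given")
    return 0.05 * float(peaks.mean())


def compare_days(metrics_a, metrics_b) -> tuple[float, float]:
    """Two-sided rank-sum comparison of a metric between two sessions.

    Exact null distribution for small tie-free samples, normal approximation
    otherwise.  Returns (statistic, p_value).
    """
    a = np.asarray(metrics_a, dtype=float)
    b = np.asarray(metrics_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def trend_slope(values, block_indices=None) -> tuple[float, float]:
    """OLS slope of a block-wise metric against block index, with its p."""
    y = np.asarray(values, dtype=float)
    x = np.arange(len(y)) if block_indices is None else np.asarray(block_indices, float)
    if len(y) < 3 or np.allclose(y, y[0]):
        # degenerate: no trend testable; slope still defined for constant y
        if len(y) >= 2 and np.allclose(y, y[0]):
            return 0.0, 1.0
        raise ValueError("need at least three observations for a trend")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.pvalue)
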