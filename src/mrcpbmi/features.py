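"""Windowing and time-domain feature extraction on the spatial-average trace.

The single detection trace is the arithmetic mean over the selected
sensorimotor channels.  A feature window is described by its leading edge
(onset time) and its length, looking back into the past: it spans
``[edge - wl, edge]`` inclusive, so a window of length ``wl`` at 20 Hz holds
``round(wl * fs) + 1`` samples.

Four features are computed per windowed segment: least-squares slope (muV/s),
negative-peak amplitude (muV), trapezoidal area (muV*s) and the Mahalanobis
distance to the Go-class cluster of windowed amplitude vectors.  The distance
uses the standard +1/2 exponent, d = sqrt((x-mu)^T Sigma^-1 (x-mu)): a
segment resembling the Go cluster must score near 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WindowSpec",
    "GoClusterStats",
    "PEAK_SEARCH_INTERVAL_S",
    "ADAPTIVE_REJECT_BEFORE_S",
    "FIXED_GO_EDGE_S",
    "NOGO_EDGE_S",
    "window_n_samples",
    "spatial_average",
    "find_negative_peak",
    "place_adaptive_window",
    "place_fixed_window",
    "window_samples",
    "fit_go_stats",
    "extract_features",
    "extract_features_batch",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("slope", "neg_peak", "area", "mahal_d")

#: Search interval for the per-trial negative peak, relative to alignment.
PEAK_SEARCH_INTERVAL_S = (-2.0, 0.5)
#: Training trials whose spatial-average peak precedes this are screened out.
ADAPTIVE_REJECT_BEFORE_S = -1.5
#: Fixed Go window edge: +0.5 s after movement-onset (compensates IIR lag).
FIXED_GO_EDGE_S = 0.5
#: No-go window edge: 0.5 s before target-onset (fixation interval).
NOGO_EDGE_S = -0.5


@dataclass(frozen=True)
class WindowSpec:
    """Feature window spanning ``[edge_s - wl_s, edge_s]``."""

    edge_s: float
    wl_s: float
    mode: str = "fixed"  # fixed | adaptive

    @property
    def span_s(self) -> tuple[float, float]:
        return (self.edge_s - self.wl_s, self.edge_s)


@dataclass
class GoClusterStats:
    """Mean and (ridge-regularized) covariance of Go windowed amplitude vectors."""

    mu: np.ndarray
    sigma: np.ndarray
    sigma_inv: np.ndarray
    ridge_eps: float
    n_window: int


def window_n_samples(wl_s: float, fs: float) -> int:
    return round(wl_s * fs) + 1


def spatial_average(epoch: np.ndarray, channel_idx=None) -> np.ndarray:
    """Pointwise mean over the selected channel rows of a channels x time epoch."""
    epoch = np.asarray(epoch, dtype=np.float64)
    if channel_idx is not None:
        if len(channel_idx) == 0:
            raise ValueError("channel list must be non-empty")
        epoch = epoch[..., channel_idx, :]
    return epoch.mean(axis=-2)


def find_negative_peak(trace: np.ndarray, fs: float, t_start: float,
                       interval: tuple[float, float] = PEAK_SEARCH_INTERVAL_S) -> float:
    """Time of the most negative sample within ``interval`` (ties -> latest)."""
    lo = round((interval[0] - t_start) * fs)
    hi = round((interval[1] - t_start) * fs)
    if lo < 0 or hi >= len(trace):
        raise ValueError("search interval extends beyond the epoch")
    seg = trace[lo:hi + 1]
    idx = len(seg) - 1 - int(np.argmin(seg[::-1]))
    return t_start + (lo + idx) / fs


def place_adaptive_window(trace: np.ndarray, wl_s: float, fs: float, t_start: float,
                          interval: tuple[float, float] = PEAK_SEARCH_INTERVAL_S,
                          reject_before_s: float = ADAPTIVE_REJECT_BEFORE_S,
                          ) -> WindowSpec | None:
    """Adaptive Go window with its edge at the trace's negative peak.

    Returns ``None`` when the peak precedes ``reject_before_s`` (strictly),
    marking the trial as likely artifact-corrupted and excluded from
    training.  If the window would leave the epoch, the edge is clamped so
    the window fits.
    """
    peak_t = find_negative_peak(trace, fs, t_start, interval)
    if peak_t < reject_before_s:
        return None
    min_edge = t_start + wl_s
    max_edge = t_start + (len(trace) - 1) / fs
    edge = min(max(peak_t, min_edge), max_edge)
    return WindowSpec(edge_s=edge, wl_s=wl_s, mode="adaptive")


def place_fixed_window(wl_s: float, align_kind: str = "go") -> WindowSpec:
    """Fixed window: Go edge at +0.5 s after movement-onset, No-go at -0.5 s
    before target-onset."""
    if align_kind == "go":
        return WindowSpec(edge_s=FIXED_GO_EDGE_S, wl_s=wl_s, mode="fixed")
    if align_kind == "nogo":
        return WindowSpec(edge_s=NOGO_EDGE_S, wl_s=wl_s, mode="fixed")
    raise ValueError(f"align_kind must be 'go' or 'nogo', got {align_kind!r}")


def window_samples(trace: np.ndarray, spec: WindowSpec, fs: float, t_start: float) -> np.ndarray:
    """Amplitude vector of the windowed segment (``n_window`` samples)."""
    n_win = window_n_samples(spec.wl_s, fs)
    edge_idx = round((spec.edge_s - t_start) * fs)
    start = edge_idx - n_win + 1
    if start < 0 or edge_idx >= len(trace):
        raise ValueError(f"window {spec.span_s} outside the epoch")
    return trace[start:edge_idx + 1]


def fit_go_stats(go_windows: np.ndarray, ridge_eps: float | None = None) -> GoClusterStats:
    """Sample mean/covariance of the Go windowed amplitude vectors.

    ``ridge_eps`` defaults to ``1e-6 * trace(Sigma) / dim`` (absolute 1e-6
    when the covariance is all-zero).  The regularized covariance must be
    invertible; a singular matrix raises with guidance to raise ``ridge_eps``.
    """
    X = np.asarray(go_windows, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two equal-length Go windows")
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1)
    d = X.shape[1]
    if ridge_eps is None:
        tr = float(np.trace(sigma))
        ridge_eps = 1e-6 * tr / d if tr > 0 else 1e-6
    reg = sigma + ridge_eps * np.eye(d)
    try:
        sigma_inv = np.linalg.inv(reg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularized Go covariance is singular; raise ridge_eps"
        ) from exc
    return GoClusterStats(mu=mu, sigma=sigma, sigma_inv=sigma_inv,
                          ridge_eps=ridge_eps, n_window=d)


def mahalanobis(x: np.ndarray, stats: GoClusterStats) -> float:
    diff = np.asarray(x, dtype=np.float64) - stats.mu
    return float(np.sqrt(max(diff @ stats.sigma_inv @ diff, 0.0)))


def extract_features(x: np.ndarray, stats: GoClusterStats, dt: float) -> np.ndarray:
    """Four features (slope, neg_peak, area, mahal_d) of one windowed segment."""
    return extract_features_batch(np.asarray(x, dtype=np.float64)[None, :], stats, dt)[0]


def extract_features_batch(X: np.ndarray, stats: GoClusterStats, dt: float) -> np.ndarray:
    """Vectorized feature extraction over rows of ``X`` (m x n_window).

    Slope is the least-squares linear-fit slope of amplitude against time;
    area is the trapezoidal integral over the window; neg_peak the minimum
    amplitude; mahal_d the Mahalanobis distance to the Go cluster.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (segments x window samples)")
    n = X.shape[1]
    if n != stats.n_window:
        raise ValueError(f"window has {n} samples, Go stats expect {stats.n_window}")
    t = np.arange(n) * dt
    tc = t - t.mean()
    slope = (X @ tc) / (tc @ tc)
    neg_peak = X.min(axis=1)
    area = np.trapezoid(X, dx=dt, axis=1)
    diff = X - stats.mu
    mahal = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", diff, stats.sigma_inv, diff), 0.0))
    return np.column_stack([slope, neg_peak, area, mahal])
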