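"""Time-course postprocessing and motion quality control.

Reproduces the standard pre-dFNC cleanup of ICA component time courses:
24-parameter motion confound expansion, Power-style framewise
displacement with fixed exclusion thresholds, dropping of the initial
dummy volumes, linear detrending, running-median despiking, confound
regression, and zero-phase low-pass Butterworth filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt

__all__ = [
    "ConfoundMatrix24",
    "QCConfig",
    "FilterSpec",
    "QCDecision",
    "expand_confounds",
    "framewise_displacement",
    "motion_qc",
    "preprocess_timecourses",
]


@dataclass
class ConfoundMatrix24:
    """T x 24 motion confounds: 6 base, 6 backward-difference derivatives,
    6 squared base, 6 squared derivatives (in that column order)."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 2 or self.values.shape[1] != 24:
            raise ValueError("confound matrix must have exactly 24 columns")

    column_roles = tuple(
        [f"trans_rot_{i}" for i in range(6)]
        + [f"deriv_{i}" for i in range(6)]
        + [f"base_sq_{i}" for i in range(6)]
        + [f"deriv_sq_{i}" for i in range(6)]
    )


@dataclass
class QCConfig:
    """Motion-exclusion thresholds (mm)."""

    mean_fd_max: float = 0.25
    fd_spike_thresh: float = 0.2
    spike_frac_max: float = 0.20
    head_radius: float = 50.0

    def __post_init__(self):
        if min(self.mean_fd_max, self.fd_spike_thresh, self.head_radius) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.spike_frac_max < 1:
            raise ValueError("spike_frac_max must lie in (0, 1)")


@dataclass
class FilterSpec:
    """Low-pass Butterworth filter, applied forward-backward (zero phase)."""

    order: int = 5
    cutoff_hz: float = 0.15
    TR: float = 1.76

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        nyquist = 0.5 / self.TR
        if not 0 < self.cutoff_hz < nyquist:
            raise ValueError(
                f"cutoff {self.cutoff_hz} Hz must lie below Nyquist {nyquist:.3f} Hz"
            )


@dataclass
class QCDecision:
    mean_fd: float
    frac_above: float
    include: bool
    reason: str


def expand_confounds(motion6: np.ndarray) -> ConfoundMatrix24:
    """Expand 6 rigid-body parameters to the 24-parameter confound set.

    Derivatives are backward differences with the first row zero;
    quadratic terms are element-wise squares of the base parameters and of
    their derivatives.
    """
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion matrix must be T x 6, got {m.shape}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    if not np.isfinite(m).all():
        raise ValueError("motion parameters must be finite")
    d = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
    return ConfoundMatrix24(values=np.hstack([m, d, m**2, d**2]))


def framewise_displacement(motion6: np.ndarray, head_radius: float = 50.0) -> np.ndarray:
    """Power-style FD: sum of absolute backward differences of the three
    translations (mm) plus ``head_radius`` times those of the three
    rotations (rad), i.e., arc length on a sphere.  FD of the first volume
    is 0.
    """
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion matrix must be T x 6, got {m.shape}")
    if not np.isfinite(m).all():
        raise ValueError("motion parameters must be finite")
    d = np.abs(np.diff(m, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.r_[0.0, fd]


def motion_qc(fd: np.ndarray, cfg: QCConfig | None = None) -> QCDecision:
    """Exclude a session whose mean FD exceeds ``mean_fd_max`` or whose
    fraction of volumes with FD above ``fd_spike_thresh`` exceeds
    ``spike_frac_max``."""
    cfg = cfg or QCConfig()
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    mean_fd = float(fd.mean())
    frac = float((fd > cfg.fd_spike_thresh).mean())
    reasons = []
    if mean_fd > cfg.mean_fd_max:
        reasons.append(f"mean FD {mean_fd:.3f} mm > {cfg.mean_fd_max} mm")
    if frac > cfg.spike_frac_max:
        reasons.append(
            f"{100 * frac:.1f}% of volumes with FD > {cfg.fd_spike_thresh} mm "
            f"(limit {100 * cfg.spike_frac_max:.0f}%)"
        )
    return QCDecision(
        mean_fd=mean_fd,
        frac_above=frac,
        include=not reasons,
        reason="; ".join(reasons) if reasons else "pass",
    )


def _despike(x: np.ndarray, window: int, k: float) -> np.ndarray:
    """Clip samples deviating from a running median by more than k MADs."""
    med = median_filter(x, size=(window, 1), mode="nearest")
    resid = x - med
    mad = 1.4826 * np.median(np.abs(resid), axis=0, keepdims=True)
    lim = k * np.where(mad > 0, mad, np.inf)
    return med + np.clip(resid, -lim, lim)


def _detrend_linear(x: np.ndarray) -> np.ndarray:
    T = x.shape[0]
    A = np.column_stack([np.ones(T), np.arange(T)])
    beta, *_ = np.linalg.lstsq(A, x, rcond=None)
    return x - A @ beta


def preprocess_timecourses(
    ts: np.ndarray,
    confounds: ConfoundMatrix24 | np.ndarray,
    filt: FilterSpec | None = None,
    n_drop: int = 4,
    despike_k: float | None = 5.0,
    despike_window: int = 7,
) -> np.ndarray:
    """Clean component time courses for windowed connectivity.

    Order of operations: (1) drop the first ``n_drop`` volumes from both
    signals and confounds; (2) remove a per-component least-squares line;
    (3) despike against a running median (``despike_k`` MADs, disabled if
    None); (4) regress out the 24 confound columns; (5) zero-phase
    low-pass Butterworth filter.  Returns a (T - n_drop) x C matrix.
    """
    filt = filt or FilterSpec()
    X = np.asarray(ts, dtype=float)
    conf = confounds.values if isinstance(confounds, ConfoundMatrix24) else np.asarray(confounds)
    if conf.shape[0] != X.shape[0]:
        raise ValueError(
            f"confound rows ({conf.shape[0]}) must match time-course rows ({X.shape[0]})"
        )
    X = X[n_drop:]
    conf = conf[n_drop:]

    X = _detrend_linear(X)
    if despike_k is not None:
        X = _despike(X, despike_window, despike_k)

    # Residualize on the confounds (plus intercept; signals are mean-free
    # after detrending, so no mean is re-added).
    A = np.column_stack([np.ones(X.shape[0]), conf - conf.mean(axis=0)])
    beta, *_ = np.linalg.lstsq(A, X, rcond=None)
    X = X - A @ beta

    b, a = butter(filt.order, filt.cutoff_hz * 2 * filt.TR, btype="low")
    return filtfilt(b, a, X, axis=0)
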