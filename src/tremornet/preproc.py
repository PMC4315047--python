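"""Temporal cleaning of BOLD runs and head-motion summaries.

The pipeline order is fixed: drop initial volumes -> linear detrend ->
band-pass -> nuisance regression.  Spatial steps (slice timing,
realignment, normalisation) are assumed done upstream; all runs share a
common voxel grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

logger = logging.getLogger(__name__)

__all__ = [
    "BoldRun",
    "MotionSummary",
    "ideal_bandpass",
    "filter_timeseries",
    "friston24",
    "nuisance_regress",
    "motion_summaries",
    "drop_initial_volumes",
    "preprocess_run",
]


@dataclass
class BoldRun:
    """One subject's 4D voxel time series with geometry.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD intensities.
    mask : ndarray of bool, shape (x, y, z)
        Analysis (brain) mask.
    tr : float
        Repetition time in seconds.
    affine : ndarray, shape (4, 4)
        Voxel-index to mm map.
    """

    data: np.ndarray
    mask: np.ndarray
    tr: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, t); got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape {self.data.shape[:3]}"
            )
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 time points")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((np.asarray(self.affine)[:3, :3] ** 2).sum(axis=0))

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)

    def masked_series(self) -> np.ndarray:
        """Return (n_mask_voxels, t) series in C order of the mask."""
        return self.data[self.mask]


@dataclass(frozen=True)
class MotionSummary:
    """Gross and micro head-motion scalars (all in mm)."""

    max_disp: float
    rms_disp: float
    mean_fd: float

    def as_array(self) -> np.ndarray:
        return np.array([self.max_disp, self.rms_disp, self.mean_fd])


def _bandpass_mask(n: int, tr: float, low: float, high: float) -> np.ndarray:
    """Boolean keep-mask over rfft frequency bins for an ideal band-pass."""
    freqs = np.fft.rfftfreq(n, d=tr)
    return (freqs >= low) & (freqs <= high)


def ideal_bandpass(x: np.ndarray, tr: float, low: float, high: float, axis: int = -1) -> np.ndarray:
    """Rectangular frequency-domain band-pass: zero every rfft bin outside
    [low, high] Hz.  Exactly idempotent."""
    n = x.shape[axis]
    keep = _bandpass_mask(n, tr, low, high)
    spec = np.fft.rfft(x, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = keep.size
    spec = spec * keep.reshape(shape)
    return np.fft.irfft(spec, n=n, axis=axis)


def bandpass_variance_fraction(n: int, tr: float, low: float, high: float) -> float:
    """Fraction of white-noise variance retained by the ideal band-pass.

    Counts rfft bins with their spectral multiplicity (DC and, for even n,
    Nyquist carry weight 1; interior bins weight 2).
    """
    keep = _bandpass_mask(n, tr, low, high)
    w = np.full(keep.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    return float(w[keep].sum() / n)


def filter_timeseries(
    run: BoldRun,
    low: float,
    high: float,
    detrend: bool = True,
    mode: str = "ideal",
    order: int = 4,
) -> BoldRun:
    """Detrend (remove per-voxel linear trend) then band-pass filter.

    Parameters
    ----------
    low, high : float
        Pass band in Hz; requires 0 <= low < high <= Nyquist.
    mode : {"ideal", "butter"}
        "ideal" zeroes out-of-band FFT coefficients (idempotent);
        "butter" applies a zero-phase Butterworth of the given order.
    """
    nyq = run.nyquist
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high; got low={low}, high={high}")
    if high > nyq + 1e-12:
        raise ValueError(f"high={high} Hz exceeds Nyquist {nyq} Hz for tr={run.tr}s")
    data = run.data
    if detrend:
        data = sp_signal.detrend(data, axis=-1, type="linear")
    if mode == "ideal":
        data = ideal_bandpass(data, run.tr, low, high, axis=-1)
    elif mode == "butter":
        sos = sp_signal.butter(order, [max(low, 1e-6), high], btype="bandpass", fs=1.0 / run.tr, output="sos")
        data = sp_signal.sosfiltfilt(sos, data, axis=-1)
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return replace(run, data=data)


def friston24(motion6: np.ndarray) -> np.ndarray:
    """Expand 6 rigid-body parameters to the 24-regressor motion model:
    the 6 parameters, their one-volume lag (first row zero-padded), and
    the squares of both sets."""
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns; got shape {m.shape}")
    lag = np.vstack([np.zeros((1, 6)), m[:-1]])
    return np.hstack([m, lag, m**2, lag**2])


def nuisance_regress(
    run: BoldRun,
    motion6: np.ndarray,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    extra_confounds: np.ndarray | None = None,
) -> BoldRun:
    """Regress nuisance signals out of every voxel series.

    Design = intercept + Friston-24 motion expansion + mean WM series +
    mean CSF series (+ any extra columns).  Residuals replace the data.
    Collinear design columns are dropped with a logged warning.
    """
    t = run.n_volumes
    motion6 = np.asarray(motion6, dtype=float)
    if motion6.shape[0] != t:
        raise ValueError(f"motion table has {motion6.shape[0]} rows, expected {t}")
    cols = [np.ones((t, 1)), friston24(motion6)]
    for name, m in (("wm", wm_mask), ("csf", csf_mask)):
        if m is not None:
            m = np.asarray(m, dtype=bool)
            if m.shape != run.mask.shape:
                raise ValueError(f"{name} mask shape {m.shape} does not match grid")
            if m.any():
                cols.append(run.data[m].mean(axis=0)[:, None])
    if extra_confounds is not None:
        cols.append(np.atleast_2d(np.asarray(extra_confounds, dtype=float)).reshape(t, -1))
    X = np.hstack(cols)

    # drop collinear columns (keep earliest of each dependent set)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        logger.warning("nuisance design rank-deficient: dropping %d collinear column(s)", (~keep).sum())
        X = X[:, keep]

    beta, *_ = np.linalg.lstsq(X, run.data.reshape(-1, t).T, rcond=None)
    resid = run.data.reshape(-1, t).T - X @ beta
    return replace(run, data=resid.T.reshape(run.data.shape))


def motion_summaries(motion6: np.ndarray, rotation_radius_mm: float = 50.0) -> MotionSummary:
    """Summarise a 6-column motion trace (3 translations mm, 3 rotations rad).

    max_disp / rms_disp are the max and RMS of the per-volume Euclidean
    translation norm.  mean_fd is Power-style frame-wise displacement: the
    mean over successive volume pairs of the summed absolute backward
    differences of all 6 parameters, rotations converted to arc length on
    a sphere of ``rotation_radius_mm``.
    """
    m = np.asarray(motion6, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError(f"motion table must have 6 columns; got shape {m.shape}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 volumes to summarise motion")
    trans_norm = np.linalg.norm(m[:, :3], axis=1)
    diffs = np.abs(np.diff(m, axis=0))
    diffs[:, 3:] *= rotation_radius_mm
    fd = diffs.sum(axis=1)
    return MotionSummary(
        max_disp=float(trans_norm.max()),
        rms_disp=float(np.sqrt((trans_norm**2).mean())),
        mean_fd=float(fd.mean()),
    )


def drop_initial_volumes(run: BoldRun, motion6: np.ndarray | None, n_drop: int = 5):
    """Remove the first ``n_drop`` volumes from the run and motion trace."""
    if n_drop < 0 or n_drop >= run.n_volumes - 1:
        raise ValueError(f"cannot drop {n_drop} of {run.n_volumes} volumes")
    out = replace(run, data=run.data[..., n_drop:])
    if motion6 is None:
        return out, None
    return out, np.asarray(motion6, dtype=float)[n_drop:]


def preprocess_run(
    run: BoldRun,
    motion6: np.ndarray,
    wm_mask: np.ndarray | None = None,
    csf_mask: np.ndarray | None = None,
    low: float = 0.01,
    high: float = 0.1,
    n_drop: int = 5,
    filter_mode: str = "ideal",
) -> tuple[BoldRun, MotionSummary]:
    """Full temporal pipeline: drop volumes -> detrend -> band-pass ->
    nuisance regression.  Returns the cleaned run and the motion summary
    of the retained volumes."""
    run, motion6 = drop_initial_volumes(run, motion6, n_drop)
    logger.info("preproc order: drop(%d) -> detrend -> bandpass(%g-%g Hz) -> nuisance", n_drop, low, high)
    run = filter_timeseries(run, low, high, detrend=True, mode=filter_mode)
    run = nuisance_regress(run, motion6, wm_mask, csf_mask)
    return run, motion_summaries(motion6)
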