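"""Functional-scan conditioning for single-slice BOLD series.

Default chain (each step per subject, never across scan boundaries):
trim -> nuisance (motion) regression -> spatial smoothing -> band-pass
(0.01-0.2 Hz zero-phase FIR) -> trim -> quadratic detrend -> unit variance,
with optional global signal regression as a tagged variant stream.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .core import BoldSeries

__all__ = [
    "regress_nuisance",
    "bandpass_fir",
    "detrend_quadratic",
    "normalize_unit_variance",
    "smooth_gaussian",
    "trim_transients",
    "global_signal_regress",
    "run_preprocess",
    "BoldPreprocessor",
]


def _ols_residuals(data: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residuals of each row of ``data`` (L x T) on a T x p design."""
    beta, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return data - (design @ beta).T


def _drop_collinear(design: np.ndarray) -> np.ndarray:
    """Keep a maximal independent column subset (warns when dropping)."""
    keep: list[int] = []
    for j in range(design.shape[1]):
        cols = design[:, keep + [j]]
        if np.linalg.matrix_rank(cols) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear regressor column {j}", stacklevel=3)
    return design[:, keep]


def regress_nuisance(series: BoldSeries, regressors: np.ndarray) -> BoldSeries:
    """Voxel-wise OLS removal of nuisance regressors (plus intercept)."""
    regressors = np.asarray(regressors, dtype=float)
    if regressors.ndim == 1:
        regressors = regressors[:, None]
    if regressors.shape[0] != series.n_frames:
        raise ValueError("regressor length does not match series frames")
    if not np.all(np.isfinite(regressors)):
        raise ValueError("regressors contain non-finite values")
    design = np.column_stack([np.ones(series.n_frames), regressors])
    design = _drop_collinear(design)
    res = _ols_residuals(series.data, design)
    return series.with_data(res, f"nuisance_regressed(k={design.shape[1] - 1})")


def bandpass_fir(series: BoldSeries, low: float = 0.01, high: float = 0.2,
                 numtaps: int | None = None) -> BoldSeries:
    """Zero-phase FIR band-pass (Hamming window design, forward-backward).

    The default order is ``round(4 / (low * TR))`` capped at T/3; applied
    with ``filtfilt`` so the net phase response is zero.
    """
    tr = series.tr_seconds
    nyq = 0.5 / tr
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, {nyq}) Hz")
    T = series.n_frames
    if numtaps is None:
        numtaps = min(int(round(4.0 / (low * tr))), T // 3)
    numtaps = max(5, numtaps | 1)  # odd order for a symmetric linear-phase kernel
    taps = signal.firwin(numtaps, [low, high], pass_zero=False, fs=1.0 / tr,
                         window="hamming")
    padlen = min(3 * numtaps, T - 2)
    # demean first: the FIR's DC gain is only approximately zero
    centred = series.data - series.data.mean(axis=1, keepdims=True)
    out = signal.filtfilt(taps, [1.0], centred, axis=1, padlen=padlen)
    return series.with_data(out, f"bandpass_fir({low}-{high}Hz,taps={numtaps})")


def detrend_quadratic(series: BoldSeries) -> BoldSeries:
    """Remove a per-voxel 2nd-order polynomial in frame index."""
    T = series.n_frames
    if T < 4:
        raise ValueError("need at least 4 frames to detrend quadratically")
    x = np.arange(T, dtype=float)
    design = np.column_stack([np.ones(T), x, x**2])
    res = _ols_residuals(series.data, design)
    return series.with_data(res, "detrend_quadratic")


def normalize_unit_variance(series: BoldSeries) -> BoldSeries:
    """Zero-mean, unit-SD voxel courses; constant voxels zeroed and flagged."""
    data = series.data
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, ddof=0, keepdims=True)
    # relative threshold: a numerically-constant voxel has sd at rounding level
    zero = sd[:, 0] <= 1e-12 * (np.abs(mean[:, 0]) + 1.0)
    sd[zero] = 1.0
    out = (data - mean) / sd
    out[zero] = 0.0
    new = series.with_data(out, "unit_variance")
    if zero.any():
        prior = set(new.flags.get("zero_variance_voxels", []))
        new.flags = dict(new.flags)
        new.flags["zero_variance_voxels"] = sorted(prior | set(np.flatnonzero(zero).tolist()))
    return new


def smooth_gaussian(series: BoldSeries, sigma_pixels: float = 2.0) -> BoldSeries:
    """Per-frame in-plane Gaussian smoothing with masked normalisation.

    Smoothing is computed on the mask-zeroed image and divided by the
    smoothed mask, so voxels near the mask edge are not biased toward zero
    and a constant frame is preserved exactly.
    """
    if sigma_pixels == 0:
        return series.with_data(series.data.copy(), "smooth(sigma=0)")
    geom = series.geometry
    m, n = geom.shape
    T = series.n_frames
    vol = np.zeros((m * n, T))
    vol[geom.mask_indices] = series.data
    vol = vol.reshape(m, n, T)
    sm = gaussian_filter(vol, sigma=(sigma_pixels, sigma_pixels, 0))
    weight = gaussian_filter(geom.mask.astype(float), sigma=sigma_pixels)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm /= weight[:, :, None]
    out = sm.reshape(m * n, T)[geom.mask_indices]
    return series.with_data(out, f"smooth(sigma={sigma_pixels})")


def trim_transients(series: BoldSeries, n_start: int, n_end: int) -> BoldSeries:
    """Drop transient frames at the start and end of the scan."""
    T = series.n_frames
    if n_start < 0 or n_end < 0:
        raise ValueError("trim counts must be non-negative")
    if n_start + n_end > T // 2:
        raise ValueError(f"refusing to trim {n_start}+{n_end} of {T} frames")
    if n_start == 0 and n_end == 0:
        return series.with_data(series.data.copy(), "trim(0,0)")
    stop = T - n_end
    return series.with_data(series.data[:, n_start:stop].copy(),
                            f"trim({n_start},{n_end})")


def global_signal_regress(series: BoldSeries) -> BoldSeries:
    """Regress the in-mask mean time course (global signal) from every voxel."""
    gs = series.data.mean(axis=0)
    out = regress_nuisance(series, gs[:, None])
    out.provenance[-1] = "GSR"
    return out


def run_preprocess(
    series: BoldSeries,
    motion: np.ndarray | None = None,
    low: float = 0.01,
    high: float = 0.2,
    trim: int = 20,
    smooth_sigma: float = 2.0,
    gsr: bool = False,
) -> BoldSeries:
    """Apply the default conditioning chain to one subject's scan."""
    s = trim_transients(series, trim, trim)
    if motion is not None:
        s = regress_nuisance(s, np.asarray(motion)[trim: len(motion) - trim])
    if smooth_sigma > 0:
        s = smooth_gaussian(s, smooth_sigma)
    s = bandpass_fir(s, low, high)
    s = trim_transients(s, trim, trim)
    s = detrend_quadratic(s)
    s = normalize_unit_variance(s)
    if gsr:
        s = global_signal_regress(s)
    return s


class BoldPreprocessor(BaseEstimator, TransformerMixin):
    """Transformer facade over the conditioning chain.

    Operates on one subject's ``(n_frames, n_voxels)`` array; the slice
    geometry is needed for in-plane smoothing.  Nuisance regressors may be
    supplied at construction (they are trimmed alongside the data).
    """

    def __init__(self, geometry=None, tr_seconds: float = 0.5, low: float = 0.01,
                 high: float = 0.2, trim: int = 20, smooth_sigma: float = 2.0,
                 gsr: bool = False, motion=None):
        self.geometry = geometry
        self.tr_seconds = tr_seconds
        self.low = low
        self.high = high
        self.trim = trim
        self.smooth_sigma = smooth_sigma
        self.gsr = gsr
        self.motion = motion

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be (n_frames, n_voxels)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        from .core import SliceGeometry

        X = np.asarray(X, dtype=float)
        geom = self.geometry
        if geom is None:  # degenerate 1 x L slice: smoothing is skipped
            geom = SliceGeometry(shape=(1, X.shape[1]),
                                 mask_indices=np.arange(X.shape[1]))
        series = BoldSeries(data=X.T, geometry=geom, tr_seconds=self.tr_seconds)
        out = run_preprocess(
            series, motion=self.motion, low=self.low, high=self.high,
            trim=self.trim,
            smooth_sigma=self.smooth_sigma if self.geometry is not None else 0.0,
            gsr=self.gsr,
        )
        return out.data.T
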