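"""Removing a QPP's contribution from the image series.

The pattern's image series is reconstructed by convolving its template with
its (projection) STC — an STC value at frame ``p`` contributes the template
over frames ``p .. p+W-1`` — and removed voxel-wise by linear regression.
The residual series is what downstream FC analysis consumes.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin

from .core import BoldSeries
from .detect import QppRecord, QppTemplate, StcSeries, detect_peaks, sliding_template_correlation

__all__ = ["build_qpp_regressor", "regress_qpp", "QPPRegressor"]


def build_qpp_regressor(template, stc_values, n_frames: int | None = None,
                        valid=None) -> np.ndarray:
    """Convolve the template with its STC into an L x T regressor matrix.

    Per voxel the regressor is the linear convolution of the STC segment
    with the voxel's W-frame template course, truncated to the segment
    length; invalid STC positions are treated as 0.
    """
    tdata = template.data if isinstance(template, QppTemplate) else np.asarray(template, float)
    if isinstance(stc_values, StcSeries):
        valid = stc_values.valid if valid is None else valid
        stc_values = stc_values.values
    stc = np.asarray(stc_values, dtype=float).copy()
    if valid is not None:
        stc = np.where(np.asarray(valid, bool), stc, 0.0)
    T = len(stc) if n_frames is None else int(n_frames)
    full = fftconvolve(stc[None, :], tdata, axes=1)  # L x (len+W-1)
    return full[:, :T]


def regress_qpp(series: BoldSeries, qpp, stc_segment=None,
                peaks_only: bool = False, threshold: float = 0.2) -> BoldSeries:
    """Voxel-wise OLS removal of a QPP's reconstructed series from a scan.

    ``stc_segment`` is the subject's stretch of the (p)STC; if omitted it is
    recomputed by sliding the template over this subject's scan.  With
    ``peaks_only`` the STC is zeroed below threshold before convolution.
    Voxels whose regressor has no variance pass through unchanged (flagged).
    """
    template = qpp.template if isinstance(qpp, QppRecord) else qpp
    name = getattr(template, "name", "") or "QPP"
    if stc_segment is None:
        stc_segment = sliding_template_correlation(template, series.data)
    if isinstance(stc_segment, StcSeries):
        values = np.where(stc_segment.valid, stc_segment.values, 0.0)
    else:
        values = np.asarray(stc_segment, dtype=float)
    if len(values) != series.n_frames:
        raise ValueError("STC segment length does not match the scan")
    if peaks_only:
        keep = np.zeros_like(values, dtype=bool)
        stc_obj = stc_segment if isinstance(stc_segment, StcSeries) else StcSeries(
            values=values, valid=np.ones_like(values, bool))
        keep[detect_peaks(stc_obj, threshold)] = True
        values = np.where(values > threshold, values, 0.0)

    reg = build_qpp_regressor(template, values, series.n_frames)
    y = series.data
    xc = reg - reg.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xvar = np.einsum("lt,lt->l", xc, xc)
    degenerate = xvar <= 1e-30
    xvar_safe = np.where(degenerate, 1.0, xvar)
    slope = np.einsum("lt,lt->l", xc, yc) / xvar_safe
    slope[degenerate] = 0.0
    resid = yc - slope[:, None] * xc  # orthogonal to both intercept and regressor
    resid[degenerate] = y[degenerate]
    out = series.with_data(resid, f"qpp_regressed({name})")
    if degenerate.any():
        out.flags = dict(out.flags)
        out.flags[f"qpp_regress_skipped_{name}"] = np.flatnonzero(degenerate).tolist()
    return out


class QPPRegressor(BaseEstimator, TransformerMixin):
    """Transformer that removes a fixed QPP from ``(n_frames, n_voxels)`` data.

    The STC of the stored template is computed on the array given to
    ``transform`` (per-subject semantics) and the convolution regressor is
    fitted and removed voxel-wise.  The intercept-and-slope fit makes the
    residual exactly orthogonal to each voxel's regressor.
    """

    def __init__(self, template=None, threshold: float = 0.2, peaks_only: bool = False):
        self.template = template
        self.threshold = threshold
        self.peaks_only = peaks_only

    def fit(self, X, y=None):
        if self.template is None:
            raise ValueError("QPPRegressor needs a template")
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be (n_frames, n_voxels)")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        from .core import SliceGeometry

        X = np.asarray(X, dtype=float)
        geom = SliceGeometry(shape=(1, X.shape[1]), mask_indices=np.arange(X.shape[1]))
        series = BoldSeries(data=X.T, geometry=geom, tr_seconds=1.0)
        out = regress_qpp(series, self.template, peaks_only=self.peaks_only,
                          threshold=self.threshold)
        return out.data.T
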