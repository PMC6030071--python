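"""Recurring spatiotemporal pattern (QPP) detection by iterated sliding
template correlation.

The algorithm: seed a template from ``W`` consecutive frames at a random
start, correlate it with every same-length window of the (concatenated)
image series — the sliding template correlation, STC — take suprathreshold
STC peaks as pattern occurrences, average the image chunks at those peaks
into an updated template, and repeat until the STC stabilises.  Many random
restarts are run; the record whose STC has the highest sum of peak
correlations is selected downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .core import ConcatSeries

__all__ = [
    "QppTemplate",
    "StcSeries",
    "QppRecord",
    "sliding_template_correlation",
    "detect_peaks",
    "refine_template",
    "find_qpps",
    "QPPDetector",
]

#: relative variance below which a window or template counts as constant
_VAR_REL_TOL = 1e-10


@dataclass
class QppTemplate:
    """An ``L x W`` spatiotemporal pattern in in-mask voxel order."""

    data: np.ndarray
    tr_seconds: float
    name: str = ""
    group: str = "NA"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("template must be L x W with W >= 2")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("template contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def window_frames(self) -> int:
        return self.data.shape[1]

    @property
    def window_seconds(self) -> float:
        return self.window_frames * self.tr_seconds


@dataclass
class StcSeries:
    """Sliding template correlation trace with validity mask and peaks.

    ``values[t]`` is the Pearson correlation between the vectorised template
    and frames ``[t, t + W)``; invalid starts (window crossing a scan
    boundary, running past the end, or with degenerate variance) carry value
    0 and ``valid`` False.
    """

    values: np.ndarray
    valid: np.ndarray
    peaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    threshold: float = 0.2

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.peaks = np.asarray(self.peaks, dtype=int)

    @property
    def peak_sum(self) -> float:
        return float(self.values[self.peaks].sum()) if self.peaks.size else 0.0

    @property
    def n_peaks(self) -> int:
        return int(self.peaks.size)


@dataclass
class QppRecord:
    """One detection outcome: template, its STC, and convergence metadata."""

    template: QppTemplate
    stc: StcSeries
    start_frame_seed: int
    iterations: int
    converged: bool
    occurrences: dict[str, np.ndarray] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    @property
    def peak_sum(self) -> float:
        return self.stc.peak_sum


# ---------------------------------------------------------------------------
# Sliding template correlation
# ---------------------------------------------------------------------------

def _valid_starts(n_frames: int, window: int, boundaries) -> np.ndarray:
    """Boolean mask over starts: window fully inside one subject's segment."""
    valid = np.zeros(n_frames, dtype=bool)
    if boundaries is None:
        boundaries = [("", 0, n_frames)]
    for _, start, end in boundaries:
        if end - start >= window:
            valid[start : end - window + 1] = True
    return valid


def _stc_values(data: np.ndarray, template: np.ndarray, valid: np.ndarray):
    """Pearson correlation of the vectorised template with every window.

    ``data`` is ``L x T``; computed with per-window exact sums (no running
    cumulative sums) so small fixtures agree with brute force to ~1e-15.
    """
    L, T = data.shape
    W = template.shape[1]
    n_starts = T - W + 1
    N = L * W

    tau = template.ravel()
    tau_sum = tau.sum()
    tau_var = float(tau @ tau) - tau_sum**2 / N
    values = np.zeros(T)
    ok = valid.copy()
    if tau_var <= _VAR_REL_TOL * max(float(tau @ tau), np.finfo(float).tiny):
        return values, np.zeros(T, dtype=bool)

    D = data.T @ template  # T x W
    dots = np.zeros(n_starts)
    for w in range(W):
        dots += D[w : w + n_starts, w]
    frame_sum = data.sum(axis=0)
    frame_sq = np.einsum("lt,lt->t", data, data)
    win = np.lib.stride_tricks.sliding_window_view
    x_sum = win(frame_sum, W).sum(axis=1)
    x_sq = win(frame_sq, W).sum(axis=1)

    x_var = x_sq - x_sum**2 / N
    degenerate = x_var <= _VAR_REL_TOL * np.maximum(x_sq, np.finfo(float).tiny)
    cov = dots - x_sum * tau_sum / N
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(x_var * tau_var)
    r[degenerate] = 0.0
    values[:n_starts] = r
    ok[:n_starts] &= ~degenerate
    ok[n_starts:] = False
    values[~ok] = 0.0
    return values, ok


def sliding_template_correlation(template, concat, boundaries=None) -> StcSeries:
    """Correlate a template with every valid window of an image series.

    Parameters
    ----------
    template : QppTemplate or L x W array.
    concat : ConcatSeries or L x T array.
    boundaries : used only when ``concat`` is a bare array.
    """
    tdata = template.data if isinstance(template, QppTemplate) else np.asarray(template)
    if isinstance(concat, ConcatSeries):
        data, boundaries = concat.data, concat.boundaries
    else:
        data = np.asarray(concat)
    if tdata.shape[0] != data.shape[0]:
        raise ValueError("template and series voxel counts differ")
    valid = _valid_starts(data.shape[1], tdata.shape[1], boundaries)
    values, ok = _stc_values(data, tdata, valid)
    return StcSeries(values=values, valid=ok)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def detect_peaks(stc: StcSeries, threshold: float = 0.2, min_separation: int = 1) -> np.ndarray:
    """Suprathreshold strict local maxima of the STC, de-duplicated.

    Within each contiguous run of valid positions, a peak is a position (or
    the first frame of a plateau) whose neighbours are strictly lower.  Among
    peaks closer than ``min_separation`` frames the larger wins; ties go to
    the earlier frame.
    """
    v, ok = stc.values, stc.valid
    candidates = []
    t = 0
    n = len(v)
    while t < n:
        if not ok[t]:
            t += 1
            continue
        run_end = t
        while run_end < n and ok[run_end]:
            run_end += 1
        seg = v[t:run_end]
        i = 1
        while i < len(seg) - 1:
            j = i
            while j + 1 < len(seg) and seg[j + 1] == seg[i]:
                j += 1  # plateau
            if j < len(seg) - 1 and seg[i] > seg[i - 1] and seg[i] > seg[j + 1]:
                if seg[i] > threshold:
                    candidates.append(t + i)
            i = j + 1
        t = run_end
    if min_separation > 1 and len(candidates) > 1:
        order = sorted(candidates, key=lambda p: (-v[p], p))
        kept: list[int] = []
        for p in order:
            if all(abs(p - q) >= min_separation for q in kept):
                kept.append(p)
        candidates = sorted(kept)
    return np.asarray(candidates, dtype=int)


# ---------------------------------------------------------------------------
# Template refinement (the iterative core)
# ---------------------------------------------------------------------------

def _average_chunks(data: np.ndarray, peaks: np.ndarray, window: int) -> np.ndarray:
    out = np.zeros((data.shape[0], window))
    for p in peaks:
        out += data[:, p : p + window]
    return out / len(peaks)


def refine_template(
    concat,
    start_frame: int,
    window_frames: int,
    threshold: float = 0.2,
    min_separation: int | None = None,
    max_iter: int = 20,
    conv_tol: float = 0.9999,
    tr_seconds: float | None = None,
    boundaries=None,
) -> QppRecord:
    """Iterate template -> STC -> peaks -> chunk average until the STC is stable.

    Convergence requires the Pearson correlation between consecutive
    iterations' STC vectors (over valid positions) to reach ``conv_tol`` on
    two successive checks.
    """
    if isinstance(concat, ConcatSeries):
        data, boundaries = concat.data, concat.boundaries
        tr = concat.tr_seconds
    else:
        data = np.asarray(concat)
        tr = tr_seconds if tr_seconds is not None else 1.0
    W = int(window_frames)
    if min_separation is None:
        min_separation = int(np.ceil(W / 2))
    valid = _valid_starts(data.shape[1], W, boundaries)
    if not valid[start_frame]:
        raise ValueError(f"start frame {start_frame} is not a valid window start")

    template = data[:, start_frame : start_frame + W].copy()
    prev_stc = None
    hits = 0
    converged = False
    stc_obj = StcSeries(values=np.zeros(data.shape[1]), valid=np.zeros(data.shape[1], bool),
                        threshold=threshold)
    peaks = np.array([], dtype=int)
    it = 0
    for it in range(1, max_iter + 1):
        values, ok = _stc_values(data, template, valid)
        peaks = detect_peaks(StcSeries(values=values, valid=ok), threshold, min_separation)
        stc_obj = StcSeries(values=values, valid=ok, peaks=peaks, threshold=threshold)
        if prev_stc is not None and ok.any():
            both = ok & prev_stc[1]
            if both.sum() >= 2 and np.std(values[both]) > 0 and np.std(prev_stc[0][both]) > 0:
                c = np.corrcoef(values[both], prev_stc[0][both])[0, 1]
            else:
                c = 0.0
            hits = hits + 1 if c >= conv_tol else 0
            if hits >= 2:
                converged = True
                break
        if peaks.size == 0:
            break  # nothing to average: unconverged record with empty peaks
        prev_stc = (values, ok)
        template = _average_chunks(data, peaks, W)

    occurrences = {}
    if boundaries is not None:
        for sid, s, e in boundaries:
            occurrences[sid] = peaks[(peaks >= s) & (peaks < e)] - 0
    return QppRecord(
        template=QppTemplate(data=template, tr_seconds=tr),
        stc=stc_obj,
        start_frame_seed=int(start_frame),
        iterations=it,
        converged=converged,
        occurrences=occurrences,
    )


def find_qpps(
    concat,
    window_seconds: float | None = None,
    n_starts: int = 500,
    threshold: float = 0.2,
    min_separation: int | None = None,
    max_iter: int = 20,
    random_state=None,
    window_frames: int | None = None,
    boundaries=None,
    tr_seconds: float | None = None,
) -> list[QppRecord]:
    """Run the refinement from ``n_starts`` random seed frames.

    Start frames are drawn uniformly (without replacement when possible)
    from valid window starts; the result is reproducible given the seed.
    """
    if isinstance(concat, ConcatSeries):
        data, boundaries, tr = concat.data, concat.boundaries, concat.tr_seconds
    else:
        data = np.asarray(concat)
        tr = tr_seconds if tr_seconds is not None else 1.0
    if window_frames is None:
        if window_seconds is None:
            raise ValueError("give window_seconds or window_frames")
        window_frames = int(round(window_seconds / tr))
    valid = _valid_starts(data.shape[1], window_frames, boundaries)
    starts_pool = np.flatnonzero(valid)
    if starts_pool.size == 0:
        raise ValueError("no valid window start exists")
    rng = np.random.default_rng(random_state)
    replace = starts_pool.size < n_starts
    starts = rng.choice(starts_pool, size=n_starts, replace=replace)
    records = []
    for s in starts:
        records.append(
            refine_template(
                data, int(s), window_frames, threshold, min_separation,
                max_iter, boundaries=boundaries, tr_seconds=tr,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------

class QPPDetector(BaseEstimator):
    """Detect the dominant quasi-periodic pattern in a BOLD series.

    A scikit-learn style estimator: ``fit`` takes ``X`` of shape
    ``(n_frames, n_voxels)`` (frames as samples).  Scan boundaries of a
    concatenated group series are passed via the ``boundaries`` fit
    parameter so that no correlation window spans two subjects.

    Parameters
    ----------
    window_frames : template length ``W`` in frames.
    n_starts : number of random restarts (500 reproduces a full run;
        lower values give a fast profile).
    threshold : STC peak threshold (0.2).
    min_separation : minimum frame distance between peaks; default
        ``ceil(W / 2)``.
    random_state : seed for the restart draw.

    Attributes
    ----------
    records_ : all restart records.
    best_record_ : converged record with the highest STC peak-correlation sum.
    template_ : its ``L x W`` pattern matrix.
    stc_, peaks_ : its sliding template correlation and peak frames.
    """

    def __init__(
        self,
        window_frames: int = 6,
        n_starts: int = 500,
        threshold: float = 0.2,
        min_separation: int | None = None,
        max_iter: int = 20,
        tr_seconds: float = 1.0,
        random_state: int | None = None,
    ):
        self.window_frames = window_frames
        self.n_starts = n_starts
        self.threshold = threshold
        self.min_separation = min_separation
        self.max_iter = max_iter
        self.tr_seconds = tr_seconds
        self.random_state = random_state

    def fit(self, X, y=None, boundaries=None):
        from .metrics import select_qpp  # local import avoids a cycle

        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_frames, n_voxels)")
        data = X.T
        self.records_ = find_qpps(
            data,
            window_frames=self.window_frames,
            n_starts=self.n_starts,
            threshold=self.threshold,
            min_separation=self.min_separation,
            max_iter=self.max_iter,
            random_state=self.random_state,
            boundaries=boundaries,
            tr_seconds=self.tr_seconds,
        )
        self.best_record_ = select_qpp(self.records_)
        self.template_ = self.best_record_.template.data
        self.stc_ = self.best_record_.stc
        self.peaks_ = self.best_record_.stc.peaks
        self.n_voxels_ = data.shape[0]
        return self

    def project(self, X, boundaries=None) -> StcSeries:
        """Projection STC of the fitted template onto another series."""
        from .metrics import project_stc

        X = np.asarray(X, dtype=float)
        return project_stc(
            self.best_record_, X.T, boundaries=boundaries,
            threshold=self.threshold, min_separation=self.min_separation,
        )
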