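"""QPP-level statistics: contrast, selection, projection, occurrence rates,
cross-group matching, window extension and significance maps."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ConcatSeries, RoiAtlas
from .detect import QppRecord, QppTemplate, StcSeries, detect_peaks, sliding_template_correlation

__all__ = [
    "template_similarity",
    "qpp_contrast",
    "select_qpp",
    "project_stc",
    "occurrence_rates",
    "compare_rates",
    "match_qpps",
    "inter_area_correlation",
    "extend_template",
    "qpp_significance_map",
]

_CV_CAP = 1e6


def template_similarity(a, b, max_lag: int | None = None):
    """Best spatial correlation between two L x W patterns over frame lags.

    Correlates the vectorised overlapping frames of ``a`` against ``b``
    shifted by each lag in ``[-max_lag, max_lag]`` (default half a window)
    and returns ``(r, lag, sign)`` for the lag with the largest |r|;
    ``sign`` is the sign of that extremum (a phase-inverted match has
    sign -1).
    """
    a = a.data if isinstance(a, QppTemplate) else np.asarray(a, float)
    b = b.data if isinstance(b, QppTemplate) else np.asarray(b, float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("patterns must share the voxel dimension")
    W = min(a.shape[1], b.shape[1])
    if max_lag is None:
        max_lag = W // 2
    min_overlap = max(2, W // 2)  # tiny overlaps give meaningless correlations
    best = (0.0, 0)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            ov = min(a.shape[1] - lag, b.shape[1])
            av, bv = a[:, lag : lag + ov], b[:, :ov]
        else:
            ov = min(a.shape[1], b.shape[1] + lag)
            av, bv = a[:, :ov], b[:, -lag : -lag + ov]
        if ov < min_overlap:
            continue
        x, y = av.ravel(), bv.ravel()
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if abs(r) > abs(best[0]):
            best = (r, lag)
    r, lag = best
    return r, lag, (1 if r >= 0 else -1)


def qpp_contrast(template) -> float:
    """Mean absolute coefficient of variation of pattern intensities per frame.

    For each frame the coefficient of variation is the sample SD over voxels
    divided by the voxel mean; the mean of its absolute value over frames is
    high when frames mix strongly positive and negative regions (high
    spatial contrast) and low for globally coherent patterns.  Frames with a
    near-zero mean but nonzero spread are capped at 1e6 (the ratio is
    unstable by construction); all-constant frames contribute 0.
    """
    data = template.data if isinstance(template, QppTemplate) else np.asarray(template, float)
    if data.ndim != 2 or data.shape[1] == 0:
        raise ValueError("template must be L x W with W >= 1")
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    cv = np.zeros(data.shape[1])
    for t in range(data.shape[1]):
        if sd[t] == 0:
            cv[t] = 0.0
        elif abs(mu[t]) < 1e-12 * sd[t]:
            cv[t] = _CV_CAP
        else:
            cv[t] = min(abs(sd[t] / mu[t]), _CV_CAP)
    return float(cv.mean())


def select_qpp(records: list[QppRecord]) -> QppRecord:
    """Pick the converged record with the highest STC peak-correlation sum.

    Ties break toward more peaks, then the earlier seed frame.
    """
    pool = [r for r in records if r.converged and r.stc.n_peaks > 0]
    if not pool:
        raise ValueError("no converged record with peaks to select from")
    return min(pool, key=lambda r: (-r.peak_sum, -r.stc.n_peaks, r.start_frame_seed))


def project_stc(qpp, target, boundaries=None, threshold: float = 0.2,
                min_separation: int | None = None) -> StcSeries:
    """Projection STC: slide a fixed template over another image series.

    Identical to the detection-time sliding correlation but without template
    iteration; peaks are detected with the same threshold rule.
    """
    template = qpp.template if isinstance(qpp, QppRecord) else qpp
    if isinstance(target, ConcatSeries):
        boundaries = target.boundaries
    stc = sliding_template_correlation(template, target, boundaries=boundaries)
    W = template.data.shape[1] if not isinstance(template, QppTemplate) else template.window_frames
    if min_separation is None:
        min_separation = int(np.ceil(W / 2))
    peaks = detect_peaks(stc, threshold, min_separation)
    return StcSeries(values=stc.values, valid=stc.valid, peaks=peaks, threshold=threshold)


def occurrence_rates(stc: StcSeries, boundaries, tr_seconds: float) -> dict[str, float]:
    """Occurrences per minute per subject (peaks inside each scan interval)."""
    rates = {}
    for sid, start, end in boundaries:
        n = int(np.sum((stc.peaks >= start) & (stc.peaks < end)))
        rates[sid] = n / ((end - start) * tr_seconds / 60.0)
    return rates


def compare_rates(rates_a, rates_b, welch: bool = False):
    """Two-sample two-tailed t-test on per-subject rates.

    Pooled-variance by default; zero variance in both groups gives p=1 for
    equal means and an infinite-t flag otherwise.
    """
    a = np.asarray(list(rates_a.values()) if isinstance(rates_a, dict) else rates_a, float)
    b = np.asarray(list(rates_b.values()) if isinstance(rates_b, dict) else rates_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two subjects per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    import warnings

    with warnings.catch_warnings():
        # tiny near-identical groups trip scipy's precision-loss warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def _lagged_correlation(x, y, xv, yv, lag: int) -> float:
    """Pearson r between x[t] and y[t+lag] over jointly valid positions."""
    n = len(x)
    if lag >= 0:
        xs, ys = x[: n - lag], y[lag:]
        ok = xv[: n - lag] & yv[lag:]
    else:
        xs, ys = x[-lag:], y[: n + lag]
        ok = xv[-lag:] & yv[: n + lag]
    xs, ys = xs[ok], ys[ok]
    if len(xs) < 3 or xs.std() == 0 or ys.std() == 0:
        return 0.0
    return float(np.corrcoef(xs, ys)[0, 1])


def match_qpps(reference_pstc: StcSeries, target_records: list[QppRecord],
               max_lag: int | None = None):
    """Match a projected QPP to the target group's own QPPs via their STCs.

    The pSTC of the reference pattern and each target record's STC live on
    the same concatenated series; the record whose STC cross-correlates most
    strongly (in absolute value, over lags up to one window) is the
    corresponding pattern.  Returns ``(best record, sign, lag)`` where a
    negative sign marks a phase-inverted match.
    """
    if not target_records:
        raise ValueError("no target records to match against")
    best = None
    for rec in target_records:
        W = rec.template.window_frames
        lags = range(-(max_lag if max_lag is not None else W),
                     (max_lag if max_lag is not None else W) + 1)
        for lag in lags:
            c = _lagged_correlation(reference_pstc.values, rec.stc.values,
                                    reference_pstc.valid, rec.stc.valid, lag)
            key = (abs(c), -abs(lag))
            if best is None or key > best[0]:
                best = (key, rec, 1 if c >= 0 else -1, lag)
    _, rec, sign, lag = best
    return rec, sign, lag


def inter_area_correlation(template, atlas: RoiAtlas, roi_pairs) -> float:
    """Mean Pearson correlation of ROI time-courses within a pattern.

    ROI courses are voxel means of the template frames; pairs with a
    constant course are skipped.  Returns NaN if every pair is degenerate.
    """
    data = template.data if isinstance(template, QppTemplate) else np.asarray(template, float)
    courses = {}

    def course(roi):
        if roi not in courses:
            courses[roi] = data[atlas.labels[roi]].mean(axis=0)
        return courses[roi]

    rs = []
    for a, b in roi_pairs:
        ca, cb = course(a), course(b)
        if ca.std() == 0 or cb.std() == 0:
            continue
        rs.append(np.corrcoef(ca, cb)[0, 1])
    return float(np.mean(rs)) if rs else float("nan")


def _usable_occurrences(peaks, window: int, extension: int, n_frames: int,
                        boundaries=None) -> np.ndarray:
    """De-overlap rule: keep the earlier of two occurrences whose (extended)
    windows overlap; drop windows that cross series or scan edges."""
    lo, hi = extension, window + extension
    segs = [(0, n_frames)] if boundaries is None else [(s, e) for _, s, e in boundaries]
    kept = []
    for p in sorted(int(q) for q in np.asarray(peaks).ravel()):
        if not any(s <= p - lo and p + hi <= e for s, e in segs):
            continue  # window would cross an edge
        if kept and p - kept[-1] < window + 2 * extension:
            continue  # overlaps the previous kept occurrence: drop the later
        kept.append(p)
    return np.asarray(kept, dtype=int)


def _occurrence_stack(data, peaks, window, extension=0):
    span = window + 2 * extension
    return np.stack([data[:, p - extension : p - extension + span] for p in peaks])


def qpp_significance_map(concat, occurrences, window: int, q: float = 0.001):
    """Voxel/frame one-sample t-map over unique occurrence chunks + FDR mask.

    For each (voxel, frame-offset) cell the intensities of the unique
    (non-overlapping) image chunks averaged into the pattern are tested
    against zero; Benjamini-Hochberg controls the FDR over all L*W tests.
    Returns ``(t_map, reject_mask)``, both L x W.
    """
    data = concat.data if isinstance(concat, ConcatSeries) else np.asarray(concat, float)
    boundaries = concat.boundaries if isinstance(concat, ConcatSeries) else None
    peaks = _usable_occurrences(occurrences, window, 0, data.shape[1], boundaries)
    if len(peaks) < 3:
        raise ValueError(f"need >= 3 non-overlapping occurrences, have {len(peaks)}")
    chunks = _occurrence_stack(data, peaks, window)  # n x L x W
    mean = chunks.mean(axis=0)
    sd = chunks.std(axis=0, ddof=1)
    n = len(peaks)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    # zero-spread cells: infinite t where the constant is nonzero, else no test
    degen = sd == 0
    t[degen & (mean != 0)] = np.inf * np.sign(mean[degen & (mean != 0)])
    t[degen & (mean == 0)] = 0.0
    p[degen] = np.where(mean[degen] != 0, 0.0, 1.0)
    reject = multipletests(p.ravel(), alpha=q, method="fdr_bh")[0].reshape(p.shape)
    return t, reject


def extend_template(concat, occurrences, window: int, extension: int,
                    q: float = 0.001):
    """Average wider chunks around each occurrence to expose a pattern's
    true temporal extent.

    Frames from ``p - E`` to ``p + W - 1 + E`` are averaged over usable
    occurrences (edge-crossing windows dropped; of two overlapping
    extended windows the later is dropped).  The estimated true length is
    the span from the first to the last frame whose RMS over significant
    voxels clears half its maximum — a biphasic pattern keeps its full
    extent even though its mid-pattern zero crossing dips below threshold.

    Returns ``(extended L x (W + 2E) template, estimated_length_frames)``.
    """
    data = concat.data if isinstance(concat, ConcatSeries) else np.asarray(concat, float)
    boundaries = concat.boundaries if isinstance(concat, ConcatSeries) else None
    peaks = _usable_occurrences(occurrences, window, extension, data.shape[1], boundaries)
    if len(peaks) < 3:
        raise ValueError(f"need >= 3 usable occurrences, have {len(peaks)}")
    chunks = _occurrence_stack(data, peaks, window, extension)
    extended = chunks.mean(axis=0)

    n = len(peaks)
    mean, sd = extended, chunks.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    degen = sd == 0
    p[degen] = np.where(mean[degen] != 0, 0.0, 1.0)
    reject = multipletests(p.ravel(), alpha=q, method="fdr_bh")[0].reshape(p.shape)
    voxels = np.flatnonzero(reject.any(axis=1))
    if voxels.size == 0:
        voxels = np.arange(extended.shape[0])
    rms = np.sqrt((extended[voxels] ** 2).mean(axis=0))
    above = np.flatnonzero(rms >= 0.5 * rms.max())
    length = int(above[-1] - above[0] + 1) if above.size else 0
    return extended, length
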