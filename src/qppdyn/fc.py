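"""Functional-connectivity measures and group statistics.

ROI-pair Pearson correlations are Fisher z-transformed (zFC) for group
comparison; network measures average zFC over within-DMN, within-TPN and
DMN-TPN cross pairs per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BoldSeries, RoiAtlas

__all__ = [
    "FcMatrix",
    "NetworkSpec",
    "fisher_z",
    "fc_matrix",
    "seed_fc_map",
    "network_fc",
    "delta_fc",
    "group_compare",
    "fdr_bh",
]

_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher z-transform with the |r|=1 clip at 1 - 1e-7."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return float(out) if out.ndim == 0 else out


@dataclass
class NetworkSpec:
    """DMN / TPN ROI name lists (disjoint, nonempty)."""

    dmn_rois: list[str]
    tpn_rois: list[str]

    def __post_init__(self):
        if not self.dmn_rois or not self.tpn_rois:
            raise ValueError("both networks need at least one ROI")
        if set(self.dmn_rois) & set(self.tpn_rois):
            raise ValueError("DMN and TPN ROI lists overlap")

    @classmethod
    def from_atlas(cls, atlas: RoiAtlas) -> "NetworkSpec":
        return cls(dmn_rois=atlas.rois_in_network("DMN"),
                   tpn_rois=atlas.rois_in_network("TPN"))


@dataclass
class FcMatrix:
    """Symmetric ROI x ROI Fisher-z connectivity for one subject."""

    z: np.ndarray
    roi_names: list[str]
    subject_id: str = ""
    condition: str = "raw"
    missing_rois: list[str] = field(default_factory=list)

    def value(self, roi_a: str, roi_b: str) -> float:
        i, j = self.roi_names.index(roi_a), self.roi_names.index(roi_b)
        return float(self.z[i, j])


def fc_matrix(series: BoldSeries, atlas: RoiAtlas, condition: str = "raw") -> FcMatrix:
    """Pairwise Pearson r of ROI-mean courses, Fisher z-transformed.

    ROIs with a constant course are flagged missing (their rows are NaN);
    the diagonal is NaN (undefined).
    """
    names = atlas.roi_names
    courses = np.stack([atlas.roi_timecourse(series.data, r) for r in names])
    sd = courses.std(axis=1)
    # numerically-constant courses sit at rounding level, not exactly zero
    degenerate = sd <= 1e-12 * (np.abs(courses.mean(axis=1)) + 1.0)
    missing = [names[i] for i in np.flatnonzero(degenerate)]
    ok = ~degenerate
    z = np.full((len(names), len(names)), np.nan)
    if ok.sum() >= 2:
        r = np.corrcoef(courses[ok])
        r = np.clip(r, -1.0, 1.0)
        sub = np.arctanh(np.clip(r, -_CLIP, _CLIP))
        z[np.ix_(ok, ok)] = sub
    np.fill_diagonal(z, np.nan)
    return FcMatrix(z=z, roi_names=list(names), subject_id=series.subject_id,
                    condition=condition, missing_rois=missing)


def seed_fc_map(series: BoldSeries, atlas: RoiAtlas, seed_roi: str) -> np.ndarray:
    """Fisher-z correlation of the seed ROI's mean course with every voxel."""
    seed = atlas.roi_timecourse(series.data, seed_roi)
    if seed.std() == 0:
        raise ValueError(f"seed ROI {seed_roi!r} has a constant course")
    data = series.data
    yc = data - data.mean(axis=1, keepdims=True)
    sc = seed - seed.mean()
    denom = np.sqrt((yc**2).sum(axis=1) * (sc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ sc) / denom
    r[denom == 0] = 0.0
    return np.arctanh(np.clip(r, -_CLIP, _CLIP))


def _network_pairs(spec: NetworkSpec, which: str):
    if which == "DMN":
        return list(combinations(spec.dmn_rois, 2))
    if which == "TPN":
        return list(combinations(spec.tpn_rois, 2))
    if which == "DMN_TPN":
        return [(a, b) for a in spec.dmn_rois for b in spec.tpn_rois]
    raise ValueError(f"unknown network measure {which!r}")


def network_fc(fcm: FcMatrix, spec: NetworkSpec, which: str) -> float:
    """Mean zFC over the requested ROI-pair set (NaN pairs excluded)."""
    vals = [fcm.value(a, b) for a, b in _network_pairs(spec, which)]
    vals = [v for v in vals if np.isfinite(v)]
    if not vals:
        raise ValueError(f"no usable ROI pairs for {which}")
    return float(np.mean(vals))


def delta_fc(before: float, after: float) -> float:
    """Per-subject FC change: after minus before, same subject and measure."""
    return float(after) - float(before)


def group_compare(values_a, values_b=None, design: str = "two_sample",
                  popmean: float = 0.0):
    """Standard t statistics with two-sided p.

    ``two_sample`` compares independent groups (pooled variance), ``paired``
    same-subject conditions, ``one_sample`` a single group against
    ``popmean``.  Degenerate zero-variance cases return p=1 for a zero
    effect and an infinite-t flag otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    if design == "one_sample":
        if len(a) < 2:
            raise ValueError("need n >= 2")
        if a.std(ddof=1) == 0:
            if a.mean() == popmean:
                return 0.0, 1.0
            return float(np.inf) * np.sign(a.mean() - popmean), 0.0
        t, p = stats.ttest_1samp(a, popmean)
        return float(t), float(p)
    b = np.asarray(values_b, dtype=float)
    if design == "two_sample":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need n >= 2 per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
        t, p = stats.ttest_ind(a, b)
        return float(t), float(p)
    if design == "paired":
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired design needs equal n >= 2")
        d = a - b
        if d.std(ddof=1) == 0:
            if d.mean() == 0:
                return 0.0, 1.0
            return float(np.inf) * np.sign(d.mean()), 0.0
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p)
    raise ValueError(f"unknown design {design!r}")


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p.ravel(), alpha=q, method="fdr_bh")[0].reshape(p.shape)
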