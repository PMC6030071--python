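"""Synthetic two-group BOLD cohorts with planted quasi-periodic patterns.

The generator emulates the structure the analysis assumes: a single brain
slice with 12 rectangular ROIs standing in for bilateral Cg, dorsal CPu
(DMN-like) and S1, S2, Ins, ventro-lateral CPu (TPN-like); recurring
spatiotemporal patterns placed additively at gamma-jittered intervals
("quasi-periodic": regular but not clocklike); quadratic drift, motion-like
confounds, and spatially smooth Gaussian noise.  Ground truth (templates,
occurrence frames, amplitudes) is recorded so recovery can be scored.

Planted pattern types (all use a band-limited monophasic burst envelope by
default; pass an explicit envelope for biphasic waves)
---------------------
``WT_like``   3 s co-activation of DMN ROIs with the TPN ROIs anti-phase —
              DMN/TPN anti-correlation.
``TG_like``   3 s pattern with Cg anti-phase to dorsal CPu and silent TPN —
              a disrupted DMN.
``GS_like``   6 s global-signal-like wave engaging every ROI with one sign
              (DMN at reduced gain).

Group structure: wild-type-like subjects express ``WT_like`` and ``GS_like``
at high rates and ``TG_like`` rarely; transgenic-like subjects the reverse,
with a reduced ``GS_like`` rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .core import BoldSeries, FormatError, RoiAtlas, SliceGeometry
from .detect import QppTemplate

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "make_atlas",
    "make_template",
    "sample_occurrences",
    "synthesize_subject",
    "synthesize_cohort",
]

# Default ROI boxes (row_start, row_stop, col_start, col_stop), left
# hemisphere of a 48 x 32 slice; the right hemisphere is the column mirror.
_DEFAULT_LAYOUT = {
    "Cg": ((6, 13, 12, 16), "DMN"),
    "Cpu_d": ((16, 23, 9, 14), "DMN"),
    "S1": ((6, 13, 4, 9), "TPN"),
    "S2": ((16, 23, 3, 8), "TPN"),
    "Ins": ((26, 32, 4, 9), "TPN"),
    "Cpu_vl": ((26, 33, 10, 15), "TPN"),
}

#: frames per minute at a given TR
def _frames_per_minute(tr: float) -> float:
    return 60.0 / tr


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the emulated study design: 8 WT + 10 TG subjects,
    20-minute scans at TR 0.5 s (2400 frames), 3 s and 6 s planted patterns
    with group-specific occurrence rates.  ``n_frames=1200`` is the fast
    profile (10-minute scans).
    """

    shape: tuple[int, int] = (48, 32)
    tr_seconds: float = 0.5
    n_frames: int = 2400
    n_wt: int = 8
    n_tg: int = 10
    # pattern windows in seconds
    window_seconds: dict = field(
        default_factory=lambda: {"WT_like": 3.0, "TG_like": 3.0, "GS_like": 6.0}
    )
    # occurrences per minute by group and pattern
    rates: dict = field(
        default_factory=lambda: {
            "WT": {"WT_like": 2.5, "TG_like": 0.6, "GS_like": 2.5},
            "TG": {"WT_like": 0.6, "TG_like": 2.0, "GS_like": 1.5},
        }
    )
    # mean amplitude applied to the unit-norm template at each occurrence
    amplitudes: dict = field(
        default_factory=lambda: {"WT_like": 15.0, "TG_like": 15.0, "GS_like": 27.0}
    )
    amplitude_sigma: float = 0.2  # lognormal spread of occurrence amplitudes
    gamma_shape: float = 5.0  # inter-occurrence interval jitter
    allow_overlap: bool = False  # let different patterns overlap in time
    noise_sd: float = 1.0
    noise_smooth_sigma: float = 0.4  # spatial smoothness of the noise field
    drift_sd: float = 2.0  # scale of per-voxel quadratic drift coefficients
    motion_gain: float = 0.5
    n_motion: int = 6

    def window_frames(self, name: str) -> int:
        return int(round(self.window_seconds[name] / self.tr_seconds))


@dataclass
class GroundTruth:
    """Everything planted: templates, occurrence frames, amplitudes, seeds."""

    templates: dict[str, QppTemplate]
    occurrences: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    amplitudes: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    motion: dict[str, np.ndarray] = field(default_factory=dict)  # sid -> T x k
    drift: dict[str, np.ndarray] = field(default_factory=dict)  # sid -> L x 2 coeffs
    noise_sd: float = 0.0
    seed: int | None = None

    def rate_per_minute(self, subject_id: str, name: str, n_frames: int, tr: float) -> float:
        occ = self.occurrences.get((subject_id, name), np.array([]))
        return len(occ) / (n_frames * tr / 60.0)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "noise_sd": self.noise_sd,
            "groups": self.groups,
            "templates": {
                k: {"tr_seconds": t.tr_seconds, "data": t.data.tolist()}
                for k, t in self.templates.items()
            },
            "occurrences": {
                f"{sid}|{name}": occ.tolist()
                for (sid, name), occ in self.occurrences.items()
            },
            "amplitudes": {
                f"{sid}|{name}": amp.tolist()
                for (sid, name), amp in self.amplitudes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        gt = cls(
            templates={
                k: QppTemplate(data=np.array(v["data"]), tr_seconds=v["tr_seconds"], name=k)
                for k, v in payload["templates"].items()
            },
            groups=payload["groups"],
            noise_sd=payload["noise_sd"],
            seed=payload["seed"],
        )
        for key, occ in payload["occurrences"].items():
            sid, name = key.split("|")
            gt.occurrences[(sid, name)] = np.asarray(occ, dtype=int)
        for key, amp in payload["amplitudes"].items():
            sid, name = key.split("|")
            gt.amplitudes[(sid, name)] = np.asarray(amp, dtype=float)
        return gt


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

def make_atlas(m: int = 48, n: int = 32, layout_spec: dict | None = None):
    """Build the synthetic slice atlas: mask and 12 bilateral rectangular ROIs.

    The mask is an elliptical "brain" united with all ROI boxes, minus a
    central ventricle hole.  Returns ``(RoiAtlas, SliceGeometry)``.
    """
    layout = layout_spec if layout_spec is not None else _DEFAULT_LAYOUT
    grid = np.zeros((m, n), dtype=int)
    boxes: dict[str, np.ndarray] = {}
    networks: dict[str, str] = {}
    hemis: dict[str, str] = {}
    for name, (box, tag) in layout.items():
        r0, r1, c0, c1 = box
        if not (0 <= r0 < r1 <= m and 0 <= c0 < c1 <= n):
            raise FormatError(f"ROI {name!r} box does not fit the {m}x{n} slice")
        for hemi in ("L", "R"):
            sel = np.zeros((m, n), dtype=bool)
            if hemi == "L":
                sel[r0:r1, c0:c1] = True
            else:
                sel[r0:r1, n - c1 : n - c0] = True
            if (grid[sel] > 0).any():
                raise FormatError(f"ROI {name!r} ({hemi}) overlaps another ROI")
            grid[sel] = 1
            key = f"{name}_{hemi}"
            boxes[key] = np.flatnonzero(sel.ravel())
            networks[key] = tag
            hemis[key] = hemi

    rr, cc = np.mgrid[0:m, 0:n]
    ellipse = ((rr - (m - 1) / 2 + 2) / (0.42 * m)) ** 2 + (
        (cc - (n - 1) / 2) / (0.46 * n)
    ) ** 2 <= 1.0
    ventricle = np.zeros((m, n), dtype=bool)
    ventricle[int(0.75 * m) : int(0.86 * m), int(0.42 * n) : int(0.58 * n)] = True
    if grid[ventricle].any():
        raise FormatError("ventricle hole intersects an ROI")
    mask = (ellipse | (grid > 0)) & ~ventricle
    geometry = SliceGeometry.from_mask(mask)

    flat_to_maskpos = np.full(m * n, -1, dtype=np.intp)
    flat_to_maskpos[geometry.mask_indices] = np.arange(geometry.n_voxels)
    labels = {name: flat_to_maskpos[flat] for name, flat in boxes.items()}
    atlas = RoiAtlas(labels=labels, networks=networks, hemisphere=hemis, geometry=geometry)
    return atlas, geometry


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def bandlimited_bump(window_frames: int, tr_seconds: float = 0.5,
                     low: float = 0.01, high: float = 0.2) -> np.ndarray:
    """One-signed burst envelope restricted to the infra-slow band.

    A half-sine pulse is passed through a zero-phase FIR band-pass with the
    given corner frequencies and cropped back to the window, so the planted
    event is (approximately) invariant under the same filtering the
    analysis applies.  Peak normalised to 1.
    """
    from scipy.signal import filtfilt, firwin

    W = int(window_frames)
    env = np.sin(np.pi * np.arange(W) / (W - 1))
    taps = firwin(401, [low, high], pass_zero=False, fs=1.0 / tr_seconds,
                  window="hamming")
    x = np.zeros(2 * 401 + W)
    x[401 : 401 + W] = env
    y = filtfilt(taps, [1.0], x, padlen=401)
    out = y[401 : 401 + W]
    return out / out.max()

def make_template(kind: str, atlas: RoiAtlas, window_frames: int,
                  envelope: np.ndarray | None = None, tr_seconds: float = 0.5) -> QppTemplate:
    """Construct a planted pattern of the given kind on the atlas ROIs.

    All non-ROI voxels are zero; the template is scaled to unit Frobenius
    norm so occurrence amplitudes have a single well-defined meaning.
    """
    W = int(window_frames)
    if W < 2:
        raise ValueError("window_frames must be >= 2")
    if envelope is None:
        # monophasic band-limited burst: one-signed events keep the planted
        # patterns separable under the positive peak threshold, and shaping
        # the burst to the infra-slow analysis band (0.01-0.2 Hz) plants the
        # kind of signal resting-state pattern analysis operates on (pass an
        # explicit envelope, e.g. a full sine, for biphasic waves)
        envelope = bandlimited_bump(W, tr_seconds)
    envelope = np.asarray(envelope, dtype=float)
    if envelope.shape != (W,):
        raise ValueError("envelope length must equal window_frames")

    data = np.zeros((atlas.geometry.n_voxels, W))
    if kind == "WT_like":
        signs = {"DMN": 1.0, "TPN": -1.0}
        for roi, idx in atlas.labels.items():
            data[idx] = signs.get(atlas.networks[roi], 0.0) * envelope
    elif kind == "TG_like":
        for roi, idx in atlas.labels.items():
            if roi.startswith("Cpu_d"):
                data[idx] = envelope
            elif roi.startswith("Cg"):
                data[idx] = -envelope
    elif kind == "GS_like":
        # one shared envelope (all ROI-pair correlations +1); DMN areas ride
        # the wave at reduced amplitude so the global pattern is not simply
        # a superset of the DMN-burst pattern
        for roi, idx in atlas.labels.items():
            gain = 0.4 if atlas.networks[roi] == "DMN" else 1.0
            data[idx] = gain * envelope
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    norm = np.linalg.norm(data)
    if norm > 0:
        data /= norm
    return QppTemplate(data=data, tr_seconds=tr_seconds, name=kind)


# ---------------------------------------------------------------------------
# Occurrence sampling
# ---------------------------------------------------------------------------

def sample_occurrences(n_frames: int, window_frames: int, mean_interval_frames: float,
                       shape: float = 5.0, seed=None) -> np.ndarray:
    """Quasi-periodic occurrence start frames.

    Inter-start intervals are i.i.d. gamma(shape, scale=mean/shape), rounded,
    with a floor of one window (occurrences of the same pattern never
    overlap); all starts satisfy ``start <= n_frames - window_frames``.
    """
    if mean_interval_frames <= window_frames:
        raise ValueError("mean interval must exceed the window length")
    if n_frames < window_frames:
        warnings.warn("series too short for a single occurrence", stacklevel=2)
        return np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    starts = []
    t = float(rng.uniform(0, mean_interval_frames))
    limit = n_frames - window_frames
    while t <= limit:
        starts.append(int(round(t)))
        gap = rng.gamma(shape, mean_interval_frames / shape)
        t += max(float(window_frames), round(gap))
    if not starts:
        warnings.warn("series too short for a single occurrence", stacklevel=2)
    return np.asarray(starts, dtype=int)


# ---------------------------------------------------------------------------
# Subject / cohort synthesis
# ---------------------------------------------------------------------------

def _motion_regressors(n_frames: int, k: int, rng) -> np.ndarray:
    """Slow, smooth motion-like traces (T x k), unit variance."""
    raw = rng.standard_normal((n_frames, k))
    smooth = gaussian_filter1d(raw, sigma=15.0, axis=0)
    sd = smooth.std(axis=0)
    sd[sd == 0] = 1.0
    return (smooth - smooth.mean(axis=0)) / sd


def synthesize_subject(config: CohortConfig, atlas: RoiAtlas, templates: dict,
                       subject_id: str, group: str, seed) -> tuple[BoldSeries, GroundTruth]:
    """Generate one subject's scan plus its ground-truth slice.

    The signal model is additive: planted patterns at their occurrence
    frames, a per-voxel quadratic drift, motion-like confounds with random
    spatial loadings, and spatially smoothed Gaussian noise.
    """
    if group not in config.rates:
        raise ValueError(f"no rates configured for group {group!r}")
    rng = np.random.default_rng(seed)
    geom = atlas.geometry
    L, T = geom.n_voxels, config.n_frames
    data = np.zeros((L, T))
    gt = GroundTruth(templates=templates, noise_sd=config.noise_sd, groups={subject_id: group})

    fpm = _frames_per_minute(config.tr_seconds)
    occupied = np.zeros(T, dtype=bool)
    for name, tmpl in templates.items():
        rate = config.rates[group].get(name, 0.0)
        W = tmpl.window_frames
        if rate <= 0:
            gt.occurrences[(subject_id, name)] = np.array([], dtype=int)
            gt.amplitudes[(subject_id, name)] = np.array([])
            continue
        occ = sample_occurrences(
            T, W, fpm / rate, shape=config.gamma_shape,
            seed=rng.integers(0, 2**31 - 1),
        )
        if not config.allow_overlap:
            # keep ground truth identifiable: occurrences of different
            # patterns never share frames (conflicting draws are dropped)
            occ = np.asarray([p for p in occ if not occupied[p : p + W].any()],
                             dtype=int)
            for p in occ:
                occupied[p : p + W] = True
        sig = config.amplitude_sigma
        amps = config.amplitudes[name] * np.exp(
            sig * rng.standard_normal(len(occ)) - sig**2 / 2
        )
        for p, a in zip(occ, amps):
            data[:, p : p + W] += a * tmpl.data
        gt.occurrences[(subject_id, name)] = occ
        gt.amplitudes[(subject_id, name)] = amps

    if config.drift_sd > 0:
        x = np.linspace(-1.0, 1.0, T)
        c = rng.normal(0.0, config.drift_sd, size=(L, 2))
        data += c[:, [0]] * x + c[:, [1]] * x**2
        gt.drift[subject_id] = c

    if config.motion_gain > 0 and config.n_motion > 0:
        motion = _motion_regressors(T, config.n_motion, rng)
        loadings = rng.standard_normal((L, config.n_motion))
        data += config.motion_gain * loadings @ motion.T
        gt.motion[subject_id] = motion

    if config.noise_sd > 0:
        m, n = geom.shape
        noise = rng.normal(0.0, config.noise_sd, size=(m, n, T))
        if config.noise_smooth_sigma > 0:
            noise = gaussian_filter(
                noise, sigma=(config.noise_smooth_sigma, config.noise_smooth_sigma, 0)
            )
        data += noise.reshape(m * n, T)[geom.mask_indices]

    series = BoldSeries(
        data=data, geometry=geom, tr_seconds=config.tr_seconds,
        subject_id=subject_id, group=group,
        provenance=[f"synthetic(seed={seed})"],
    )
    gt.seed = int(seed) if np.isscalar(seed) else None
    return series, gt


def synthesize_cohort(config: CohortConfig | None = None, seed=0):
    """Generate the default two-group cohort (8 WT + 10 TG by default).

    Per-subject seeds are spawned deterministically from the master seed.
    Returns ``(list of BoldSeries, GroundTruth, RoiAtlas)``.
    """
    if config is None:
        config = CohortConfig()
    atlas, _ = make_atlas(*config.shape)
    templates = {
        name: make_template(name, atlas, config.window_frames(name),
                            tr_seconds=config.tr_seconds)
        for name in config.window_seconds
    }
    root = np.random.SeedSequence(seed)
    subjects = [(f"WT{i+1:02d}", "WT") for i in range(config.n_wt)] + [
        (f"TG{i+1:02d}", "TG") for i in range(config.n_tg)
    ]
    children = root.spawn(len(subjects))
    series_list = []
    truth = GroundTruth(templates=templates, noise_sd=config.noise_sd, seed=int(seed))
    for (sid, grp), child in zip(subjects, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        series, gt = synthesize_subject(config, atlas, templates, sid, grp, sub_seed)
        series_list.append(series)
        truth.occurrences.update(gt.occurrences)
        truth.amplitudes.update(gt.amplitudes)
        truth.motion.update(gt.motion)
        truth.drift.update(gt.drift)
        truth.groups[sid] = grp
    return series_list, truth, atlas
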