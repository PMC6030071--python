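"""Core data model and file I/O for single-slice BOLD image series.

Conventions used throughout the package
---------------------------------------
* A slice is ``m`` rows by ``n`` columns; in-mask voxels are enumerated in
  row-major (C) order over ``(row, col)``, 0-based.  Every L-indexed array
  (series, templates, atlas voxel sets) shares this ordering.
* Frames are 0-based; time in seconds of frame ``t`` is ``t * tr_seconds``.
* :class:`BoldSeries` stores data as an ``L x T`` matrix (masked voxels by
  frames); estimator classes accept the transposed ``T x L`` view so that
  frames play the role of samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "SliceGeometry",
    "BoldSeries",
    "ConcatSeries",
    "RoiAtlas",
    "read_bold",
    "write_bold",
    "concat_group",
    "split_concat",
]


class FormatError(ValueError):
    """Raised when an on-disk image does not match the expected layout."""


class ConfigError(ValueError):
    """Raised for invalid configuration values (e.g. non-positive TR)."""


@dataclass(frozen=True)
class SliceGeometry:
    """Spatial layout of a single slice plus its brain mask.

    Parameters
    ----------
    shape : (m, n) slice dimensions in voxels.
    mask_indices : sorted flat row-major indices of in-mask voxels.
    """

    shape: tuple[int, int]
    mask_indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.mask_indices, dtype=np.intp)
        if idx.ndim != 1 or (idx.size and (idx.min() < 0 or idx.max() >= self.size)):
            raise FormatError("mask indices out of slice bounds")
        if not np.all(np.diff(idx) > 0):
            idx = np.unique(idx)
        object.__setattr__(self, "mask_indices", idx)

    @property
    def size(self) -> int:
        return int(self.shape[0]) * int(self.shape[1])

    @property
    def n_voxels(self) -> int:
        return int(self.mask_indices.size)

    @property
    def mask(self) -> np.ndarray:
        """Boolean (m, n) mask image."""
        flat = np.zeros(self.size, dtype=bool)
        flat[self.mask_indices] = True
        return flat.reshape(self.shape)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "SliceGeometry":
        mask = np.asarray(mask).astype(bool)
        if mask.ndim != 2:
            raise FormatError(f"mask must be 2D, got shape {mask.shape}")
        return cls(shape=tuple(mask.shape), mask_indices=np.flatnonzero(mask.ravel()))

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter an L-vector (or L x k matrix) back into (m, n[, k]) images."""
        values = np.asarray(values)
        if values.shape[0] != self.n_voxels:
            raise FormatError("value length does not match mask voxel count")
        out = np.full((self.size,) + values.shape[1:], fill, dtype=float)
        out[self.mask_indices] = values
        return out.reshape(self.shape + values.shape[1:])

    def __eq__(self, other):
        return (
            isinstance(other, SliceGeometry)
            and self.shape == other.shape
            and np.array_equal(self.mask_indices, other.mask_indices)
        )


@dataclass
class BoldSeries:
    """Masked voxels-by-time BOLD matrix with geometry and metadata.

    ``data`` is ``L x T`` with ``L == geometry.n_voxels``; all values finite
    and ``T >= 2``.  ``provenance`` is append-only: each processing step adds
    a short description of what it did.
    """

    data: np.ndarray
    geometry: SliceGeometry
    tr_seconds: float
    subject_id: str = ""
    group: str = "NA"
    provenance: list[str] = field(default_factory=lambda: ["raw"])
    flags: dict = field(default_factory=dict)  # e.g. zero-variance voxel indices

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("BoldSeries data must be 2D (voxels x frames)")
        if self.data.shape[0] != self.geometry.n_voxels:
            raise FormatError(
                f"data has {self.data.shape[0]} rows but mask has "
                f"{self.geometry.n_voxels} voxels"
            )
        if self.data.shape[1] < 2:
            raise FormatError("BoldSeries needs at least 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("BoldSeries data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ConfigError("tr_seconds must be positive")
        if self.group not in ("WT", "TG", "NA"):
            raise ConfigError(f"unknown group {self.group!r}")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def frames(self) -> np.ndarray:
        """T x L view (frames as samples), the estimator-facing layout."""
        return self.data.T

    def with_data(self, data: np.ndarray, step: str) -> "BoldSeries":
        """Return a copy carrying new data and an extended provenance."""
        return replace(self, data=data, provenance=self.provenance + [step])


@dataclass
class ConcatSeries:
    """Group image series: subject scans concatenated along time.

    ``boundaries`` is an ordered list of ``(subject_id, start, end)``
    half-open frame intervals that partition ``[0, T_total)``.
    """

    data: np.ndarray
    boundaries: list[tuple[str, int, int]]
    geometry: SliceGeometry
    tr_seconds: float
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        t = 0
        for _, start, end in self.boundaries:
            if start != t or end <= start:
                raise FormatError("boundaries must be contiguous, ordered, non-empty")
            t = end
        if t != self.data.shape[1]:
            raise FormatError("boundaries do not cover the concatenated series")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def subject_ids(self) -> list[str]:
        return [sid for sid, _, _ in self.boundaries]

    def segment(self, subject_id: str) -> tuple[int, int]:
        for sid, start, end in self.boundaries:
            if sid == subject_id:
                return start, end
        raise KeyError(f"subject {subject_id!r} not in concatenated series")


@dataclass
class RoiAtlas:
    """Integer-labelled ROIs on the slice, with network and hemisphere tags.

    ``labels`` maps ROI name to its voxel index set expressed as positions in
    the shared in-mask voxel order (not flat slice indices); sets are
    pairwise disjoint.  ``networks`` tags each ROI as DMN, TPN or other.
    """

    labels: dict[str, np.ndarray]
    networks: dict[str, str]
    hemisphere: dict[str, str]
    geometry: SliceGeometry

    def __post_init__(self):
        seen: set[int] = set()
        for name, idx in self.labels.items():
            idx = np.asarray(idx, dtype=np.intp)
            self.labels[name] = idx
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise FormatError(f"ROI {name!r} overlaps another ROI")
            seen.update(idx.tolist())
            tag = self.networks.get(name, "other")
            if tag in ("DMN", "TPN") and idx.size == 0:
                raise FormatError(f"network ROI {name!r} is empty")

    @property
    def roi_names(self) -> list[str]:
        return list(self.labels)

    def rois_in_network(self, tag: str) -> list[str]:
        return [r for r, t in self.networks.items() if t == tag]

    def roi_timecourse(self, data: np.ndarray, roi: str) -> np.ndarray:
        """Mean over ROI voxels of an L x T matrix -> length-T course."""
        return np.asarray(data)[self.labels[roi]].mean(axis=0)

    # ---- NIfTI + JSON round trip ------------------------------------
    def to_files(self, nifti_path, json_path) -> None:
        lab_img = np.zeros(self.geometry.size, dtype=np.int16)
        meta = {"rois": {}, "shape": list(self.geometry.shape)}
        for k, name in enumerate(self.roi_names, start=1):
            flat = self.geometry.mask_indices[self.labels[name]]
            lab_img[flat] = k
            meta["rois"][name] = {
                "label": k,
                "network": self.networks.get(name, "other"),
                "hemisphere": self.hemisphere.get(name, "NA"),
            }
        img = nib.Nifti1Image(
            lab_img.reshape(self.geometry.shape + (1,)).astype(np.int16), np.eye(4)
        )
        nib.save(img, str(nifti_path))
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)

    @classmethod
    def from_files(cls, nifti_path, json_path, geometry: SliceGeometry) -> "RoiAtlas":
        lab = np.asanyarray(nib.load(str(nifti_path)).dataobj)
        lab = _as_slice(lab).astype(int).ravel()
        with open(json_path) as fh:
            meta = json.load(fh)
        flat_to_maskpos = {int(f): i for i, f in enumerate(geometry.mask_indices)}
        labels, networks, hemis = {}, {}, {}
        for name, info in meta["rois"].items():
            flat = np.flatnonzero(lab == info["label"])
            labels[name] = np.array(sorted(flat_to_maskpos[f] for f in flat), dtype=np.intp)
            networks[name] = info["network"]
            hemis[name] = info["hemisphere"]
        return cls(labels=labels, networks=networks, hemisphere=hemis, geometry=geometry)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _as_slice(vol: np.ndarray) -> np.ndarray:
    """Collapse a (m, n[, 1[, ...]]) array to 2D, rejecting true 3D volumes."""
    vol = np.asarray(vol)
    spatial = vol.shape[:3] if vol.ndim >= 3 else vol.shape
    if len(spatial) == 3 and 1 not in spatial:
        raise FormatError("only single-slice data supported (one spatial dim must be 1)")
    return np.squeeze(vol)


def read_bold(nifti_path, mask_path, tr_seconds=None, subject_id="", group="NA") -> BoldSeries:
    """Load a single-slice 2D+time NIfTI and extract in-mask voxel courses.

    The TR is taken from the NIfTI header (``pixdim[4]``) unless
    ``tr_seconds`` overrides it.
    """
    img = nib.load(str(nifti_path))
    vol = np.asanyarray(img.dataobj)
    if vol.ndim < 3:
        raise FormatError("BOLD NIfTI must have at least 3 dims with a time axis")
    spatial, t = vol.shape[:-1], vol.shape[-1]
    if len(spatial) == 3 and 1 not in spatial:
        raise FormatError("only single-slice data supported")
    mask_img = np.asanyarray(nib.load(str(mask_path)).dataobj)
    if tuple(np.squeeze(mask_img).shape) != tuple(np.squeeze(vol[..., 0]).shape):
        raise FormatError(
            f"mask dims {np.squeeze(mask_img).shape} != image dims "
            f"{np.squeeze(vol[..., 0]).shape}"
        )
    geometry = SliceGeometry.from_mask(np.squeeze(mask_img) > 0)
    flat = vol.reshape(-1, t)
    data = flat[geometry.mask_indices]
    if tr_seconds is None:
        tr_seconds = float(img.header["pixdim"][4])
    if tr_seconds <= 0:
        raise ConfigError("TR not present in header; pass tr_seconds explicitly")
    return BoldSeries(
        data=data, geometry=geometry, tr_seconds=tr_seconds,
        subject_id=subject_id, group=group,
    )


def write_bold(series: BoldSeries, nifti_path, mask_path=None) -> None:
    """Write a BoldSeries (and optionally its mask) as single-slice NIfTI."""
    m, n = series.geometry.shape
    vol = np.zeros((m, n, 1, series.n_frames), dtype=np.float32)
    flat = vol.reshape(-1, series.n_frames)
    flat[series.geometry.mask_indices] = series.data
    img = nib.Nifti1Image(vol, np.eye(4))
    img.header["pixdim"][4] = series.tr_seconds
    nib.save(img, str(nifti_path))
    if mask_path is not None:
        mimg = nib.Nifti1Image(
            series.geometry.mask.astype(np.uint8).reshape(m, n, 1), np.eye(4)
        )
        nib.save(mimg, str(mask_path))


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concat_group(series_list: list[BoldSeries]) -> ConcatSeries:
    """Concatenate subject scans along time into a group image series."""
    if not series_list:
        raise FormatError("need at least one series to concatenate")
    ref = series_list[0]
    for s in series_list[1:]:
        if s.geometry != ref.geometry or s.tr_seconds != ref.tr_seconds:
            raise FormatError("geometry/TR mismatch across subjects")
    boundaries, t = [], 0
    for s in series_list:
        boundaries.append((s.subject_id, t, t + s.n_frames))
        t += s.n_frames
    return ConcatSeries(
        data=np.concatenate([s.data for s in series_list], axis=1),
        boundaries=boundaries,
        geometry=ref.geometry,
        tr_seconds=ref.tr_seconds,
        groups={s.subject_id: s.group for s in series_list},
    )


def split_concat(concat: ConcatSeries) -> list[BoldSeries]:
    """Inverse of :func:`concat_group` (bit-exact round trip)."""
    out = []
    for sid, start, end in concat.boundaries:
        out.append(
            BoldSeries(
                data=concat.data[:, start:end].copy(),
                geometry=concat.geometry,
                tr_seconds=concat.tr_seconds,
                subject_id=sid,
                group=concat.groups.get(sid, "NA"),
            )
        )
    return out
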