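"""Confocal XRF depth-stack processing.

A stack acquired at an oblique beam-sample geometry shows a lateral image
shift of ``depth_step * tan(angle)`` per plane; :func:`shift_correct`
removes it.  Thresholding at a multiple of the background isolates
exogenous particles, and :func:`particle_features` measures their 3-D
connected components.  Invalid pixels are NaN throughout this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import scipy.ndimage

from .errors import GeometryError, MaskError

__all__ = [
    "ConfocalStack",
    "ParticleFeature",
    "shift_correct",
    "estimate_background",
    "threshold_map",
    "log_display",
    "particle_features",
]


@dataclass
class ConfocalStack:
    """Ordered per-depth elemental maps with acquisition geometry.

    ``planes`` is (n_planes, rows, cols); NaN marks invalid pixels.
    ``shift_axis``/``shift_sign`` configure the lateral skew direction
    (the scan orientation is not fixed by the geometry alone).
    """

    planes: np.ndarray
    depth_step_um: float
    geometry_angle_deg: float = 45.0
    pixel_size_um: float = 1.0
    probe_depth_um: float | None = None
    shift_axis: int = 0
    shift_sign: int = 1

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3 or self.planes.shape[0] < 1:
            raise ValueError("planes must be (n_planes, rows, cols) with >= 1 plane")
        if self.depth_step_um < 0:
            raise ValueError("depth_step_um must be non-negative")
        if not 0 < self.geometry_angle_deg < 90:
            raise ValueError("geometry_angle_deg must lie in (0, 90)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.shift_axis not in (0, 1):
            raise ValueError("shift_axis must be 0 (rows) or 1 (cols)")
        if self.shift_sign not in (-1, 1):
            raise ValueError("shift_sign must be -1 or +1")

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    def shift_px_per_plane(self) -> float:
        """Lateral skew per plane in pixels."""
        return (self.depth_step_um
                * math.tan(math.radians(self.geometry_angle_deg))
                / self.pixel_size_um) * self.shift_sign


@dataclass(frozen=True)
class ParticleFeature:
    """One 26-connected 3-D component of a thresholded stack."""

    id: int
    voxels: tuple[tuple[int, int, int], ...]  # (plane, row, col)
    volume_voxels: int
    extent_um: float
    depth_span_planes: int
    centroid: tuple[float, float, float]

    def __post_init__(self) -> None:
        planes = [v[0] for v in self.voxels]
        if self.depth_span_planes != max(planes) - min(planes) + 1:
            raise ValueError("depth span inconsistent with voxel list")
        if self.volume_voxels != len(self.voxels):
            raise ValueError("volume inconsistent with voxel list")


def shift_correct(stack: ConfocalStack) -> ConfocalStack:
    """Undo the per-plane lateral skew of the acquisition geometry.

    Plane ``k`` is translated by ``-k * depth_step * tan(angle)`` pixels
    along the configured axis with linear interpolation; vacated margins
    become NaN.  A shift reaching the image extent raises
    :class:`GeometryError`.
    """
    per_plane = stack.shift_px_per_plane()
    extent = stack.planes.shape[1 + stack.shift_axis]
    max_shift = abs(per_plane) * (stack.n_planes - 1)
    if max_shift >= extent:
        raise GeometryError(
            f"cumulative shift {max_shift:.1f} px exceeds image extent {extent} px")
    corrected = np.empty_like(stack.planes)
    for k in range(stack.n_planes):
        vector = [0.0, 0.0]
        vector[stack.shift_axis] = -per_plane * k
        corrected[k] = scipy.ndimage.shift(
            stack.planes[k], vector, order=1, mode="constant", cval=np.nan)
    return replace(stack, planes=corrected)


def estimate_background(image: np.ndarray,
                        tissue_mask: np.ndarray | None = None) -> float:
    """Scalar background level of a 2-D map.

    With a tissue mask: the median of off-tissue pixels.  Without: the
    median of the lowest-intensity quartile (robust to sparse bright
    particles).  NaN pixels are ignored.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if tissue_mask is not None:
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
        if tissue_mask.shape != image.shape:
            raise MaskError("tissue mask shape does not match image")
        off = image[~tissue_mask]
        off = off[np.isfinite(off)]
        if off.size == 0:
            raise MaskError("no valid off-tissue pixels under the mask")
        return float(np.median(off))
    values = np.sort(image[np.isfinite(image)].ravel())
    if values.size == 0:
        raise ValueError("image contains no valid pixels")
    quartile = values[: max(1, values.size // 4)]
    return float(np.median(quartile))


def threshold_map(image: np.ndarray, background: float,
                  factor: float = 10.0) -> np.ndarray:
    """Zero out pixels below ``factor * background``; keep the rest unchanged.

    NaN (invalid) pixels stay NaN.  Idempotent.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    if background < 0:
        raise ValueError("background must be non-negative")
    image = np.asarray(image, dtype=float)
    out = image.copy()
    out[image < factor * background] = 0.0
    return out


def log_display(image: np.ndarray) -> np.ndarray:
    """Order-preserving log scaling ``log10(1 + value)`` for display."""
    image = np.asarray(image, dtype=float)
    if np.any(image[np.isfinite(image)] < 0):
        raise ValueError("log display requires non-negative values")
    return np.log10(1.0 + image)


_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def particle_features(stack: ConfocalStack) -> list[ParticleFeature]:
    """26-connected 3-D components of positive voxels of a (shift-corrected,
    thresholded) stack.

    ``extent_um`` is the maximum single-plane extent: the larger of the
    in-plane bounding-box sides, in micrometres.
    """
    binary = np.nan_to_num(stack.planes, nan=0.0) > 0
    labels, n = scipy.ndimage.label(binary, structure=_STRUCTURE_26)
    features = []
    for idx, slc in enumerate(scipy.ndimage.find_objects(labels), start=1):
        coords = np.argwhere(labels[slc] == idx)
        coords += [s.start for s in slc]
        planes = coords[:, 0]
        extent_vox = 0
        for p in np.unique(planes):
            in_plane = coords[planes == p]
            extent_vox = max(extent_vox,
                             int(np.ptp(in_plane[:, 1])) + 1,
                             int(np.ptp(in_plane[:, 2])) + 1)
        features.append(ParticleFeature(
            id=idx,
            voxels=tuple(map(tuple, coords.tolist())),
            volume_voxels=len(coords),
            extent_um=extent_vox * stack.pixel_size_um,
            depth_span_planes=int(planes.max() - planes.min() + 1),
            centroid=tuple(coords.mean(axis=0)),
        ))
    return features
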