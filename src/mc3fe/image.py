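"""Voxel-level operations: masks, region labelling, anatomical frame.

Conventions: voxel indices are 0-based; world coordinates are node-centred,
``world = origin + index * spacing`` (the origin is the centre of voxel
(0,0,0)).  Axis order is (x, y, z) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .errors import AmbiguousAxisError, DegenerateGeometryError, InvalidInputError

__all__ = [
    "Label",
    "VoxelImage",
    "LabelVolume",
    "AnatomicalFrame",
    "erode_surface",
    "fit_anatomical_frame",
    "isolate_distal",
    "label_regions",
    "sclerotic_volume_fraction",
]


class Label(IntEnum):
    """Voxel region labels."""

    OUTSIDE = 0
    CORTEX = 1
    TRABECULAR = 2
    SCL = 3  # sclerotic: dense adapted subchondral trabecular bone (HU > threshold)
    LYS = 4  # lytic: isolated focal low-density volume inside the PSG


#: 6-connected (face adjacency) structuring element.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)
#: 26-connected (vertex adjacency) structuring element.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _check_grid(values: np.ndarray, spacing, what: str) -> None:
    arr = np.asarray(values)
    if arr.ndim != 3 or arr.size == 0:
        raise InvalidInputError(f"{what} must be a non-empty 3-D grid")
    sp = np.asarray(spacing, dtype=float)
    if sp.shape != (3,) or np.any(sp <= 0):
        raise InvalidInputError("spacing must be three strictly positive lengths (mm)")


@dataclass
class VoxelImage:
    """A 3-D grid of CT numbers with voxel spacing and world origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        _check_grid(self.values, self.spacing, "image")
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coords(self, index_array: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of (n, 3) voxel indices."""
        return np.asarray(self.origin) + np.asarray(index_array, dtype=float) * np.asarray(
            self.spacing
        )


@dataclass
class LabelVolume:
    """Voxel labels over :class:`Label`, congruent with a source image."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        _check_grid(self.labels, self.spacing, "label volume")
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, *labels: Label) -> np.ndarray:
        return np.isin(self.labels, [int(l) for l in labels])

    @property
    def bone_mask(self) -> np.ndarray:
        return self.labels != int(Label.OUTSIDE)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed anatomical frame of the distal MC3.

    ``long_axis`` points proximally; ``frontal_normal`` points dorsally;
    ``sagittal_normal`` spans the medio-lateral direction;
    ``transverse_normal`` is parallel to the long axis.
    """

    long_axis: np.ndarray
    sagittal_normal: np.ndarray
    frontal_normal: np.ndarray
    transverse_normal: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        for name in ("long_axis", "sagittal_normal", "frontal_normal", "transverse_normal"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise InvalidInputError(f"{name} must be a unit 3-vector")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        for a, b in (
            ("sagittal_normal", "frontal_normal"),
            ("sagittal_normal", "transverse_normal"),
            ("frontal_normal", "transverse_normal"),
        ):
            if abs(float(np.dot(getattr(self, a), getattr(self, b)))) > 1e-9:
                raise InvalidInputError(f"{a} and {b} are not orthogonal")
        if abs(abs(float(np.dot(self.transverse_normal, self.long_axis))) - 1.0) > 1e-9:
            raise InvalidInputError("transverse_normal must be parallel to long_axis")

    def axial_coordinate(self, points_mm: np.ndarray) -> np.ndarray:
        """Signed coordinate along the long axis (mm, increasing proximally)."""
        return (np.asarray(points_mm, dtype=float) - self.origin) @ self.long_axis


def erode_surface(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Erode the external surface with a 6-connected structuring element.

    Raises :class:`DegenerateGeometryError` if the mask erodes to empty.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 3 or not m.any():
        raise InvalidInputError("mask must be a non-empty 3-D binary volume")
    if iterations < 1:
        raise InvalidInputError("iterations must be >= 1")
    out = ndimage.binary_erosion(m, structure=STRUCT_6, iterations=iterations)
    if not out.any():
        raise DegenerateGeometryError("erosion produced an empty mask")
    return out


def fit_anatomical_frame(
    mask: np.ndarray,
    spacing,
    dorsal_hint,
    proximal_hint=None,
    origin=(0.0, 0.0, 0.0),
) -> AnatomicalFrame:
    """Fit the anatomical frame from the bone voxel cloud.

    The long axis is the first principal direction of the voxel point cloud
    (a surrogate for a cylinder fit: for elongated near-cylindrical masks
    the two agree to well under a degree).  The sagittal plane is supplied
    by a dorsal landmark direction (``dorsal_hint``) rather than detected:
    the frontal normal is the dorsal hint orthogonalized against the long
    axis, and the sagittal normal completes the right-handed frame.

    ``proximal_hint`` optionally disambiguates the long-axis sign (it is
    flipped to have positive dot product with the hint).
    """
    m = np.asarray(mask, dtype=bool)
    _check_grid(m, spacing, "mask")
    idx = np.argwhere(m)
    if idx.shape[0] < 100:
        raise InvalidInputError("mask must contain at least 100 voxels")
    pts = np.asarray(origin, dtype=float) + idx * np.asarray(spacing, dtype=float)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    extents = np.sqrt(np.maximum(evals, 0.0))
    if extents[1] <= 0 or extents[2] / extents[1] < 1.5:
        raise AmbiguousAxisError(
            f"principal extent ratio {extents[2] / max(extents[1], 1e-300):.3f} < 1.5; "
            "long axis is ambiguous"
        )
    long_axis = evecs[:, 2] / np.linalg.norm(evecs[:, 2])
    if proximal_hint is not None:
        if float(np.dot(long_axis, np.asarray(proximal_hint, dtype=float))) < 0:
            long_axis = -long_axis
    elif long_axis[np.argmax(np.abs(long_axis))] < 0:
        long_axis = -long_axis  # deterministic sign convention
    dorsal = np.asarray(dorsal_hint, dtype=float)
    dorsal = dorsal - np.dot(dorsal, long_axis) * long_axis
    nrm = np.linalg.norm(dorsal)
    if nrm < 1e-9:
        raise InvalidInputError("dorsal_hint is parallel to the long axis")
    frontal_normal = dorsal / nrm
    sagittal_normal = np.cross(frontal_normal, long_axis)
    sagittal_normal /= np.linalg.norm(sagittal_normal)
    return AnatomicalFrame(
        long_axis=long_axis,
        sagittal_normal=sagittal_normal,
        frontal_normal=frontal_normal,
        transverse_normal=long_axis,
        origin=centroid,
    )


def isolate_distal(
    mask: np.ndarray,
    frame: AnatomicalFrame,
    spacing,
    length_mm: float = 63.5,
    origin=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Keep voxels within ``length_mm`` of the distal-most bone voxel.

    Distance is measured along the frame's long axis (which points
    proximally, so the distal extreme is the minimum axial coordinate).
    """
    m = np.asarray(mask, dtype=bool)
    _check_grid(m, spacing, "mask")
    if length_mm <= 0:
        raise InvalidInputError("length_mm must be positive")
    idx = np.argwhere(m)
    if idx.size == 0:
        raise InvalidInputError("mask is empty")
    pts = np.asarray(origin, dtype=float) + idx * np.asarray(spacing, dtype=float)
    t = frame.axial_coordinate(pts)
    extent = float(t.max() - t.min())
    if extent + 1e-9 < length_mm:
        raise InvalidInputError(
            f"mask extent {extent:.3f} mm along the long axis is shorter than {length_mm} mm"
        )
    keep = t <= t.min() + length_mm + 1e-9
    out = np.zeros_like(m)
    out[tuple(idx[keep].T)] = True
    return out


def label_regions(
    image: VoxelImage,
    bone_mask: np.ndarray,
    trabecular_mask: np.ndarray,
    psg_region_mask: np.ndarray | None = None,
    threshold_hu: float = 1500.0,
    min_lysis_voxels: int = 8,
) -> LabelVolume:
    """Label bone voxels as CORTEX / TRABECULAR / SCL / LYS.

    SCL: trabecular voxels with HU > ``threshold_hu``.
    LYS: 26-connected components of voxels with HU < threshold that lie
    inside the PSG search region, are isolated focal defects (their outer
    boundary touches only dense bone — sclerotic or cortical — so diffuse
    sub-threshold trabecular bone never qualifies), and have at least
    ``min_lysis_voxels`` voxels.  Neither connectivity, the minimum size,
    nor the PSG search region has a canonical definition; all three are
    configurable here.
    """
    bone = np.asarray(bone_mask, dtype=bool)
    trab = np.asarray(trabecular_mask, dtype=bool)
    if bone.shape != image.values.shape or trab.shape != image.values.shape:
        raise InvalidInputError("masks must be congruent with the image")
    if not bone.any():
        raise InvalidInputError("bone mask is empty")
    if np.any(trab & ~bone):
        raise InvalidInputError("trabecular mask must be a subset of the bone mask")

    hu = image.values
    labels = np.zeros(hu.shape, dtype=np.uint8)
    labels[bone] = int(Label.CORTEX)
    labels[trab] = int(Label.TRABECULAR)
    scl = trab & (hu > threshold_hu)
    labels[scl] = int(Label.SCL)

    if psg_region_mask is not None:
        psg = np.asarray(psg_region_mask, dtype=bool)
        if psg.shape != hu.shape:
            raise InvalidInputError("psg_region_mask must be congruent with the image")
        candidates = trab & psg & (hu < threshold_hu)
        dense = scl | (bone & ~trab)  # sclerotic or cortical bone
        comp, n = ndimage.label(candidates, structure=STRUCT_26)
        for i in range(1, n + 1):
            comp_mask = comp == i
            if int(comp_mask.sum()) < int(min_lysis_voxels):
                continue
            boundary = ndimage.binary_dilation(comp_mask, structure=STRUCT_26) & ~comp_mask
            if np.all(dense[boundary]):  # isolated: surrounded by dense bone
                labels[comp_mask] = int(Label.LYS)

    return LabelVolume(labels=labels, spacing=image.spacing, origin=image.origin)


def sclerotic_volume_fraction(labels: LabelVolume, condyle_mask: np.ndarray) -> float:
    """Normalized sclerotic volume V_SCL = V_sclerosis / V_condyle.

    Both volumes are voxel counts times the voxel volume, restricted to the
    condyle mask.
    """
    condyle = np.asarray(condyle_mask, dtype=bool)
    if condyle.shape != labels.labels.shape:
        raise InvalidInputError("condyle mask must be congruent with the label volume")
    n_condyle = int(condyle.sum())
    if n_condyle == 0:
        raise InvalidInputError("condyle mask is empty")
    n_scl = int((condyle & (labels.labels == int(Label.SCL))).sum())
    return n_scl / n_condyle
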