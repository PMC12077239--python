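"""Synthetic phantoms: calibration phantom, condyle phantoms, recovery cases.

The condyle phantom is a deliberately idealized stand-in for a segmented
distal MC3 — a cylindrical shaft capped by a spherical condyle, with a
cortical shell, a subchondral sclerotic blob under the palmaro-distal
articular surface near the parasagittal groove, and an optional spherical
lytic inclusion inside it.  The pipeline's correctness claims are about
equations and procedures, not anatomy; the phantom exists so that every
stage (calibration, labelling, meshing, solving, tuning) has inputs with
exactly known ground truth.  All generators are pure functions of
(spec, seed) and bit-reproducible.

Orientation convention for phantoms: the long axis is z with the proximal
cut at z = 0 and the condyle distal (high z); dorsal is +y, palmar is -y,
medial is +x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    DEFAULT_CURVE,
    DEFAULT_LAW,
    CalibrationCurve,
    DensityModulusLaw,
    RegionFactors,
)
from .errors import InvalidSpecError
from .image import AnatomicalFrame, Label, LabelVolume, VoxelImage, sclerotic_volume_fraction
from .meshing import LoadPatchSpec, PsgStripSpec

__all__ = [
    "CondylePhantomSpec",
    "CondylePhantom",
    "RecoveryCase",
    "CTRL_SPEC",
    "PSG_SBI_SPEC",
    "make_calibration_phantom",
    "make_condyle_phantom",
    "make_recovery_case",
]


def make_calibration_phantom(
    plug_densities=(200.0, 800.0, 1250.0, 1750.0),
    curve: CalibrationCurve = DEFAULT_CURVE,
    noise_sd_hu: float = 0.0,
    seed: int = 0,
    shape=(48, 48, 12),
    spacing_mm: float = 1.0,
    plug_radius_mm: float = 5.0,
    background_hu: float = 0.0,
):
    """Synthesize a scan of a 4-plug HA calibration phantom.

    Cylindrical plugs of known density are placed in a uniform background;
    plug HU values follow the forward calibration map plus optional
    Gaussian noise.  Returns ``(VoxelImage, {density: roi_mask})`` where
    the ROI masks are the plug interiors (radially eroded by one voxel to
    avoid edge voxels, as one would when placing ROIs on a real scan).
    """
    rho = np.asarray(plug_densities, dtype=float)
    if rho.size < 2 or np.any(rho <= 0) or not np.all(np.diff(rho) > 0):
        raise InvalidSpecError("plug densities must be positive and strictly increasing")
    nx, ny, nz = shape
    xi, yi = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    # plug centres on a regular grid; error out if geometry cannot fit
    n = rho.size
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    centers = []
    for i in range(n):
        r, c = divmod(i, ncol)
        centers.append(
            (
                (c + 0.5) * nx / ncol,
                (r + 0.5) * ny / nrow,
            )
        )
    r_vox = plug_radius_mm / spacing_mm
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < 2 * r_vox:
                raise InvalidSpecError("plug geometry overlaps; reduce plug_radius_mm")
        cx, cy = centers[i]
        if cx - r_vox < 0 or cx + r_vox > nx or cy - r_vox < 0 or cy + r_vox > ny:
            raise InvalidSpecError("plug extends outside the phantom volume")

    values = np.full(shape, background_hu, dtype=float)
    rois: dict[float, np.ndarray] = {}
    for density, (cx, cy) in zip(rho, centers):
        disc = (xi + 0.5 - cx) ** 2 + (yi + 0.5 - cy) ** 2 <= r_vox**2
        plug = np.repeat(disc[:, :, None], nz, axis=2)
        values[plug] = curve.hu_from_density(density)
        roi_disc = (xi + 0.5 - cx) ** 2 + (yi + 0.5 - cy) ** 2 <= (r_vox - 1.0) ** 2
        rois[float(density)] = np.repeat(roi_disc[:, :, None], nz, axis=2)
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd_hu, size=shape)
    image = VoxelImage(values=values, spacing=(spacing_mm,) * 3, origin=(0.0, 0.0, 0.0))
    return image, rois


@dataclass(frozen=True)
class CondylePhantomSpec:
    """Parameters of the synthetic condyle phantom.

    Defaults give a ~40 x 40 x 80 voxel volume at 0.5 mm spacing so that a
    full tune-and-validate run stays within desk-scale solve times.  HU
    values straddle the sclerosis threshold (1500): sclerotic bone above,
    everything trabecular below, and the lytic inclusion well below.
    """

    shape: tuple[int, int, int] = (40, 40, 80)
    spacing_mm: float = 0.5
    shaft_radius_mm: float = 6.5
    shaft_length_mm: float = 26.0
    condyle_radius_mm: float = 8.5
    cortical_thickness_mm: float = 1.5
    background_trabecular_hu: float = 1200.0
    cortical_hu: float = 2000.0
    sclerotic_hu: float = 1800.0
    sclerotic_target_fraction: float = 0.185
    lysis_radius_mm: float = 0.0  # 0 disables the lytic inclusion (CTRL class)
    lysis_hu: float = 600.0
    lysis_center_mm: tuple[float, float, float] | None = None  # default: on the groove, subchondral
    noise_sd_hu: float = 0.0
    seed: int = 0
    groove_offset_mm: float = 2.0  # parasagittal groove plane offset, medial of the ridge
    psg_region_halfwidth_mm: float = 2.5
    outside_hu: float = -100.0

    def __post_init__(self) -> None:
        if not (self.sclerotic_hu > 1500.0 > self.lysis_hu):
            raise InvalidSpecError("need sclerotic_hu > 1500 > lysis_hu")
        if self.background_trabecular_hu >= 1500.0:
            raise InvalidSpecError("background trabecular HU must be below the 1500 threshold")
        if self.condyle_radius_mm < self.shaft_radius_mm:
            raise InvalidSpecError("condyle radius must be >= shaft radius")
        if not (0.0 <= self.sclerotic_target_fraction < 1.0):
            raise InvalidSpecError("sclerotic_target_fraction must be in [0, 1)")


@dataclass
class CondylePhantom:
    """A rasterized condyle phantom with full ground truth."""

    spec: CondylePhantomSpec
    image: VoxelImage
    labels: LabelVolume  # ground-truth labels (noise-free rule applied to clean HU)
    bone_mask: np.ndarray
    trabecular_mask: np.ndarray
    condyle_mask: np.ndarray
    psg_region_mask: np.ndarray
    frame: AnatomicalFrame
    psg_strip_spec: PsgStripSpec
    load_patch_spec: LoadPatchSpec

    @property
    def v_scl(self) -> float:
        return sclerotic_volume_fraction(self.labels, self.condyle_mask)


#: Control-class phantom: sclerosis but no focal lysis.
CTRL_SPEC = CondylePhantomSpec()
#: Fatigue-injury-class phantom: focal PSG lysis inside a larger sclerotic
#: volume (bones with PSG subchondral injury carry more sclerosis, which is
#: what pushes their adaptive factor positive under the tuned law).
PSG_SBI_SPEC = CondylePhantomSpec(lysis_radius_mm=1.6, sclerotic_target_fraction=0.20)


def _lysis_sphere(spec, sphere_center, u, x, y, z):
    """Centre and rasterized mask of the lytic sphere for a spec."""
    if spec.lysis_center_mm is not None:
        lc = np.asarray(spec.lysis_center_mm, dtype=float)
    else:
        depth_c = spec.cortical_thickness_mm + spec.lysis_radius_mm + 0.75
        lc = sphere_center + (spec.condyle_radius_mm - depth_c) * u
    mask = (x - lc[0]) ** 2 + (y - lc[1]) ** 2 + (z - lc[2]) ** 2 <= spec.lysis_radius_mm**2
    return lc, mask


def make_condyle_phantom(spec: CondylePhantomSpec = CondylePhantomSpec()) -> CondylePhantom:
    """Rasterize a condyle phantom with known regions and landmarks."""
    nx, ny, nz = spec.shape
    h = spec.spacing_mm
    xi, yi, zi = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    x, y, z = xi * h, yi * h, zi * h  # world mm, node-centred, origin at voxel (0,0,0)

    cx, cy = (nx - 1) / 2.0 * h, (ny - 1) / 2.0 * h
    zc = spec.shaft_length_mm  # sphere centre height
    sphere_center = np.array([cx, cy, zc])

    r2d = np.hypot(x - cx, y - cy)
    r3d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - zc) ** 2)
    shaft = (r2d <= spec.shaft_radius_mm) & (z <= zc)
    ball = r3d <= spec.condyle_radius_mm
    bone = shaft | ball
    if zc + spec.condyle_radius_mm >= (nz - 1) * h or not bone[:, :, 0].any():
        raise InvalidSpecError("phantom geometry does not fit the volume")

    # cortical shell: surface depth below cortical thickness.  Signed depth
    # is computed analytically from the two primitives (union: take the
    # larger depth) rather than by erosion so the shell is isotropic; the
    # proximal cut face at z=0 is an artificial surface and gets no shell.
    depth_shaft = np.where(z <= zc, spec.shaft_radius_mm - r2d, -np.inf)
    depth_ball = np.where(ball, spec.condyle_radius_mm - r3d, -np.inf)
    depth = np.maximum(depth_shaft, depth_ball)
    trabecular = bone & (depth > spec.cortical_thickness_mm)
    cortex = bone & ~trabecular

    condyle = bone & (z >= zc)
    n_condyle = int(condyle.sum())

    # sclerotic blob: the N trabecular condyle voxels closest to a
    # palmaro-distal surface anchor near the groove
    u = np.array([spec.groove_offset_mm / spec.condyle_radius_mm, -0.5, 0.8660254])
    u /= np.linalg.norm(u)
    anchor = sphere_center + spec.condyle_radius_mm * u
    n_target = int(round(spec.sclerotic_target_fraction * n_condyle))
    cand = trabecular & condyle
    cand_idx = np.argwhere(cand)
    if n_target > cand_idx.shape[0]:
        raise InvalidSpecError(
            f"sclerotic_target_fraction {spec.sclerotic_target_fraction} infeasible: "
            f"only {cand_idx.shape[0]}/{n_condyle} condyle voxels are trabecular"
        )
    scl_mask = np.zeros_like(bone)
    if n_target > 0:
        pts = cand_idx * h
        d_anchor = np.linalg.norm(pts - anchor, axis=1)
        flat = cand_idx[:, 0] * ny * nz + cand_idx[:, 1] * nz + cand_idx[:, 2]
        order = np.lexsort((flat, d_anchor))
        chosen = cand_idx[order[:n_target]]
        scl_mask[tuple(chosen.T)] = True
        if spec.lysis_radius_mm > 0:
            # guarantee the lytic defect is fully encased in dense bone: its
            # 26-neighbour shell of trabecular voxels must belong to the
            # sclerotic set, swapping out the farthest-from-anchor members so
            # the total sclerotic voxel count (hence V_SCL) is unchanged
            from scipy import ndimage

            from .image import STRUCT_26

            lc, lys_guess = _lysis_sphere(spec, sphere_center, u, x, y, z)
            shell = ndimage.binary_dilation(lys_guess, structure=STRUCT_26) & ~lys_guess
            required = shell & trabecular
            missing = required & ~scl_mask
            n_missing = int(missing.sum())
            if n_missing > 0:
                if not np.all(trabecular[required] | cortex[required]):
                    raise InvalidSpecError("lysis shell leaves the bone")
                removable = scl_mask & ~required & ~lys_guess
                rem_idx = np.argwhere(removable)
                d_rem = np.linalg.norm(rem_idx * h - anchor, axis=1)
                rflat = rem_idx[:, 0] * ny * nz + rem_idx[:, 1] * nz + rem_idx[:, 2]
                rorder = np.lexsort((rflat, -d_rem))
                if n_missing > rem_idx.shape[0]:
                    raise InvalidSpecError("sclerotic region too small to encase the lysis")
                scl_mask[tuple(rem_idx[rorder[:n_missing]].T)] = False
                scl_mask[missing] = True

    # parasagittal groove plane and PSG search region
    x_groove = cx + spec.groove_offset_mm
    psg_region = condyle & (np.abs(x - x_groove) <= spec.psg_region_halfwidth_mm)

    # optional lytic inclusion
    lys_mask = np.zeros_like(bone)
    if spec.lysis_radius_mm > 0:
        lc, lys_mask = _lysis_sphere(spec, sphere_center, u, x, y, z)
        if not lys_mask.any():
            raise InvalidSpecError("lytic sphere rasterized to zero voxels")
        if np.any(lys_mask & ~scl_mask):
            raise InvalidSpecError("lytic sphere is not contained in the sclerotic region")
        if np.any(lys_mask & ~psg_region):
            raise InvalidSpecError("lytic sphere is not contained in the PSG search region")
        scl_mask = scl_mask & ~lys_mask

    values = np.full(spec.shape, spec.outside_hu, dtype=float)
    values[cortex] = spec.cortical_hu
    values[trabecular] = spec.background_trabecular_hu
    values[scl_mask] = spec.sclerotic_hu
    values[lys_mask] = spec.lysis_hu
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[cortex] = int(Label.CORTEX)
    labels[trabecular] = int(Label.TRABECULAR)
    labels[scl_mask] = int(Label.SCL)
    labels[lys_mask] = int(Label.LYS)

    frame = AnatomicalFrame(
        long_axis=np.array([0.0, 0.0, -1.0]),  # points proximally
        sagittal_normal=np.array([1.0, 0.0, 0.0]),
        frontal_normal=np.array([0.0, 1.0, 0.0]),  # dorsal
        transverse_normal=np.array([0.0, 0.0, -1.0]),
        origin=np.array([cx, cy, zc]),
    )
    psg_strip_spec = PsgStripSpec(
        point_mm=(x_groove, cy, zc),
        normal=(1.0, 0.0, 0.0),
        max_distal_distance_mm=spec.condyle_radius_mm + 2.0,
    )
    patch_dir = np.array([0.35, -0.75, 0.56])
    patch_dir /= np.linalg.norm(patch_dir)
    patch_center = sphere_center + spec.condyle_radius_mm * patch_dir
    load_patch_spec = LoadPatchSpec(
        center_mm=tuple(patch_center),
        radius_mm=3.5,
        direction=(0.0, -1.0, 0.0),  # outward normal roughly palmar
        min_normal_dot=0.1,
    )

    return CondylePhantom(
        spec=spec,
        image=VoxelImage(values=values, spacing=(h,) * 3, origin=(0.0, 0.0, 0.0)),
        labels=LabelVolume(labels=labels, spacing=(h,) * 3, origin=(0.0, 0.0, 0.0)),
        bone_mask=bone,
        trabecular_mask=trabecular,
        condyle_mask=condyle,
        psg_region_mask=psg_region,
        frame=frame,
        psg_strip_spec=psg_strip_spec,
        load_patch_spec=load_patch_spec,
    )


@dataclass
class RecoveryCase:
    """A synthetic specimen whose 'measured' PSG strain has known factors."""

    specimen_id: str
    group: str  # "CTRL" or "PSG-SBI"
    phantom: CondylePhantom
    solver: "RegionScaledSolver"  # noqa: F821 - forward ref, see fe module
    true_factors: RegionFactors
    measured_strain: float
    v_scl: float

    def forward(self, factors: RegionFactors) -> float:
        return self.solver.psg_strain(factors)

    @property
    def has_lysis(self) -> bool:
        return self.solver.has_lysis


def make_recovery_case(
    spec: CondylePhantomSpec,
    true_a_scl: float,
    true_d_lys: float,
    specimen_id: str = "synthetic",
    load_case=None,
    curve: CalibrationCurve = DEFAULT_CURVE,
    law: DensityModulusLaw = DEFAULT_LAW,
    fine_edge_mm: float = 0.5,
    coarse_edge_mm: float = 1.0,
    strip_width_mm: float = 3.0,
) -> RecoveryCase:
    """Forward-generate a tuning target with known true factors.

    Builds the phantom, meshes and tags it, runs the forward pipeline with
    the true (a_scl, d_lys) and records the resulting PSG mean strain as
    the synthetic 'measured' target for parameter-recovery experiments.
    """
    from .fe import LoadCase, RegionScaledSolver
    from .meshing import tag_boundary_sets, voxels_to_tets

    true = RegionFactors(true_a_scl, true_d_lys)  # validates ranges
    phantom = make_condyle_phantom(spec)
    mesh = voxels_to_tets(
        phantom.labels,
        phantom.image,
        curve=curve,
        law=law,
        fine_edge_mm=fine_edge_mm,
        coarse_edge_mm=coarse_edge_mm,
    )
    tag_boundary_sets(
        mesh,
        phantom.frame,
        phantom.psg_strip_spec,
        phantom.load_patch_spec,
        strip_width_mm=strip_width_mm,
    )
    solver = RegionScaledSolver(
        mesh,
        phantom.frame,
        law=law,
        load_case=load_case if load_case is not None else LoadCase(),
    )
    measured = solver.psg_strain(true)
    return RecoveryCase(
        specimen_id=specimen_id,
        group="PSG-SBI" if spec.lysis_radius_mm > 0 else "CTRL",
        phantom=phantom,
        solver=solver,
        true_factors=true,
        measured_strain=measured,
        v_scl=phantom.v_scl,
    )
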