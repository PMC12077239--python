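"""Linear isotropic elasticity on tetrahedral meshes.

Constant-strain (linear) tetrahedra, engineering strain ordering
(exx, eyy, ezz, gxy, gyz, gzx).  Units: mm / N / MPa, so displacements are
mm and strains dimensionless.  Tensile strain is positive and "maximum
principal strain" is the algebraically largest eigenvalue of the
small-strain tensor, matching surface-tension reporting from digital image
correlation.

The experiment being virtualized: the proximal cut surface is fully
constrained and a 7.5 kN load, distributed over the nodes of a palmar patch
on the medial condyle, acts at 60 deg / 30 deg to the frontal / transverse
planes, pushing the patch dorsally and proximally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import cg, spsolve

from .calibration import DEFAULT_CURVE, DEFAULT_LAW, RegionFactors
from .errors import (
    ConstraintDeficiencyError,
    DegenerateGeometryError,
    InfeasibleAnglesError,
    InvalidInputError,
)
from .image import AnatomicalFrame, Label
from .meshing import LoadPatchSpec, PsgStripSpec, TetrahedralMesh, tag_boundary_sets, voxels_to_tets

__all__ = [
    "LoadCase",
    "StrainField",
    "PSGStrainSummary",
    "ElasticModel",
    "RegionScaledSolver",
    "direction_from_angles",
    "element_moduli",
    "assemble_and_solve",
    "psg_summary",
    "convergence_study",
]

#: Threshold below which the reduced system is solved by direct sparse LU.
_DIRECT_DOF_LIMIT = 6000


@dataclass(frozen=True)
class LoadCase:
    """Total load magnitude and direction angles for the indenter load."""

    total_force_n: float = 7500.0
    angle_to_frontal_deg: float = 60.0
    angle_to_transverse_deg: float = 30.0
    distribution: str = "uniform-nodal"

    def __post_init__(self) -> None:
        if self.total_force_n <= 0:
            raise InvalidInputError("total_force_n must be positive")
        if self.distribution not in ("uniform-nodal", "area-weighted"):
            raise InvalidInputError("distribution must be 'uniform-nodal' or 'area-weighted'")


@dataclass
class StrainField:
    """Displacements, element strains and principal strains of one solve."""

    displacements: np.ndarray  # (N, 3) mm
    element_strain: np.ndarray  # (M, 6) engineering components
    element_principal: np.ndarray  # (M, 3) eigenvalues, sorted descending
    surface_max_principal: np.ndarray  # (F,) owner-tet max principal per boundary facet


@dataclass(frozen=True)
class PSGStrainSummary:
    """Area-weighted mean maximum principal strain over the PSG strip."""

    mean_max_principal: float
    facet_count: int
    area_mm2: float


def direction_from_angles(
    angle_to_frontal_deg: float,
    angle_to_transverse_deg: float,
    frame: AnatomicalFrame,
    medial_sign: float = 1.0,
) -> np.ndarray:
    """Unit load direction from angles to the frontal and transverse planes.

    The component out of the frontal plane is sin(angle_to_frontal) in the
    dorsal sense, the component out of the transverse plane is
    sin(angle_to_transverse) in the proximal sense, and the remaining
    medio-lateral component closes the unit norm (``medial_sign`` picks its
    sense; it is zero for the default 60/30 case, which lies in the
    sagittal plane).
    """
    sf = np.sin(np.radians(angle_to_frontal_deg))
    st = np.sin(np.radians(angle_to_transverse_deg))
    rem = 1.0 - sf * sf - st * st
    if rem < -1e-12:
        raise InfeasibleAnglesError(
            f"sin^2({angle_to_frontal_deg}) + sin^2({angle_to_transverse_deg}) > 1"
        )
    # angle pairs on the feasibility boundary (e.g. 60/30) must give an
    # exactly in-plane direction despite rounding in the sines
    ml = np.sqrt(rem) if rem > 1e-12 else 0.0
    d = sf * frame.frontal_normal + st * frame.long_axis + medial_sign * ml * frame.sagittal_normal
    return d / np.linalg.norm(d)


def element_moduli(
    mesh: TetrahedralMesh,
    law=DEFAULT_LAW,
    factors: RegionFactors = RegionFactors(0.0, 0.0),
) -> np.ndarray:
    """Per-element Young's modulus (MPa) from element ash density and region."""
    rho = np.maximum(mesh.element_rho_ash, law.density_floor_g_cm3)
    base = law.coefficient_mpa * rho**law.exponent
    scale = np.ones_like(base)
    scale[mesh.element_region == int(Label.SCL)] = 1.0 - factors.a_scl
    scale[mesh.element_region == int(Label.LYS)] = 1.0 - factors.d_lys
    return base * scale


def _isotropic_d0(nu: float) -> np.ndarray:
    """Isotropic elasticity matrix for unit Young's modulus (engineering shear)."""
    lam = nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = 1.0 / (2.0 * (1.0 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.arange(3), np.arange(3)] = lam + 2.0 * mu
    d[np.arange(3, 6), np.arange(3, 6)] = mu
    return d


class ElasticModel:
    """Precomputed element geometry for repeated assembly on one mesh."""

    def __init__(self, mesh: TetrahedralMesh, nu: float = 0.3):
        if not (0.0 <= nu < 0.5):
            raise InvalidInputError("Poisson's ratio must be in [0, 0.5)")
        self.mesh = mesh
        self.nu = nu
        p = mesh.nodes[mesh.tets]
        d = (p[:, 1:] - p[:, :1]).transpose(0, 2, 1)  # columns x1-x0, x2-x0, x3-x0
        self.volumes = np.linalg.det(d) / 6.0
        if np.any(self.volumes <= 0):
            raise InvalidInputError("mesh contains non-positively oriented tets")
        dinv = np.linalg.inv(d)
        grads = np.empty((mesh.n_tets, 4, 3))
        grads[:, 1:, :] = dinv  # rows of D^-1 are grad(N1..N3)
        grads[:, 0, :] = -dinv.sum(axis=1)
        b = np.zeros((mesh.n_tets, 6, 12))
        for a in range(4):
            gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
            c = 3 * a
            b[:, 0, c] = gx
            b[:, 1, c + 1] = gy
            b[:, 2, c + 2] = gz
            b[:, 3, c] = gy
            b[:, 3, c + 1] = gx
            b[:, 4, c + 1] = gz
            b[:, 4, c + 2] = gy
            b[:, 5, c] = gz
            b[:, 5, c + 2] = gx
        self.b_matrices = b
        self.d0 = _isotropic_d0(nu)
        dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(mesh.n_tets, 12)
        self._rows = np.repeat(dofs, 12, axis=1).ravel()
        self._cols = np.tile(dofs, (1, 12)).ravel()
        self.n_dofs = 3 * mesh.n_nodes

    def assemble(self, youngs: np.ndarray) -> sparse.csr_array:
        """Global stiffness for a per-element Young's modulus array (MPa)."""
        e = np.asarray(youngs, dtype=float)
        if e.shape != (self.mesh.n_tets,):
            raise InvalidInputError("youngs must be per-element")
        db = np.einsum("ij,ejk->eik", self.d0, self.b_matrices)
        ke = np.einsum("eji,ejk->eik", self.b_matrices, db)
        ke *= (e * self.volumes)[:, None, None]
        k = sparse.coo_array(
            (ke.ravel(), (self._rows, self._cols)), shape=(self.n_dofs, self.n_dofs)
        ).tocsr()
        return k

    def strains(self, u: np.ndarray, element_idx=None) -> np.ndarray:
        """Element engineering strains from a nodal displacement field."""
        idx = slice(None) if element_idx is None else element_idx
        ue = u.reshape(-1, 3)[self.mesh.tets[idx]].reshape(-1, 12)
        return np.einsum("eij,ej->ei", self.b_matrices[idx], ue)


def _principal(strain6: np.ndarray) -> np.ndarray:
    """Principal strains (descending) from engineering components."""
    m = strain6.shape[0]
    t = np.empty((m, 3, 3))
    t[:, 0, 0] = strain6[:, 0]
    t[:, 1, 1] = strain6[:, 1]
    t[:, 2, 2] = strain6[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = 0.5 * strain6[:, 3]
    t[:, 1, 2] = t[:, 2, 1] = 0.5 * strain6[:, 4]
    t[:, 0, 2] = t[:, 2, 0] = 0.5 * strain6[:, 5]
    return np.linalg.eigvalsh(t)[:, ::-1]


def nodal_load_vector(mesh: TetrahedralMesh, load_case: LoadCase, frame: AnatomicalFrame) -> np.ndarray:
    """Nodal force vector for the load case applied on LOAD_SURFACE.

    'uniform-nodal' distributes the total force equally over the patch
    nodes (the experiment's literal description); 'area-weighted' applies
    consistent nodal forces for a uniform traction over the patch facets.
    """
    if "LOAD_SURFACE" not in mesh.facet_sets:
        raise InvalidInputError("mesh has no LOAD_SURFACE set; call tag_boundary_sets first")
    direction = direction_from_angles(
        load_case.angle_to_frontal_deg, load_case.angle_to_transverse_deg, frame
    )
    f = np.zeros((mesh.n_nodes, 3))
    if load_case.distribution == "uniform-nodal":
        nodes = mesh.node_sets["LOAD_SURFACE"]
        f[nodes] = load_case.total_force_n * direction / nodes.size
    else:
        fidx = mesh.facet_sets["LOAD_SURFACE"]
        _, areas = mesh.facet_normals_areas()
        a = areas[fidx]
        per_facet = load_case.total_force_n * (a / a.sum())
        for facet, load in zip(mesh.surface_facets[fidx], per_facet):
            f[facet] += load * direction / 3.0
    return f.ravel()


def solve_reduced(
    k: sparse.csr_array,
    f: np.ndarray,
    fixed_dofs: np.ndarray,
    fixed_values: np.ndarray | None = None,
    rtol: float = 1e-10,
    x0: np.ndarray | None = None,
    method: str = "auto",
    preconditioner=None,
) -> np.ndarray:
    """Solve K u = f with Dirichlet conditions on fixed_dofs.

    ``fixed_values`` (default zero) prescribes the constrained DOFs.
    ``method``: 'auto' uses direct sparse LU below a size threshold and
    Jacobi-preconditioned conjugate gradients above it (deterministic;
    relative-residual tolerance ``rtol``, direct fallback if CG stalls);
    'direct' and 'cg' force one path.  ``preconditioner`` optionally
    replaces the Jacobi preconditioner (a LinearOperator or sparse matrix).
    """
    n = k.shape[0]
    fixed = np.zeros(n, dtype=bool)
    fixed[fixed_dofs] = True
    if not fixed.any():
        raise ConstraintDeficiencyError("no constrained DOFs; rigid-body modes remain")
    free = np.flatnonzero(~fixed)
    kff = k[free][:, free]
    diag = kff.diagonal()
    if np.any(diag <= 0):
        raise ConstraintDeficiencyError("non-positive diagonal in constrained stiffness")
    u = np.zeros(n)
    if fixed_values is not None:
        u[fixed_dofs] = fixed_values
        ff = f[free] - k[free] @ u
    else:
        ff = f[free]
    if method not in ("auto", "direct", "cg"):
        raise InvalidInputError("method must be 'auto', 'direct' or 'cg'")
    direct = method == "direct" or (method == "auto" and free.size <= _DIRECT_DOF_LIMIT)
    if direct:
        u[free] = spsolve(kff.tocsc(), ff)
        return u
    m_inv = sparse.diags_array(1.0 / diag) if preconditioner is None else preconditioner
    x0f = x0[free] if x0 is not None else None
    maxiter = 50 * int(np.sqrt(free.size)) + 5000
    sol, info = cg(kff, ff, x0=x0f, rtol=rtol, atol=0.0, maxiter=maxiter, M=m_inv)
    if info != 0:
        sol = spsolve(kff.tocsc(), ff)
    u[free] = sol
    return u


def assemble_and_solve(
    mesh: TetrahedralMesh,
    youngs: np.ndarray,
    frame: AnatomicalFrame,
    load_case: LoadCase = LoadCase(),
    nu: float = 0.3,
    rtol: float = 1e-10,
    model: ElasticModel | None = None,
) -> StrainField:
    """Assemble and solve the linear elastic problem; return the strain field."""
    if "PROXIMAL_FIXED" not in mesh.node_sets or mesh.node_sets["PROXIMAL_FIXED"].size == 0:
        raise InvalidInputError("PROXIMAL_FIXED node set is empty; cannot constrain the model")
    youngs = np.asarray(youngs, dtype=float)
    if np.any(youngs <= 0):
        raise InvalidInputError("all element moduli must be positive")
    model = model if model is not None else ElasticModel(mesh, nu)
    k = model.assemble(youngs)
    f = nodal_load_vector(mesh, load_case, frame)
    fixed = (3 * mesh.node_sets["PROXIMAL_FIXED"][:, None] + np.arange(3)).ravel()
    u = solve_reduced(k, f, fixed, rtol=rtol)
    strain = model.strains(u)
    principal = _principal(strain)
    return StrainField(
        displacements=u.reshape(-1, 3),
        element_strain=strain,
        element_principal=principal,
        surface_max_principal=principal[mesh.facet_owner, 0],
    )


def psg_summary(field: StrainField, mesh: TetrahedralMesh) -> PSGStrainSummary:
    """Area-weighted mean of the facet max principal strain over PSG_STRIP."""
    if "PSG_STRIP" not in mesh.facet_sets or mesh.facet_sets["PSG_STRIP"].size == 0:
        raise DegenerateGeometryError("PSG_STRIP facet set is empty")
    idx = mesh.facet_sets["PSG_STRIP"]
    _, areas = mesh.facet_normals_areas()
    a = areas[idx]
    smax = field.surface_max_principal[idx]
    return PSGStrainSummary(
        mean_max_principal=float(np.sum(a * smax) / np.sum(a)),
        facet_count=int(idx.size),
        area_mm2=float(a.sum()),
    )


class RegionScaledSolver:
    """Repeated forward solves on one mesh under varying region factors.

    The stiffness is linear in each region's modulus scale, so it is
    assembled once per region group (plain, sclerotic, lytic, each with the
    unmodified power-law modulus) and recombined per candidate as
    ``K = K_plain + (1-a) K_scl + (1-d) K_lys``.  Solves are warm-started
    from the previous solution, which makes exhaustive factor grids cheap.
    """

    def __init__(
        self,
        mesh: TetrahedralMesh,
        frame: AnatomicalFrame,
        law=DEFAULT_LAW,
        load_case: LoadCase = LoadCase(),
        nu: float = 0.3,
        rtol: float = 1e-10,
    ):
        if "PROXIMAL_FIXED" not in mesh.node_sets:
            raise InvalidInputError("mesh is missing boundary sets; call tag_boundary_sets first")
        self.mesh = mesh
        self.frame = frame
        self.law = law
        self.load_case = load_case
        self.rtol = rtol
        self.model = ElasticModel(mesh, nu)
        base = element_moduli(mesh, law, RegionFactors(0.0, 0.0))
        scl = mesh.element_region == int(Label.SCL)
        lys = mesh.element_region == int(Label.LYS)
        plain = ~(scl | lys)
        self.n_scl = int(scl.sum())
        self.n_lys = int(lys.sum())
        self.k_plain = self.model.assemble(np.where(plain, base, 0.0))
        self.k_scl = self.model.assemble(np.where(scl, base, 0.0)) if self.n_scl else None
        self.k_lys = self.model.assemble(np.where(lys, base, 0.0)) if self.n_lys else None
        self.fixed_dofs = (3 * mesh.node_sets["PROXIMAL_FIXED"][:, None] + np.arange(3)).ravel()
        self.f = nodal_load_vector(mesh, load_case, frame)
        idx = mesh.facet_sets["PSG_STRIP"]
        _, areas = mesh.facet_normals_areas()
        self._strip_areas = areas[idx]
        self._strip_owners = mesh.facet_owner[idx]
        self._warm: np.ndarray | None = None

    @property
    def has_sclerosis(self) -> bool:
        return self.n_scl > 0

    @property
    def has_lysis(self) -> bool:
        return self.n_lys > 0

    def stiffness(self, factors: RegionFactors) -> sparse.csr_array:
        k = self.k_plain.copy()
        if self.k_scl is not None:
            k = k + (1.0 - factors.a_scl) * self.k_scl
        if self.k_lys is not None:
            k = k + (1.0 - factors.d_lys) * self.k_lys
        return k

    def displacements(self, factors: RegionFactors) -> np.ndarray:
        k = self.stiffness(factors)
        u = solve_reduced(k, self.f, self.fixed_dofs, rtol=self.rtol, x0=self._warm)
        self._warm = u
        return u

    def psg_strain(self, factors: RegionFactors) -> float:
        """Area-weighted mean PSG max principal strain for given factors."""
        u = self.displacements(factors)
        strain = self.model.strains(u, element_idx=self._strip_owners)
        smax = _principal(strain)[:, 0]
        return float(np.sum(self._strip_areas * smax) / np.sum(self._strip_areas))

    def solve_field(self, factors: RegionFactors) -> StrainField:
        u = self.displacements(factors)
        strain = self.model.strains(u)
        principal = _principal(strain)
        return StrainField(
            displacements=u.reshape(-1, 3),
            element_strain=strain,
            element_principal=principal,
            surface_max_principal=principal[self.mesh.facet_owner, 0],
        )


def convergence_study(
    labels,
    image,
    frame: AnatomicalFrame,
    psg_plane: PsgStripSpec,
    load_patch_spec: LoadPatchSpec,
    edge_schedule,
    curve=DEFAULT_CURVE,
    law=DEFAULT_LAW,
    load_case: LoadCase = LoadCase(),
    factors: RegionFactors = RegionFactors(0.0, 0.0),
    strip_width_mm: float = 3.0,
    nu: float = 0.3,
) -> pd.DataFrame:
    """PSG strain summary across a refining (fine, coarse) edge schedule.

    Returns one row per level with element count, PSG mean strain and the
    relative change versus the finest level.
    """
    schedule = [(float(f), float(c)) for f, c in edge_schedule]
    if len(schedule) < 2:
        raise InvalidInputError("edge_schedule needs at least two levels")
    for (f0, c0), (f1, c1) in zip(schedule, schedule[1:]):
        if f1 > f0 + 1e-12 or c1 > c0 + 1e-12:
            raise InvalidInputError("edge_schedule must be monotonically refining")
    rows = []
    for fine, coarse in schedule:
        mesh = voxels_to_tets(
            labels, image, curve=curve, law=law, fine_edge_mm=fine, coarse_edge_mm=coarse
        )
        tag_boundary_sets(mesh, frame, psg_plane, load_patch_spec, strip_width_mm=strip_width_mm)
        youngs = element_moduli(mesh, law, factors)
        field = assemble_and_solve(mesh, youngs, frame, load_case, nu=nu)
        summary = psg_summary(field, mesh)
        rows.append(
            {
                "fine_edge_mm": fine,
                "coarse_edge_mm": coarse,
                "n_elements": mesh.n_tets,
                "psg_mean_max_principal": summary.mean_max_principal,
            }
        )
    df = pd.DataFrame(rows)
    finest = df["psg_mean_max_principal"].iloc[-1]
    df["rel_change_vs_finest"] = np.abs(df["psg_mean_max_principal"] - finest) / abs(finest)
    return df
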