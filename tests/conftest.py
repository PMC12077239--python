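"""Shared fixtures.

Heavy objects (default-size phantoms, their meshes and solvers) are
session-scoped so the forward model is built once and reused by the
tuning, validation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import mc3fe as m

#: Small phantom for fast unit tests (a few thousand elements).
SMALL_SPEC = m.CondylePhantomSpec(
    shape=(26, 26, 46),
    spacing_mm=0.5,
    shaft_radius_mm=4.0,
    shaft_length_mm=14.0,
    condyle_radius_mm=5.5,
    cortical_thickness_mm=1.0,
    sclerotic_target_fraction=0.185,
)

SMALL_LYTIC_SPEC = m.CondylePhantomSpec(
    shape=(26, 26, 46),
    spacing_mm=0.5,
    shaft_radius_mm=4.0,
    shaft_length_mm=14.0,
    condyle_radius_mm=5.5,
    cortical_thickness_mm=1.0,
    sclerotic_target_fraction=0.185,
    lysis_radius_mm=1.1,
)

#: Default study-scale phantoms (the generator's two specimen classes).
DEFAULT_CTRL_SPEC = m.CTRL_SPEC
DEFAULT_LYTIC_SPEC = m.PSG_SBI_SPEC


@pytest.fixture(scope="session")
def small_phantom() -> m.CondylePhantom:
    return m.make_condyle_phantom(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_lytic_phantom() -> m.CondylePhantom:
    return m.make_condyle_phantom(SMALL_LYTIC_SPEC)


@pytest.fixture(scope="session")
def small_mesh(small_phantom):
    mesh = m.voxels_to_tets(small_phantom.labels, small_phantom.image)
    m.tag_boundary_sets(
        mesh,
        small_phantom.frame,
        small_phantom.psg_strip_spec,
        small_phantom.load_patch_spec,
    )
    return mesh


@pytest.fixture(scope="session")
def ctrl_case() -> m.RecoveryCase:
    """Default-size control phantom with an on-grid true adaptive factor."""
    return m.make_recovery_case(DEFAULT_CTRL_SPEC, true_a_scl=0.25, true_d_lys=0.0, specimen_id="CTRL-A")


@pytest.fixture(scope="session")
def lytic_case() -> m.RecoveryCase:
    """Default-size lytic phantom; target generated with the tuned a_scl
    (from the default law at the phantom's v_scl) and an on-grid d_lys."""
    phantom = m.make_condyle_phantom(DEFAULT_LYTIC_SPEC)
    a = float(m.ascl_from_vscl(phantom.v_scl))
    return m.make_recovery_case(
        DEFAULT_LYTIC_SPEC, true_a_scl=a, true_d_lys=0.80, specimen_id="PSG-SBI-A"
    )


def bar_labels_image(
    nx=8, ny=8, nz=24, spacing=0.5, hu=1200.0
) -> tuple[m.LabelVolume, m.VoxelImage]:
    """A full cuboid of trabecular bone: the FE verification workhorse."""
    shape = (nx, ny, nz)
    labels = np.full(shape, int(m.Label.TRABECULAR), dtype=np.uint8)
    values = np.full(shape, hu, dtype=float)
    return (
        m.LabelVolume(labels=labels, spacing=(spacing,) * 3),
        m.VoxelImage(values=values, spacing=(spacing,) * 3),
    )


def bar_frame() -> m.AnatomicalFrame:
    """Frame with the long axis along -z: proximal (fixed) end at z=0."""
    return m.AnatomicalFrame(
        long_axis=np.array([0.0, 0.0, -1.0]),
        sagittal_normal=np.array([1.0, 0.0, 0.0]),
        frontal_normal=np.array([0.0, 1.0, 0.0]),
        transverse_normal=np.array([0.0, 0.0, -1.0]),
        origin=np.zeros(3),
    )


@pytest.fixture()
def bar_mesh():
    """Meshed bar with bottom (z=0) proximal-fixed and top facets loaded."""
    labels, image = bar_labels_image()
    mesh = m.voxels_to_tets(labels, image, fine_edge_mm=0.5, coarse_edge_mm=1.0)
    frame = bar_frame()
    z_top = mesh.nodes[:, 2].max()
    patch = m.LoadPatchSpec(
        center_mm=(2.0, 2.0, z_top),
        radius_mm=100.0,
        direction=(0.0, 0.0, 1.0),
        min_normal_dot=0.99,
    )
    strip = m.PsgStripSpec(point_mm=(2.0, 2.0, z_top), normal=(1.0, 0.0, 0.0))
    m.tag_boundary_sets(mesh, frame, strip, patch, strip_width_mm=100.0)
    return mesh, frame
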