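"""Mask conditioning, anatomical frame, distal isolation and region labelling."""

import numpy as np
import pytest

import mc3fe as m


def _cylinder_mask(shape, radius_vox, axis=2):
    idx = np.indices(shape).astype(float)
    c = [(s - 1) / 2 for s in shape]
    others = [a for a in range(3) if a != axis]
    r = np.hypot(idx[others[0]] - c[others[0]], idx[others[1]] - c[others[1]])
    return r <= radius_vox


class TestErodeSurface:
    def test_cube_erodes_to_inner_cube(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[1:6, 1:6, 1:6] = True  # 5x5x5 cube
        out = m.erode_surface(mask)
        assert out.sum() == 27  # 3x3x3

    def test_single_voxel_erodes_to_empty(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        with pytest.raises(m.DegenerateGeometryError):
            m.erode_surface(mask)

    def test_result_strictly_contained_in_input(self):
        rng = np.random.default_rng(7)
        blob = rng.random((12, 12, 12)) > 0.25
        blob[0] = blob[-1] = False  # keep a border
        try:
            out = m.erode_surface(blob)
        except m.DegenerateGeometryError:
            return
        assert np.all(~out | blob)  # out subset of input
        assert out.sum() < blob.sum()

    def test_two_single_erosions_equal_one_double(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[1:8, 1:8, 1:8] = True
        once_twice = m.erode_surface(m.erode_surface(mask))
        double = m.erode_surface(mask, iterations=2)
        assert np.array_equal(once_twice, double)


class TestAnatomicalFrame:
    def test_axis_of_grid_aligned_cylinder(self):
        mask = _cylinder_mask((21, 21, 61), 6.0)
        frame = m.fit_anatomical_frame(mask, (0.5, 0.5, 0.5), dorsal_hint=(0, 1, 0), proximal_hint=(0, 0, 1))
        assert np.allclose(frame.long_axis, [0, 0, 1], atol=1e-6)

    def test_axis_of_rotated_cylinder(self):
        # rasterize a cylinder rotated 30 degrees about x
        theta = np.radians(30.0)
        axis = np.array([0.0, -np.sin(theta), np.cos(theta)])
        shape = (31, 61, 61)
        idx = np.indices(shape).astype(float)
        c = np.array([(s - 1) / 2 for s in shape])
        p = np.stack([idx[0] - c[0], idx[1] - c[1], idx[2] - c[2]], axis=-1)
        along = p @ axis
        radial = np.linalg.norm(p - along[..., None] * axis, axis=-1)
        mask = (radial <= 5.0) & (np.abs(along) <= 25.0)
        frame = m.fit_anatomical_frame(mask, (1, 1, 1), dorsal_hint=(1, 0, 0), proximal_hint=axis)
        angle = np.degrees(np.arccos(np.clip(np.abs(frame.long_axis @ axis), -1, 1)))
        assert angle < 0.5

    def test_sphere_is_ambiguous(self):
        idx = np.indices((25, 25, 25)).astype(float)
        r = np.linalg.norm(idx - 12.0, axis=0)
        with pytest.raises(m.AmbiguousAxisError):
            m.fit_anatomical_frame(r <= 10.0, (1, 1, 1), dorsal_hint=(0, 1, 0))

    def test_frame_is_orthonormal(self):
        mask = _cylinder_mask((21, 21, 61), 6.0)
        f = m.fit_anatomical_frame(mask, (0.5, 0.5, 0.5), dorsal_hint=(0, 1, 0.3), proximal_hint=(0, 0, 1))
        for a in (f.long_axis, f.sagittal_normal, f.frontal_normal):
            assert np.linalg.norm(a) == pytest.approx(1.0, abs=1e-9)
        assert abs(f.sagittal_normal @ f.frontal_normal) < 1e-9
        assert abs(f.frontal_normal @ f.long_axis) < 1e-9


class TestIsolateDistal:
    def _frame(self):
        return m.AnatomicalFrame(
            long_axis=np.array([0.0, 0.0, -1.0]),  # distal at high z
            sagittal_normal=np.array([1.0, 0.0, 0.0]),
            frontal_normal=np.array([0.0, 1.0, 0.0]),
            transverse_normal=np.array([0.0, 0.0, -1.0]),
            origin=np.zeros(3),
        )

    def test_retains_the_distal_63_5_mm(self):
        mask = _cylinder_mask((15, 15, 100), 5.0)  # 100 mm at 1 mm spacing
        out = m.isolate_distal(mask, self._frame(), (1, 1, 1), length_mm=63.5)
        zs = np.flatnonzero(out.any(axis=(0, 1)))
        extent = zs.max() - zs.min()
        assert abs(extent - 63.5) <= 1.0  # one voxel
        assert zs.max() == 99  # distal-most slice kept

    def test_full_length_is_identity(self):
        mask = _cylinder_mask((15, 15, 50), 5.0)
        out = m.isolate_distal(mask, self._frame(), (1, 1, 1), length_mm=49.0)
        assert np.array_equal(out, mask)

    def test_short_mask_rejected(self):
        mask = _cylinder_mask((15, 15, 50), 5.0)  # 49 mm extent
        with pytest.raises(m.InvalidInputError):
            m.isolate_distal(mask, self._frame(), (1, 1, 1), length_mm=63.5)


def _shell_phantom(pocket_center=None, pocket_r=2.2, shell_hu=1800.0, pocket_hu=600.0):
    """16^3 all-bone volume, trabecular interior at shell_hu, optional pocket."""
    shape = (16, 16, 16)
    values = np.full(shape, shell_hu)
    bone = np.ones(shape, dtype=bool)
    trab = np.zeros(shape, dtype=bool)
    trab[2:14, 2:14, 2:14] = True
    psg = np.zeros(shape, dtype=bool)
    psg[4:12, 4:12, 4:12] = True
    if pocket_center is not None:
        idx = np.indices(shape).astype(float)
        r = np.sqrt(sum((idx[a] - pocket_center[a]) ** 2 for a in range(3)))
        values[r <= pocket_r] = pocket_hu
    img = m.VoxelImage(values=values, spacing=(1.0, 1.0, 1.0))
    return img, bone, trab, psg


class TestLabelRegions:
    def test_all_below_threshold_gives_no_scl_no_lys(self):
        img, bone, trab, psg = _shell_phantom(shell_hu=1200.0)
        lab = m.label_regions(img, bone, trab, psg)
        assert not lab.mask(m.Label.SCL).any()
        assert not lab.mask(m.Label.LYS).any()

    def test_isolated_pocket_in_psg_is_lysis(self):
        img, bone, trab, psg = _shell_phantom(pocket_center=(8, 8, 8))
        lab = m.label_regions(img, bone, trab, psg)
        lys = lab.mask(m.Label.LYS)
        # voxel count matches the rasterized sphere (independent count)
        idx = np.indices(img.values.shape).astype(float)
        r = np.sqrt(sum((idx[a] - 8) ** 2 for a in range(3)))
        assert lys.sum() == (r <= 2.2).sum()
        from scipy import ndimage

        _, n = ndimage.label(lys, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_pocket_outside_psg_region_is_not_lysis(self):
        img, bone, trab, psg = _shell_phantom(pocket_center=(8, 8, 8))
        psg_far = np.zeros_like(psg)
        psg_far[12:, 12:, 12:] = True
        lab = m.label_regions(img, bone, trab, psg_far)
        assert not lab.mask(m.Label.LYS).any()

    def test_small_pocket_below_min_size_ignored(self):
        img, bone, trab, psg = _shell_phantom(pocket_center=(8, 8, 8), pocket_r=1.0)
        lab = m.label_regions(img, bone, trab, psg, min_lysis_voxels=8)
        assert not lab.mask(m.Label.LYS).any()

    def test_scl_subset_of_trabecular(self):
        img, bone, trab, psg = _shell_phantom(pocket_center=(8, 8, 8))
        lab = m.label_regions(img, bone, trab, psg)
        assert np.all(~lab.mask(m.Label.SCL) | trab)
        assert np.all(~lab.mask(m.Label.LYS) | psg)

    def test_deterministic_and_idempotent(self):
        img, bone, trab, psg = _shell_phantom(pocket_center=(8, 8, 8))
        a = m.label_regions(img, bone, trab, psg)
        b = m.label_regions(img, bone, trab, psg)
        assert np.array_equal(a.labels, b.labels)

    def test_empty_bone_rejected(self):
        img, bone, trab, psg = _shell_phantom()
        with pytest.raises(m.InvalidInputError):
            m.label_regions(img, np.zeros_like(bone), np.zeros_like(trab), psg)


class TestScleroticVolumeFraction:
    def _labels(self, scl_mask, shape=(8, 8, 8)):
        lab = np.full(shape, int(m.Label.TRABECULAR), dtype=np.uint8)
        lab[scl_mask] = int(m.Label.SCL)
        return m.LabelVolume(labels=lab, spacing=(1.0, 1.0, 1.0))

    def test_scl_equals_condyle_gives_one(self):
        scl = np.ones((8, 8, 8), dtype=bool)
        assert m.sclerotic_volume_fraction(self._labels(scl), scl) == 1.0

    def test_no_scl_gives_zero(self):
        condyle = np.ones((8, 8, 8), dtype=bool)
        assert m.sclerotic_volume_fraction(self._labels(np.zeros((8, 8, 8), bool)), condyle) == 0.0

    def test_fraction_in_unit_interval_and_monotone(self):
        condyle = np.ones((8, 8, 8), dtype=bool)
        scl_small = np.zeros((8, 8, 8), bool)
        scl_small[:2] = True
        scl_big = np.zeros((8, 8, 8), bool)
        scl_big[:4] = True
        f_small = m.sclerotic_volume_fraction(self._labels(scl_small), condyle)
        f_big = m.sclerotic_volume_fraction(self._labels(scl_big), condyle)
        assert 0.0 <= f_small < f_big <= 1.0

    def test_empty_condyle_rejected(self):
        with pytest.raises(m.InvalidInputError):
            m.sclerotic_volume_fraction(
                self._labels(np.zeros((8, 8, 8), bool)), np.zeros((8, 8, 8), bool)
            )
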