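"""Shell/ring construction, HU histograms, follow-up selection, Dice, COM alignment."""

import numpy as np
import pytest

from peridose.cohort import BinaryMask, DoseGrid, ImageVolume, ValidationError
from peridose.geometry import (
    RegionSpec,
    com_align,
    dice,
    hu_histogram,
    pericardial_shell,
    reference_ring,
    select_followup,
)
from tests.conftest import digital_sphere


class TestPericardialShell:
    def test_sphere_shell_matches_analytic_volume(self):
        # 4 mm shell of a 20 mm sphere; fine 0.5 mm grid keeps the
        # voxelization error of the distance-transform convention small
        heart = digital_sphere(20.0, spacing=0.5)
        shell = pericardial_shell(heart, 4.0)
        analytic = 4.0 / 3.0 * np.pi * (20.0**3 - 16.0**3)
        measured = shell.n_voxels * shell.voxel_volume_mm3
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_zero_thickness_gives_empty_shell(self, sphere_20mm):
        assert pericardial_shell(sphere_20mm, 0.0).n_voxels == 0

    def test_thickness_beyond_radius_gives_whole_mask(self, sphere_20mm):
        shell = pericardial_shell(sphere_20mm, 25.0)
        np.testing.assert_array_equal(shell.voxels, sphere_20mm.voxels)

    def test_shell_is_subset_of_heart(self, sphere_20mm):
        shell = pericardial_shell(sphere_20mm, 4.0)
        assert not np.any(shell.voxels & ~sphere_20mm.voxels)

    @pytest.mark.parametrize("t1,t2", [(2.0, 4.0), (4.0, 8.0), (0.5, 20.0)])
    def test_monotone_in_thickness(self, sphere_20mm, t1, t2):
        s1 = pericardial_shell(sphere_20mm, t1)
        s2 = pericardial_shell(sphere_20mm, t2)
        assert not np.any(s1.voxels & ~s2.voxels)

    def test_anisotropic_spacing_measured_in_mm(self):
        # slab at 3 mm z-spacing: a 4 mm shell includes the z-face layer
        # (3 mm deep) but not the second layer (6 mm deep)
        mask = np.zeros((20, 20, 9), dtype=bool)
        mask[2:18, 2:18, 2:7] = True
        m = BinaryMask(mask, (1.0, 1.0, 3.0))
        shell = pericardial_shell(m, 4.0)
        assert shell.voxels[10, 10, 2] and shell.voxels[10, 10, 6]
        assert not shell.voxels[10, 10, 4]
        assert shell.voxels[3, 10, 4]  # 2 mm from the in-plane boundary

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            pericardial_shell(BinaryMask(np.zeros((4, 4, 4), bool)), 4.0)


class TestReferenceRing:
    def test_zero_dose_gives_full_annulus(self, sphere_20mm, uniform_dose):
        ring = reference_ring(sphere_20mm, uniform_dose(sphere_20mm, 0.0))
        dist_ok = ~sphere_20mm.voxels
        assert ring.n_voxels > 0
        assert not np.any(ring.voxels & sphere_20mm.voxels)
        # every non-heart voxel of this small grid is within 50 mm -> ring = complement
        np.testing.assert_array_equal(ring.voxels, dist_ok)

    def test_high_uniform_dose_empties_ring(self, sphere_20mm, uniform_dose):
        ring = reference_ring(sphere_20mm, uniform_dose(sphere_20mm, 10.0))
        assert ring.n_voxels == 0

    def test_half_space_dose_restricts_ring_exactly(self, sphere_20mm):
        dose_arr = np.zeros(sphere_20mm.shape)
        half = sphere_20mm.shape[0] // 2
        dose_arr[half:] = 2.0
        dose = DoseGrid(dose_arr, 30, sphere_20mm.spacing)
        ring = reference_ring(sphere_20mm, dose)
        expected = reference_ring(sphere_20mm, DoseGrid(np.zeros_like(dose_arr), 30,
                                                        sphere_20mm.spacing))
        np.testing.assert_array_equal(ring.voxels, expected.voxels & (dose_arr <= 1.0))

    def test_ring_width_respected(self):
        heart = digital_sphere(10.0, spacing=1.0, margin_mm=70.0)
        ring = reference_ring(heart, DoseGrid(np.zeros(heart.shape), 30, heart.spacing),
                              RegionSpec(ring_width_mm=20.0))
        c = (heart.shape[0] - 1) // 2
        assert ring.voxels[c, c, c + 25]  # 15 mm outside surface
        assert not ring.voxels[c, c, c + 45]  # 35 mm outside surface


class TestHuHistogram:
    def test_degenerate_single_bin(self):
        vol = ImageVolume(np.zeros((4, 1, 1)))
        region = BinaryMask(np.ones((4, 1, 1), bool))
        h = hu_histogram(vol, region, normalize=True)
        assert h[1000] == pytest.approx(1.0)  # HU 0 -> center bin
        assert h.sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_voxel_symmetry(self):
        vol = ImageVolume(np.array([-5.0, 12.0]).reshape(2, 1, 1))
        region = BinaryMask(np.ones((2, 1, 1), bool))
        h = hu_histogram(vol, region, normalize=True)
        assert h[-5 + 1000] == pytest.approx(0.5)
        assert h[12 + 1000] == pytest.approx(0.5)

    def test_matches_brute_force_tally(self, random_volume):
        vol = random_volume(shape=(10, 10, 10), seed=11)
        rng = np.random.default_rng(1)
        region = BinaryMask(rng.random((10, 10, 10)) < 0.5)
        h = hu_histogram(vol, region, normalize=False)
        # naive loop oracle
        expected = np.zeros(2001)
        for hu in vol.voxels[region.voxels].ravel():
            expected[int(round(hu)) + 1000] += vol.voxel_volume_mm3
        np.testing.assert_allclose(h, expected)

    def test_empty_region_rejected(self, random_volume):
        with pytest.raises(ValidationError):
            hu_histogram(random_volume(), BinaryMask(np.zeros((8, 8, 8), bool)))


class TestSelectFollowup:
    def _ring(self, shape=(20, 20, 20)):
        return BinaryMask(np.ones(shape, bool))

    def test_single_candidate(self, random_volume):
        base = random_volume(seed=0, shape=(20, 20, 20))
        assert select_followup(base, [base], self._ring()) == 0

    def test_exact_copy_beats_offset(self, random_volume):
        base = random_volume(seed=0, shape=(20, 20, 20), lo=-500, hi=500)
        offset = ImageVolume(base.voxels + 50.0, base.spacing)
        assert select_followup(base, [offset, base], self._ring()) == 1

    def test_lowest_kernel_noise_selected(self, random_volume):
        # matched-kernel candidate (sigma 5 vs 20 vs 40 HU) wins in >= 95% of
        # seeded replicates; a small replicate count here, the full study
        # condition is exercised in the acceptance suite
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = ImageVolume(rng.normal(0, 30, size=(16, 16, 16)))
            cands = [ImageVolume(base.voxels + rng.normal(0, s, size=base.shape))
                     for s in (40.0, 5.0, 20.0)]
            wins += select_followup(base, cands, self._ring((16, 16, 16))) == 1
        assert wins >= 19

    def test_order_invariance_up_to_tiebreak(self, random_volume):
        base = random_volume(seed=3, shape=(12, 12, 12))
        rng = np.random.default_rng(7)
        cands = [ImageVolume(base.voxels + rng.normal(0, s, base.shape))
                 for s in (30, 5, 15)]
        ring = self._ring((12, 12, 12))
        best = cands[select_followup(base, cands, ring)]
        perm = [cands[2], cands[0], cands[1]]
        assert perm[select_followup(base, perm, ring)] is best

    def test_empty_candidates_rejected(self, random_volume):
        with pytest.raises(ValidationError):
            select_followup(random_volume(), [], self._ring((8, 8, 8)))


class TestDice:
    def test_identical_masks(self, sphere_20mm):
        assert dice(sphere_20mm, sphere_20mm) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[:3], b[3:] = True, True
        assert dice(BinaryMask(a), BinaryMask(b)) == 0.0

    def test_half_cube_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2, :2, :2] = True  # 8 voxels
        b = np.zeros((4, 4, 4), bool)
        b[:2, :2, :1] = True  # half of it, 4 voxels
        assert dice(BinaryMask(a), BinaryMask(b)) == pytest.approx(2 / 3)

    def test_symmetry(self, sphere_20mm):
        rng = np.random.default_rng(0)
        b = BinaryMask(rng.random(sphere_20mm.shape) < 0.3, sphere_20mm.spacing)
        assert dice(sphere_20mm, b) == dice(b, sphere_20mm)

    def test_both_empty_rejected(self):
        e = BinaryMask(np.zeros((4, 4, 4), bool))
        with pytest.raises(ValidationError):
            dice(e, e)


class TestComAlign:
    def _mask_at(self, offset):
        m = np.zeros((24, 24, 24), bool)
        m[6 + offset[0]:12 + offset[0], 6 + offset[1]:12 + offset[1],
          6 + offset[2]:12 + offset[2]] = True
        return BinaryMask(m)

    def test_identity_when_aligned(self, random_volume):
        vol = random_volume(shape=(24, 24, 24), seed=1)
        m = self._mask_at((0, 0, 0))
        out = com_align(vol, m, m)
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_recovers_constructed_shift(self, random_volume):
        vol = random_volume(shape=(24, 24, 24), seed=2)
        moving, fixed = self._mask_at((3, 0, 0)), self._mask_at((0, 0, 0))
        out = com_align(vol, moving, fixed)
        np.testing.assert_array_equal(out.voxels[:21], vol.voxels[3:])

    def test_padding_is_air(self, random_volume):
        vol = random_volume(shape=(24, 24, 24), seed=2)
        out = com_align(vol, self._mask_at((3, 0, 0)), self._mask_at((0, 0, 0)))
        assert np.all(out.voxels[21:] == -1000.0)
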