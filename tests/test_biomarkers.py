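"""Tissue labeling, EQD2, and the three biomarker equations against
independent brute-force voxel-loop oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peridose.biomarkers import (
    TISSUE_SCHEME,
    DoseBinning,
    aggregate_delta_huv,
    delta_huv,
    delta_v,
    eqd2,
    eqd2_grid,
    label_tissue,
    mean_region_dose,
    smooth_curve,
    vmc,
)
from peridose.cohort import BinaryMask, ValidationError
from peridose.synthetic import generate_toy_patient, random_toy_patient


def brute_force_biomarkers(base, fu, doses, binning=DoseBinning(), label_timepoint="followup"):
    """Naive per-voxel loop oracle for all three biomarkers (unit voxel volume)."""
    base = [int(round(b)) for b in base]
    fu = [int(round(f)) for f in fu]
    n = len(base)
    curve = {}
    for b, f in zip(base, fu):
        curve[b - f] = curve.get(b - f, 0.0) + 100.0 / n
    vmc_tab = {}
    denom = sum(b + 1000.0 for b in base)
    for b, f, d in zip(base, fu, doses):
        label = label_tissue(f if label_timepoint == "followup" else b)
        for k, (lo, hi) in enumerate(zip(binning.edges[:-1], binning.edges[1:])):
            if lo <= d < hi:
                key = (label, binning.labels[k])
                vmc_tab[key] = vmc_tab.get(key, 0.0) + 100.0 * (b - f) / denom
    dv = {}
    for b, f in zip(base, fu):
        dv[label_tissue(b)] = dv.get(label_tissue(b), 0.0) + 100.0 / n
        dv[label_tissue(f)] = dv.get(label_tissue(f), 0.0) - 100.0 / n
    return curve, vmc_tab, dv


class TestTissueLabels:
    @pytest.mark.parametrize(
        "hu,label",
        [
            (130, "Calcification"), (1000, "Calcification"),
            (129, "Fibrous"), (65, "Fibrous"),
            (64, "Heme"), (13, "Heme"),
            (12, "Fluid"), (-5, "Fluid"), (0, "Fluid"),
            (-6, "Fat"), (-1000, "Fat"),
        ],
    )
    def test_range_boundaries(self, hu, label):
        assert label_tissue(hu) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            label_tissue(1001)

    def test_every_integer_hu_has_exactly_one_label(self):
        hu = np.arange(-1000, 1001)
        codes = TISSUE_SCHEME.label_array(hu)
        assert set(np.unique(codes)) <= set(range(5))
        # scalar and vectorized paths agree
        for v in (-6, -5, 12, 13, 64, 65, 129, 130):
            assert TISSUE_SCHEME.labels[codes[v + 1000]] == label_tissue(v)


class TestEqd2:
    def test_two_gy_per_fraction_is_identity(self):
        assert eqd2(60.0, 2.0, 3.0) == pytest.approx(60.0)

    def test_hypofractionated_example(self):
        assert eqd2(45.0, 1.5, 3.0) == pytest.approx(40.5)

    def test_zero_dose(self):
        assert eqd2(0.0, 0.0) == 0.0

    def test_linear_in_total_dose(self):
        assert eqd2(30.0, 10.0, 3.0) == pytest.approx(2 * eqd2(15.0, 10.0, 3.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            eqd2(-1.0, 2.0)

    def test_grid_conversion_uses_per_fraction_map(self):
        study = random_toy_patient(50, seed=0)
        # toy dose grids carry a 2 Gy/fx map, so EQD2 equals physical dose
        np.testing.assert_allclose(eqd2_grid(study.dose), study.dose.physical_dose)


class TestMeanRegionDose:
    def test_uniform_field(self, sphere_20mm, uniform_dose):
        d = uniform_dose(sphere_20mm, 5.0)
        assert mean_region_dose(d.physical_dose, sphere_20mm) == 5.0

    def test_random_field_matches_loop(self, sphere_20mm):
        rng = np.random.default_rng(3)
        field = rng.uniform(0, 30, sphere_20mm.shape)
        expected = sum(field[i] for i in zip(*np.where(sphere_20mm.voxels)))
        expected /= sphere_20mm.n_voxels
        assert mean_region_dose(field, sphere_20mm) == pytest.approx(expected)

    def test_empty_region_rejected(self):
        with pytest.raises(ValidationError):
            mean_region_dose(np.zeros((4, 4, 4)), BinaryMask(np.zeros((4, 4, 4), bool)))


class TestDeltaHuv:
    def test_identity_pair_concentrates_at_zero(self):
        s = random_toy_patient(100, seed=1)
        curve = delta_huv(s.baseline, s.baseline, s.heart_mask)
        assert curve.at(0) == pytest.approx(100.0)

    def test_two_voxel_symmetry(self):
        s = generate_toy_patient([(5, 0), (0, 0)])
        curve = delta_huv(s.baseline, s.followup_candidates[0], s.heart_mask)
        assert curve.at(5) == pytest.approx(50.0)
        assert curve.at(0) == pytest.approx(50.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_and_sums_to_100(self, seed):
        s = random_toy_patient(500, seed=seed)
        curve = delta_huv(s.baseline, s.followup_candidates[0], s.heart_mask)
        oracle, _, _ = brute_force_biomarkers(
            s.baseline.voxels.ravel(), s.followup_candidates[0].voxels.ravel(),
            s.dose.physical_dose.ravel())
        for dhu, pct in oracle.items():
            assert curve.at(dhu) == pytest.approx(pct, abs=1e-9)
        assert curve.values.sum() == pytest.approx(100.0, abs=1e-6)

    def test_mean_shift_is_volume_weighted_mean(self):
        s = generate_toy_patient([(10, 0), (0, 0), (30, 10), (0, 0)])
        curve = delta_huv(s.baseline, s.followup_candidates[0], s.heart_mask)
        assert curve.mean_shift() == pytest.approx((10 + 0 + 20 + 0) / 4)


class TestAggregateDeltaHuv:
    def test_one_patient_per_bin_passthrough(self):
        s1 = generate_toy_patient([(10, 0)])
        s2 = generate_toy_patient([(0, 10)])
        c1 = delta_huv(s1.baseline, s1.followup_candidates[0], s1.heart_mask)
        c2 = delta_huv(s2.baseline, s2.followup_candidates[0], s2.heart_mask)
        agg = aggregate_delta_huv([c1, c2], [0.1, 30.0])
        assert set(agg) == {"[0,0.2)Gy", ">=20Gy"}
        np.testing.assert_allclose(agg["[0,0.2)Gy"].values, c1.values)

    def test_mean_of_identical_curves_is_idempotent(self):
        s = random_toy_patient(50, seed=4)
        c = delta_huv(s.baseline, s.followup_candidates[0], s.heart_mask)
        agg = aggregate_delta_huv([c, c], [1.0, 1.0])
        np.testing.assert_allclose(agg["[0.2,2)Gy"].values, c.values)

    def test_three_curves_match_loop_mean(self):
        curves = [delta_huv(s.baseline, s.followup_candidates[0], s.heart_mask)
                  for s in (random_toy_patient(60, seed=i) for i in range(3))]
        agg = aggregate_delta_huv(curves, [3.0, 3.5, 4.0])
        expected = np.mean([c.values for c in curves], axis=0)
        np.testing.assert_allclose(agg["[2,5)Gy"].values, expected)

    def test_empty_bins_absent_not_zero(self):
        s = random_toy_patient(10, seed=5)
        c = delta_huv(s.baseline, s.followup_candidates[0], s.heart_mask)
        agg = aggregate_delta_huv([c], [50.0])
        assert list(agg) == [">=20Gy"]


class TestVmc:
    def test_single_voxel_worked_example(self):
        # one voxel, HU 0 -> 10 at 5 Gy: mass change -1.0% in the
        # (Fluid-at-followup, [5,12.5) Gy) cell; negative = mass increase
        s = generate_toy_patient([(0, 10)], [5.0])
        table = vmc(s.baseline, s.followup_candidates[0], s.heart_mask,
                    eqd2_grid(s.dose))
        assert table.loc["Fluid", "[5,12.5)Gy"] == pytest.approx(-1.0)
        assert table.values.sum() == pytest.approx(-1.0)

    def test_identity_pair_all_zero(self):
        s = random_toy_patient(100, seed=6)
        table = vmc(s.baseline, s.baseline, s.heart_mask, eqd2_grid(s.dose))
        assert np.all(table.values == 0)

    @pytest.mark.parametrize("label_timepoint", ["followup", "baseline"])
    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_triple_loop_oracle(self, seed, label_timepoint):
        s = random_toy_patient(500, seed=seed)
        table = vmc(s.baseline, s.followup_candidates[0], s.heart_mask,
                    eqd2_grid(s.dose), label_timepoint=label_timepoint)
        _, oracle, _ = brute_force_biomarkers(
            s.baseline.voxels.ravel(), s.followup_candidates[0].voxels.ravel(),
            s.dose.physical_dose.ravel(), label_timepoint=label_timepoint)
        for tissue in table.index:
            for dbin in table.columns:
                assert table.loc[tissue, dbin] == pytest.approx(
                    oracle.get((tissue, dbin), 0.0), abs=1e-9)

    def test_mass_increase_makes_total_more_negative(self):
        s = random_toy_patient(300, seed=8)
        fu = s.followup_candidates[0]
        base_total = vmc(s.baseline, fu, s.heart_mask, eqd2_grid(s.dose)).values.sum()
        from peridose.cohort import ImageVolume

        fu_up = ImageVolume(np.clip(fu.voxels + 20, -1000, 1000), fu.spacing)
        up_total = vmc(s.baseline, fu_up, s.heart_mask, eqd2_grid(s.dose)).values.sum()
        assert up_total < base_total

    def test_all_air_shell_rejected(self):
        s = generate_toy_patient([(-1000, -1000)])
        with pytest.raises(ValidationError):
            vmc(s.baseline, s.followup_candidates[0], s.heart_mask, eqd2_grid(s.dose))


class TestDeltaV:
    def test_two_voxel_worked_example(self):
        # both Fat at baseline; one becomes Fluid: Fat +50 (loss), Fluid -50
        s = generate_toy_patient([(-50, -50), (-50, 0)])
        dv = delta_v(s.baseline, s.followup_candidates[0], s.heart_mask)
        assert dv["Fat"] == pytest.approx(50.0)
        assert dv["Fluid"] == pytest.approx(-50.0)
        assert dv[["Calcification", "Fibrous", "Heme"]].abs().sum() == 0

    def test_identity_pair_all_zero(self):
        s = random_toy_patient(100, seed=9)
        dv = delta_v(s.baseline, s.baseline, s.heart_mask)
        assert np.all(dv.values == 0)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_loop_oracle_and_conserves(self, seed):
        s = random_toy_patient(500, seed=seed)
        dv = delta_v(s.baseline, s.followup_candidates[0], s.heart_mask)
        _, _, oracle = brute_force_biomarkers(
            s.baseline.voxels.ravel(), s.followup_candidates[0].voxels.ravel(),
            s.dose.physical_dose.ravel())
        for tissue in dv.index:
            assert dv[tissue] == pytest.approx(oracle.get(tissue, 0.0), abs=1e-9)
        assert dv.sum() == pytest.approx(0.0, abs=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_conservation_property(self, seed):
        s = random_toy_patient(64, seed=seed)
        dv = delta_v(s.baseline, s.followup_candidates[0], s.heart_mask)
        assert dv.sum() == pytest.approx(0.0, abs=1e-6)


class TestSmoothCurve:
    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        np.testing.assert_array_equal(smooth_curve(x, 1), x)

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(smooth_curve(np.full(9, 2.5), 5), np.full(9, 2.5))

    def test_shrinking_edges_hand_example(self):
        np.testing.assert_allclose(smooth_curve(np.array([0.0, 3.0, 0.0]), 3),
                                   [1.5, 1.0, 1.5])

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            smooth_curve(np.zeros(5), 4)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        got = smooth_curve(x, 7)
        expected = [x[max(0, i - 3):i + 4].mean() for i in range(30)]
        np.testing.assert_allclose(got, expected)
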