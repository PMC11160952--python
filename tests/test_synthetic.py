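"""Synthetic angiogram pairs, metrics-level cohorts, and oracle fixtures."""

import numpy as np
import pytest
from shapely.geometry import LinearRing

from octa_intereye import (CohortGenParams, ImageGenParams,
                           generate_angiogram_pair, generate_metrics_cohort,
                           make_fixture)
from octa_intereye.faz import FazTrace, faz_metrics
from octa_intereye.synthetic import STAGES


class TestAngiogramPair:
    def test_planted_coverage_is_realized(self, clean_pair):
        _, _, _, truth_r, truth_l = clean_pair
        assert truth_r.true_capillary_fraction == pytest.approx(0.25, abs=0.02)
        assert truth_l.true_capillary_fraction == pytest.approx(0.25, abs=0.02)

    def test_zero_irregularity_gives_near_circular_faz(self):
        params = ImageGenParams(image_size=250, pixel_pitch=0.024,
                                faz_irregularity=0.0, noise_sd=0.0, seed=1)
        _, _, truth, _ = generate_angiogram_pair(params)
        m = faz_metrics(FazTrace(truth.faz_polygon, params.pixel_pitch))
        assert m.fazc >= 0.99

    def test_same_seed_is_bit_identical(self, small_pair):
        params, right, left, truth_r, _ = small_pair
        right2, left2, truth_r2, truth_l2 = generate_angiogram_pair(params)
        assert np.array_equal(right.pixels, right2.pixels)
        assert np.array_equal(left.pixels, left2.pixels)
        assert np.array_equal(truth_r.vessel_mask, truth_r2.vessel_mask)
        assert np.array_equal(truth_r.faz_polygon, truth_r2.faz_polygon)

    def test_eyes_differ_from_each_other(self, small_pair):
        _, right, left, *_ = small_pair
        assert not np.array_equal(right.pixels, left.pixels)
        assert right.eye_side == "right" and left.eye_side == "left"

    def test_ground_truth_consistency(self, small_pair):
        _, _, _, truth, _ = small_pair
        assert not (truth.big_vessel_mask & ~truth.vessel_mask).any()
        ring = LinearRing(truth.faz_polygon)
        assert ring.is_simple and ring.is_closed

    def test_faz_region_is_avascular(self, small_pair):
        from skimage.draw import polygon as draw_polygon

        params, _, _, truth, _ = small_pair
        rr, cc = draw_polygon(truth.faz_polygon[:, 1], truth.faz_polygon[:, 0],
                              shape=truth.vessel_mask.shape)
        faz_px = np.zeros_like(truth.vessel_mask)
        faz_px[rr, cc] = True
        assert not (truth.vessel_mask & faz_px).any()

    def test_planted_left_deficit(self):
        params = ImageGenParams(image_size=250, pixel_pitch=0.024, noise_sd=0.0,
                                left_capillary_delta=-0.02, seed=9)
        _, _, truth_r, truth_l = generate_angiogram_pair(params)
        delta = truth_r.true_capillary_fraction - truth_l.true_capillary_fraction
        assert delta == pytest.approx(0.02, abs=0.005)

    @pytest.mark.parametrize("bad", [
        dict(capillary_fraction=0.0), dict(capillary_fraction=1.0),
        dict(faz_mean_radius=1.6), dict(image_size=100),  # 100 px * 0.012 < 6 mm
        dict(faz_irregularity=1.0), dict(noise_sd=-1.0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            ImageGenParams(**bad)


class TestMetricsCohort:
    def test_shape_and_columns(self, default_cohort):
        df = default_cohort
        assert list(df.columns) == ["patient_id", "side", "stage", "age", "sex",
                                    "hba1c", "response"]
        assert len(df) == 2 * 34 * 5
        assert set(df["stage"]) == set(STAGES)
        assert (df.groupby("patient_id").size() == 2).all()

    def test_degenerate_noise_gives_pure_side_effect(self):
        params = CohortGenParams(n_per_stage=5, side_effect=0.0,
                                 interaction_effects=(0.0,) * 5,
                                 patient_sd=0.0, residual_sd=1e-12, seed=0)
        df = generate_metrics_cohort(params)
        wide = df.pivot_table(index="patient_id", columns="side", values="response")
        assert np.allclose(wide["right"], wide["left"], atol=1e-9)

    def test_side_effect_recovered_in_paired_means(self):
        params = CohortGenParams(n_per_stage=30, side_effect=-0.009,
                                 patient_sd=0.015, residual_sd=0.008, seed=5)
        df = generate_metrics_cohort(params)
        wide = df.pivot_table(index="patient_id", columns="side", values="response")
        assert (wide["right"] - wide["left"]).mean() == pytest.approx(0.009, abs=0.003)

    def test_empirical_moments_converge(self):
        params = CohortGenParams(n_per_stage=100, stage_effects=(0.0,) * 5,
                                 side_effect=0.0, seed=12)
        df = generate_metrics_cohort(params)
        n = len(df)
        assert df["response"].mean() == pytest.approx(
            params.grand_mean, abs=3 * params.residual_sd / np.sqrt(n) + 3 * params.patient_sd / np.sqrt(500))
        patient_means = df.groupby("patient_id")["response"].mean()
        between_var = patient_means.var() - params.residual_sd ** 2 / 2
        assert between_var == pytest.approx(params.patient_sd ** 2, rel=0.25)

    def test_demographics_match_population(self):
        df = generate_metrics_cohort(CohortGenParams(n_per_stage=100, seed=3))
        per_patient = df.drop_duplicates("patient_id")
        assert per_patient["age"].mean() == pytest.approx(57.2, abs=2.0)
        assert per_patient["hba1c"].mean() == pytest.approx(7.34, abs=0.2)
        assert (per_patient["sex"] == "male").mean() == pytest.approx(111 / 168, abs=0.07)

    def test_seed_determinism(self):
        a = generate_metrics_cohort(CohortGenParams(seed=77))
        b = generate_metrics_cohort(CohortGenParams(seed=77))
        assert a.equals(b)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CohortGenParams(n_per_stage=1)
        with pytest.raises(ValueError):
            CohortGenParams(residual_sd=0.0)
        with pytest.raises(ValueError):
            CohortGenParams(patient_sd=-0.1)


class TestFixtures:
    def test_sierpinski_pixel_count(self):
        carpet = make_fixture("sierpinski_carpet", 243)
        assert carpet.sum() == 8 ** 5
        assert carpet.shape == (243, 243)

    def test_sierpinski_requires_power_of_three(self):
        with pytest.raises(ValueError):
            make_fixture("sierpinski_carpet", 200)

    def test_filled_disc_area(self):
        disc = make_fixture("filled_disc", 300)
        r = 300 // 2 - 1
        assert disc.sum() == pytest.approx(np.pi * r ** 2, rel=0.01)

    def test_square_polygon_closed_form(self):
        from shapely.geometry import Polygon

        poly = make_fixture("square_polygon", 7)
        assert Polygon(poly).area == 49.0
        assert Polygon(poly).exterior.length == 28.0

    def test_checkerboard_half_coverage(self):
        board = make_fixture("checkerboard", 100)
        assert board.mean() == 0.5

    def test_unknown_fixture_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("klein_bottle", 100)
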