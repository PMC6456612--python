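"""Unit and property tests for the flow-void measurement chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from ccflow import (
    BinaryMask,
    DegenerateInputError,
    ThresholdParams,
    binarize_superficial,
    build_artifact_mask,
    compute_threshold,
    label_components,
    qc_filter,
    quantify,
    segment_voids,
    smooth,
    summarize,
)
from ccflow.quantify import QC_FLAGS

from _oracles import (
    flood_fill_components,
    label_map_components,
    otsu_exhaustive,
    population_threshold,
)
from conftest import make_angiogram


class TestBinarizeSuperficial:
    def test_otsu_separates_bimodal_image(self):
        img = np.zeros((4, 4))
        img.ravel()[8:] = 100.0
        mask = binarize_superficial(make_angiogram(img))
        # oracle: exhaustive between-class-variance search
        thr = otsu_exhaustive(img)
        assert 0 < thr < 100
        assert np.array_equal(mask.values, img > thr)
        assert mask.values.sum() == 8

    def test_constant_image_yields_empty_mask_with_warning(self):
        mask = binarize_superficial(make_angiogram(np.full((4, 4), 7.0)))
        assert not mask.values.any()
        assert mask.warning is not None

    def test_mean_plus_k_sd_rule(self):
        img = np.array([[10.0, 20.0], [30.0, 40.0]])
        mask = binarize_superficial(make_angiogram(img), method="mean_plus_k_sd", k=0.0)
        assert np.array_equal(mask.values, img > 25.0)


class TestArtifactMask:
    def test_zero_dilation_is_identity(self):
        vessel = BinaryMask(np.eye(5, dtype=bool), kind="vessel")
        art = build_artifact_mask(vessel, dilation_um=0.0, um_per_px=19.74)
        assert np.array_equal(art.values, vessel.values)
        assert art.kind == "artifact"

    def test_single_pixel_dilates_to_3x3_block(self):
        vessel = np.zeros((5, 5), dtype=bool)
        vessel[2, 2] = True
        art = build_artifact_mask(
            BinaryMask(vessel, kind="vessel"), dilation_um=20.0, um_per_px=6000 / 304
        )
        expected = np.zeros((5, 5), dtype=bool)
        expected[1:4, 1:4] = True  # brute-force 8-neighbourhood dilation by 1 px
        assert np.array_equal(art.values, expected)

    def test_empty_mask_stays_empty(self):
        art = build_artifact_mask(
            BinaryMask(np.zeros((4, 4), bool), kind="vessel"), 40.0, 19.74
        )
        assert not art.values.any()

    def test_negative_dilation_rejected(self):
        with pytest.raises(ValueError, match="dilation"):
            build_artifact_mask(BinaryMask(np.zeros((4, 4), bool), "vessel"), -1.0, 19.74)


class TestSmooth:
    def test_constant_image_unchanged(self):
        angio = make_angiogram(np.full((16, 16), 5.0))
        out = smooth(angio, ThresholdParams())
        assert np.allclose(out.intensities, 5.0)

    def test_impulse_mass_is_preserved(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        out = smooth(make_angiogram(img), ThresholdParams(sigma_um=20.0))
        assert out.intensities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_sigma_zero_is_identity(self):
        img = np.random.default_rng(0).random((8, 8))
        out = smooth(make_angiogram(img), ThresholdParams(sigma_um=0.0))
        assert np.array_equal(out.intensities, img)

    def test_pixel_scale_of_default_protocol(self):
        # 20 um at a 6 mm / 304 px scan is almost exactly one pixel
        angio = make_angiogram(np.zeros((304, 304)))
        assert 20.0 / angio.um_per_px == pytest.approx(1.01333, abs=1e-3)


class TestComputeThreshold:
    @pytest.mark.parametrize("eta,expected", [(1.0, 13.8197), (2.0, 2.6393)])
    def test_matches_population_sd_arithmetic(self, eta, expected):
        img = make_angiogram([[10.0, 20.0], [30.0, 40.0]])
        thr = compute_threshold(img, None, eta=eta)
        assert thr == pytest.approx(expected, abs=1e-4)
        assert thr == pytest.approx(population_threshold(img.intensities, eta), abs=1e-12)

    def test_constant_image_threshold_is_the_constant(self):
        thr = compute_threshold(make_angiogram(np.full((3, 3), 9.0)), None, eta=1.0)
        assert thr == 9.0

    def test_artifact_pixels_are_excluded_from_statistics(self):
        img = make_angiogram([[10.0, 20.0], [30.0, 1000.0]])
        artifact = BinaryMask(np.array([[False, False], [False, True]]), "artifact")
        thr = compute_threshold(img, artifact, eta=1.0)
        assert thr == pytest.approx(population_threshold([10, 20, 30], 1.0), abs=1e-12)

    def test_too_few_analyzable_pixels(self):
        img = make_angiogram([[1.0, 2.0], [3.0, 4.0]])
        artifact = BinaryMask(np.array([[True, True], [True, False]]), "artifact")
        with pytest.raises(DegenerateInputError):
            compute_threshold(img, artifact, eta=1.0)


class TestSegmentVoids:
    def test_only_pixels_strictly_below_threshold(self):
        img = make_angiogram([[10.0, 20.0], [30.0, 40.0]])
        void = segment_voids(img, 13.8197)
        assert np.array_equal(void.values, [[True, False], [False, False]])

    def test_strictness_at_the_threshold(self):
        img = make_angiogram(np.full((2, 2), 9.0))
        assert not segment_voids(img, 9.0, strictly_below=True).values.any()
        assert segment_voids(img, 9.0, strictly_below=False).values.all()

    def test_voids_inside_artifact_mask_are_removed(self):
        img = make_angiogram([[1.0, 50.0], [50.0, 50.0]])
        artifact = BinaryMask(np.array([[True, False], [False, False]]), "artifact")
        void = segment_voids(img, 10.0, artifact)
        assert not void.values.any()


class TestLabelComponents:
    def test_fully_connected_block(self):
        mask = np.ones((2, 2), dtype=bool)
        for conn in (4, 8):
            _, sizes = label_components(mask, conn)
            assert list(sizes) == [4]

    def test_diagonal_pixels_depend_on_connectivity(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert len(label_components(mask, 8)[1]) == 1
        assert len(label_components(mask, 4)[1]) == 2

    def test_empty_mask(self):
        label_map, sizes = label_components(np.zeros((3, 3), bool), 8)
        assert label_map.max() == 0 and len(sizes) == 0

    @settings(max_examples=200, deadline=None)
    @given(
        mask=st.lists(st.booleans(), min_size=36, max_size=36).map(
            lambda bits: np.array(bits).reshape(6, 6)
        ),
        conn=st.sampled_from([4, 8]),
    )
    def test_agrees_with_flood_fill_oracle(self, mask, conn):
        label_map, sizes = label_components(mask, conn)
        oracle = flood_fill_components(mask, conn)
        assert label_map_components(label_map) == set(oracle)
        assert sorted(sizes) == sorted(len(c) for c in oracle)


class TestSummarize:
    def test_area_size_count_arithmetic(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0:3] = True  # component of 3
        mask[4, 4] = True  # component of 1
        label_map, sizes = label_components(mask, 8)
        res = summarize(label_map, sizes, analyzable_px=25, excluded_px=0, threshold_value=1.0)
        assert res.area_pct == pytest.approx(16.0)
        assert res.mean_size_px == pytest.approx(2.0)
        assert res.count == 2

    def test_no_voids_mean_size_is_missing(self):
        label_map, sizes = label_components(np.zeros((5, 5), bool), 8)
        res = summarize(label_map, sizes, 25, 0, 1.0)
        assert res.count == 0 and res.area_pct == 0.0
        assert np.isnan(res.mean_size_px)

    def test_saturated_grid(self):
        label_map, sizes = label_components(np.ones((5, 5), bool), 8)
        res = summarize(label_map, sizes, 25, 0, 1.0)
        assert (res.area_pct, res.mean_size_px, res.count) == (100.0, 25.0, 1)

    def test_zero_analyzable_area_rejected(self):
        label_map, sizes = label_components(np.zeros((2, 2), bool), 8)
        with pytest.raises(DegenerateInputError):
            summarize(label_map, sizes, 0, 4, 1.0)


class TestQuantifyEndToEnd:
    def test_implanted_voids_recovered_on_clean_scene(self, quiet_scene):
        res = quantify(quiet_scene.superficial, quiet_scene.choriocapillaris)
        assert res.area_pct == pytest.approx(
            100 * quiet_scene.implanted_void_fraction, abs=0.5
        )

    def test_scene_without_voids_or_noise_is_void_free(self):
        from ccflow import SyntheticSceneConfig, generate_scene

        cfg = SyntheticSceneConfig(
            seed=0, void_rate=0, speckle_cv=0.0, artifact_strength=0.0, vessel_density=0.0
        )
        scene = generate_scene(cfg)
        res = quantify(scene.superficial, scene.choriocapillaris)
        assert res.area_pct == 0.0 and res.count == 0

    def test_dimension_mismatch_rejected(self):
        a = make_angiogram(np.zeros((4, 4)))
        b = make_angiogram(np.zeros((5, 5)))
        with pytest.raises(ValueError, match="dimensions"):
            quantify(a, b)

    def test_conservation_identities(self, default_scene):
        res = quantify(default_scene.superficial, default_scene.choriocapillaris)
        _, sizes = label_components(res.label_map > 0, 8)
        assert res.total_void_px == sizes.sum()
        assert res.count * res.mean_size_px == pytest.approx(res.total_void_px, abs=1e-9)
        assert res.analyzable_px + res.excluded_px == default_scene.config.grid_size**2

    def test_voids_buried_inside_artifact_do_not_change_area(self):
        # a thick vessel band; voids strictly interior to the artifact mask
        # (beyond the smoothing support) must not leak into the metrics
        n = 64
        sup = np.full((n, n), 100.0)
        sup[20:44, :] = 200.0
        cc = np.full((n, n), 1000.0)
        cc[10, 10] = 500.0  # a real void outside the band
        base = quantify(make_angiogram(sup), make_angiogram(cc))
        cc2 = cc.copy()
        cc2[28:36, 20:40] = 1.0  # buried >= 8 px inside the 24 px band
        mod = quantify(make_angiogram(sup), make_angiogram(cc2))
        assert mod.area_pct == base.area_pct
        assert mod.count == base.count


class TestQcFilter:
    def test_study_attrition_counts(self):
        records = (
            [{"scan": i} for i in range(85)]
            + [{"scan": 85 + i, "eye_disease": True} for i in range(7)]
            + [{"scan": 92 + i, "missing": True} for i in range(16)]
        )
        included, excluded, counts = qc_filter(records)
        assert counts["enrolled"] == 108
        assert counts["eye_disease"] == 7 and counts["missing"] == 16
        assert counts["analyzed"] == len(included) == 85
        assert len(excluded) == 23

    def test_no_flags_passes_everything(self):
        included, excluded, counts = qc_filter([{"scan": 1}, {"scan": 2}])
        assert len(included) == 2 and not excluded

    def test_double_flagged_record_counted_once(self):
        rec = {"scan": 1, "motion_artifact": True, "missing": True}
        included, excluded, counts = qc_filter([rec])
        assert len(excluded) == 1
        assert counts["missing"] == 1 and counts["motion_artifact"] == 0

    def test_unknown_flag_key_is_schema_error(self):
        with pytest.raises(KeyError, match="unknown QC flag"):
            qc_filter([{"scan": 1, "blurry": True}])

    def test_flag_order_covers_all_reasons(self):
        for flag in QC_FLAGS:
            _, excluded, counts = qc_filter([{flag: True}])
            assert counts[flag] == 1 and len(excluded) == 1
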