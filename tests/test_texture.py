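import numpy as np
import pytest

from nodetex.texture import (
    FeatureGrid,
    ar_model_params,
    extract_all,
    features_table,
    gradient_features,
    histogram_features,
    run_length_features,
    wavelet_features,
)

from conftest import make_quantized
from oracles import brute_rl_features


class TestRunLength:
    def test_simple_row(self):
        roi = make_quantized([[1, 1, 2]])
        feats = run_length_features(roi, "H")
        assert feats["RLNonUni"] == pytest.approx(1.0)
        assert feats["GLevNonU"] == pytest.approx(1.0)
        assert feats["Fraction"] == pytest.approx(2 / 3)

    def test_constant_row_single_run(self):
        roi = make_quantized([[3, 3, 3, 3, 3]], bits=4)
        feats = run_length_features(roi, "H")
        assert feats["RLNonUni"] == pytest.approx(1.0)
        assert feats["GLevNonU"] == pytest.approx(1.0)
        assert feats["LngREmph"] == pytest.approx(25.0)

    def test_alternating_levels(self):
        roi = make_quantized([[1, 2, 1, 2]])
        feats = run_length_features(roi, "H")
        assert feats["RLNonUni"] == pytest.approx(4.0)
        assert feats["ShrtREmp"] == pytest.approx(1.0)

    def test_mask_gap_breaks_runs(self):
        levels = [[2, 2, 2, 2]]
        mask = [[True, True, False, True]]
        roi = make_quantized(levels, mask=mask)
        feats = run_length_features(roi, "H")
        # runs are (2,2) and (2,1): RLNonUni = (1+1)/2
        assert feats["RLNonUni"] == pytest.approx(1.0)
        assert feats["GLevNonU"] == pytest.approx(2.0)

    @pytest.mark.parametrize("direction", ["H", "V", "Z", "N"])
    def test_matches_brute_force(self, random_small_rois, direction):
        for roi in random_small_rois:
            ours = run_length_features(roi, direction)
            expect = brute_rl_features(roi.levels, roi.mask, direction)
            for name, v in expect.items():
                assert ours[name] == pytest.approx(v), (direction, name)


class TestHistogram:
    def test_three_levels(self):
        roi = make_quantized([[1, 2, 3]])
        feats = histogram_features(roi)
        assert feats["Mean"] == pytest.approx(2.0)
        assert feats["Variance"] == pytest.approx(2 / 3)
        assert feats["Perc50"] == pytest.approx(2.0)

    def test_symmetric_histogram_zero_skew(self):
        roi = make_quantized([[1, 2, 2, 3], [3, 2, 2, 1]])
        assert histogram_features(roi)["Skewness"] == pytest.approx(0.0)

    def test_constant_roi_missing_shape_stats(self):
        roi = make_quantized(np.full((2, 3), 4), bits=4)
        feats = histogram_features(roi)
        assert feats["Variance"] == 0.0
        assert feats["Skewness"] is None and feats["Kurtosis"] is None


class TestGradient:
    def test_constant_roi(self):
        roi = make_quantized(np.full((5, 5), 3), bits=4)
        feats = gradient_features(roi)
        assert feats["GrMean"] == pytest.approx(0.0)
        assert feats["GrNonZeros"] == pytest.approx(0.0)

    def test_linear_ramp_unit_magnitude(self):
        # level increases by 1 per column: central difference magnitude 1
        roi = make_quantized(np.tile(np.arange(1, 9), (5, 1)), bits=4)
        feats = gradient_features(roi)
        assert feats["GrMean"] == pytest.approx(1.0)
        assert feats["GrVariance"] == pytest.approx(0.0)

    def test_checkerboard_central_difference_zero(self):
        board = 1 + (np.indices((5, 5)).sum(axis=0) % 2)
        feats = gradient_features(make_quantized(board, bits=4))
        assert feats["GrMean"] == pytest.approx(0.0)

    def test_no_interior_voxel_missing(self):
        feats = gradient_features(make_quantized([[1, 2, 3]]))
        assert all(v is None for v in feats.values())


class TestARModel:
    def test_row_copy_recovers_north_coefficient(self, rng):
        # each row copies the one above: level(x) = 1.0 * North neighbour
        row = rng.integers(1, 16, size=16)
        levels = np.tile(row, (16, 1))
        feats = ar_model_params(make_quantized(levels, bits=4))
        assert feats["Teta3"] == pytest.approx(1.0, abs=1e-8)
        for other in ("Teta1", "Teta2", "Teta4"):
            assert feats[other] == pytest.approx(0.0, abs=1e-8)
        assert feats["SigmaAR"] == pytest.approx(0.0, abs=1e-8)

    def test_white_noise_near_zero_coefficients(self, rng):
        levels = rng.integers(1, 16, size=(40, 40))
        feats = ar_model_params(make_quantized(levels, bits=4))
        for name in ("Teta1", "Teta2", "Teta3", "Teta4"):
            assert abs(feats[name]) < 0.1

    def test_too_few_voxels_missing(self):
        feats = ar_model_params(make_quantized(np.ones((3, 3), dtype=int)))
        assert all(v is None for v in feats.values())


class TestWavelet:
    def test_constant_roi_detail_energy_zero(self):
        feats = wavelet_features(make_quantized(np.full((8, 8), 5), bits=4), scales=2)
        for s in (1, 2):
            assert feats[f"WavEnLL{s}"] > 0
            for band in ("LH", "HL", "HH"):
                assert feats[f"WavEn{band}{s}"] == pytest.approx(0.0)

    def test_column_stripes_load_on_lh(self):
        stripes = np.tile(np.array([1, 3]), (8, 4))  # varies along columns
        feats = wavelet_features(make_quantized(stripes, bits=4), scales=1)
        assert feats["WavEnLH1"] > 10 * max(feats["WavEnHL1"], 1e-12)
        assert feats["WavEnHH1"] == pytest.approx(0.0)

    def test_too_small_roi_scale_missing(self):
        feats = wavelet_features(make_quantized(np.ones((3, 3), dtype=int)), scales=2)
        assert feats["WavEnLL2"] is None


class TestExtractAll:
    def test_default_grid_key_count(self, rng):
        # 32x32 in-plane so even the scale-5 wavelet subbands fit
        levels = rng.integers(1, 65, size=(32, 32, 2))
        roi = make_quantized(levels, bits=6)
        fv = extract_all(roi)
        assert len(fv.values) == FeatureGrid().n_keys() == 279
        assert fv.n_missing == 0

    def test_determinism(self, rng):
        levels = rng.integers(1, 65, size=(10, 10, 3))
        roi = make_quantized(levels, bits=6)
        assert extract_all(roi).as_named_dict() == extract_all(roi).as_named_dict()

    def test_single_voxel_roi_histogram_only(self):
        fv = extract_all(make_quantized([[3]], bits=6))
        named = {str(k): v for k, v in fv.values.items()}
        assert named["CS6Mean"] == 3.0  # histogram features present
        assert named["CH1S6Entropy"] is None  # no pairs
        assert named["CS6GrMean"] is None

    def test_features_table_shape(self, rng):
        rois = [make_quantized(rng.integers(1, 65, size=(8, 8, 2)), bits=6) for _ in range(3)]
        vecs = [extract_all(r, lesion_id=f"l{i}") for i, r in enumerate(rois)]
        table = features_table(vecs, {"l0": "benign", "l1": "benign", "l2": "malignant"})
        assert table.shape == (3, 280)  # class column + 279 features
        assert list(table["class"]) == ["benign", "benign", "malignant"]
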