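"""Preprocessing: truncation, AWLS baseline, SG derivative, normalization,
replicate averaging and train-anchored centering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import ftirchem as fc
from ftirchem.errors import ConfigError, MetadataError, NormalizationError, RangeError
from ftirchem.io import SpectrumSet, WavenumberGrid


def _set_from(grid_values, matrix, sample_ids=None):
    matrix = np.atleast_2d(matrix)
    n = matrix.shape[0]
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(n)],
            "sample_id": sample_ids or [f"s{i}" for i in range(n)],
            "replicate_index": 1,
            "class_label": "AD",
            "biofluid": "plasma",
        }
    )
    return SpectrumSet(grid=WavenumberGrid(np.asarray(grid_values, float)),
                       absorbance=matrix, meta=meta)


class TestTruncate:
    def test_full_instrument_range_cut_to_fingerprint(self):
        grid = np.arange(4000.0, 399.0, -4.0)
        ss = _set_from(grid, np.ones((2, grid.size)))
        cut = fc.truncate_range(ss, 900, 1800)
        assert cut.grid.n == 226  # (1800 - 900) / 4 + 1

    def test_identity_cut(self, small_set):
        cut = fc.truncate_range(small_set, 900, 1800)
        np.testing.assert_array_equal(cut.absorbance, small_set.absorbance)

    def test_empty_overlap(self, small_set):
        with pytest.raises(RangeError):
            fc.truncate_range(small_set, 100, 200)


class TestAwls:
    grid = np.arange(900.0, 1801.0, 4.0)

    def test_straight_line_input_is_fully_removed(self):
        y = 0.3 + 2e-4 * self.grid
        _, corrected, conv = fc.awls_baseline(y)
        assert conv
        assert np.max(np.abs(corrected)) < 1e-6 * np.max(np.abs(y))

    def test_zero_spectrum_gives_zero_baseline(self):
        base, corrected, _ = fc.awls_baseline(np.zeros(self.grid.size))
        assert np.allclose(base, 0) and np.allclose(corrected, 0)

    def test_gaussian_peak_over_line_is_recovered(self):
        peak = 1.0 * np.exp(-0.5 * ((self.grid - 1650.0) / 20.0) ** 2)
        y = peak + 0.1 + 1e-4 * self.grid
        _, corrected, _ = fc.awls_baseline(y, lam=1e5)
        assert np.max(np.abs(corrected - peak)) < 0.05

    def test_negative_excursions_are_rare(self):
        rng = np.random.default_rng(3)
        sigma = 0.002
        peak = 0.8 * np.exp(-0.5 * ((self.grid - 1500.0) / 30.0) ** 2)
        bad = 0
        for _ in range(10):
            y = peak + 0.05 + 5e-5 * self.grid + rng.normal(0, sigma, self.grid.size)
            _, corrected, _ = fc.awls_baseline(y)
            bad += np.mean(corrected < -5 * sigma)
        assert bad / 10 < 0.01


class TestSavgolDerivative:
    def test_exact_on_quadratic(self):
        grid = np.arange(900.0, 1801.0, 4.0)
        ss = _set_from(grid, (grid ** 2)[None, :])
        out = fc.savgol_derivative(ss, window=9, polyorder=2, deriv=2)
        np.testing.assert_allclose(out.absorbance[0][4:-4], 2.0, atol=1e-8)

    def test_constant_maps_to_zero(self):
        grid = np.arange(900.0, 1801.0, 4.0)
        out = fc.savgol_derivative(_set_from(grid, np.full((1, grid.size), 3.3)))
        np.testing.assert_allclose(out.absorbance, 0, atol=1e-10)

    def test_analytic_sine_second_derivative(self):
        # at this frequency a quartic local fit is needed for ~0.1% accuracy;
        # a quadratic one systematically underestimates curvature by ~5%
        grid = np.arange(900.0, 1801.0, 4.0)
        ss = _set_from(grid, np.sin(0.05 * grid)[None, :])
        out = fc.savgol_derivative(ss, window=9, polyorder=4, deriv=2)
        expected = -0.0025 * np.sin(0.05 * grid)
        interior = slice(8, -8)
        err = np.abs(out.absorbance[0][interior] - expected[interior])
        assert np.max(err) < 0.01 * np.max(np.abs(expected))

    def test_descending_grid_matches_ascending(self):
        grid = np.arange(900.0, 1801.0, 4.0)
        y = np.exp(-0.5 * ((grid - 1400) / 50.0) ** 2)
        up = fc.savgol_derivative(_set_from(grid, y[None, :]))
        down = fc.savgol_derivative(_set_from(grid[::-1], y[::-1][None, :]))
        np.testing.assert_allclose(down.absorbance[0][::-1], up.absorbance[0],
                                   atol=1e-12)

    @given(seed=st.integers(0, 1000))
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.arange(1000.0, 1201.0, 4.0)
        a, b = rng.normal(size=(2, grid.size))
        f = lambda m: fc.savgol_derivative(_set_from(grid, m[None, :])).absorbance[0]
        np.testing.assert_allclose(f(a + b), f(a) + f(b), atol=1e-10)

    def test_window_larger_than_grid(self, small_set):
        with pytest.raises(ConfigError):
            fc.savgol_derivative(small_set, window=2 * small_set.grid.n + 1)


class TestVectorNormalize:
    def test_three_four_five(self):
        ss = _set_from([1000.0, 1004.0], np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(fc.vector_normalize(ss).absorbance[0], [0.6, 0.8])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        grid = np.arange(900.0, 1101.0, 4.0)
        once = fc.vector_normalize(_set_from(grid, rng.random((3, grid.size))))
        twice = fc.vector_normalize(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-12)
        np.testing.assert_allclose(
            np.linalg.norm(once.absorbance, axis=1), 1.0, atol=1e-12
        )

    def test_zero_norm_names_the_spectrum(self):
        ss = _set_from([1000.0, 1004.0], np.array([[1.0, 2.0], [0.0, 0.0]]))
        with pytest.raises(NormalizationError, match="s1"):
            fc.vector_normalize(ss)


class TestAverageReplicates:
    def test_mean_of_two(self):
        ss = _set_from([1000.0, 1004.0], np.array([[0.0, 0.0], [2.0, 2.0]]),
                       sample_ids=["a", "a"])
        out = fc.average_replicates(ss)
        np.testing.assert_array_equal(out.absorbance, [[1.0, 1.0]])
        assert out.meta.loc[0, "n_replicates"] == 2

    def test_identical_replicates_average_to_themselves(self, small_set):
        rep = small_set.copy_with(
            absorbance=np.tile(small_set.absorbance[:1], (6, 1))
        )
        out = fc.average_replicates(rep)
        np.testing.assert_allclose(out.absorbance[0], small_set.absorbance[0])

    def test_cohort_scale_counts(self):
        # 63 samples x 10 replicate locations -> 63 sample-level spectra
        cfg = fc.SyntheticConfig(seed=5)
        ss, _, _ = fc.generate_cohort(cfg)
        assert ss.n_spectra == 630
        out = fc.average_replicates(ss)
        assert out.n_spectra == 63

    def test_conflicting_labels_rejected(self):
        ss = _set_from([1000.0, 1004.0], np.ones((2, 2)), sample_ids=["a", "a"])
        ss.meta.loc[1, "class_label"] = "DR"
        with pytest.raises(MetadataError):
            fc.average_replicates(ss)


class TestMeanCenter:
    def test_small_example(self):
        tr, ap, mean = fc.mean_center(np.array([[0.0, 0.0], [2.0, 2.0]]),
                                      np.array([[1.0, 1.0]]))
        np.testing.assert_array_equal(mean, [1.0, 1.0])
        np.testing.assert_array_equal(tr, [[-1.0, -1.0], [1.0, 1.0]])
        np.testing.assert_array_equal(ap, [[0.0, 0.0]])  # the train mean row

    def test_random_column_means_vanish(self):
        rng = np.random.default_rng(11)
        tr, _, _ = fc.mean_center(rng.random((20, 30)))
        assert np.max(np.abs(tr.mean(axis=0))) < 1e-10

    def test_empty_train_rejected(self):
        with pytest.raises(fc.DataError):
            fc.mean_center(np.empty((0, 3)))


class TestChain:
    def test_pipeline_is_pure(self, small_set):
        cfg = fc.PreprocessConfig()
        a = fc.preprocess_spectra(small_set, cfg)
        b = fc.preprocess_spectra(small_set, cfg)
        np.testing.assert_array_equal(a.absorbance, b.absorbance)

    def test_second_derivative_profile_changes_output(self, small_set):
        base = fc.preprocess_spectra(small_set)
        deriv = fc.preprocess_spectra(small_set, fc.second_derivative_profile())
        assert not np.allclose(base.absorbance, deriv.absorbance)
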