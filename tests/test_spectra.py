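"""Spectral preprocessing chain against closed-form and oracle solutions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myotex import spectra as sp
from myotex.containers import SpectraSet
from myotex.spectra import (
    EMSCCorrection,
    RegionSelector,
    SavitzkyGolaySecondDerivative,
    UnstandardizedPCA,
    differential_peaks,
    emsc_correct,
    pca_scores,
    select_region,
    sg_second_derivative,
)


def _set(wavenumbers, absorbance, groups=None):
    return SpectraSet(wavenumbers=np.asarray(wavenumbers, dtype=float),
                      absorbance=np.asarray(absorbance, dtype=float),
                      groups=groups)


def _gaussian(wn, center, width, amp=1.0):
    return amp * np.exp(-0.5 * ((wn - center) / width) ** 2)


class TestSavitzkyGolay:
    wn = np.arange(750.0, 1750.0, 4.0)

    def test_quadratic_differentiates_exactly(self):
        out = sg_second_derivative(_set(self.wn, self.wn**2))
        np.testing.assert_allclose(out.absorbance[0], 2.0, atol=1e-8)

    def test_linear_has_zero_second_derivative(self):
        out = sg_second_derivative(_set(self.wn, 3.0 * self.wn + 7.0))
        np.testing.assert_allclose(out.absorbance[0], 0.0, atol=1e-8)

    def test_sinusoid_matches_analytic_second_derivative(self):
        omega = 0.01  # omega * step = 0.04, well below 1/window
        y = np.sin(omega * self.wn)
        out = sg_second_derivative(_set(self.wn, y)).absorbance[0]
        expected = -(omega**2) * np.sin(omega * self.wn)
        interior = slice(6, -6)
        err = np.abs(out[interior] - expected[interior]).max()
        assert err <= 0.01 * omega**2

    def test_grid_step_scaling(self):
        # doubling the step quarters nothing: derivative is per (cm^-1)^2
        coarse = np.arange(0.0, 400.0, 8.0)
        out = sg_second_derivative(_set(coarse, 5.0 * coarse**2))
        np.testing.assert_allclose(out.absorbance[0], 10.0, atol=1e-8)

    @pytest.mark.parametrize("kwargs", [
        {"window_points": 10},
        {"window_points": 5, "poly_order": 5},
        {"poly_order": 1},
        {"window_points": 100001},
    ])
    def test_invalid_filter_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            sg_second_derivative(_set(self.wn, self.wn), **kwargs)

    def test_uneven_grid_raises(self):
        wn = np.array([1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0,
                       256.0, 512.0, 1024.0, 2048.0])
        with pytest.raises(ValueError, match="evenly spaced"):
            sg_second_derivative(_set(wn, wn))


class TestEMSC:
    wn = np.arange(750.0, 1750.0, 4.0)
    x = 2.0 * (wn - wn[0]) / (wn[-1] - wn[0]) - 1.0
    m = _gaussian(wn, 1200.0, 60.0)

    def test_constructed_distortion_identified_exactly(self):
        z = 0.5 + 2.0 * self.m + 0.1 * self.x + 0.01 * self.x**2
        res = emsc_correct(_set(self.wn, z[None, :]), reference=self.m)
        p = res.parameters.iloc[0]
        assert p["a"] == pytest.approx(0.5, abs=1e-8)
        assert p["b"] == pytest.approx(2.0, abs=1e-8)
        assert p["d1"] == pytest.approx(0.1, abs=1e-8)
        assert p["d2"] == pytest.approx(0.01, abs=1e-8)
        np.testing.assert_allclose(res.corrected.absorbance[0], self.m,
                                   atol=1e-8)

    def test_reference_itself_is_identity(self):
        res = emsc_correct(_set(self.wn, self.m[None, :]), reference=self.m)
        p = res.parameters.iloc[0]
        assert p["b"] == pytest.approx(1.0, abs=1e-8)
        for c in ("a", "d1", "d2"):
            assert p[c] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(res.corrected.absorbance[0], self.m,
                                   atol=1e-10)

    def test_parameters_match_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        Z = (rng.uniform(0.5, 2.0, (6, 1))
             * (self.m + rng.normal(0, 0.01, (6, len(self.wn))))
             + rng.uniform(-0.2, 0.2, (6, 1)))
        res = emsc_correct(_set(self.wn, Z), reference=self.m)
        design = np.column_stack([np.ones_like(self.x), self.x, self.x**2,
                                  self.m])
        oracle = np.linalg.solve(design.T @ design, design.T @ Z.T).T
        got = res.parameters[["a", "d1", "d2", "b"]].to_numpy()
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_recombination_reproduces_input(self):
        rng = np.random.default_rng(9)
        Z = rng.uniform(0.8, 1.2, (4, 1)) * self.m + rng.normal(0, 0.02,
                                                                (4, 1))
        res = emsc_correct(_set(self.wn, Z), reference=self.m)
        p = res.parameters
        recombined = (p["b"].to_numpy()[:, None] * res.corrected.absorbance
                      + p["a"].to_numpy()[:, None]
                      + np.outer(p["d1"], self.x) + np.outer(p["d2"], self.x**2))
        np.testing.assert_allclose(recombined, Z, atol=1e-8)

    def test_idempotence_against_same_reference(self):
        rng = np.random.default_rng(11)
        Z = (rng.uniform(0.5, 1.5, (5, 1)) * self.m
             + rng.normal(0, 0.05, (5, len(self.wn))))
        once = emsc_correct(_set(self.wn, Z), reference=self.m)
        twice = emsc_correct(once.corrected, reference=self.m)
        p = twice.parameters
        np.testing.assert_allclose(p["b"], 1.0, atol=1e-8)
        np.testing.assert_allclose(p[["a", "d1", "d2"]], 0.0, atol=1e-8)
        np.testing.assert_allclose(twice.corrected.absorbance,
                                   once.corrected.absorbance, atol=1e-8)

    def test_near_zero_scale_flagged_not_divided(self):
        Z = np.vstack([self.m, 1e-12 * self.m])
        with pytest.warns(UserWarning, match="left uncorrected"):
            res = emsc_correct(_set(self.wn, Z), reference=self.m)
        assert bool(res.parameters["flagged"].iloc[1])
        np.testing.assert_allclose(res.corrected.absorbance[1], Z[1])

    @given(a=st.floats(-1, 1), b=st.floats(0.2, 5),
           d1=st.floats(-0.5, 0.5), d2=st.floats(-0.5, 0.5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_distortion_family_always_inverted(self, a, b, d1, d2):
        z = a + b * self.m + d1 * self.x + d2 * self.x**2
        res = emsc_correct(_set(self.wn, z[None, :]), reference=self.m)
        np.testing.assert_allclose(res.corrected.absorbance[0], self.m,
                                   atol=1e-7)


class TestRegionSelection:
    def test_fingerprint_window_has_51_columns(self):
        # a 4 cm^-1 grid containing 800: (1000 - 800)/4 + 1 = 51 points
        wn = np.arange(600.0, 1404.0, 4.0)
        sub = select_region(_set(wn, np.ones((1, wn.size))), 800, 1000)
        assert sub.absorbance.shape[1] == 51
        assert sub.wavenumbers[0] == 800.0 and sub.wavenumbers[-1] == 1000.0

    def test_fingerprint_window_on_instrument_grid(self, default_spectra):
        # the 750-anchored instrument grid has no 800 point (798/802), so
        # the inclusive window holds the 50 points 802..998
        sub = select_region(default_spectra, 800, 1000)
        assert sub.absorbance.shape[1] == 50
        assert sub.wavenumbers[0] == 802.0 and sub.wavenumbers[-1] == 998.0

    def test_full_range_is_identity(self, default_spectra):
        sub = select_region(default_spectra, 0, 10_000)
        np.testing.assert_array_equal(sub.absorbance,
                                      default_spectra.absorbance)

    def test_empty_overlap_raises(self, default_spectra):
        with pytest.raises(ValueError, match="empty region"):
            select_region(default_spectra, 10, 20)

    def test_bounds_are_inclusive(self):
        wn = np.arange(100.0, 200.0, 10.0)
        sub = select_region(_set(wn, np.ones((1, 10))), 120, 150)
        np.testing.assert_array_equal(sub.wavenumbers,
                                      [120.0, 130.0, 140.0, 150.0])


class TestPCA:
    def test_two_spectra_give_symmetric_pc1(self):
        wn = np.arange(10.0)
        X = np.vstack([np.sin(wn), np.sin(wn) + 0.3])
        scores = pca_scores(_set(wn, X), n_components=1).scores
        assert scores[0, 0] == pytest.approx(-scores[1, 0])

    def test_variance_conservation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 5))
        res = UnstandardizedPCA(n_components=4).fit(X)
        centered = X - X.mean(axis=0)
        total = (centered**2).sum() / (len(X) - 1)
        assert res.total_variance_ == pytest.approx(total)
        assert np.all(np.diff(res.explained_variance_) <= 1e-12)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 8))
        est = UnstandardizedPCA(n_components=3).fit(X)
        scores = est.transform(X)
        cov = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:3]
        np.testing.assert_allclose(est.explained_variance_, evals[order],
                                   atol=1e-10)
        centered = X - X.mean(axis=0)
        for i, j in enumerate(order):
            v = evecs[:, j]
            v = v * np.sign(v[np.argmax(np.abs(v))])  # same sign convention
            np.testing.assert_allclose(est.components_[i], v, atol=1e-10)
            np.testing.assert_allclose(scores[:, i], centered @ v, atol=1e-10)

    def test_scores_are_column_centred(self, corrected_spectra):
        sub = select_region(corrected_spectra, 800, 1000)
        scores = pca_scores(sub, n_components=2).scores
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_sign_convention_largest_loading_positive(self, corrected_spectra):
        sub = select_region(corrected_spectra, 800, 1000)
        loadings = pca_scores(sub, n_components=2).loadings
        for row in loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_constant_shift_leaves_scores_unchanged(self, corrected_spectra):
        sub = select_region(corrected_spectra, 800, 1000)
        shifted = sub.copy_with(absorbance=sub.absorbance + 0.7)
        np.testing.assert_allclose(pca_scores(sub, 2).scores,
                                   pca_scores(shifted, 2).scores, atol=1e-9)

    def test_rank_deficiency_returns_fewer_components(self):
        wn = np.arange(6.0)
        base = np.sin(wn)
        X = np.vstack([base, 2 * base, 3 * base, 4 * base])
        with pytest.warns(UserWarning, match="rank"):
            est = UnstandardizedPCA(n_components=3).fit(X)
        assert est.n_components_ == 1

    def test_excessive_components_raise(self):
        with pytest.raises(ValueError, match="n_components"):
            UnstandardizedPCA(n_components=5).fit(np.eye(3))

    def test_pc1_separates_texture_groups(self, corrected_spectra):
        """Hard vs soft classification by thresholding PC1 of the
        800-1000 cm^-1 region must reach 90% accuracy."""
        sub = select_region(corrected_spectra, 800, 1000)
        pc1 = pca_scores(sub, n_components=2).scores[:, 0]
        hard = sub.groups == "hard"
        thr = (pc1[hard].mean() + pc1[~hard].mean()) / 2.0
        pred = pc1 > thr if pc1[hard].mean() > thr else pc1 <= thr
        assert (pred == hard).mean() >= 0.90


class TestDifferentialPeaks:
    def test_identical_means_give_no_peaks(self):
        wn = np.arange(800.0, 1000.0, 4.0)
        y = _gaussian(wn, 900.0, 10.0)
        assert len(differential_peaks(y, y, wn)) == 0

    def test_single_extra_band_localised_within_one_step(self):
        wn = np.arange(750.0, 1400.0, 4.0)
        base = _gaussian(wn, 1100.0, 30.0)
        hard = base + _gaussian(wn, 900.0, 8.0, amp=0.3)
        peaks = differential_peaks(hard, base, wn)
        assert len(peaks) == 1
        assert abs(peaks[0] - 900.0) <= 4.0

    def test_generator_gag_bands_recovered(self, corrected_spectra):
        sub = select_region(corrected_spectra, 800, 1400)
        means = sp.group_mean_spectra(sub)
        peaks = differential_peaks(means["hard"], means["soft"],
                                   sub.wavenumbers, n_peaks=3)
        for center in (850.0, 925.0, 1314.0):
            assert np.abs(peaks - center).min() <= 4.0

    def test_mismatched_shapes_raise(self):
        with pytest.raises(ValueError):
            differential_peaks(np.ones(5), np.ones(4), np.arange(5.0))


class TestProcessingLog:
    def test_logged_chain_replays_bit_identically(self, default_spectra):
        first = select_region(
            emsc_correct(sg_second_derivative(default_spectra)).corrected,
            800, 1000)
        replay = default_spectra
        for entry in first.processing_log:
            if entry["step"] == "sg_second_derivative":
                replay = sg_second_derivative(replay, entry["window_points"],
                                              entry["poly_order"])
            elif entry["step"] == "emsc_correct":
                replay = emsc_correct(replay).corrected
            elif entry["step"] == "select_region":
                replay = select_region(replay, entry["lo_cm1"],
                                       entry["hi_cm1"])
        np.testing.assert_array_equal(replay.absorbance, first.absorbance)
        assert replay.processing_log == first.processing_log


class TestSklearnCompat:
    def test_transformers_clone_and_pipeline(self, default_spectra):
        from sklearn.base import clone
        from sklearn.pipeline import Pipeline

        wn = default_spectra.wavenumbers
        pipe = Pipeline([
            ("deriv", SavitzkyGolaySecondDerivative(wavenumbers=wn)),
            ("emsc", EMSCCorrection(wavenumbers=wn)),
            ("region", RegionSelector(800, 1000, wavenumbers=wn)),
            ("pca", UnstandardizedPCA(n_components=2)),
        ])
        clone(pipe)  # parameter contract
        scores = pipe.fit_transform(default_spectra.absorbance)
        assert scores.shape == (default_spectra.n_spectra, 2)
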