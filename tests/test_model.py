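"""Binding-constant algebra, the combined linear score, and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import albudock as ad
from albudock.docking import EnsembleScore
from albudock.model import CombinedModel


class TestCombinedScore:
    def test_published_intercept_at_origin(self):
        assert ad.combined_score(0.0, 0.0) == pytest.approx(25.41)

    def test_hand_arithmetic_example(self):
        # 25.41 + (-1.95)(-12.33) + 7.68 * 2.0
        assert ad.combined_score(-12.33, 2.0) == pytest.approx(64.8135)

    def test_zero_model(self):
        zero = CombinedModel(0.0, 0.0, 0.0)
        assert ad.combined_score(-8.0, 3.3, zero) == 0.0

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            ad.combined_score(float("nan"), 1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(-20, 5), st.floats(-20, 5), st.floats(-3, 8),
        st.floats(-5, 5), st.floats(-3, 3),
    )
    def test_affine_in_docking_score(self, a, b, logp, da, db):
        """score(x + d) - score(x) depends only on d, not on x."""
        d = da + db
        lhs = ad.combined_score(a + d, logp) - ad.combined_score(a, logp)
        rhs = ad.combined_score(b + d, logp) - ad.combined_score(b, logp)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_monotone_directions_of_default_coefficients(self):
        base = ad.combined_score(-8.0, 2.0)
        assert ad.combined_score(-8.0, 2.5) > base      # more lipophilic
        assert ad.combined_score(-9.0, 2.0) > base      # better docking score

    def test_model_file_roundtrip(self, tmp_path):
        model = ad.fit_combined([0, -5, -9, -2.5], [1, 2, 0.5, 3], [30, 70, 80, 50],
                                n_boot=50, seed=3)
        path = tmp_path / "model.txt"
        model.save(path)
        loaded = CombinedModel.load(path)
        assert loaded.intercept == model.intercept
        assert loaded.alpha == model.alpha
        assert loaded.beta == model.beta
        assert loaded.fit_meta["ci95"]["alpha"] == pytest.approx(
            model.fit_meta["ci95"]["alpha"]
        )


class TestFitCombined:
    def test_noise_free_exact_recovery(self, rng):
        xp = rng.normal(-8, 4, size=50)
        lp = rng.normal(1.5, 1.5, size=50)
        y = 25.41 - 1.95 * xp + 7.68 * lp
        model = ad.fit_combined(xp, lp, y, n_boot=20, seed=0)
        assert model.intercept == pytest.approx(25.41, abs=1e-9)
        assert model.alpha == pytest.approx(-1.95, abs=1e-10)
        assert model.beta == pytest.approx(7.68, abs=1e-10)

    def test_error_shrinks_with_sample_size(self):
        """Estimates concentrate on the truth as n grows: the RMSE over
        replicates drops roughly like 1/sqrt(n), and the replicate-mean
        error is indistinguishable from zero (no systematic bias)."""
        rng = np.random.default_rng(42)
        rmse, bias, stderr = {}, {}, {}
        truth = np.array([25.41, -1.95, 7.68])
        for n in (50, 500):
            est = []
            for _ in range(200):
                xp = rng.normal(-8, 4, size=n)
                lp = rng.normal(1.5, 1.5, size=n)
                y = truth[0] + truth[1] * xp + truth[2] * lp + rng.normal(0, 10, n)
                m = ad.fit_combined(xp, lp, y, n_boot=2, seed=0)
                est.append([m.intercept, m.alpha, m.beta])
            est = np.asarray(est)
            rmse[n] = np.sqrt(np.mean((est - truth) ** 2, axis=0))
            bias[n] = np.mean(est, axis=0) - truth
            stderr[n] = np.std(est, axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(rmse[500] < 0.5 * rmse[50])
        for n in (50, 500):
            assert np.all(np.abs(bias[n]) < 4 * stderr[n])

    def test_too_few_records(self):
        with pytest.raises(ValueError, match="at least 3"):
            ad.fit_combined([0, 1], [1, 2], [10, 20])

    def test_collinear_predictors_rejected(self):
        xp = [1.0, 2.0, 3.0, 4.0]
        with pytest.raises(ValueError, match="collinear"):
            ad.fit_combined(xp, [2 * v for v in xp], [1, 2, 3, 4])

    def test_bootstrap_meta_recorded(self):
        rng = np.random.default_rng(0)
        xp, lp = rng.normal(size=20), rng.normal(size=20)
        y = 1 + xp + lp + rng.normal(0, 0.1, 20)
        m = ad.fit_combined(xp, lp, y, n_boot=200, seed=5)
        assert m.fit_meta["n_boot"] == 200
        assert m.fit_meta["seed"] == 5
        lo, hi = m.fit_meta["ci95"]["beta"]
        assert lo < m.beta < hi


class TestBindingMath:
    def test_percent_fraction_correspondence(self):
        assert ad.fb_from_percent(25.0) == 0.25
        assert ad.fb_from_percent(0.0) == 0.0
        assert ad.percent_from_fb(1.0) == 100.0

    def test_ka_at_half_saturation(self):
        # fb = 0.5 at [HSA] = 0.6 mM requires Ka = 1/[HSA] ~ 1666.7 / M
        assert ad.ka_from_fb(0.5) == pytest.approx(1666.6667, rel=1e-4)

    def test_ka_of_zero_fraction(self):
        assert ad.ka_from_fb(0.0) == 0.0

    @pytest.mark.parametrize("fb", [0.1, 0.25, 0.8, 0.99])
    def test_roundtrip_identities(self, fb):
        assert ad.fb_from_ka(ad.ka_from_fb(fb)) == pytest.approx(fb, rel=1e-12)
        ka = ad.ka_from_fb(fb)
        assert ad.ka_from_ki(ad.ki_from_ka(ka)) == pytest.approx(ka, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 0.999), st.floats(1e-6, 1e-2))
    def test_roundtrip_property_on_unit_interval(self, fb, conc):
        assert ad.fb_from_ka(ad.ka_from_fb(fb, conc), conc) == pytest.approx(
            fb, abs=1e-9
        )

    def test_saturated_fraction_rejected(self):
        with pytest.raises(ValueError):
            ad.ka_from_fb(1.0)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            ad.ka_from_fb(0.5, albumin_conc=0.0)

    def test_binding_constants_container(self):
        bc = ad.BindingConstants(fb=0.9)
        assert bc.hsa_percent == 90.0
        assert bc.ka * bc.ki == pytest.approx(1.0)


class TestClassifyBinder:
    @pytest.mark.parametrize(
        "percent,expected",
        [(10, "weak"), (85, "binder"), (50, "intermediate"),
         (25, "intermediate"), (80, "intermediate"),
         (24.999, "weak"), (80.001, "binder")],
    )
    def test_cutoffs_strict(self, percent, expected):
        assert ad.classify_binder(percent) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ad.classify_binder(101.0)


class TestSitePreference:
    def test_equal_scores_is_site_I(self):
        ens = EnsembleScore("L", -8.0, best_site_I=-8.0, best_site_II=-8.0)
        pref = ad.site_preference(ens)
        assert pref.delta == 0.0
        assert pref.predicted_site == "site_I"

    def test_delta_arithmetic(self):
        ens = EnsembleScore("L", -12.0, best_site_I=-12.0, best_site_II=-8.0)
        pref = ad.site_preference(ens)
        assert pref.delta == 4.0
        assert pref.predicted_site == "site_II"

    def test_missing_site_is_indeterminate(self):
        ens = EnsembleScore("L", -12.0, best_site_I=-12.0, best_site_II=None)
        assert ad.site_preference(ens).predicted_site == "indeterminate"

    def test_threshold_boundary_inclusive_for_site_I(self):
        ens = EnsembleScore("L", -10.0, best_site_I=-10.0, best_site_II=-8.0)
        assert ad.site_preference(ens, threshold=2.0).predicted_site == "site_I"
        assert ad.site_preference(ens, threshold=1.9).predicted_site == "site_II"
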