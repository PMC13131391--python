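"""Threshold construction, score assignment, exact category probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import ordidrift as od
from ordidrift.binning import ThresholdSystem


class TestThresholdConstruction:
    def test_stature_grid_matches_published_bins(self, stature_in):
        assert np.allclose(stature_in.tau,
                           [54.5, 55.5, 56.5, 57.5, 58.5, 59.5, 60.5, 61.5])

    def test_two_category_split_cuts_at_center(self):
        ts = od.make_equal_interval_thresholds(0.0, 1.0, 2)
        assert np.allclose(ts.tau, [0.0])

    def test_previous_system_grid(self):
        ts = od.make_equal_interval_thresholds(56.0, 1.0, 9)
        assert np.allclose(ts.tau, np.arange(52.5, 60.0, 1.0))

    @pytest.mark.parametrize("center,width,k", [(58, 0.0, 9), (58, -1, 9), (58, 1, 1)])
    def test_rejects_degenerate_grids(self, center, width, k):
        with pytest.raises(ValueError):
            od.make_equal_interval_thresholds(center, width, k)

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError):
            ThresholdSystem(3, np.array([1.0, 1.0]))

    def test_yaml_round_trip(self, stature_in):
        ts = stature_in.with_delta(2.0)
        again = ThresholdSystem.from_yaml(ts.to_yaml())
        assert again.k == ts.k and again.delta == 2.0
        assert np.allclose(again.tau, ts.tau)

    def test_unit_conversion_round_trip(self, stature_in):
        back = stature_in.to_unit("cm").to_unit("in")
        assert np.allclose(back.tau, stature_in.tau)


class TestAssignScore:
    def test_paper_example_58_maps_to_central_score(self, stature_in):
        assert od.assign_score(58.0, stature_in) == 5

    def test_boundary_goes_to_upper_bin(self, stature_in):
        assert od.assign_score(54.5, stature_in) == 2

    def test_shift_by_two_inches_raises_score(self, stature_in):
        # brute-force interval search on the shifted cut points
        shifted = stature_in.with_delta(2.0)
        tau = shifted.effective_tau
        expected = int(np.flatnonzero(
            np.concatenate([[-np.inf], tau]) <= 58.0)[-1]) + 1
        assert od.assign_score(58.0, shifted) == expected == 7

    def test_extremes_map_to_end_categories(self, stature_in):
        assert od.assign_score(-1e6, stature_in) == 1
        assert od.assign_score(1e6, stature_in) == 9

    def test_rejects_nan(self, stature_in):
        with pytest.raises(ValueError):
            od.assign_score(np.nan, stature_in)

    def test_vectorized_agrees_with_scalar(self, stature_in):
        ys = np.array([52.0, 54.5, 58.0, 61.49, 70.0])
        vec = od.assign_score(ys, stature_in)
        assert vec.tolist() == [od.assign_score(v, stature_in) for v in ys]


PRINTED_P = {
    0.0: [.0306, .0595, .122, .182, .212, .182, .122, .0595, .0306],
    2.0: [.0016, .0064, .0226, .0595, .122, .182, .212, .182, .212],
    4.0: [.00003, .00023, .00134, .0064, .0226, .0595, .122, .182, .606],
}


class TestCategoryProbabilities:
    @pytest.mark.parametrize("delta", [0.0, 2.0, 4.0])
    def test_printed_probability_vectors(self, model_in, stature_in, delta):
        dist = od.category_probabilities(model_in, stature_in.with_delta(delta))
        # printed values carry the source's rounding of the normal quantiles
        assert np.allclose(dist.p, PRINTED_P[delta], atol=2e-3)

    def test_probabilities_sum_to_one(self, model_in, stature_in):
        for d in (0.0, 1.3, 7.0):
            dist = od.category_probabilities(model_in, stature_in.with_delta(d))
            assert abs(dist.p.sum() - 1.0) < 1e-12

    def test_two_categories_at_mean_split_evenly(self):
        m = od.LatentTraitModel.from_h2(0.0, 1.0, 0.4)
        ts = od.make_equal_interval_thresholds(0.0, 1.0, 2)
        dist = od.category_probabilities(m, ts)
        assert np.allclose(dist.p, [0.5, 0.5])

    def test_delta_equivalent_to_mean_shift(self, model_in, stature_in):
        """Shifting thresholds down by delta == raising the mean by delta."""
        a = od.category_probabilities(model_in, stature_in.with_delta(3.0))
        shifted_model = od.LatentTraitModel(model_in.mu + 3.0, model_in.sigma_u2,
                                            model_in.sigma_e2, model_in.unit)
        b = od.category_probabilities(shifted_model, stature_in)
        assert np.allclose(a.p, b.p, atol=1e-14)

    def test_refuses_mixed_units(self, model_in, stature_cm):
        with pytest.raises(ValueError, match="mixed units"):
            od.category_probabilities(model_in, stature_cm)

    def test_ceiling_effect_monotone_in_delta(self, model_in, stature_in):
        top = [od.category_probabilities(model_in, stature_in.with_delta(d)).p[-1]
               for d in np.linspace(0, 8, 17)]
        assert np.all(np.diff(top) >= 0)

    def test_empirical_frequencies_match_analytic(self, model_in, stature_in):
        rng = np.random.default_rng(123)
        n = 10**6
        y = rng.normal(model_in.mu, model_in.sigma_y, n)
        for d in (0.0, 2.0):
            ts = stature_in.with_delta(d)
            s = od.assign_score(y, ts)
            freq = np.bincount(s, minlength=10)[1:] / n
            p = od.category_probabilities(model_in, ts).p
            tol = 3 * np.sqrt(p * (1 - p) / n)
            assert np.all(np.abs(freq - p) <= tol + 1e-12)


class TestScoreMoments:
    def test_symmetric_case_mean_is_central_score(self, model_in, stature_in):
        dist = od.category_probabilities(model_in, stature_in)
        mean, var, m2 = od.score_moments(dist)
        assert mean == pytest.approx(5.0, abs=1e-10)
        assert var == pytest.approx(3.39, abs=5e-3)
        assert m2 == pytest.approx(28.39, abs=5e-3)

    def test_shifted_moments(self, model_in, stature_in):
        dist = od.category_probabilities(model_in, stature_in.with_delta(2.0))
        mean, var, _ = od.score_moments(dist)
        assert mean == pytest.approx(6.869, abs=1e-3)
        assert var == pytest.approx(2.80, abs=5e-3)


class TestScorePhenotypeCorrelation:
    def test_closed_form_matches_monte_carlo(self, model_in, stature_in):
        for d in (0.0, 4.0):
            ts = stature_in.with_delta(d)
            cf, _ = od.score_phenotype_correlation(model_in, ts)
            mc, rho = od.score_phenotype_correlation(
                model_in, ts, "monte_carlo", n_mc=400_000, seed=5)
            assert cf == pytest.approx(mc, abs=0.003)
            assert rho is not None

    def test_binary_split_reduces_to_two_over_pi(self):
        m = od.LatentTraitModel.from_h2(0.0, 1.0, 0.4)
        ts = od.make_equal_interval_thresholds(0.0, 1.0, 2)
        r2, _ = od.score_phenotype_correlation(m, ts)
        assert r2 == pytest.approx(2 / np.pi, rel=1e-12)

    def test_unknown_method_rejected(self, model_in, stature_in):
        with pytest.raises(ValueError):
            od.score_phenotype_correlation(model_in, stature_in, "exact")


class TestEqualIntervalBinner:
    def test_transform_matches_assign_score(self, stature_in):
        y = np.linspace(50, 66, 40)
        binner = od.EqualIntervalBinner(center=58, width=1, k=9).fit(y)
        assert np.array_equal(binner.transform(y), od.assign_score(y, stature_in))

    def test_rescale_and_delta_parameters(self):
        binner = od.EqualIntervalBinner(center=58, width=1, k=9, delta=2.0,
                                        rescale=5.0)
        out = binner.fit_transform(np.array([58.0]))
        assert out[0] == 35.0  # score 7 on the shifted grid, times 5

    def test_sklearn_param_interface(self):
        binner = od.EqualIntervalBinner()
        assert binner.get_params()["k"] == 9
        binner.set_params(k=5, delta=1.0)
        assert binner.fit(np.zeros(1)).thresholds_.k == 5


@settings(derandomize=True, deadline=None, max_examples=60)
@given(mu=st.floats(-30, 30), sigma=st.floats(0.3, 8), delta=st.floats(0, 6),
       k=st.integers(2, 15))
def test_probability_invariants_hold_for_any_configuration(mu, sigma, delta, k):
    """Probabilities are a distribution and delta-shift equals mean-shift."""
    model = od.LatentTraitModel.from_h2(mu, sigma, 0.43)
    ts = od.make_equal_interval_thresholds(0.0, 1.0, k, delta=delta)
    dist = od.category_probabilities(model, ts)
    assert abs(dist.p.sum() - 1.0) < 1e-9
    assert dist.var >= -1e-12
    shifted = od.LatentTraitModel.from_h2(mu + delta, sigma, 0.43)
    ref = od.category_probabilities(shifted, ts.with_delta(0.0))
    assert np.allclose(dist.p, ref.p, atol=1e-12)
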