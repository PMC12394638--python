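import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from personet.bootstrap_infer import (BootstrapDraws, bootstrap_edges,
                                      bootstrap_network_draws,
                                      case_dropping_stability,
                                      difference_test, make_pseudo_subjects,
                                      quantile_type6)
from personet.model_core import ModelParams, params_to_vector


class TestQuantileType6:
    @pytest.mark.parametrize("prob, expected", [
        (0.5, 5.5), (0.25, 2.75), (0.75, 8.25), (0.0, 1.0), (1.0, 10.0),
    ])
    def test_one_to_ten(self, prob, expected):
        assert quantile_type6(np.arange(1, 11), prob) == \
            pytest.approx(expected, abs=1e-12)

    def test_single_value_clamps(self):
        for prob in (0.0, 0.3, 1.0):
            assert quantile_type6([7.0], prob) == 7.0

    def test_empty_sample(self):
        with pytest.raises(ValueError, match="empty"):
            quantile_type6([], 0.5)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=40),
           st.floats(0, 1))
    def test_matches_weibull_plotting_position(self, values, prob):
        # np.quantile's "weibull" method is the (m+1)p plotting position,
        # an independent implementation of the same estimator
        ours = quantile_type6(values, prob)
        ref = float(np.quantile(np.array(values), prob, method="weibull"))
        assert ours == pytest.approx(ref, abs=1e-9)


class TestPseudoSubjects:
    def test_numeric_plus_four_binary_gives_sixteen(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(31.5, 8.4, 50)]
                            + [rng.integers(0, 2, 50) for _ in range(4)])
        subs = make_pseudo_subjects(X, ["numeric"] + ["binary"] * 4)
        assert len(subs) == 16
        for s in subs:
            assert s.profile[0] == pytest.approx(X[:, 0].mean())
            assert np.isin(s.profile[1:], (0, 1)).all()

    def test_all_numeric_single_profile(self):
        X = np.random.default_rng(1).normal(size=(20, 2))
        subs = make_pseudo_subjects(X, ["numeric", "numeric"])
        assert len(subs) == 1
        np.testing.assert_allclose(subs[0].profile, X.mean(axis=0))

    def test_two_binary_big_endian_order(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0]])
        subs = make_pseudo_subjects(X, ["binary", "binary"])
        profiles = [tuple(s.profile) for s in subs]
        assert profiles == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_guard_against_blowup(self):
        X = np.zeros((5, 13))
        with pytest.raises(ValueError, match="13 binary"):
            make_pseudo_subjects(X, ["binary"] * 13)


class TestDifferenceTest:
    def test_identical_draws(self):
        d = np.arange(10.0)
        res = difference_test(d, d)
        assert res == {"ci_low": 0.0, "ci_high": 0.0, "reject": False}

    def test_constant_shift_rejects(self):
        d = np.random.default_rng(2).normal(size=50)
        res = difference_test(d + 10, d)
        assert res["ci_low"] == pytest.approx(10.0)
        assert res["ci_high"] == pytest.approx(10.0)
        assert res["reject"]

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            difference_test([1.0, 2.0], [1.0])

    def test_null_calibration(self):
        # Monte-Carlo null calibration: draws centered at estimates that
        # themselves fluctuate with matching variance (the consistent-
        # bootstrap regime) reject at about the nominal 5% level
        rng = np.random.default_rng(3)
        rejections = []
        for _ in range(400):
            a_hat, b_hat = rng.normal(size=2)  # truly-equal quantities
            draws_a = a_hat + rng.normal(size=500)
            draws_b = b_hat + rng.normal(size=500)
            rejections.append(difference_test(draws_a, draws_b)["reject"])
        rate = np.mean(rejections)
        assert 0.02 < rate < 0.09

    def test_centered_draws_never_reject(self):
        # the quantile CI of centered difference draws virtually always
        # contains zero: independent zero-mean draw vectors do not reject
        rng = np.random.default_rng(4)
        rejections = [difference_test(rng.normal(size=500),
                                      rng.normal(size=500))["reject"]
                      for _ in range(100)]
        assert np.mean(rejections) < 0.02


def _constant_estimator(params):
    class _Fit:
        pass

    def estimator(panel, eta):
        f = _Fit()
        f.params = params
        return f
    return estimator


def _moment_estimator():
    """Deterministic, data-dependent stand-in for the eLasso fit."""
    class _Fit:
        pass

    def estimator(panel, eta):
        prev = panel.y[:, :-1, :].reshape(-1, panel.n_symptoms).astype(float)
        nxt = panel.y[:, 1:, :].reshape(-1, panel.n_symptoms).astype(float)
        f = _Fit()
        p, d = panel.n_symptoms, panel.n_covariates
        f.params = ModelParams(np.zeros(p), np.zeros((p, d)),
                               nxt.T @ prev / len(prev), np.zeros((p, p, d)))
        return f
    return estimator


class TestBootstrapDraws:
    def test_constant_estimator_zero_width_cis(self, ring_panel):
        params = ModelParams.zeros(10, 0)
        params.sigma1[0, 1] = 0.7
        draws = bootstrap_edges(ring_panel, B=10, seed=0,
                                estimator=_constant_estimator(params))
        lo, hi = draws.ci()
        np.testing.assert_array_equal(lo, hi)
        np.testing.assert_allclose(lo, params_to_vector(params))

    def test_deterministic_with_seed(self, ring_panel):
        est = _moment_estimator()
        a = bootstrap_edges(ring_panel, B=5, seed=7, estimator=est)
        b = bootstrap_edges(ring_panel, B=5, seed=7, estimator=est)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.B == 5

    def test_centrality_draw_labels(self, ring_panel):
        est = _moment_estimator()
        subs = make_pseudo_subjects(ring_panel.X, [])
        params, cents = bootstrap_network_draws(ring_panel, B=3, seed=1,
                                                profiles=subs, estimator=est)
        assert cents.draws.shape == (3, 3 * 1 * 10)
        assert cents.labels[0] == "in_strength[ps:Y1]"

    def test_rejects_tiny_B(self, ring_panel):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_edges(ring_panel, B=1, seed=0)


class TestCaseDropping:
    def test_no_dropping_with_deterministic_estimator(self, ring_panel):
        est = _moment_estimator()
        res = case_dropping_stability(ring_panel, proportions=(1.0,), B=3,
                                      seed=0, estimator=est)
        for (prop, metric), cors in res.correlations.items():
            np.testing.assert_allclose(cors, 1.0, atol=1e-12)

    def test_minimum_subject_guard(self, ring_panel):
        with pytest.raises(ValueError, match="minimum"):
            case_dropping_stability(ring_panel, proportions=(0.01,), B=2,
                                    seed=0, estimator=_moment_estimator())

    def test_summary_shape(self, ring_panel):
        est = _moment_estimator()
        res = case_dropping_stability(ring_panel, proportions=(0.9, 0.5),
                                      B=4, seed=2, estimator=est)
        df = res.summary()
        assert len(df) == 2 * 3  # proportions x metrics
        assert set(df["metric"]) == {"in_strength", "out_strength",
                                     "betweenness"}
        assert df["mean_correlation"].between(-1, 1).all()
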