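"""Unit and property tests for the MSP, energy and Mahalanobis scores.

The brute-force oracles here are deliberately naive re-implementations
(python loops, math.exp) kept independent of the vectorized code paths they
check.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oodeval import (
    EnergyConfig,
    EnergyDetector,
    FeatureTable,
    LinearAdapter,
    MahalanobisDetector,
    MSPDetector,
    energy,
    energy_confidence,
    fit_gaussian_model,
    mahalanobis_confidence,
    msp_confidence,
    score_dataset,
)

# ------------------------------------------------------------------ oracles


def _msp_oracle(logits):
    exps = [math.exp(v) for v in logits]
    return max(exps) / sum(exps)


def _energy_oracle(logits, T=1.0):
    return -T * math.log(sum(math.exp(v / T) for v in logits))


def _mah_oracle(x, means, cov_inv):
    best = None
    for mu in means:
        diff = [xi - mi for xi, mi in zip(x, mu)]
        d2 = 0.0
        for i in range(len(diff)):
            for j in range(len(diff)):
                d2 += diff[i] * cov_inv[i][j] * diff[j]
        if best is None or d2 < best:
            best = d2
    return -best


def _pooled_cov_oracle(X, y):
    """Sum of within-class scatter matrices divided by the total count."""
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    S = np.zeros((d, d))
    for c in set(y):
        Xc = X[np.asarray(y) == c]
        mu = Xc.mean(axis=0)
        for row in Xc:
            diff = (row - mu)[:, None]
            S += diff @ diff.T
    return S / len(X)


# ------------------------------------------------------------------- values


class TestMSP:
    def test_uniform_logits_give_one_over_c(self):
        assert msp_confidence([0.0, 0.0, 0.0, 0.0]) == pytest.approx(0.25, abs=1e-12)

    def test_hand_evaluated_example(self):
        # e^{ln 2} / (2 + 1 + 1) = 0.5
        assert msp_confidence([math.log(2), 0.0, 0.0]) == pytest.approx(0.5, abs=1e-12)

    def test_shift_invariance(self, rng):
        logits = rng.normal(size=6)
        assert msp_confidence(logits + 1000.0) == pytest.approx(
            msp_confidence(logits), abs=1e-12
        )

    def test_matches_bruteforce_on_small_instances(self, rng):
        for _ in range(20):
            logits = rng.normal(size=rng.integers(2, 6)).tolist()
            assert msp_confidence(logits) == pytest.approx(
                _msp_oracle(logits), abs=1e-9
            )

    def test_overflow_safety(self):
        out = msp_confidence([1000.0, 0.0])
        assert 0 < out <= 1

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=10))
    @settings(deadline=None)
    def test_range_bounds(self, logits):
        c = len(logits)
        v = msp_confidence(logits)
        assert 1 / c - 1e-12 <= v <= 1 + 1e-12

    def test_attains_floor_iff_constant(self, rng):
        assert msp_confidence([3.0] * 5) == pytest.approx(0.2, abs=1e-12)
        logits = rng.normal(size=5)
        logits[0] += 0.1
        assert msp_confidence(logits) > 0.2

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            msp_confidence([np.nan, 0.0])
        with pytest.raises(ValueError):
            msp_confidence([np.inf, 0.0])


class TestEnergy:
    def test_zero_logits_give_minus_log_c(self):
        assert energy([0.0, 0.0, 0.0]) == pytest.approx(-math.log(3), abs=1e-12)

    def test_direct_evaluation(self):
        assert energy([10.0, 0.0]) == pytest.approx(
            -math.log(math.exp(10) + 1), abs=1e-9
        )

    def test_matches_bruteforce(self, rng):
        for _ in range(20):
            logits = rng.normal(size=rng.integers(2, 6)).tolist()
            T = float(rng.uniform(0.1, 5.0))
            assert energy(logits, T) == pytest.approx(
                _energy_oracle(logits, T), abs=1e-9
            )

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=8))
    @settings(deadline=None)
    def test_logsumexp_bounds(self, logits):
        e = energy(logits)
        hi = -max(logits)
        lo = hi - math.log(len(logits))
        assert lo - 1e-9 <= e <= hi + 1e-9

    def test_low_temperature_recovers_max_logit_ranking(self, rng):
        logit_sets = rng.normal(size=(50, 7))
        conf = np.asarray([energy_confidence(l, 1e-3) for l in logit_sets])
        max_logit = logit_sets.max(axis=1)
        assert np.array_equal(np.argsort(conf), np.argsort(max_logit))

    def test_overflow_safety(self):
        assert np.isfinite(energy([800.0, -800.0]))

    def test_rejects_bad_temperature(self):
        with pytest.raises(ValueError):
            energy([1.0, 2.0], 0.0)
        with pytest.raises(ValueError):
            EnergyConfig(temperature=-1.0)


class TestGaussianFit:
    def test_pooled_covariance_matches_scatter_oracle(self):
        X = np.array(
            [[0.0, 0.0], [2.0, 0.0], [1.0, 3.0], [5.0, 5.0], [7.0, 5.0], [6.0, 8.0]]
        )
        y = [0, 0, 0, 1, 1, 1]
        model = fit_gaussian_model(X, y, reg_eps=0.0)
        np.testing.assert_allclose(model.covariance, _pooled_cov_oracle(X, y), atol=1e-12)
        np.testing.assert_allclose(model.means[0], X[:3].mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(model.means[1], X[3:].mean(axis=0), atol=1e-12)

    def test_parameter_recovery_within_sampling_error(self, rng):
        true_means = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
        n = 50
        X = np.vstack([m + rng.normal(size=(n, 2)) for m in true_means])
        y = np.repeat([0, 1, 2], n)
        model = fit_gaussian_model(X, y)
        # per-coordinate error bounded by 3 sigma / sqrt(n)
        assert np.all(np.abs(model.means - true_means) < 3 / math.sqrt(n))

    def test_degenerate_point_classes_need_regularization(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0], [5.0, 5.0]])
        y = [0, 0, 1, 1]
        model = fit_gaussian_model(X, y, reg_eps=1e-6)
        np.testing.assert_allclose(model.covariance, np.zeros((2, 2)), atol=1e-12)
        with pytest.raises(np.linalg.LinAlgError):
            fit_gaussian_model(X, y, reg_eps=0.0)

    def test_singleton_class_rejected_by_name(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="2"):
            fit_gaussian_model(X, [0, 0, 2])

    def test_per_class_covariance_option(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        model = fit_gaussian_model(X, y, tied=False)
        assert model.covariance.shape == (2, 3, 3)
        assert model.precision.shape == (2, 3, 3)


class TestMahalanobis:
    def test_zero_at_class_mean(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.repeat([0, 1, 2], 10)
        model = fit_gaussian_model(X, y)
        for mu in model.means:
            assert mahalanobis_confidence(mu, model) == pytest.approx(0.0, abs=1e-9)

    def test_identity_covariance_gives_squared_euclidean(self):
        from oodeval import GaussianClassModel

        model = GaussianClassModel(
            means=np.array([[0.0, 1.0], [10.0, 1.0]]),
            covariance=np.eye(2),
            precision=np.eye(2),
            reg_eps=0.0,
        )
        # nearest mean at euclidean distance 2 -> confidence -4
        assert mahalanobis_confidence([0.0, 3.0], model) == pytest.approx(-4.0)

    def test_class_order_invariance(self, rng):
        X = rng.normal(size=(40, 4))
        y = np.repeat([0, 1, 2, 3], 10)
        model = fit_gaussian_model(X, y)
        perm = [2, 0, 3, 1]
        from oodeval import GaussianClassModel

        permuted = GaussianClassModel(
            means=model.means[perm],
            covariance=model.covariance,
            precision=model.precision,
            reg_eps=model.reg_eps,
        )
        x = rng.normal(size=4)
        assert mahalanobis_confidence(x, model) == pytest.approx(
            mahalanobis_confidence(x, permuted), abs=1e-12
        )

    def test_never_positive(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        model = fit_gaussian_model(X, y)
        scores = mahalanobis_confidence(rng.normal(size=(100, 3)), model)
        assert np.all(scores <= 0)

    def test_matches_bruteforce_2d(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.repeat([0, 1], 10)
        model = fit_gaussian_model(X, y)
        cov_inv = model.precision.tolist()
        means = model.means.tolist()
        for x in rng.normal(size=(10, 2)):
            assert mahalanobis_confidence(x, model) == pytest.approx(
                _mah_oracle(x.tolist(), means, cov_inv), abs=1e-9
            )

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        model = fit_gaussian_model(X, np.repeat([0, 1], 10))
        with pytest.raises(ValueError):
            mahalanobis_confidence([1.0, 2.0], model)


# --------------------------------------------------------------- estimators


class TestDetectorEstimators:
    def test_sklearn_params_roundtrip(self):
        det = EnergyDetector(temperature=2.0)
        assert det.get_params() == {"temperature": 2.0}
        det.set_params(temperature=0.5)
        assert det.temperature == 0.5
        mah = MahalanobisDetector(reg_eps=1e-4, tied_covariance=False)
        assert mah.get_params() == {"reg_eps": 1e-4, "tied_covariance": False}

    def test_detectors_agree_with_functions(self, rng):
        logits = rng.normal(size=(30, 5))
        np.testing.assert_allclose(
            MSPDetector().fit(logits).score_samples(logits), msp_confidence(logits)
        )
        np.testing.assert_allclose(
            EnergyDetector(1.5).fit(logits).score_samples(logits),
            energy_confidence(logits, 1.5),
        )
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        det = MahalanobisDetector().fit(X, y)
        model = fit_gaussian_model(X, y)
        np.testing.assert_allclose(
            det.score_samples(X), mahalanobis_confidence(X, model)
        )

    def test_unfitted_mahalanobis_raises(self, rng):
        with pytest.raises(RuntimeError):
            MahalanobisDetector().score_samples(rng.normal(size=(3, 2)))


class TestScoreDataset:
    def test_empty_table_gives_empty_set(self, random_linear_adapter):
        empty = FeatureTable(
            ids=np.asarray([], dtype=object),
            domain=np.asarray([], dtype=object),
            labels=np.asarray([], dtype=object),
            features=np.empty((0, 4)),
        )
        out = score_dataset(empty, random_linear_adapter, "MSP")
        assert len(out) == 0

    def test_batch_equals_elementwise(self, small_id_table, random_linear_adapter):
        conf = score_dataset(small_id_table, random_linear_adapter, "MSP")
        expected = [
            msp_confidence(random_linear_adapter.logits(row))
            for row in small_id_table.features
        ]
        np.testing.assert_allclose(conf.scores, expected, atol=1e-12)

    def test_msp_ebm_do_not_depend_on_fitting_data(
        self, small_id_table, random_linear_adapter
    ):
        model = fit_gaussian_model(
            small_id_table.features, small_id_table.label_array()
        )
        for method in ("MSP", "EBM"):
            with_model = score_dataset(
                small_id_table, random_linear_adapter, method, model=model
            )
            without = score_dataset(small_id_table, random_linear_adapter, method)
            np.testing.assert_array_equal(with_model.scores, without.scores)

    def test_mah_requires_model(self, small_id_table, random_linear_adapter):
        with pytest.raises(ValueError, match="Gaussian"):
            score_dataset(small_id_table, random_linear_adapter, "MAH")

    def test_unknown_method_rejected(self, small_id_table, random_linear_adapter):
        with pytest.raises(ValueError):
            score_dataset(small_id_table, random_linear_adapter, "ODIN")
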