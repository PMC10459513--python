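"""Bayesian spike-count decoding: fitting, likelihoods, posteriors, evaluation."""

import math
from fractions import Fraction

import numpy as np
import pytest

from spikewire.inference import (
    ClassConditionalModel,
    evaluate,
    fit_model,
    poisson_pmf,
    posterior,
)


def exact_poisson(s: int, lam: float) -> float:
    """Independent oracle: lam^s e^-lam / s! in exact rational arithmetic."""
    if lam == 0:
        return 1.0 if s == 0 else 0.0
    return float(Fraction(lam).limit_denominator(10**12) ** s / math.factorial(s)) * math.exp(-lam)


def decode_oracle(prior, lam, counts):
    """Direct non-log enumeration of the decoding chain: per-neuron scores
    prior * pmf normalized over classes, combined with spike-share neuron
    weights, renormalized over classes."""
    n_classes, n_neurons = prior.shape
    per_neuron = np.zeros((n_classes, n_neurons))
    for j in range(n_neurons):
        scores = [prior[i, j] * exact_poisson(int(counts[j]), lam[i, j])
                  for i in range(n_classes)]
        per_neuron[:, j] = np.array(scores) / sum(scores)
    total = counts.sum()
    w = counts / total if total > 0 else np.full(n_neurons, 1 / n_neurons)
    class_score = per_neuron @ w
    return class_score / class_score.sum()


class TestFitModel:
    def test_lambda_is_class_mean(self):
        counts = np.array([[3.0], [5.0]])
        model = fit_model(counts, np.array([0, 0]))
        assert model.lam[0, 0] == pytest.approx(4.0)

    def test_silent_neuron_gets_uniform_prior(self):
        counts = np.array([[0.0, 4.0], [0.0, 1.0], [0.0, 0.0], [0.0, 2.0]])
        model = fit_model(counts, np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(model.prior[:, 0], 0.5)
        assert model.lam[0, 0] == model.epsilon  # floored

    def test_prior_columns_sum_to_one(self, rng):
        counts = rng.poisson(3, size=(40, 6)).astype(float)
        labels = rng.integers(0, 3, size=40)
        while len(np.unique(labels)) < 3:
            labels = rng.integers(0, 3, size=40)
        model = fit_model(counts, labels)
        np.testing.assert_allclose(model.prior.sum(axis=0), 1.0, rtol=1e-12)

    def test_missing_class_raises(self):
        with pytest.raises(ValueError, match="class"):
            fit_model(np.ones((2, 3)), np.array([0, 2]))

    def test_gaussian_family_floors_sigma(self):
        counts = np.array([[5.0], [5.0]])  # zero variance
        model = fit_model(counts, np.array([0, 0]), family="gaussian")
        assert model.sigma[0, 0] == 0.5

    def test_parameter_recovery_from_known_rates(self, rng):
        lam_true = 7.0
        n = 2000
        counts = rng.poisson(lam_true, size=(n, 1)).astype(float)
        model = fit_model(counts, np.zeros(n, dtype=int))
        se = math.sqrt(lam_true / n)
        assert abs(model.lam[0, 0] - lam_true) < 3 * se


class TestPoissonPmf:
    def test_closed_form_values(self):
        assert poisson_pmf(0, 1.0) == pytest.approx(math.exp(-1), rel=1e-12)
        assert poisson_pmf(0, 0.0) == 1.0
        assert poisson_pmf(3, 2.5) == pytest.approx(exact_poisson(3, 2.5), rel=1e-10)

    def test_normalization(self):
        s = np.arange(0, 200)
        assert poisson_pmf(s, 5.0).sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_count_raises(self):
        with pytest.raises(ValueError):
            poisson_pmf(-1, 2.0)
        with pytest.raises(ValueError):
            poisson_pmf(2, -1.0)

    @pytest.mark.parametrize("lam", [0.5, 5.0, 50.0])
    @pytest.mark.parametrize("s", [0, 3, 25, 200])
    def test_log_space_matches_exact_arithmetic(self, lam, s):
        assert poisson_pmf(s, lam) == pytest.approx(
            exact_poisson(s, lam), rel=1e-10, abs=1e-300
        )


class TestPosterior:
    def test_matches_enumeration_oracle(self):
        prior = np.array([[0.7, 0.2], [0.3, 0.8]])
        lam = np.array([[4.0, 1.0], [0.5, 6.0]])
        model = ClassConditionalModel(lam, prior)
        for counts in ([3.0, 0.0], [0.0, 5.0], [2.0, 2.0], [0.0, 0.0]):
            counts = np.array(counts)
            pred = posterior(model, counts)
            np.testing.assert_allclose(
                pred.posterior, decode_oracle(prior, lam, counts), atol=1e-12
            )
            assert pred.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_neuron_strong_likelihood_wins(self):
        model = ClassConditionalModel(
            lam=np.array([[10.0], [1.0]]), prior=np.array([[0.5], [0.5]])
        )
        assert posterior(model, np.array([9.0])).label == 0

    def test_symmetric_model_gives_uniform_posterior_lowest_label(self):
        model = ClassConditionalModel(
            lam=np.full((3, 4), 2.0), prior=np.full((3, 4), 1 / 3)
        )
        pred = posterior(model, np.array([1.0, 3.0, 0.0, 2.0]))
        np.testing.assert_allclose(pred.posterior, 1 / 3, rtol=1e-12)
        assert pred.label == 0

    def test_dimension_mismatch_raises(self):
        model = ClassConditionalModel(lam=np.ones((2, 3)), prior=np.full((2, 3), 0.5))
        with pytest.raises(ValueError, match="shape"):
            posterior(model, np.zeros(4))

    def test_poisson_beats_gaussian_on_low_counts(self):
        """Directional check on sparse counts (lambda <= 3): averaged over
        seeded draws, the Poisson family decodes synthetic population
        responses better than the Gaussian family with its floored
        standard deviations."""
        acc = {"poisson": [], "gaussian": []}
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            n_classes, n_neurons = 4, 20
            lam = np.full((n_classes, n_neurons), 0.1)
            for i in range(n_classes):
                lam[i, rng.choice(n_neurons, 4, replace=False)] = rng.uniform(
                    1.0, 3.0, 4
                )
            labels = rng.integers(0, n_classes, size=200)
            counts = rng.poisson(lam[labels]).astype(float)
            test_labels = rng.integers(0, n_classes, size=300)
            test_counts = rng.poisson(lam[test_labels]).astype(float)
            for family in ("poisson", "gaussian"):
                model = fit_model(counts, labels, family=family)
                preds = [posterior(model, c).label for c in test_counts]
                acc[family].append(np.mean(np.array(preds) == test_labels))
        assert np.mean(acc["poisson"]) > np.mean(acc["gaussian"])


@pytest.fixture(scope="module")
def tiny_setup():
    from spikewire.data_io import generate_synthetic_dataset
    from spikewire.network import NetworkConfig
    from spikewire.training import train_and_fit

    ds = generate_synthetic_dataset(2, 8, rng=np.random.default_rng(0))
    cfg = NetworkConfig(n_neurons=10, rng_seed=3)
    result = train_and_fit(cfg, list(ds), rng=np.random.default_rng(5))
    return result, list(ds)


class TestEvaluate:
    def test_report_carries_mean_and_sd(self, tiny_setup):
        result, samples = tiny_setup
        report = evaluate(result.model, result.network, samples, repetitions=2, rng=1)
        assert 0.0 <= report.mean_accuracy <= 1.0
        assert report.sd_accuracy >= 0.0
        assert report.confusion.sum() == 2 * len(samples)

    def test_single_repetition_has_zero_sd(self, tiny_setup):
        result, samples = tiny_setup
        report = evaluate(result.model, result.network, samples, repetitions=1, rng=1)
        assert report.sd_accuracy == 0.0

    def test_same_seed_reproduces_accuracy(self, tiny_setup):
        result, samples = tiny_setup
        a = evaluate(result.model, result.network, samples, repetitions=2, rng=11)
        b = evaluate(result.model, result.network, samples, repetitions=2, rng=11)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)

    def test_empty_test_set_raises(self, tiny_setup):
        result, _ = tiny_setup
        with pytest.raises(ValueError, match="empty"):
            evaluate(result.model, result.network, [], repetitions=1, rng=0)
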