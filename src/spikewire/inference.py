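"""Bayesian decoding of per-neuron spike counts.

During training, the spike counts each first-layer neuron produces for each
class are re-modeled as Poisson: lambda[i, j] is the expected count of
neuron j under class i, and a per-neuron prior P(c_i | n_j) records how
often neuron j responds to class i.  At test time the class-conditional
likelihood of the observed count vector s is combined with the priors:

    P(c_i | s_j, n_j)  ~  P(c_i | n_j) * P(s_j | c_i, n_j)      (per neuron)
    P(c_i | s)         =  sum_j P(n_j, c_i | s)                 (population)

with each neuron given equal weight; the predicted label is the argmax
class.  A Gaussian count model is provided for comparison — with the low,
integer spike counts of a 350 ms window the Poisson family is the better
fit, and the comparison quantifies that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ClassConditionalModel",
    "Prediction",
    "EvaluationReport",
    "fit_model",
    "poisson_pmf",
    "posterior",
    "evaluate",
]


@dataclass
class ClassConditionalModel:
    """Per-(class, neuron) spike-count model with responsiveness priors.

    ``lam[i, j]`` is the expected spike count of neuron j under class i
    (floored at ``epsilon`` to avoid zero-likelihood lockout); ``prior[i, j]``
    is the Laplace-smoothed probability that a spike response of neuron j
    belongs to class i, normalized over classes per neuron.  The Gaussian
    family additionally stores per-(class, neuron) standard deviations.
    """

    lam: np.ndarray
    prior: np.ndarray
    family: str = "poisson"
    sigma: np.ndarray | None = None
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.lam.shape != self.prior.shape:
            raise ValueError("lam and prior shapes differ")
        if self.family == "gaussian" and self.sigma is None:
            raise ValueError("gaussian family requires sigma")

    @property
    def n_classes(self) -> int:
        return self.lam.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.lam.shape[1]


@dataclass
class Prediction:
    """Posterior class probabilities and the argmax label."""

    posterior: np.ndarray
    label: int


@dataclass
class EvaluationReport:
    """Accuracy over repeated seeded test passes, with a confusion matrix."""

    accuracies: np.ndarray
    confusion: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies))


def fit_model(
    counts: np.ndarray,
    labels: np.ndarray,
    family: str = "poisson",
    epsilon: float = 1e-3,
    sigma_floor: float = 0.5,
    alpha: float = 1.0,
) -> ClassConditionalModel:
    """Fit the class-conditional count model from labeled training counts.

    Parameters
    ----------
    counts : (n_samples, n_neurons) array
        Per-presentation spike counts of the first layer.
    labels : (n_samples,) integer class labels covering 0..C-1.
    family : "poisson" or "gaussian".
    epsilon : floor applied to the estimated rates.
    sigma_floor : floor on the Gaussian standard deviations.
    alpha : Laplace smoothing count for the responsiveness priors.
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels)
    if counts.ndim != 2 or counts.shape[0] != labels.shape[0]:
        raise ValueError("counts must be (n_samples, n_neurons) matching labels")
    classes = np.arange(labels.max() + 1)
    n_classes, n_neurons = classes.size, counts.shape[1]

    lam = np.empty((n_classes, n_neurons))
    responded = np.empty((n_classes, n_neurons))
    sigma = np.empty((n_classes, n_neurons))
    for i in classes:
        members = counts[labels == i]
        if members.shape[0] == 0:
            raise ValueError(f"no training samples for class {i}")
        lam[i] = members.mean(axis=0)
        responded[i] = (members >= 1).sum(axis=0)
        sigma[i] = members.std(axis=0)

    lam = np.maximum(lam, epsilon)
    prior = (responded + alpha) / (responded + alpha).sum(axis=0, keepdims=True)
    if family == "gaussian":
        sigma = np.maximum(sigma, sigma_floor)
        return ClassConditionalModel(lam, prior, "gaussian", sigma, epsilon)
    return ClassConditionalModel(lam, prior, "poisson", None, epsilon)


def poisson_pmf(s, lam):
    """Poisson probability lam^s e^{-lam} / s! evaluated via log space.

    Vectorized; ``lam = 0, s = 0`` returns 1 (degenerate point mass).
    """
    s_arr = np.asarray(s)
    if np.any(s_arr < 0) or not np.all(np.equal(np.mod(s_arr, 1), 0)):
        raise ValueError("spike count must be a non-negative integer")
    if np.any(np.asarray(lam) < 0):
        raise ValueError("rate must be non-negative")
    out = np.exp(stats.poisson.logpmf(s_arr, lam))
    return float(out) if np.isscalar(s) and np.isscalar(lam) else out


def _log_likelihood(model: ClassConditionalModel, counts: np.ndarray) -> np.ndarray:
    """(n_classes, n_neurons) log-likelihood of the observed counts."""
    if model.family == "poisson":
        return stats.poisson.logpmf(counts[None, :], model.lam)
    return stats.norm.logpdf(counts[None, :], model.lam, model.sigma)


def posterior(model: ClassConditionalModel, counts: np.ndarray) -> Prediction:
    """Decode a spike-count vector into class posterior probabilities.

    Per neuron, the unnormalized class score is prior * likelihood
    (accumulated in log space and normalized over classes within the
    neuron); the per-neuron posteriors are then combined over the
    population weighted by each neuron's share of the observed spikes —
    the estimate of the neuron-attribution term P(n_j | s), so neurons
    that did not fire carry no vote.  If no neuron fired, all neurons are
    weighted equally.  Ties resolve to the lowest class index.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (model.n_neurons,):
        raise ValueError(
            f"counts has shape {counts.shape}, expected ({model.n_neurons},)"
        )
    log_score = np.log(model.prior) + _log_likelihood(model, counts)
    # normalize over classes within each neuron (log-softmax per column)
    per_neuron = np.exp(log_score - logsumexp(log_score, axis=0, keepdims=True))
    total = counts.sum()
    if total > 0:
        neuron_weight = counts / total
    else:
        neuron_weight = np.full(model.n_neurons, 1.0 / model.n_neurons)
    class_score = per_neuron @ neuron_weight
    post = class_score / class_score.sum()
    return Prediction(post, int(np.argmax(post)))


def evaluate(
    model: ClassConditionalModel,
    network,
    test_samples,
    repetitions: int = 10,
    rng: np.random.Generator | int | None = None,
) -> EvaluationReport:
    """Frozen-network test passes: accuracy mean/SD over seeded repetitions.

    Each repetition re-presents every test sample with fresh Poisson
    encodings (plasticity, wiring and threshold adaptation all frozen) and
    decodes the first-layer counts.  The confusion matrix accumulates over
    all repetitions (rows = true class, columns = predicted).
    """
    test_samples = list(test_samples)
    if not test_samples:
        raise ValueError("test set is empty")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = np.random.default_rng(rng)

    c = model.n_classes
    confusion = np.zeros((c, c), dtype=np.int64)
    accuracies = np.empty(repetitions)
    for r in range(repetitions):
        correct = 0
        for sample in test_samples:
            rec1, _ = network.present(sample, rng, learn=False)
            pred = posterior(model, rec1.counts.astype(float))
            confusion[sample.label, pred.label] += 1
            correct += pred.label == sample.label
        accuracies[r] = correct / len(test_samples)
    return EvaluationReport(accuracies, confusion)
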