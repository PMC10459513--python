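"""Training orchestration: presentation loop, counting pass, checkpoints.

A training run presents each sample once with STDP active, then runs the
inhibition-weight update / synaptic-wiring rule on the presentation's
first-layer spike counts.  After training, a frozen counting pass collects
per-sample spike counts from which the Bayesian class-conditional model is
fitted.  Checkpoints bundle the weight matrices, adaptive thresholds,
wiring state and configuration into a single ``.npz`` archive.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .inference import ClassConditionalModel, fit_model
from .network import Network, NetworkConfig, build_network
from .wiring import WiringEvent, post_presentation_hook

__all__ = [
    "TrainResult",
    "train_network",
    "collect_counts",
    "train_and_fit",
    "save_checkpoint",
    "load_checkpoint",
    "write_wiring_audit",
]


@dataclass
class TrainResult:
    network: Network
    model: ClassConditionalModel | None
    train_counts: np.ndarray | None
    train_labels: np.ndarray | None

    @property
    def wiring_events(self) -> list[WiringEvent]:
        return self.network.wiring_state.events

    @property
    def n_wirings(self) -> int:
        return self.network.wiring_state.n_wirings


def train_network(
    network: Network,
    samples,
    rng: np.random.Generator | int | None = None,
    wiring_enabled: bool = True,
    log=None,
) -> Network:
    """Run one training pass: STDP during each presentation, wiring after.

    ``log``, if given, is called once per presentation with a dict carrying
    the presentation index, the selected maximum neuron (or None) and the
    spike-count total — the audit trail for the update rule.
    """
    from .wiring import select_max_neuron

    rng = np.random.default_rng(rng)
    for idx, sample in enumerate(samples):
        rec1, _ = network.present(sample, rng, learn=True)
        counts = rec1.counts
        if wiring_enabled:
            post_presentation_hook(
                network.weights.W_SF,
                counts,
                network.wiring_state,
                network.config.wiring,
            )
        if log is not None:
            m = select_max_neuron(counts, network.config.wiring)
            log(
                {
                    "presentation": idx,
                    "max_neuron": m,
                    "total_spikes": int(counts.sum()),
                    "n_wirings": network.wiring_state.n_wirings,
                }
            )
    return network


def collect_counts(
    network: Network, samples, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Frozen pass over ``samples``: per-sample first-layer spike counts."""
    rng = np.random.default_rng(rng)
    counts, labels = [], []
    for sample in samples:
        rec1, _ = network.present(sample, rng, learn=False)
        counts.append(rec1.counts)
        labels.append(sample.label)
    return np.asarray(counts), np.asarray(labels)


def train_and_fit(
    config: NetworkConfig,
    train_samples,
    family: str = "poisson",
    rng: np.random.Generator | int | None = None,
    wiring_enabled: bool = True,
    log=None,
) -> TrainResult:
    """Build, train, and fit the decoder in one call.

    The master generator is fanned out into independent child streams for
    weight initialization, the training presentations, and the counting
    pass, so each phase is reproducible on its own.
    """
    rng = np.random.default_rng(rng)
    init_rng, train_rng, count_rng = rng.spawn(3)
    network = build_network(config, init_rng)
    train_network(network, train_samples, train_rng, wiring_enabled, log)
    counts, labels = collect_counts(network, train_samples, count_rng)
    model = fit_model(counts, labels, family=family)
    return TrainResult(network, model, counts, labels)


def save_checkpoint(path, network: Network, model: ClassConditionalModel | None = None) -> None:
    """Serialize a network (and optionally a fitted model) to ``.npz``."""
    arrays = {
        "W_in": network.weights.W_in,
        "W_FS": network.weights.W_FS,
        "W_SF": network.weights.W_SF,
        "theta_first": network.state_first.theta_adapt,
        "theta_second": network.state_second.theta_adapt,
        "prev_counts": network.wiring_state.prev_counts,
        "n_wirings": np.array(network.wiring_state.n_wirings),
        "presentation_index": np.array(network.wiring_state.presentation_index),
        "config_json": np.array(json.dumps(network.config.to_dict())),
    }
    if model is not None:
        arrays["model_lam"] = model.lam
        arrays["model_prior"] = model.prior
        arrays["model_family"] = np.array(model.family)
        arrays["model_epsilon"] = np.array(model.epsilon)
        if model.sigma is not None:
            arrays["model_sigma"] = model.sigma
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[Network, ClassConditionalModel | None]:
    """Restore a network and (if present) its fitted model from ``.npz``."""
    with np.load(path, allow_pickle=False) as data:
        config = NetworkConfig.from_dict(json.loads(str(data["config_json"])))
        network = Network(config)
        network.weights.W_in = data["W_in"].copy()
        network.weights.W_FS = data["W_FS"].copy()
        network.weights.W_SF = data["W_SF"].copy()
        network.state_first.theta_adapt = data["theta_first"].copy()
        network.state_second.theta_adapt = data["theta_second"].copy()
        network.wiring_state.prev_counts = data["prev_counts"].copy()
        network.wiring_state.n_wirings = int(data["n_wirings"])
        network.wiring_state.presentation_index = int(data["presentation_index"])
        model = None
        if "model_lam" in data:
            model = ClassConditionalModel(
                lam=data["model_lam"].copy(),
                prior=data["model_prior"].copy(),
                family=str(data["model_family"]),
                sigma=data["model_sigma"].copy() if "model_sigma" in data else None,
                epsilon=float(data["model_epsilon"]),
            )
    return network, model


def write_wiring_audit(path, events: list[WiringEvent]) -> None:
    """Write the wiring audit trail (one converted synapse per row) as CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["presentation", "max_neuron", "wired_neuron", "old_weight"])
        for ev in events:
            writer.writerow([ev.presentation, ev.max_neuron, ev.wired_neuron, ev.old_weight])
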