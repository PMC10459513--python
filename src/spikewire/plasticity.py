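"""Spike timing-dependent plasticity on the input -> first-layer synapses.

Pairwise rule: a presynaptic spike at t_pre followed by a postsynaptic spike
at t_post potentiates the synapse by A+ * exp(-(t_post - t_pre)/tau+); the
reverse order depresses it by A- * exp(-|dt|/tau-).  The online realization
keeps exponentially decaying eligibility traces per pre and post neuron and
applies all-to-all pairing; for isolated spike pairs it reproduces the
pairwise rule exactly.

Defaults follow the convention of unsupervised digit-classification
networks in this family: A+ = 1e-4, A- = 1e-2, tau+/- = 1 ms, plastic
weights clipped to [0, 1], and per-neuron input-weight normalization to a
fixed column total so that competitive learning does not degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "STDPParameters",
    "STDPTraces",
    "stdp_pair_update",
    "stdp_trace_step",
    "init_input_weights",
    "normalize_input_weights",
]


@dataclass(frozen=True)
class STDPParameters:
    A_plus: float = 1e-4
    A_minus: float = 1e-2
    tau_plus: float = 1.0
    tau_minus: float = 1.0
    w_min: float = 0.0
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if self.A_plus < 0 or self.A_minus < 0:
            raise ValueError("STDP amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be below w_max")


@dataclass
class STDPTraces:
    """Pre- and post-synaptic eligibility traces (one scalar per neuron)."""

    pre: np.ndarray
    post: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int, n_post: int) -> "STDPTraces":
        return cls(np.zeros(n_pre), np.zeros(n_post))

    def reset(self) -> None:
        self.pre[:] = 0.0
        self.post[:] = 0.0


def stdp_pair_update(
    w: float, t_pre: float, t_post: float, params: STDPParameters
) -> float:
    """Apply the pairwise STDP rule for a single pre/post spike pair.

    Potentiation when the pre spike precedes (or coincides with) the post
    spike, depression otherwise; the magnitude decays exponentially with the
    absolute timing difference.  The result is clipped to the weight bounds.
    """
    if not (math.isfinite(w) and math.isfinite(t_pre) and math.isfinite(t_post)):
        raise ValueError("weight and spike times must be finite")
    dt = abs(t_post - t_pre)
    if t_pre <= t_post:
        w = w + params.A_plus * math.exp(-dt / params.tau_plus)
    else:
        w = w - params.A_minus * math.exp(-dt / params.tau_minus)
    return min(max(w, params.w_min), params.w_max)


def stdp_trace_step(
    pre_spikes: np.ndarray,
    post_spikes: np.ndarray,
    traces: STDPTraces,
    weights: np.ndarray,
    params: STDPParameters,
    dt: float = 1.0,
) -> None:
    """One timestep of trace-based STDP; mutates ``weights`` and ``traces``.

    Order of operations within the step: decay both traces; depress rows of
    presynaptic spikers against the existing post trace (strictly earlier
    post spikes only, so a coincident pair is pure potentiation); register
    the current spikes in the traces; potentiate columns of postsynaptic
    spikers against the pre trace (which includes coincident pre spikes);
    clip to bounds.
    """
    pre_spikes = np.asarray(pre_spikes, dtype=bool)
    post_spikes = np.asarray(post_spikes, dtype=bool)
    if weights.shape != (pre_spikes.size, post_spikes.size):
        raise ValueError(
            f"weights shape {weights.shape} does not match "
            f"({pre_spikes.size}, {post_spikes.size})"
        )

    traces.pre *= math.exp(-dt / params.tau_plus)
    traces.post *= math.exp(-dt / params.tau_minus)

    if pre_spikes.any():
        weights[pre_spikes, :] -= params.A_minus * traces.post[None, :]

    traces.pre[pre_spikes] += 1.0
    traces.post[post_spikes] += 1.0

    if post_spikes.any():
        weights[:, post_spikes] += params.A_plus * traces.pre[:, None]

    if pre_spikes.any() or post_spikes.any():
        np.clip(weights, params.w_min, params.w_max, out=weights)


def init_input_weights(
    n_input: int,
    n_neurons: int,
    rng: np.random.Generator,
    low: float = 0.0,
    high: float = 0.3,
) -> np.ndarray:
    """Uniform random initialization of the plastic input weight matrix."""
    return rng.uniform(low, high, size=(n_input, n_neurons))


def normalize_input_weights(weights: np.ndarray, total: float = 78.4) -> None:
    """Rescale each neuron's incoming weights so the column sums equal ``total``.

    Keeps the total synaptic drive per first-layer neuron fixed, which is
    what makes STDP competitive: a neuron can only strengthen some synapses
    at the expense of others.  Columns with zero sum are left untouched.
    Mutates in place.
    """
    sums = weights.sum(axis=0)
    nonzero = sums > 0
    weights[:, nonzero] *= total / sums[nonzero]
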