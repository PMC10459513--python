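"""Dynamic inhibition-weight update and Hebbian synaptic wiring.

After each training presentation, the most active first-layer neuron m (if
it fired at least ``S_min`` spikes) is taken as fully trained for the input
and is excluded from further inhibition change.  Every other neuron k that
reacted (fired at least one spike) and is still inhibited by m's partner
(W_SF[m, k] < 0) has that inhibition weight moved by a gradient-like step
proportional to the change in its spike count between the previous and the
current presentation:

    W_SF[m, k] += L1 * (S_k - S_k_prev)   if the count increased
    W_SF[m, k] += L2 * (S_k - S_k_prev)   otherwise

Neurons that keep firing alongside m therefore see their inhibition weaken.
Once an entry rises above the wiring threshold (default -38) while still
negative, it is switched to a fixed excitatory weight of +25: neuron k is
wired into m's assembly and will henceforth be driven to fire together with
m ("cells that fire together, wire together").  Wired entries are frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WiringParameters",
    "WiringState",
    "WiringEvent",
    "select_max_neuron",
    "update_inhibition_row",
    "apply_synaptic_wiring",
    "post_presentation_hook",
]


@dataclass(frozen=True)
class WiringParameters:
    """Knobs of the inhibition update / wiring rule.

    ``theta_inhibit`` is the wiring threshold on the (negative) inhibition
    weight; ``L1``/``L2`` the learning rates for positive/negative count
    changes; ``S_min`` the minimum spike count for a neuron to qualify as
    the maximum neuron; ``wired_value`` the fixed excitatory weight a wired
    connection is set to.
    """

    theta_inhibit: float = -38.0
    L1: float = 0.5
    L2: float = 0.07
    S_min: int = 4
    wired_value: float = 25.0

    def __post_init__(self) -> None:
        if self.theta_inhibit >= 0:
            raise ValueError("theta_inhibit must be negative")
        if self.L1 <= 0 or self.L2 <= 0:
            raise ValueError("learning rates must be positive")
        if self.S_min < 1:
            raise ValueError("S_min must be at least 1")


@dataclass(frozen=True)
class WiringEvent:
    """Audit record of one inhibitory entry converted to excitatory."""

    presentation: int
    max_neuron: int
    wired_neuron: int
    old_weight: float


@dataclass
class WiringState:
    """Carry-over between presentations: previous counts and wiring tally."""

    prev_counts: np.ndarray
    n_wirings: int = 0
    events: list[WiringEvent] = field(default_factory=list)
    presentation_index: int = 0

    @classmethod
    def initial(cls, n_neurons: int) -> "WiringState":
        return cls(prev_counts=np.zeros(n_neurons, dtype=np.int64))


def select_max_neuron(counts: np.ndarray, params: WiringParameters) -> int | None:
    """Index of the maximum-spiking neuron, or None if below ``S_min``.

    Ties are broken toward the lowest index.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("counts is empty")
    m = int(np.argmax(counts))
    return m if counts[m] >= params.S_min else None


def update_inhibition_row(
    W_SF: np.ndarray,
    m: int,
    counts: np.ndarray,
    prev_counts: np.ndarray,
    params: WiringParameters,
) -> np.ndarray:
    """Gradient-style update of row m of the inhibition matrix, in place.

    Only neurons that reacted this presentation (>= 1 spike) and are still
    inhibited (entry < 0) are touched; the maximum neuron itself and
    already-wired (non-negative) entries are skipped.
    """
    if not 0 <= m < W_SF.shape[0]:
        raise IndexError(f"max-neuron index {m} out of range")
    counts = np.asarray(counts)
    prev_counts = np.asarray(prev_counts)

    eligible = (counts >= 1) & (W_SF[m] < 0)
    eligible[m] = False
    if eligible.any():
        diff = (counts - prev_counts).astype(float)
        rate = np.where(diff > 0, params.L1, params.L2)
        W_SF[m, eligible] += rate[eligible] * diff[eligible]
    return W_SF[m]


def apply_synaptic_wiring(
    W_SF: np.ndarray, m: int, params: WiringParameters
) -> tuple[np.ndarray, list[tuple[int, float]]]:
    """Convert entries of row m that crossed the wiring threshold to +25.

    An entry qualifies when it is still negative but has risen strictly
    above ``theta_inhibit``.  Returns the wired column indices with their
    pre-conversion weights.
    """
    row = W_SF[m]
    wire = (row < 0) & (row > params.theta_inhibit)
    wired = [(int(k), float(row[k])) for k in np.flatnonzero(wire)]
    row[wire] = params.wired_value
    return W_SF, wired


def post_presentation_hook(
    W_SF: np.ndarray,
    counts: np.ndarray,
    state: WiringState,
    params: WiringParameters,
) -> WiringState:
    """Run one post-presentation round of the inhibition update + wiring.

    Selects the maximum neuron; if one qualifies, updates its inhibition row
    and applies synaptic wiring; always rolls the presentation counts into
    ``prev_counts``.  Mutates ``W_SF`` and ``state`` and returns the state.
    """
    counts = np.asarray(counts)
    m = select_max_neuron(counts, params)
    if m is not None:
        update_inhibition_row(W_SF, m, counts, state.prev_counts, params)
        _, wired = apply_synaptic_wiring(W_SF, m, params)
        state.n_wirings += len(wired)
        for k, old in wired:
            state.events.append(
                WiringEvent(state.presentation_index, m, k, old)
            )
    state.prev_counts = counts.astype(np.int64).copy()
    state.presentation_index += 1
    return state
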