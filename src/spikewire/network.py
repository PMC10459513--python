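"""Three-layer network topology and the per-presentation simulation loop.

Layout: 784 Poisson input neurons fully connect to N first-layer neurons
through the plastic matrix W_in; each first-layer neuron connects one-to-one
to its second-layer partner with a fixed +25 weight (W_FS, diagonal); each
second-layer neuron feeds back onto every *other* first-layer neuron with an
initial -50 inhibitory weight (W_SF, zero diagonal) — lateral inhibition.
The wiring rule later flips selected W_SF entries to +25, binding neurons
into co-firing assemblies.

Synaptic currents are injected with per-layer membrane resistance
R = tau_m/dt by default, so a single spike through a weight-w synapse
depolarizes its target by w mV — the voltage-injection convention under
which the +/-25 and -50 weights are meaningful (a +25 relay spike lifts a
resting neuron straight to threshold).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .core_dynamics import LIFParameters, NeuronPopulationState, lif_step
from .encoding import N_INPUT, ImageSample, SpikeRecord, poisson_encode
from .plasticity import (
    STDPParameters,
    STDPTraces,
    init_input_weights,
    normalize_input_weights,
    stdp_trace_step,
)
from .wiring import WiringParameters, WiringState

__all__ = ["NetworkConfig", "WeightSet", "Network", "build_network"]


def _lif_with_voltage_injection(**overrides) -> LIFParameters:
    p = LIFParameters(**overrides)
    if "R" not in overrides:
        p = replace(p, R=p.tau_m / p.dt)
    return p


@dataclass
class NetworkConfig:
    """Full configuration of the network and its learning rules."""

    n_neurons: int = 100
    n_input: int = N_INPUT
    excitatory_weight: float = 25.0
    inhibition_init: float = -50.0
    duration_ms: float = 350.0
    rest_ms: float = 150.0
    dt: float = 1.0
    lif_first: LIFParameters = field(
        default_factory=_lif_with_voltage_injection
    )
    lif_second: LIFParameters = field(
        default_factory=lambda: _lif_with_voltage_injection(adaptive_enabled=False)
    )
    stdp: STDPParameters = field(
        # Amplitudes as the reference simulator applies them: the pre-spike
        # (depression) amplitude is 1e-4 and the post-spike (potentiation)
        # amplitude 1e-2.  With the assignment reversed the rule is net
        # anti-Hebbian (depression outweighs potentiation ~100:1 on the
        # synapses driving a winner) and no class templates can form.
        default_factory=lambda: STDPParameters(A_plus=1e-2, A_minus=1e-4)
    )
    wiring: WiringParameters = field(default_factory=WiringParameters)
    normalize_input: bool = True
    # Per-neuron total of incoming plastic weight.  With tau_m = 20 ms and a
    # 25 mV gap between rest and threshold, a sparse stroke image (~100
    # bright pixels at <= 0.1275 spikes/ms) must sustain > 1.25 mV/ms of
    # drive to make the layer fire at all; 160 yields winner rates of
    # ~10-20 spikes per 350 ms presentation.
    norm_total: float = 160.0
    w_init_low: float = 0.0
    w_init_high: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError("n_neurons must be positive")
        if self.n_input <= 0:
            raise ValueError("n_input must be positive")
        if self.excitatory_weight <= 0:
            raise ValueError("excitatory_weight must be positive")
        if self.inhibition_init >= 0:
            raise ValueError("inhibition_init must be negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = copy.deepcopy(d)
        for key, sub in (
            ("lif_first", LIFParameters),
            ("lif_second", LIFParameters),
            ("stdp", STDPParameters),
            ("wiring", WiringParameters),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)


@dataclass
class WeightSet:
    """The three weight matrices of the network.

    W_in : (n_input, N) plastic, non-negative (STDP).
    W_FS : (N, N) fixed diagonal, +25 — first-to-second relay; never updated.
    W_SF : (N, N) second-to-first feedback; zero diagonal, off-diagonal
           initially -50, mutated only by the wiring rule.
    """

    W_in: np.ndarray
    W_FS: np.ndarray
    W_SF: np.ndarray


class Network:
    """A built network: weights, per-layer neuron states, and learning state."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | int | None = None):
        self.config = config
        rng = np.random.default_rng(config.rng_seed if rng is None else rng)
        n = config.n_neurons
        W_in = init_input_weights(
            config.n_input, n, rng, config.w_init_low, config.w_init_high
        )
        W_FS = np.diag(np.full(n, config.excitatory_weight))
        W_SF = np.full((n, n), config.inhibition_init, dtype=float)
        np.fill_diagonal(W_SF, 0.0)
        self.weights = WeightSet(W_in, W_FS, W_SF)
        self.state_first = NeuronPopulationState.at_rest(n, config.lif_first)
        self.state_second = NeuronPopulationState.at_rest(n, config.lif_second)
        self.traces = STDPTraces.zeros(config.n_input, n)
        self.wiring_state = WiringState.initial(n)

    @property
    def n_neurons(self) -> int:
        return self.config.n_neurons

    def present(
        self,
        image: ImageSample | np.ndarray | SpikeRecord,
        rng: np.random.Generator | int | None = None,
        learn: bool = True,
        record_potentials: bool = False,
    ):
        """Present one sample for ``duration_ms`` and run the rest interval.

        Per timestep: draw the input spikes; compute the first-layer current
        from the input spikes plus the previous step's second-layer feedback
        (one-timestep synaptic delay on both inter-layer paths); step the
        first layer; compute the second-layer current from the previous
        step's first-layer spikes; step the second layer; if learning,
        apply trace-based STDP to W_in.  Input-weight normalization (when
        enabled) is applied once, at presentation onset.

        With ``learn=False`` the presentation is fully frozen: no STDP, no
        normalization, and no adaptive-threshold change.

        Returns ``(first_record, second_record)`` or, with
        ``record_potentials=True``, ``(first_record, second_record, u_trace)``
        where ``u_trace`` is the (timesteps x N) first-layer membrane trace.
        """
        cfg = self.config
        if isinstance(image, SpikeRecord):
            input_record = image
        else:
            input_record = poisson_encode(image, cfg.duration_ms, cfg.dt, rng)
        raster_in = input_record.raster.astype(bool)
        n_steps = raster_in.shape[0]
        if raster_in.shape[1] != cfg.n_input:
            raise ValueError("input raster width does not match n_input")

        if learn and cfg.normalize_input:
            normalize_input_weights(self.weights.W_in, cfg.norm_total)

        n = cfg.n_neurons
        raster1 = np.zeros((n_steps, n), dtype=np.uint8)
        raster2 = np.zeros((n_steps, n), dtype=np.uint8)
        u_trace = np.zeros((n_steps, n)) if record_potentials else None

        theta1_frozen = None if learn else self.state_first.theta_adapt.copy()
        theta2_frozen = None if learn else self.state_second.theta_adapt.copy()

        self.traces.reset()
        s1_prev = np.zeros(n, dtype=bool)
        s2_prev = np.zeros(n, dtype=bool)

        W_in_T = self.weights.W_in  # (n_input, n); current = spikes @ W_in
        for t in range(n_steps):
            in_spikes = raster_in[t]
            i1 = in_spikes @ W_in_T + self.weights.W_SF.T @ s2_prev
            self.state_first, s1 = lif_step(self.state_first, i1, cfg.lif_first)
            i2 = self.weights.W_FS.T @ s1_prev
            self.state_second, s2 = lif_step(self.state_second, i2, cfg.lif_second)
            if learn:
                stdp_trace_step(
                    in_spikes, s1, self.traces, self.weights.W_in, cfg.stdp, cfg.dt
                )
            raster1[t] = s1
            raster2[t] = s2
            if record_potentials:
                u_trace[t] = self.state_first.u
            s1_prev, s2_prev = s1, s2

        if not learn:
            self.state_first.theta_adapt = theta1_frozen
            self.state_second.theta_adapt = theta2_frozen
        self._rest(learn)

        rec1 = SpikeRecord.from_raster(raster1, cfg.duration_ms, cfg.dt)
        rec2 = SpikeRecord.from_raster(raster2, cfg.duration_ms, cfg.dt)
        if record_potentials:
            return rec1, rec2, u_trace
        return rec1, rec2

    def _rest(self, learn: bool) -> None:
        """Inter-presentation rest interval with zero input, in closed form.

        With no input the membrane decays monotonically toward rest and can
        never cross threshold, so no spikes occur; the interval reduces to
        resetting the membranes to rest, expiring refractory clocks, and
        (during learning) decaying the adaptive-threshold offsets.
        """
        cfg = self.config
        for state, lif in (
            (self.state_first, cfg.lif_first),
            (self.state_second, cfg.lif_second),
        ):
            state.u[:] = lif.u_rest
            state.refrac_remaining[:] = 0.0
            if learn and cfg.rest_ms > 0:
                state.theta_adapt *= np.exp(-cfg.rest_ms / lif.tau_theta)


def build_network(
    config: NetworkConfig, rng: np.random.Generator | int | None = None
) -> Network:
    """Construct a fresh network from the configuration (seeded)."""
    return Network(config, rng)
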