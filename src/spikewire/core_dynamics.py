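"""Leaky integrate-and-fire dynamics for a homogeneous neuron population.

The membrane potential of each neuron follows

    tau_m * du/dt = -(u - u_rest) + R * I(t)

integrated with explicit Euler at step ``dt``.  A neuron whose updated
potential reaches its threshold (base threshold plus an optional adaptive
offset) emits a spike, is reset to the resting potential, and is clamped at
rest for a refractory period during which it cannot fire.  The adaptive
offset implements homeostasis: it grows by a small increment on every spike
and decays exponentially with a very long time constant, so chronically
active neurons become harder to excite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LIFParameters", "NeuronPopulationState", "lif_step"]


@dataclass(frozen=True)
class LIFParameters:
    """Parameters of the leaky integrate-and-fire model.

    Attributes
    ----------
    tau_m : float
        Membrane time constant in ms.
    u_rest : float
        Resting (and reset) potential in mV.
    R : float
        Membrane resistance (dimensionless scaling of the input current).
    theta_base : float
        Base firing threshold in mV.
    t_refrac : float
        Refractory period in ms; the membrane is clamped at ``u_rest`` and
        no spike can be emitted while it runs.
    dt : float
        Integration step in ms.
    theta_plus : float
        Adaptive-threshold increment in mV added on each spike.
    tau_theta : float
        Decay time constant of the adaptive threshold offset in ms.
    adaptive_enabled : bool
        If False the threshold stays fixed at ``theta_base``.
    """

    tau_m: float = 20.0
    u_rest: float = -65.0
    R: float = 1.0
    theta_base: float = -40.0
    t_refrac: float = 5.0
    dt: float = 1.0
    theta_plus: float = 0.05
    tau_theta: float = 1e7
    adaptive_enabled: bool = True

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.t_refrac < 0:
            raise ValueError(f"t_refrac must be non-negative, got {self.t_refrac}")
        if self.theta_base <= self.u_rest:
            raise ValueError(
                f"theta_base ({self.theta_base}) must exceed u_rest ({self.u_rest})"
            )
        if self.theta_plus < 0:
            raise ValueError(f"theta_plus must be non-negative, got {self.theta_plus}")
        if self.tau_theta <= 0:
            raise ValueError(f"tau_theta must be positive, got {self.tau_theta}")

    @property
    def theta_decay(self) -> float:
        """Per-step multiplicative decay of the adaptive threshold offset."""
        return math.exp(-self.dt / self.tau_theta)


@dataclass
class NeuronPopulationState:
    """Dynamic state of one layer: potentials, threshold offsets, refractory clocks."""

    u: np.ndarray
    theta_adapt: np.ndarray
    refrac_remaining: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.u) == len(self.theta_adapt) == len(self.refrac_remaining)):
            raise ValueError("state vectors must have identical length")

    @classmethod
    def at_rest(cls, n: int, params: LIFParameters) -> "NeuronPopulationState":
        """Fresh state with all neurons at rest and no adaptation."""
        return cls(
            u=np.full(n, params.u_rest, dtype=float),
            theta_adapt=np.zeros(n, dtype=float),
            refrac_remaining=np.zeros(n, dtype=float),
        )

    def __len__(self) -> int:
        return len(self.u)

    def copy(self) -> "NeuronPopulationState":
        return NeuronPopulationState(
            self.u.copy(), self.theta_adapt.copy(), self.refrac_remaining.copy()
        )


def lif_step(
    state: NeuronPopulationState,
    input_current: np.ndarray,
    params: LIFParameters,
) -> tuple[NeuronPopulationState, np.ndarray]:
    """Advance a population one timestep; return the new state and spike vector.

    Non-refractory neurons take one Euler step
    ``u <- u + (dt/tau_m) * (-(u - u_rest) + R*I)``; those whose updated
    potential reaches ``theta_base + theta_adapt`` spike, reset to rest and
    enter the refractory period.  Refractory neurons stay clamped at rest and
    run down their clocks.  The adaptive offset decays every step and, when
    enabled, grows by ``theta_plus`` on each spike.

    Returns
    -------
    (NeuronPopulationState, ndarray of bool)
        Fresh state (inputs are not mutated) and the spike indicator vector.
    """
    input_current = np.asarray(input_current, dtype=float)
    if input_current.shape != state.u.shape:
        raise ValueError(
            f"input_current has shape {input_current.shape}, "
            f"population has shape {state.u.shape}"
        )
    if not np.all(np.isfinite(input_current)):
        raise ValueError("input_current contains non-finite values")

    refractory = state.refrac_remaining > 0

    du = (params.dt / params.tau_m) * (
        -(state.u - params.u_rest) + params.R * input_current
    )
    u = np.where(refractory, params.u_rest, state.u + du)

    threshold = params.theta_base + state.theta_adapt
    spikes = (~refractory) & (u >= threshold)

    u[spikes] = params.u_rest

    refrac = np.where(refractory, state.refrac_remaining - params.dt, 0.0)
    np.maximum(refrac, 0.0, out=refrac)
    refrac[spikes] = params.t_refrac

    theta = state.theta_adapt * params.theta_decay
    if params.adaptive_enabled:
        theta[spikes] += params.theta_plus

    return NeuronPopulationState(u, theta, refrac), spikes
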