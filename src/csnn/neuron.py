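"""Izhikevich point-neuron dynamics.

The two-variable Izhikevich model reproduces the firing repertoire of
cortical neurons at the cost of two ODEs:

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I_ex + I_g
    du/dt = a (b v - u)
    if v >= 30:  v <- c, u <- u + d   (spike and reset)

with membrane voltage ``v`` (mV), recovery variable ``u``, exterior current
``I_ex`` and synaptic current ``I_g``.  Excitatory neurons use the
regular-spiking parameter set and inhibitory neurons the fast-spiking one.
Integration is forward Euler; the spike is stamped at the step where the
threshold crossing is detected, before reset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeuronParams", "NeuronState", "EXCITATORY", "INHIBITORY", "step_neuron"]

#: spike detection threshold (mV)
V_PEAK = 30.0
#: standard initial membrane voltage (mV)
V_REST = -65.0


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich constants (a, b, c, d)."""

    a: float
    b: float
    c: float
    d: float


#: regular-spiking (excitatory) parameter set
EXCITATORY = NeuronParams(a=0.02, b=0.20, c=-65.0, d=8.0)
#: fast-spiking (inhibitory) parameter set
INHIBITORY = NeuronParams(a=0.02, b=0.25, c=-65.0, d=2.0)


@dataclass
class NeuronState:
    """Membrane state (v, u)."""

    v: float
    u: float

    @classmethod
    def resting(cls, params: NeuronParams) -> "NeuronState":
        """Standard initial condition v0 = -65 mV, u0 = b * v0."""
        return cls(v=V_REST, u=params.b * V_REST)


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    i_ex: float,
    i_g: float,
    dt: float,
) -> tuple[NeuronState, bool]:
    """One forward-Euler step; returns the new state and a spike flag.

    Both variables are advanced from the pre-step state (simultaneous
    update).  If the updated voltage reaches +30 mV the neuron spikes:
    ``v`` is reset to ``c`` and ``u`` incremented by ``d``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(state.v) and np.isfinite(state.u) and np.isfinite(i_ex) and np.isfinite(i_g)):
        raise ValueError("non-finite neuron state or input current")
    v, u = state.v, state.u
    i_total = i_ex + i_g
    v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + i_total)
    u_new = u + dt * params.a * (params.b * v - u)
    if v_new >= V_PEAK:
        return NeuronState(v=params.c, u=u_new + params.d), True
    return NeuronState(v=v_new, u=u_new), False


def step_neurons_inplace(
    v: np.ndarray,
    u: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    i_total: np.ndarray,
    dt: float,
) -> np.ndarray:
    """Vectorized Euler step over a population, mutating ``v`` and ``u``.

    Returns the boolean spike mask.  ``v`` holds the post-reset voltages on
    exit; callers that need the pre-reset peak (e.g. for delayed-voltage
    buffers feeding synaptic kinetics) should copy ``v`` between the update
    and the reset — the engine does this via the returned mask and the
    convention that the peak equals the computed ``v`` before reset.
    """
    dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_total
    du = a * (b * v - u)
    v += dt * dv
    u += dt * du
    spiked = v >= V_PEAK
    return spiked
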