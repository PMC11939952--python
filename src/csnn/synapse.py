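"""Delayed conductance synapses with neurotransmitter kinetics and dual STDP.

Each synapse carries a weight ``g`` (dimensionless conductance, clipped to
[0, gmax]), a neurotransmitter binding fraction ``r`` in [0, 1], and a
transmission delay ``td``.  The synaptic current into the postsynaptic
neuron is

    I_g(t) = g(t) r(t) (E - V_post(t))

with reversal potential E = 0 mV for excitatory synapses (ES) and -70 mV
for inhibitory ones (IS).  ``r`` follows first-order kinetics driven by the
*delayed* presynaptic voltage,

    dr/dt = alpha H (1 - r) - beta r,    H = 1 / (1 + exp(-V_pre(t - td)))

so transmitter release is gated by presynaptic spikes arriving ``td`` ms
late.  Between spike events the weight decays exponentially
(``mu dg/dt = -g``); on paired pre/post spikes it jumps by a
spike-timing-dependent plasticity (STDP) window scaled by ``gmax``.  The ES
window potentiates causal pairs (pre before post) and depresses acausal
ones; the IS window has the opposite signs.  Because the depression area
exceeds the potentiation area, uncorrelated activity drives weights down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityParams",
    "SynapseState",
    "synaptic_current",
    "step_kinetics",
    "decay_weight",
    "stdp_window_ex",
    "stdp_window_in",
    "apply_stdp",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Synaptic plasticity constants (defaults: standard conductance-STDP set).

    ``e_ex``/``e_in`` are reversal potentials (mV); ``alpha``/``beta`` the
    forward/reverse transmitter rate constants (1/ms); ``mu_ex``/``mu_in``
    weight decay time constants (ms); ``gmax`` the weight ceiling;
    ``a_plus``/``a_minus`` the ES potentiation/depression amplitudes,
    ``b_plus``/``b_minus`` the IS ones; ``tau_plus``/``tau_minus`` the STDP
    window time constants (ms).  ``v_half``/``v_slope`` parameterize the
    transmitter gate H = 1/(1 + exp(-(V - v_half)/v_slope)).
    """

    e_ex: float = 0.0
    e_in: float = -70.0
    alpha_ex: float = 2.0
    alpha_in: float = 0.9
    beta_ex: float = 1.0
    beta_in: float = 0.1
    mu_ex: float = 3.0
    mu_in: float = 5.0
    gmax: float = 0.015
    a_plus: float = 0.1
    a_minus: float = 0.105
    b_plus: float = 0.02
    b_minus: float = 0.03
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    v_half: float = 0.0
    v_slope: float = 1.0

    def reversal(self, kind: str) -> float:
        return self.e_ex if kind == "ES" else self.e_in

    def alpha(self, kind: str) -> float:
        return self.alpha_ex if kind == "ES" else self.alpha_in

    def beta(self, kind: str) -> float:
        return self.beta_ex if kind == "ES" else self.beta_in

    def mu(self, kind: str) -> float:
        return self.mu_ex if kind == "ES" else self.mu_in


@dataclass
class SynapseState:
    """State of one synapse: endpoints, kind ('ES'/'IS'), weight, kinetics, delay."""

    pre_id: int
    post_id: int
    kind: str
    g: float
    r: float = 0.0
    td: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("ES", "IS"):
            raise ValueError("kind must be 'ES' or 'IS'")


def synaptic_current(s: SynapseState, v_post: float, p: PlasticityParams) -> float:
    """Conductance current g r (E - V_post) into the postsynaptic neuron."""
    return s.g * s.r * (p.reversal(s.kind) - v_post)


def transmitter_gate(v_pre_delayed, p: PlasticityParams):
    """Logistic gate H of the delayed presynaptic voltage."""
    with np.errstate(over="ignore"):  # deep hyperpolarization saturates to 0
        return 1.0 / (1.0 + np.exp(-(v_pre_delayed - p.v_half) / p.v_slope))


def step_kinetics(
    s: SynapseState, v_pre_delayed: float, p: PlasticityParams, dt: float
) -> SynapseState:
    """Advance the binding fraction r one Euler step, clamped to [0, 1]."""
    h = float(transmitter_gate(v_pre_delayed, p))
    r_new = s.r + dt * (p.alpha(s.kind) * h * (1.0 - s.r) - p.beta(s.kind) * s.r)
    s.r = float(np.clip(r_new, 0.0, 1.0))
    return s


def decay_weight(s: SynapseState, p: PlasticityParams, dt: float) -> SynapseState:
    """Exponential weight decay, Euler factor (1 - dt/mu)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    s.g = max(0.0, s.g * (1.0 - dt / p.mu(s.kind)))
    return s


def stdp_window_ex(delta_t: float, p: PlasticityParams) -> float:
    """ES modification window w(dt), dt = t_pre - t_post.

    Causal pairs (pre before post, dt < 0) potentiate by A+ exp(dt/tau+);
    acausal pairs (dt >= 0) depress by -A- exp(-dt/tau-).
    """
    if delta_t < 0:
        return p.a_plus * np.exp(delta_t / p.tau_plus)
    return -p.a_minus * np.exp(-delta_t / p.tau_minus)


def stdp_window_in(delta_t: float, p: PlasticityParams) -> float:
    """IS modification window m(dt): mirror of the ES window with B-amplitudes."""
    if delta_t < 0:
        return -p.b_plus * np.exp(delta_t / p.tau_plus)
    return p.b_minus * np.exp(-delta_t / p.tau_minus)


def apply_stdp(s: SynapseState, delta_t: float, p: PlasticityParams) -> SynapseState:
    """Apply one STDP pairing: g <- clip(g + window(dt) * gmax, 0, gmax)."""
    w = stdp_window_ex(delta_t, p) if s.kind == "ES" else stdp_window_in(delta_t, p)
    s.g = float(np.clip(s.g + w * p.gmax, 0.0, p.gmax))
    return s
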