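"""Exterior stimulus waveforms and their injection sites.

Three stimulus kinds drive the network:

* ``white_gaussian`` — zero-mean Gaussian noise current, drawn independently
  per neuron and per time step, added to the exterior current I_ex for the
  whole run.  The strength is given in dBW and converted to the noise power
  (variance) by ``sigma^2 = 10^(dBW/10)``.
* ``impulse`` — a rectangular current pulse of amplitude ``strength`` (mA)
  lasting 200 ms, switched on at the same onset ``t0`` for every neuron,
  added to I_ex.
* ``ac_field`` — an alternating magnetic-field disturbance
  ``Ac cos(2 pi f t)`` (mV) coupled into the membrane equation as an
  additional term of the voltage derivative.

Strengths 5–25 in steps of 2.5 (dBW / mA / mV respectively) form the
standard grid used in the coding analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusSpec",
    "STIMULUS_KINDS",
    "STRENGTH_GRID",
    "white_gaussian_current",
    "impulse_current",
    "ac_field_voltage",
]

STIMULUS_KINDS = ("white_gaussian", "impulse", "ac_field")
#: standard strength grid (dBW, mA or mV depending on kind)
STRENGTH_GRID = tuple(np.arange(5.0, 25.0 + 1e-9, 2.5))


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus condition.

    ``strength`` is Ag in dBW (white_gaussian), As in mA (impulse) or Ac in
    mV (ac_field).  ``t0``/``duration`` apply to the impulse, ``freq`` (Hz)
    to the AC field, ``mu_g`` to the Gaussian mean.
    """

    kind: str
    strength: float
    t0: float = 0.0
    duration: float = 200.0
    freq: float = 50.0
    mu_g: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(f"unknown stimulus kind: {self.kind!r}")

    @property
    def noise_sigma(self) -> float:
        """Std. deviation of the Gaussian stimulus: sqrt(10^(dBW/10))."""
        return float(np.sqrt(10.0 ** (self.strength / 10.0)))


def white_gaussian_current(
    spec: StimulusSpec, t: float, rng: np.random.Generator, n: int = 1
) -> np.ndarray:
    """Independent Gaussian current draws for ``n`` neurons at time ``t``."""
    if spec.kind != "white_gaussian":
        raise ValueError("spec is not a white_gaussian stimulus")
    return rng.normal(spec.mu_g, spec.noise_sigma, size=n)


def impulse_current(spec: StimulusSpec, t: float) -> float:
    """Rectangular pulse: ``strength`` on [t0, t0 + duration], else 0."""
    if spec.kind != "impulse":
        raise ValueError("spec is not an impulse stimulus")
    return spec.strength if spec.t0 <= t <= spec.t0 + spec.duration else 0.0


def ac_field_voltage(spec: StimulusSpec, t: float) -> float:
    """AC field disturbance Ac cos(2 pi f t) at time ``t`` (ms)."""
    if spec.kind != "ac_field":
        raise ValueError("spec is not an ac_field stimulus")
    return spec.strength * np.cos(2.0 * np.pi * spec.freq * t / 1000.0)
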