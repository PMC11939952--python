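"""Inter-spike-interval time coding and the three-feature coding sample.

The coding primitive is the inter-spike interval, ISI_p = t_p - t_{p-1},
computed per neuron.  Three pooled scalar features summarize a run's ISI
pattern (often called the "eigenvectors" of a coding sample in this
literature, although they are plain scalars, not linear-algebra
eigenvectors):

* feature 1 — the highest ISI across all neurons (ISI time-domain view),
* feature 2 — the highest bin proportion of the pooled ISI histogram,
* feature 3 — the highest disparity |ISI_{p+1} - ISI_p| between adjacent
  ISIs of the same neuron (joint-ISI view).

Together they form the 3-vector compared across stimulus strengths and
kinds by the similarity and clustering analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ISISeries",
    "CodingSample",
    "extract_isi",
    "isi_histogram",
    "joint_isi",
    "extract_eigenvectors",
]

#: default pooled-histogram bin width (ms) and range (ms)
DEFAULT_HIST_BIN_MS = 5.0
DEFAULT_HIST_RANGE = (0.0, 200.0)


@dataclass
class ISISeries:
    """Ordered ISIs of one neuron: ISI_p = t_p - t_{p-1}."""

    neuron_id: int
    isis: np.ndarray


@dataclass
class CodingSample:
    """One run's 3-feature coding vector with its stimulus annotation."""

    ev1: float  # highest ISI (ms)
    ev2: float  # highest ISI-histogram proportion (fraction)
    ev3: float  # highest adjacent-ISI disparity (ms)
    label: str = ""
    strength: float = float("nan")

    def vector(self, features=("ev1", "ev2", "ev3")) -> np.ndarray:
        return np.array([getattr(self, f) for f in features], dtype=float)


def extract_isi(spikes: list) -> list[ISISeries]:
    """Consecutive spike-time differences per neuron.

    Neurons with fewer than two spikes yield an empty series.  Spike times
    must be sorted; non-positive intervals indicate an unsorted or
    duplicated train and raise.
    """
    out = []
    for i, s in enumerate(spikes):
        s = np.asarray(s, dtype=float)
        isis = np.diff(s) if len(s) >= 2 else np.array([])
        if len(isis) and (isis <= 0).any():
            raise ValueError(f"spike times of neuron {i} are not strictly increasing")
        out.append(ISISeries(neuron_id=i, isis=isis))
    return out


def isi_histogram(
    isis: np.ndarray,
    bin_width: float = DEFAULT_HIST_BIN_MS,
    hist_range: tuple = DEFAULT_HIST_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Proportion of ISIs per bin; returns (edges, proportions).

    Bins tile ``hist_range`` with ``bin_width``; ISIs at or beyond the upper
    limit are counted in the final bin so proportions always sum to 1.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size == 0:
        raise ValueError("cannot build a histogram from an empty ISI set")
    lo, hi = hist_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(np.clip(isis, lo, np.nextafter(hi, lo)), bins=edges)
    return edges, counts / counts.sum()


def joint_isi(series: list[ISISeries]) -> np.ndarray:
    """Adjacent-ISI pairs (ISI_p, ISI_{p+1}) pooled over neurons; shape (P, 2)."""
    pairs = [
        np.column_stack([s.isis[:-1], s.isis[1:]])
        for s in series
        if len(s.isis) >= 2
    ]
    return np.concatenate(pairs) if pairs else np.empty((0, 2))


def extract_eigenvectors(
    trace,
    bin_width: float = DEFAULT_HIST_BIN_MS,
    hist_range: tuple = DEFAULT_HIST_RANGE,
    label: str = "",
    strength: float = float("nan"),
    t_min: float = 0.0,
) -> CodingSample:
    """The three pooled ISI features of one run.

    ``trace`` is a ``SimulationTrace`` or any object with a ``spikes`` list.
    ``t_min`` optionally drops ISIs terminating before a warm-up cutoff
    (0 by default: no truncation).
    """
    spikes = trace.spikes if hasattr(trace, "spikes") else trace
    series = extract_isi(spikes)
    if t_min > 0:
        series = [
            ISISeries(s.neuron_id, s.isis[np.asarray(spikes[s.neuron_id])[1:] >= t_min])
            for s in series
        ]
    pooled = np.concatenate([s.isis for s in series]) if series else np.array([])
    if pooled.size == 0:
        raise ValueError("no ISIs: fewer than two spikes in every neuron")
    _, props = isi_histogram(pooled, bin_width=bin_width, hist_range=hist_range)
    pairs = joint_isi(series)
    disparity = np.abs(pairs[:, 1] - pairs[:, 0]).max() if len(pairs) else 0.0
    return CodingSample(
        ev1=float(pooled.max()),
        ev2=float(props.max()),
        ev3=float(disparity),
        label=label,
        strength=strength,
    )
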