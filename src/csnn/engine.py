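"""Clocked network simulation coupling topology, neurons, synapses and stimuli.

Each step of length ``dt`` proceeds in a fixed order (the tie-breaking
convention that makes runs bit-reproducible):

1. fetch delayed presynaptic voltages from per-neuron ring buffers,
2. advance transmitter kinetics and apply weight decay on all synapses,
3. accumulate conductance currents per postsynaptic neuron,
4. add the exterior drive (constant baseline + stimulus) at its injection
   site,
5. advance all neurons one Euler step and detect spikes,
6. apply STDP: presynaptic spikes *arriving* this step (after their delay)
   pair with the latest postsynaptic spike (acausal branch, dt >= 0);
   postsynaptic spikes pair with the latest earlier presynaptic arrival
   (causal branch, dt < 0).  Exact same-step pairings are counted once, on
   the arrival trigger.

The trace records per-neuron spike times, the mean synaptic weight (MSW)
per recording bin (100 ms by default) — the bin average of the per-step
population-mean weight, i.e. "MSW over the interval" — and the mean
inter-spike interval per bin (each ISI assigned to the bin of its
terminating spike).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .neuron import EXCITATORY, INHIBITORY, V_PEAK, V_REST, NeuronParams
from .stimuli import StimulusSpec
from .synapse import PlasticityParams
from .topology import NetworkTopology

__all__ = ["SimulationTrace", "run_simulation", "compute_msw"]

#: default constant background drive added to I_ex
DEFAULT_BASELINE_CURRENT = 5.0
#: default MSW / mean-ISI recording bin (ms)
DEFAULT_BIN_MS = 100.0


@dataclass
class SimulationTrace:
    """Output of one network run."""

    spikes: list  # per-neuron ndarray of spike times (ms), strictly increasing
    msw_series: np.ndarray  # mean synaptic weight at each bin end
    mean_isi_series: np.ndarray  # mean ISI per bin (NaN where no ISI terminates)
    bin_ms: float
    duration: float
    dt: float
    config_hash: str = ""
    g_final: np.ndarray = field(default=None, repr=False)

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(len(self.msw_series)) * self.bin_ms

    def total_spikes(self) -> int:
        return int(sum(len(s) for s in self.spikes))

    def spikes_dataframe(self) -> pd.DataFrame:
        """All spikes as (neuron_id, spike_time_ms), sorted by time."""
        ids = np.concatenate(
            [np.full(len(s), i, dtype=np.int64) for i, s in enumerate(self.spikes)]
        ) if self.total_spikes() else np.array([], dtype=np.int64)
        times = (
            np.concatenate(self.spikes) if self.total_spikes() else np.array([])
        )
        order = np.argsort(times, kind="stable")
        return pd.DataFrame(
            {"neuron_id": ids[order], "spike_time_ms": times[order]}
        )

    def to_csv(self, spikes_path=None, msw_path=None, isi_path=None) -> None:
        if spikes_path is not None:
            self.spikes_dataframe().to_csv(spikes_path, index=False)
        if msw_path is not None:
            pd.DataFrame(
                {"bin_start_ms": self.bin_starts, "msw": self.msw_series}
            ).to_csv(msw_path, index=False)
        if isi_path is not None:
            pd.DataFrame(
                {"bin_start_ms": self.bin_starts, "mean_isi_ms": self.mean_isi_series}
            ).to_csv(isi_path, index=False)

    @classmethod
    def from_spikes_csv(cls, path, n_neurons, duration, dt, bin_ms=DEFAULT_BIN_MS):
        """Re-analysis entry point: rebuild a trace (spikes only) from CSV."""
        df = pd.read_csv(path)
        spikes = [
            np.sort(df.loc[df["neuron_id"] == i, "spike_time_ms"].to_numpy())
            for i in range(n_neurons)
        ]
        mean_isi = _binned_mean_isi(spikes, duration, bin_ms)
        n_bins = int(round(duration / bin_ms))
        return cls(
            spikes=spikes,
            msw_series=np.full(n_bins, np.nan),
            mean_isi_series=mean_isi,
            bin_ms=bin_ms,
            duration=duration,
            dt=dt,
        )


def compute_msw(weight_snapshots: np.ndarray) -> np.ndarray:
    """Mean synaptic weight per recording bin.

    ``weight_snapshots`` has one row per bin holding every synapse's weight
    sampled at the bin end; the MSW is the row mean.
    """
    w = np.atleast_2d(np.asarray(weight_snapshots, dtype=float))
    return w.mean(axis=1)


def _binned_mean_isi(spikes, duration, bin_ms) -> np.ndarray:
    """Mean ISI per bin; an ISI belongs to the bin of its terminating spike."""
    n_bins = int(round(duration / bin_ms))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for s in spikes:
        if len(s) < 2:
            continue
        isis = np.diff(s)
        idx = np.minimum((s[1:] / bin_ms).astype(int), n_bins - 1)
        np.add.at(sums, idx, isis)
        np.add.at(counts, idx, 1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def _config_hash(topology, stimulus, duration, dt, seed, i_baseline, bin_ms, p) -> str:
    payload = repr(
        (
            topology.n_nodes,
            topology.n_edges,
            sorted(topology.meta.items()),
            stimulus,
            duration,
            dt,
            seed,
            i_baseline,
            bin_ms,
            p,
        )
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_simulation(
    topology: NetworkTopology,
    stimulus: StimulusSpec | None,
    duration: float = 1000.0,
    dt: float = 0.1,
    seed: int | None = None,
    plasticity: PlasticityParams | None = None,
    exc_params: NeuronParams = EXCITATORY,
    inh_params: NeuronParams = INHIBITORY,
    i_baseline: float = DEFAULT_BASELINE_CURRENT,
    bin_ms: float = DEFAULT_BIN_MS,
    stdp_mode: str = "nearest_two_sided",
) -> SimulationTrace:
    """Simulate the network for ``duration`` ms and return its trace.

    Initial conditions: every neuron at v0 = -65 mV, u0 = b v0; synaptic
    weights are the topological weights rescaled linearly to (0, gmax];
    binding fractions start at 0.  ``stimulus=None`` runs with the constant
    baseline drive only.  ``stdp_mode`` is ``"nearest_two_sided"`` (default:
    both causal and acausal pairings) or ``"post_only"`` (causal branch
    only, on postsynaptic spikes).
    """
    p = plasticity or PlasticityParams()
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        raise ValueError("duration must be an integer multiple of dt")
    bin_steps = int(round(bin_ms / dt))
    if abs(bin_steps * dt - bin_ms) > 1e-9 or n_steps % bin_steps != 0:
        raise ValueError("recording bins must tile the duration exactly")
    if stdp_mode not in ("nearest_two_sided", "post_only"):
        raise ValueError(f"unknown stdp_mode: {stdp_mode!r}")

    rng = np.random.default_rng(seed)
    n = topology.n_nodes
    pre = topology.pre.copy()
    post = topology.post.copy()
    n_syn = len(pre)

    # neuron arrays (Dale's principle: synapse kind = presynaptic neuron kind)
    is_exc = topology.node_kind == "E"
    a = np.where(is_exc, exc_params.a, inh_params.a).astype(float)
    b = np.where(is_exc, exc_params.b, inh_params.b).astype(float)
    c = np.where(is_exc, exc_params.c, inh_params.c).astype(float)
    d = np.where(is_exc, exc_params.d, inh_params.d).astype(float)
    v = np.full(n, V_REST)
    u = b * V_REST

    syn_exc = is_exc[pre]
    e_rev = np.where(syn_exc, p.e_ex, p.e_in)
    alpha = np.where(syn_exc, p.alpha_ex, p.alpha_in)
    beta = np.where(syn_exc, p.beta_ex, p.beta_in)
    decay = 1.0 - dt / np.where(syn_exc, p.mu_ex, p.mu_in)

    # initial weights: topological weights rescaled linearly to (0, gmax]
    g = topology.weight / topology.weight.max() * p.gmax
    g = g.astype(float).copy()
    r = np.zeros(n_syn)

    dsteps = np.maximum(1, np.round(topology.delay_ms / dt).astype(np.int64))
    buf_len = int(dsteps.max()) + 1
    vhist = np.full((buf_len, n), V_REST)
    shist = np.zeros((buf_len, n), dtype=bool)

    # afferent synapse index lists in CSR form, grouped by postsynaptic neuron
    aff_order = np.argsort(post, kind="stable")
    aff_ptr = np.searchsorted(post[aff_order], np.arange(n + 1))

    last_pre_arrival = np.full(n_syn, -np.inf)
    last_post_spike = np.full(n, -np.inf)

    kind = stimulus.kind if stimulus is not None else None
    two_sided = stdp_mode == "nearest_two_sided"

    spike_steps: list[tuple[float, np.ndarray]] = []
    msw = np.empty(n_steps // bin_steps)
    msw_accum = 0.0

    for k in range(1, n_steps + 1):
        t = k * dt

        # 1. delayed presynaptic voltages / spike arrivals
        rows = (k - dsteps) % buf_len
        v_del = vhist[rows, pre]

        # 2. kinetics + weight decay (exp may overflow harmlessly to H=0)
        with np.errstate(over="ignore"):
            h = 1.0 / (1.0 + np.exp(-(v_del - p.v_half) / p.v_slope))
        r += dt * (alpha * h * (1.0 - r) - beta * r)
        np.clip(r, 0.0, 1.0, out=r)
        g *= decay

        # 3. synaptic currents
        i_syn = g * r * (e_rev - v[post])
        i_g = np.bincount(post, weights=i_syn, minlength=n)

        # 4. exterior drive
        i_ex = np.full(n, i_baseline)
        if kind == "white_gaussian":
            i_ex += rng.normal(stimulus.mu_g, stimulus.noise_sigma, size=n)
        elif kind == "impulse":
            if stimulus.t0 <= t <= stimulus.t0 + stimulus.duration:
                i_ex += stimulus.strength
        elif kind == "ac_field":
            # ΔV = Ac cos(2πft) rides on v: couple its time derivative into dv
            i_ex += (
                -stimulus.strength
                * 2e-3 * np.pi * stimulus.freq
                * np.sin(2e-3 * np.pi * stimulus.freq * t)
            )

        # 5. neuron update (simultaneous Euler on v, u)
        i_total = i_ex + i_g
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + i_total
        du = a * (b * v - u)
        v += dt * dv
        u += dt * du
        spiked = v >= V_PEAK
        vhist[k % buf_len] = v  # pre-reset peak drives the transmitter gate
        shist[k % buf_len] = spiked
        if spiked.any():
            ids = np.nonzero(spiked)[0]
            spike_steps.append((t, ids))
            v[ids] = c[ids]
            u[ids] += d[ids]
            last_post_spike[ids] = t

        # 6. STDP
        arrived = np.nonzero(shist[rows, pre])[0]
        if len(arrived):
            last_pre_arrival[arrived] = t
            if two_sided:
                tpost = last_post_spike[post[arrived]]
                ok = np.isfinite(tpost)
                if ok.any():
                    sel = arrived[ok]
                    dt_pair = t - tpost[ok]  # >= 0: acausal branch
                    w = np.where(
                        syn_exc[sel],
                        -p.a_minus * np.exp(-dt_pair / p.tau_minus),
                        p.b_minus * np.exp(-dt_pair / p.tau_minus),
                    )
                    g[sel] = np.clip(g[sel] + w * p.gmax, 0.0, p.gmax)
        if spiked.any():
            aff = np.concatenate(
                [aff_order[aff_ptr[j]:aff_ptr[j + 1]] for j in ids]
            ) if len(ids) else np.array([], dtype=np.int64)
            if len(aff):
                tpre = last_pre_arrival[aff]
                ok = np.isfinite(tpre) & (tpre < t)  # ties handled on arrival
                sel = aff[ok]
                if len(sel):
                    dt_pair = tpre[ok] - t  # < 0: causal branch
                    w = np.where(
                        syn_exc[sel],
                        p.a_plus * np.exp(dt_pair / p.tau_plus),
                        -p.b_plus * np.exp(dt_pair / p.tau_plus),
                    )
                    g[sel] = np.clip(g[sel] + w * p.gmax, 0.0, p.gmax)

        msw_accum += g.mean()
        if k % bin_steps == 0:
            msw[k // bin_steps - 1] = msw_accum / bin_steps
            msw_accum = 0.0
            if not np.isfinite(v).all():
                raise RuntimeError(f"non-finite membrane state at step {k}")

    # assemble per-neuron spike trains
    spikes = [[] for _ in range(n)]
    for t, ids in spike_steps:
        for i in ids:
            spikes[i].append(t)
    spikes = [np.asarray(s, dtype=float) for s in spikes]

    mean_isi = _binned_mean_isi(spikes, duration, bin_ms)
    return SimulationTrace(
        spikes=spikes,
        msw_series=msw,
        mean_isi_series=mean_isi,
        bin_ms=bin_ms,
        duration=duration,
        dt=dt,
        config_hash=_config_hash(
            topology, stimulus, duration, dt, seed, i_baseline, bin_ms, p
        ),
        g_final=g,
    )
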