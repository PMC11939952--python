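# csnn — complex spiking neural networks and specific neural coding

`csnn` simulates *complex spiking neural networks* (CSNNs): networks of
Izhikevich point neurons whose topology combines small-world (SW) and
scale-free (SF) structure, wired by conductance synapses with biological
transmission delays and spike-timing-dependent plasticity (STDP).  Its
analysis layer quantifies **specific neural coding (SNC)** — the property
that a network produces reproducible inter-spike-interval (ISI) coding
patterns for the *kind* of an exterior stimulus, largely independent of its
strength.  It is aimed at computational neuroscientists studying how
brain-like topology and synaptic plasticity shape stimulus coding.

## Model

**Neurons.** Each node follows the Izhikevich model

    dv/dt = 0.04 v² + 5 v + 140 − u + I_ex + I_g
    du/dt = a (b v − u),        if v ≥ 30 mV:  v ← c, u ← u + d

with regular-spiking parameters (a, b, c, d) = (0.02, 0.20, −65, 8) for
excitatory cells and fast-spiking (0.02, 0.25, −65, 2) for inhibitory
cells, mixed 4:1.

**Synapses.** Edge i→j carries a weight g ∈ [0, gmax], a transmitter
binding fraction r ∈ [0, 1] and a delay td ~ U[0.1, 40] ms:

    I_g(t) = g r (E − V_post),         E = 0 mV (ES) / −70 mV (IS)
    dr/dt  = α H (1 − r) − β r,        H = [1 + exp(−V_pre(t − td))]⁻¹
    μ dg/dt = −g                       (decay between spike events)

On paired pre/post spikes the weight jumps by an exponential STDP window
scaled by gmax: causal pairs (Δt = t_pre − t_post < 0) potentiate
excitatory synapses by A₊ e^{Δt/τ₊} and acausal pairs depress them by
−A₋ e^{−Δt/τ₋}; inhibitory synapses use the mirrored window with B±.
Because A₋τ₋ > A₊τ₊, uncorrelated activity depresses on average.

**Topology.** A Barrat–Barthelemy–Vespignani-style growth process
(strength-preferential attachment with local weight reinforcement δ),
randomized by a reconnection probability Pn, produces weighted graphs
whose degree exponent γ and small-world coefficient
σ = (C/C_rand)/(L/L_rand) match human functional-brain-network values at
Pn = 0.3.  Weighted metrics follow the Barrat clustering coefficient C̃w
and the inverse-weight shortest path length L̃w.

**Stimuli and coding.** Three exterior stimuli — white Gaussian current
(strength in dBW), a 200 ms current impulse (mA), and an AC magnetic-field
voltage disturbance Ac·cos(2πft) (mV) — are applied at nine strengths
(5–25, step 2.5).  Each run is summarized by three pooled ISI features:
the highest ISI, the highest ISI-histogram proportion, and the highest
adjacent-ISI disparity.  Within-class cosine similarity, K-means (K=3)
clustering accuracy, and the Pearson correlation between 100 ms-binned
mean synaptic weight (MSW) and mean ISI (with a Student-t significance
test, n = 10 bins) quantify the coding.

## Worked example

```python
import csnn

topo = csnn.generate_bbv(500, 0.3, seed=1)          # N=500, Pn=0.3
print(csnn.fit_gamma(topo), csnn.small_world_sigma(topo, n_random=20, seed=2))
print(csnn.weighted_clustering(topo), csnn.weighted_spl(topo))

trace = csnn.run_simulation(topo, csnn.StimulusSpec("white_gaussian", 5.0), seed=42)
sample = csnn.extract_eigenvectors(trace, label="white_gaussian", strength=5.0)
report = csnn.relevance_analysis(trace, "white_gaussian", 5.0)
print(sample.ev1, sample.ev2, sample.ev3)
print(report.r, report.t, report.significance)
```

prints (on this machine):

```
gamma = 1.99   sigma = 1.85
C~w   = 0.149  L~w   = 3.35
coding sample: ev1=110.4 ms  ev2=0.298  ev3=22.1 ms
MSW vs mean-ISI: R=-0.971  t=-11.55  sig=0.01
```

The network is scale-free (γ ≈ 2) and small-world (σ ≈ 1.9); its weighted
path length sits in the biological band.  Under a weak white-Gaussian
stimulus the 1000 ms run yields a 3-feature coding sample, and the mean
synaptic weight is strongly anti-correlated with the mean ISI across the
ten 100 ms bins (significant at the 0.01 level) — the signature that
synaptic plasticity drives the coding dynamics.

A command-line interface wraps the same pipeline:

```
csnn generate-topology --n-nodes 500 --pn 0.3 --seed 1 --out topo/
csnn simulate --config run.yaml --out runs/
csnn analyze --config run.yaml --runs runs/ --out tables/
csnn reproduce-paper --seed 0 --out repro/
```

`reproduce-paper` emits the five summary tables (topology sweep, graph
metrics, within-class similarity, clustering accuracy, MSW–ISI
correlation) plus a pass/fail summary against the biological reference
bands; re-running with the same config reuses finished runs.

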