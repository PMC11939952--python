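"""Run configuration: YAML-backed, validated, with deterministic seed derivation.

A :class:`RunConfig` bundles every tunable of a reproduction run — topology
generation, neuron/synapse overrides, the stimulus grid, integration
settings and the master seed.  Per-run seeds are derived from the master
seed by hashing a counter key (stimulus kind, strength, replicate index),
so any single run can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .stimuli import STIMULUS_KINDS, STRENGTH_GRID

__all__ = ["TopologyConfig", "RunConfig", "derive_seed", "load_config", "save_config"]


def derive_seed(master_seed: int, *keys) -> int:
    """Deterministic sub-seed < 2**31 from a master seed and counter keys."""
    payload = repr((int(master_seed),) + tuple(keys)).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (2**31)


@dataclass
class TopologyConfig:
    """Generator settings (defaults reproduce the N=500, Pn=0.3 setup)."""

    n_nodes: int = 500
    pn: float = 0.3
    m_edges: int = 20
    w0: float = 0.52
    delta: float = 0.052
    rewire_strategy: str = "growth_and_rewire"

    def validate(self) -> None:
        if self.n_nodes < 3 or self.n_nodes < self.m_edges + 1:
            raise ValueError("n_nodes must be >= max(3, m_edges + 1)")
        if not 0 <= self.pn <= 1:
            raise ValueError("pn must lie in [0, 1]")
        if self.w0 <= 0 or self.delta <= 0:
            raise ValueError("w0 and delta must be positive")


@dataclass
class RunConfig:
    """Full experiment configuration."""

    topology: TopologyConfig = field(default_factory=TopologyConfig)
    stimulus_kinds: tuple = STIMULUS_KINDS
    strengths: tuple = STRENGTH_GRID
    duration: float = 1000.0
    dt: float = 0.1
    i_baseline: float = 5.0
    bin_ms: float = 100.0
    hist_bin_ms: float = 5.0
    impulse_t0: float = 0.0
    impulse_duration: float = 200.0
    ac_freq: float = 50.0
    master_seed: int = 0
    n_replicates: int = 1
    kmeans_repeats: int = 100
    sigma_n_random: int = 20
    synapse_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.topology.validate()
        for kind in self.stimulus_kinds:
            if kind not in STIMULUS_KINDS:
                raise ValueError(f"unknown stimulus kind: {kind!r}")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")
        if self.duration % self.bin_ms:
            raise ValueError("bin_ms must tile the duration")
        if self.n_replicates < 1 or self.kmeans_repeats < 1:
            raise ValueError("n_replicates and kmeans_repeats must be >= 1")

    def seed_for(self, *keys) -> int:
        return derive_seed(self.master_seed, *keys)

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read and validate a YAML config; unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    topo = TopologyConfig(**raw.pop("topology", {}))
    allowed = {f for f in RunConfig.__dataclass_fields__ if f != "topology"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("stimulus_kinds", "strengths"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(topology=topo, **raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    data = asdict(cfg)
    data["stimulus_kinds"] = list(cfg.stimulus_kinds)
    data["strengths"] = [float(s) for s in cfg.strengths]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
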