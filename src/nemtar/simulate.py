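"""Synthetic perturbation-screen generator and benchmark harness.

An instance is generated in four steps mirroring the model's data-
generating process: (1) sample a random DAG over m S-genes via a random
topological order with independent edge inclusion, then transitively
close it; (2) draw a per-S-gene aberration frequency and per-patient
Bernoulli perturbation states; (3) attach a fixed number of E-genes to
each S-gene; (4) predict the noise-free effects and flip cells with the
simulation error rates (0 -> 1 with alpha_sim, 1 -> 0 with beta_sim).

The benchmark harness infers each instance with a chosen search method
and scores edge recovery on the off-diagonal entries of the two closures
(TPR, TNR, Accuracy, Precision).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import inference
from .model_core import (
    NULL_ATTACHMENT,
    EffectObservations,
    EGeneAttachment,
    NoiseRates,
    PerturbationStates,
    SGeneNetwork,
    predict_effects,
    transitive_closure,
)

__all__ = [
    "SimulationConfig",
    "SimulatedInstance",
    "BenchmarkMetrics",
    "sample_network",
    "sample_states",
    "sample_attachment",
    "sample_observations",
    "simulate_instance",
    "evaluate_network",
    "run_benchmark",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the gastric-cancer analysis scale: 177 patients,
    ~80 E-genes per S-gene, per-S-gene aberration frequencies between 5%
    and 30%, and a pre-closure random-DAG edge probability of 0.25.
    """

    m: int = 6
    n_patients: int = 177
    egenes_per_sgene: int = 80
    freq_range: tuple[float, float] = (0.05, 0.30)
    edge_prob: float = 0.25
    alpha_sim: float = 0.05
    beta_sim: float = 0.05
    null_egene_fraction: float = 0.0
    n_networks: int = 200
    seed: int | None = None

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least two S-genes")
        if self.n_networks < 1:
            raise ValueError("need at least one network")
        for name in ("edge_prob", "alpha_sim", "beta_sim", "null_egene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.freq_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"freq_range must be ordered within [0, 1], got {self.freq_range}")


@dataclass
class SimulatedInstance:
    truth: SGeneNetwork
    attachment: EGeneAttachment
    states: PerturbationStates
    observations: EffectObservations
    seed: int


@dataclass
class BenchmarkMetrics:
    """Edge-level confusion metrics between two closed networks."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def tnr(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 1.0

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else 1.0

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            # nothing predicted: perfect when there is nothing to find
            return 1.0 if self.fn == 0 else 0.0
        return self.tp / (self.tp + self.fp)


def _sgene_names(m: int) -> list[str]:
    return [f"S{j + 1}" for j in range(m)]


def sample_network(m: int, edge_prob: float = 0.25, seed=None) -> SGeneNetwork:
    """Random transitively closed DAG over m S-genes.

    A uniformly random topological order is drawn and each forward pair
    becomes an edge independently with probability ``edge_prob``; the
    result is transitively closed.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    adj = np.zeros((m, m), dtype=np.int8)
    for a in range(m):
        for b in range(a + 1, m):
            if rng.random() < edge_prob:
                adj[order[a], order[b]] = 1
    return SGeneNetwork(_sgene_names(m), transitive_closure(adj))


def sample_states(
    m: int,
    n_patients: int,
    freq_range: tuple[float, float] = (0.05, 0.30),
    seed=None,
) -> PerturbationStates:
    """Per-patient Bernoulli aberration states.

    Each S-gene first draws its cohort aberration frequency uniformly
    from ``freq_range``; patients then carry independent Bernoulli
    states at that frequency.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(freq_range[0], freq_range[1], size=m)
    states = (rng.random((n_patients, m)) < freqs).astype(np.int8)
    return PerturbationStates(
        [f"P{k + 1}" for k in range(n_patients)], _sgene_names(m), states
    )


def sample_attachment(
    m: int,
    egenes_per_sgene: int = 80,
    null_fraction: float = 0.0,
    seed=None,
) -> EGeneAttachment:
    """Attach a fixed number of E-genes to every S-gene.

    By default every E-gene is informative; ``null_fraction`` adds that
    proportion of extra null-attached E-genes for robustness studies.
    """
    rng = np.random.default_rng(seed)
    attach = np.repeat(np.arange(m), egenes_per_sgene)
    if null_fraction > 0:
        n_null = int(round(null_fraction * attach.size))
        attach = np.concatenate([attach, np.full(n_null, NULL_ATTACHMENT)])
    rng.shuffle(attach)
    names = [f"E{i + 1}" for i in range(attach.size)]
    return EGeneAttachment(names, attach)


def sample_observations(
    truth: SGeneNetwork,
    states: PerturbationStates,
    attachment: EGeneAttachment,
    alpha_sim: float,
    beta_sim: float,
    seed=None,
) -> EffectObservations:
    """Noise-free predicted effects corrupted by independent bit flips.

    Cells predicted 0 flip to 1 with probability ``alpha_sim`` (false
    positives); cells predicted 1 flip to 0 with probability ``beta_sim``
    (false negatives).
    """
    rng = np.random.default_rng(seed)
    clean = predict_effects(truth, states, attachment)
    u = rng.random(clean.shape)
    flip = np.where(clean == 1, u < beta_sim, u < alpha_sim)
    noisy = np.where(flip, 1 - clean, clean).astype(np.int8)
    return EffectObservations(states.patient_ids, attachment.egene_names, noisy)


def simulate_instance(config: SimulationConfig, seed=None) -> SimulatedInstance:
    """One complete synthetic instance under the given study conditions."""
    seed_seq = np.random.SeedSequence(config.seed if seed is None else seed)
    s_net, s_states, s_attach, s_obs = (
        s.generate_state(1)[0] for s in seed_seq.spawn(4)
    )
    truth = sample_network(config.m, config.edge_prob, s_net)
    states = sample_states(config.m, config.n_patients, config.freq_range, s_states)
    attachment = sample_attachment(
        config.m, config.egenes_per_sgene, config.null_egene_fraction, s_attach
    )
    observations = sample_observations(
        truth, states, attachment, config.alpha_sim, config.beta_sim, s_obs
    )
    return SimulatedInstance(
        truth, attachment, states, observations, int(seed_seq.entropy)
    )


def evaluate_network(truth: SGeneNetwork, inferred: SGeneNetwork) -> BenchmarkMetrics:
    """Edge confusion over ordered off-diagonal pairs of the two closures."""
    if truth.names != inferred.names:
        raise ValueError("truth and inferred networks must share the node set")
    off = ~np.eye(truth.m, dtype=bool)
    t = truth.adjacency[off].astype(bool)
    p = inferred.adjacency[off].astype(bool)
    return BenchmarkMetrics(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        fn=int((t & ~p).sum()),
        tn=int((~t & ~p).sum()),
    )


_METHODS = {
    "exhaustive": lambda inst, rates, seed, kw: inference.exhaustive_search(
        inst.observations, inst.states, rates
    ),
    "pairwise": lambda inst, rates, seed, kw: inference.pairwise_search(
        inst.observations, inst.states, rates
    ),
    "triples": lambda inst, rates, seed, kw: inference.triples_search(
        inst.observations, inst.states, rates
    ),
    "greedy": lambda inst, rates, seed, kw: inference.greedy_hill_climb(
        inst.observations, inst.states, rates
    ),
    "mcmc": lambda inst, rates, seed, kw: inference.mcmc_search(
        inst.observations, inst.states, rates, seed=seed, **kw
    ),
}


def run_benchmark(
    config: SimulationConfig,
    method: str = "greedy",
    rates: NoiseRates | None = None,
    **method_kwargs,
) -> pd.DataFrame:
    """Generate, infer and score ``config.n_networks`` instances.

    ``rates`` are the noise rates assumed during inference; they default
    to the simulation rates (the matched-model regime).  Returns one row
    per instance with the confusion counts, the four edge metrics and the
    wall-clock inference time.  Fully deterministic under ``config.seed``.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    if rates is None:
        rates = NoiseRates(config.alpha_sim, config.beta_sim)
    seed_seq = np.random.SeedSequence(config.seed)
    rows = []
    for rep, child in enumerate(seed_seq.spawn(config.n_networks)):
        inst_seed, method_seed = (s.generate_state(1)[0] for s in child.spawn(2))
        inst = simulate_instance(replace(config, n_networks=1), seed=inst_seed)
        t0 = time.perf_counter()
        result = _METHODS[method](inst, rates, method_seed, method_kwargs)
        elapsed = time.perf_counter() - t0
        metrics = evaluate_network(inst.truth, result.network)
        rows.append(
            {
                "replicate": rep,
                "m": config.m,
                "alpha_sim": config.alpha_sim,
                "beta_sim": config.beta_sim,
                "method": method,
                "tp": metrics.tp,
                "fp": metrics.fp,
                "fn": metrics.fn,
                "tn": metrics.tn,
                "tpr": metrics.tpr,
                "tnr": metrics.tnr,
                "accuracy": metrics.accuracy,
                "precision": metrics.precision,
                "log_marginal": result.log_marginal,
                "seconds": elapsed,
            }
        )
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and median of the four edge metrics per condition."""
    keys = ["method", "m", "alpha_sim", "beta_sim"]
    agg = table.groupby(keys)[["tpr", "tnr", "accuracy", "precision"]].agg(
        ["mean", "median"]
    )
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
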