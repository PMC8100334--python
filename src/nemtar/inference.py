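"""Structure search over transitively closed DAGs of S-genes.

Five strategies are provided, from exact to heuristic:

* :func:`exhaustive_search` — global optimum over all transitively closed
  DAGs, feasible only up to five S-genes;
* :func:`pairwise_search` — each unordered S-gene pair is classified into
  one of four local models (unconnected, superset, subset,
  undistinguishable) by marginal likelihood, and the directed verdicts are
  assembled and closed;
* :func:`triples_search` — every node triple is scored against the 29
  quasi-orders on three labeled nodes; edges present in a majority of the
  per-triple MAP models are kept, then closed;
* :func:`greedy_hill_climb` — edge-addition hill climbing from an initial
  graph (default empty), committing the best-improving edge until no edge
  improves the marginal likelihood;
* :func:`mcmc_search` — Metropolis–Hastings over skeleton graphs with
  single-edge-toggle proposals; the consensus network collects closure
  edges whose posterior inclusion frequency reaches a threshold.

All methods return an :class:`InferenceResult` whose ``log_marginal`` is
the marginal log-likelihood of the returned (closed) network recomputed
from scratch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np

from .model_core import (
    EffectObservations,
    NoiseRates,
    PerturbationStates,
    SGeneNetwork,
    _closure_and_acyclic,
    attachment_logliks,
    marginal_loglikelihood,
    transitive_closure,
)

__all__ = [
    "InferenceResult",
    "enumerate_quasi_orders",
    "enumerate_closed_dags",
    "exhaustive_search",
    "pairwise_search",
    "triples_search",
    "greedy_hill_climb",
    "mcmc_search",
]

#: Minimal gain for an edge addition to count as an improvement.
IMPROVEMENT_TOL = 1e-9


@dataclass
class InferenceResult:
    network: SGeneNetwork
    log_marginal: float
    method: str
    diagnostics: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------


def _all_digraphs(m: int) -> np.ndarray:
    """Stack of all 2^(m^2-m) off-diagonal digraphs, shape (N, m, m)."""
    off = [(i, j) for i in range(m) for j in range(m) if i != j]
    n_bits = len(off)
    codes = np.arange(1 << n_bits, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(n_bits)) & 1
    adj = np.zeros((codes.size, m, m), dtype=bool)
    for b, (i, j) in enumerate(off):
        adj[:, i, j] = bits[:, b].astype(bool)
    return adj


def _vector_closure(adj: np.ndarray) -> np.ndarray:
    """Warshall closure applied to a stack of adjacency matrices.

    Diagonal entries become 1 for nodes on a directed cycle, which is the
    acyclicity detector used by the callers.
    """
    closed = adj.copy()
    m = adj.shape[1]
    for k in range(m):
        closed |= closed[:, :, k, None] & closed[:, None, k, :]
    return closed


def enumerate_quasi_orders(m: int) -> list[np.ndarray]:
    """All distinct transitively closed digraphs on m labeled nodes.

    Reflexivity is implicit, so cycles among distinct nodes are allowed
    (these are the quasi-orders, e.g. the undistinguishable pair A<->B).
    There are 4 on two nodes and 29 on three.  Limited to m <= 4, beyond
    which the candidate space explodes.
    """
    if not (1 <= m <= 4):
        raise ValueError(
            f"quasi-order enumeration supports 1 <= m <= 4 nodes, got {m}"
        )
    adj = _all_digraphs(m)
    closed = _vector_closure(adj)
    off = ~np.eye(m, dtype=bool)
    is_closed = (closed[:, off] == adj[:, off]).all(axis=1)
    return [a.astype(np.int8) for a in adj[is_closed]]


def enumerate_closed_dags(m: int) -> list[np.ndarray]:
    """All transitively closed DAGs (labeled posets) on m <= 5 nodes."""
    if not (1 <= m <= 5):
        raise ValueError(
            f"exhaustive DAG enumeration supports 1 <= m <= 5 nodes, got {m}; "
            "use a heuristic search for larger networks"
        )
    adj = _all_digraphs(m)
    closed = _vector_closure(adj)
    off = ~np.eye(m, dtype=bool)
    is_closed = (closed[:, off] == adj[:, off]).all(axis=1)
    acyclic = ~closed[:, np.eye(m, dtype=bool)].any(axis=1)
    return [a.astype(np.int8) for a in adj[is_closed & acyclic]]


# ---------------------------------------------------------------------------
# Shared scoring helpers
# ---------------------------------------------------------------------------


def _score_relation(
    relation: np.ndarray,
    states: np.ndarray,
    data: np.ndarray,
    rates: NoiseRates,
) -> float:
    """Marginal log-likelihood of any closed relation (cycles allowed)."""
    m = relation.shape[0]
    reach = (relation.astype(bool) | np.eye(m, dtype=bool)).astype(np.int8)
    ll = attachment_logliks(reach, states, data, rates)
    mx = ll.max(axis=1)
    lse = mx + np.log(np.exp(ll - mx[:, None]).sum(axis=1))
    return float(lse.sum() - data.shape[1] * np.log(m + 1))


def _edge_tuple(adj: np.ndarray) -> tuple[tuple[int, int], ...]:
    return tuple(zip(*np.nonzero(adj)))


def _validate_inputs(
    data: EffectObservations, states: PerturbationStates
) -> None:
    if data.patient_ids != states.patient_ids:
        raise ValueError("patient rows of observations and states are not aligned")


def _result(
    adjacency: np.ndarray,
    names: list[str],
    states: PerturbationStates,
    data: EffectObservations,
    rates: NoiseRates,
    method: str,
    diagnostics: dict[str, Any],
) -> InferenceResult:
    network = SGeneNetwork(names, adjacency)
    score = marginal_loglikelihood(network, states, data, rates)
    return InferenceResult(network, score, method, diagnostics)


def _acyclic_part(adj: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Drop edges internal to strongly connected components.

    Locally inferred verdicts can assemble into directed cycles, which the
    final DAG cannot represent (mutually undistinguishable S-genes).  Edges
    within an SCC are removed and reported; edges between SCCs survive.
    """
    g = nx.DiGraph(zip(*np.nonzero(adj)))
    comp = {}
    for c, nodes in enumerate(nx.strongly_connected_components(g)):
        for v in nodes:
            comp[v] = c
    kept = np.zeros_like(adj)
    dropped: list[tuple[int, int]] = []
    for i, j in zip(*np.nonzero(adj)):
        if comp.get(i) != comp.get(j):
            kept[i, j] = 1
        else:
            dropped.append((int(i), int(j)))
    return kept, dropped


# ---------------------------------------------------------------------------
# Exhaustive search
# ---------------------------------------------------------------------------


def exhaustive_search(
    data: EffectObservations,
    states: PerturbationStates,
    rates: NoiseRates,
) -> InferenceResult:
    """Global maximum-marginal-likelihood network over all closed DAGs.

    Feasible only for m <= 5 S-genes.  Score ties (within 1e-9) are broken
    by fewest edges, then lexicographic edge order.
    """
    _validate_inputs(data, states)
    names = states.sgene_names
    m = len(names)
    candidates = enumerate_closed_dags(m)  # raises for m > 5
    scores = np.array(
        [_score_relation(a, states.states, data.data, rates) for a in candidates]
    )
    best = scores.max()
    tied = [i for i in range(len(candidates)) if scores[i] >= best - IMPROVEMENT_TOL]
    tied.sort(key=lambda i: (int(candidates[i].sum()), _edge_tuple(candidates[i])))
    winner = tied[0]
    return _result(
        candidates[winner], names, states, data, rates, "exhaustive",
        {"n_candidates": len(candidates), "n_tied": len(tied)},
    )


# ---------------------------------------------------------------------------
# Pairwise search
# ---------------------------------------------------------------------------

_PAIR_MODELS = {
    "unconnected": np.array([[0, 0], [0, 0]], dtype=np.int8),
    "superset": np.array([[0, 1], [0, 0]], dtype=np.int8),  # A -> B
    "subset": np.array([[0, 0], [1, 0]], dtype=np.int8),  # A <- B
    "undistinguishable": np.array([[0, 1], [1, 0]], dtype=np.int8),  # A <-> B
}


def pairwise_search(
    data: EffectObservations,
    states: PerturbationStates,
    rates: NoiseRates,
) -> InferenceResult:
    """Classify every S-gene pair into one of four local models.

    Each pair (A, B) is scored on the two perturbation columns alone
    against: unconnected, A->B (effects of A a superset of B's), A<-B,
    and A<->B (undistinguishable).  The MAP verdicts contribute their
    directed edges (undistinguishable contributes none), the assembly is
    reduced to its acyclic part and transitively closed.
    """
    _validate_inputs(data, states)
    names = states.sgene_names
    m = len(names)
    if m < 2:
        raise ValueError("pairwise search needs at least two S-genes")
    verdicts: dict[tuple[str, str], str] = {}
    raw = np.zeros((m, m), dtype=np.int8)
    model_items = list(_PAIR_MODELS.items())
    for a, b in itertools.combinations(range(m), 2):
        sub_states = states.states[:, [a, b]]
        scores = [
            _score_relation(adj, sub_states, data.data, rates)
            for _, adj in model_items
        ]
        best = max(scores)
        tied = [i for i, s in enumerate(scores) if s >= best - IMPROVEMENT_TOL]
        # prefer fewer edges, then listed order (superset before subset)
        tied.sort(key=lambda i: (int(model_items[i][1].sum()), i))
        name, adj = model_items[tied[0]]
        verdicts[(names[a], names[b])] = name
        if adj[0, 1] and not adj[1, 0]:
            raw[a, b] = 1
        elif adj[1, 0] and not adj[0, 1]:
            raw[b, a] = 1
    acyclic, dropped = _acyclic_part(raw)
    closed = transitive_closure(acyclic)
    return _result(
        closed, names, states, data, rates, "pairwise",
        {
            "pair_verdicts": verdicts,
            "dropped_cycle_edges": [(names[i], names[j]) for i, j in dropped],
        },
    )


# ---------------------------------------------------------------------------
# Triples search
# ---------------------------------------------------------------------------


def triples_search(
    data: EffectObservations,
    states: PerturbationStates,
    rates: NoiseRates,
    majority: float = 0.5,
) -> InferenceResult:
    """Edgewise averaging of MAP quasi-orders over all node triples.

    Every triple is scored against the 29 quasi-orders on its three
    perturbation columns.  A directed edge enters the final graph iff it
    appears in strictly more than ``majority`` of the MAP models of the
    (m-2) triples containing both endpoints; the thresholded graph is
    reduced to its acyclic part and then closed.
    """
    _validate_inputs(data, states)
    names = states.sgene_names
    m = len(names)
    if m < 3:
        raise ValueError("triples search needs at least three S-genes")
    models = enumerate_quasi_orders(3)
    order = sorted(
        range(len(models)), key=lambda i: (int(models[i].sum()), _edge_tuple(models[i]))
    )
    edge_votes = np.zeros((m, m), dtype=np.int64)
    map_models: dict[tuple[str, str, str], np.ndarray] = {}
    for triple in itertools.combinations(range(m), 3):
        sub_states = states.states[:, list(triple)]
        scores = [
            _score_relation(models[i], sub_states, data.data, rates) for i in order
        ]
        best = max(scores)
        # order already sorts by edge count then lexicographic edges
        winner = models[order[next(
            i for i, s in enumerate(scores) if s >= best - IMPROVEMENT_TOL
        )]]
        map_models[tuple(names[t] for t in triple)] = winner
        for li, gi in enumerate(triple):
            for lj, gj in enumerate(triple):
                if li != lj and winner[li, lj]:
                    edge_votes[gi, gj] += 1
    n_triples_per_pair = m - 2
    raw = (edge_votes > majority * n_triples_per_pair).astype(np.int8)
    acyclic, dropped = _acyclic_part(raw)
    closed = transitive_closure(acyclic)
    return _result(
        closed, names, states, data, rates, "triples",
        {
            "map_models": map_models,
            "edge_votes": edge_votes,
            "dropped_cycle_edges": [(names[i], names[j]) for i, j in dropped],
        },
    )


# ---------------------------------------------------------------------------
# Greedy hill climbing
# ---------------------------------------------------------------------------


def greedy_hill_climb(
    data: EffectObservations,
    states: PerturbationStates,
    rates: NoiseRates,
    init: SGeneNetwork | None = None,
) -> InferenceResult:
    """Edge-addition hill climbing on transitively closed DAGs.

    From the initial network (default empty) every addable off-diagonal
    edge that keeps the graph acyclic is scored after re-closure; the edge
    with the largest marginal-log-likelihood gain above 1e-9 is committed.
    Ties go to the lexicographically smallest (source, target) pair.
    Add-only: committed edges are never removed or reversed.
    """
    _validate_inputs(data, states)
    names = states.sgene_names
    m = len(names)
    if init is None:
        current = np.zeros((m, m), dtype=np.int8)
    else:
        if init.names != names:
            raise ValueError("init network S-gene order does not match the states")
        current = init.adjacency.copy()
    current_score = _score_relation(current, states.states, data.data, rates)
    trace = [current_score]
    steps: list[tuple[str, str]] = []
    while True:
        best_gain = IMPROVEMENT_TOL
        best_edge = None
        best_adj = None
        best_score = None
        for u in range(m):
            for v in range(m):
                # closure[u,v]==1 means present; closure[v,u]==1 means a cycle
                if u == v or current[u, v] or current[v, u]:
                    continue
                cand = current.copy()
                cand[u, v] = 1
                cand = transitive_closure(cand)
                score = _score_relation(cand, states.states, data.data, rates)
                gain = score - current_score
                if gain > best_gain:
                    best_gain = gain
                    best_edge = (u, v)
                    best_adj = cand
                    best_score = score
        if best_edge is None:
            break
        current = best_adj
        current_score = best_score
        trace.append(current_score)
        steps.append((names[best_edge[0]], names[best_edge[1]]))
    return _result(
        current, names, states, data, rates, "greedy",
        {"score_trace": trace, "added_edges": steps},
    )


# ---------------------------------------------------------------------------
# MCMC search
# ---------------------------------------------------------------------------


def mcmc_search(
    data: EffectObservations,
    states: PerturbationStates,
    rates: NoiseRates,
    n_iter: int = 10000,
    burn_in: int = 2000,
    seed: int | None = None,
    consensus_threshold: float = 0.5,
    init: SGeneNetwork | None = None,
) -> InferenceResult:
    """Metropolis–Hastings sampling over S-gene graph skeletons.

    The chain state is an acyclic skeleton; a proposal toggles one
    uniformly chosen off-diagonal edge and is rejected outright if the
    toggle creates a directed cycle.  Proposals are scored by the marginal
    log-likelihood of their transitive closure and accepted with
    probability min(1, exp(delta)).  After burn-in the edge inclusion
    frequencies of the visited closures are accumulated; the consensus
    network is the closure of the acyclic part of the edges whose
    frequency reaches ``consensus_threshold``.
    """
    _validate_inputs(data, states)
    if not (n_iter > burn_in >= 0):
        raise ValueError(f"need n_iter > burn_in >= 0, got {n_iter}, {burn_in}")
    names = states.sgene_names
    m = len(names)
    rng = np.random.default_rng(seed)
    if init is None:
        skeleton = np.zeros((m, m), dtype=np.int8)
    else:
        if init.names != names:
            raise ValueError("init network S-gene order does not match the states")
        skeleton = init.adjacency.copy()
    closure = transitive_closure(skeleton)
    score_cache: dict[bytes, float] = {}

    def score_of(closed: np.ndarray) -> float:
        key = closed.tobytes()
        if key not in score_cache:
            score_cache[key] = _score_relation(
                closed, states.states, data.data, rates
            )
        return score_cache[key]

    current_score = score_of(closure)
    off_pairs = [(i, j) for i in range(m) for j in range(m) if i != j]
    freq = np.zeros((m, m), dtype=np.float64)
    n_recorded = 0
    n_accept = 0
    pair_idx = rng.integers(0, len(off_pairs), size=n_iter)
    unif = rng.random(n_iter)
    for t in range(n_iter):
        u, v = off_pairs[pair_idx[t]]
        proposal = skeleton.copy()
        proposal[u, v] ^= 1
        prop_closure, acyclic = _closure_and_acyclic(proposal)
        if acyclic:
            prop_score = score_of(prop_closure)
            delta = prop_score - current_score
            if delta >= 0 or unif[t] < np.exp(delta):
                skeleton = proposal
                closure = prop_closure
                current_score = prop_score
                n_accept += 1
        if t >= burn_in:
            freq += closure
            n_recorded += 1
    freq /= n_recorded
    raw = (freq >= consensus_threshold).astype(np.int8)
    acyclic_raw, dropped = _acyclic_part(raw)
    consensus = transitive_closure(acyclic_raw)
    return _result(
        consensus, names, states, data, rates, "mcmc",
        {
            "edge_frequency": freq,
            "acceptance_rate": n_accept / n_iter,
            "n_recorded": n_recorded,
            "dropped_cycle_edges": [(names[i], names[j]) for i, j in dropped],
            "final_score": current_score,
        },
    )
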