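"""Core probabilistic model for nested-effects network inference.

A nested effects model explains binary downstream observations (E-genes)
through a hidden, transitively closed signaling graph over regulators
(S-genes) and a hidden attachment of each E-gene to at most one S-gene.
Here perturbations are "natural": each patient carries an arbitrary subset
of aberrant S-genes, encoded in a binary state matrix, and an E-gene is
expected to show an effect in a patient whenever some perturbed regulator
reaches its attachment point in the graph.

The module provides the domain containers, transitive closure and
reachability, effect prediction, the two-rate binary noise model
(type-I rate alpha for false alarms, type-II rate beta for missed
effects), the marginal log-likelihood of a network (attachments
integrated out under a uniform prior over the m S-genes plus a null
S-gene that predicts no effects), and the per-E-gene attachment
posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NULL_ATTACHMENT",
    "SGeneNetwork",
    "PerturbationStates",
    "EGeneAttachment",
    "EffectObservations",
    "NoiseRates",
    "AttachmentPosterior",
    "transitive_closure",
    "predict_effects",
    "cell_loglik",
    "marginal_loglikelihood",
    "attachment_posterior",
]

#: Sentinel attachment index for the null S-gene (an E-gene attached to it
#: is predicted to show no effect in any patient).  For a model with m
#: S-genes the null index is m, i.e. one past the last real S-gene.
NULL_ATTACHMENT = -1

_LOG_TOL = 1e-9


def _as_binary_matrix(x, name: str) -> np.ndarray:
    a = np.asarray(x)
    if a.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {a.shape}")
    if a.size and not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1 entries only)")
    return a.astype(np.int8)


def transitive_closure(adjacency) -> np.ndarray:
    """Smallest superset of the input edge set closed under transitivity.

    Operates on the off-diagonal relation; the diagonal of the input is
    returned unchanged (self-reachability is implicit throughout the
    package).  Input cycles are permitted — closure is defined for any
    relation.  Idempotent and monotone in the edge set.
    """
    adj = _as_binary_matrix(adjacency, "adjacency")
    m, m2 = adj.shape
    if m != m2:
        raise ValueError(f"adjacency must be square, got {adj.shape}")
    diag = np.diagonal(adj).copy()
    closed = adj.astype(bool)
    for k in range(m):
        closed |= np.outer(closed[:, k], closed[k, :])
    closed = closed.astype(np.int8)
    np.fill_diagonal(closed, diag)
    return closed


def _closure_and_acyclic(adjacency: np.ndarray) -> tuple[np.ndarray, bool]:
    """Closure plus an off-diagonal acyclicity flag (no length>=1 cycle)."""
    adj = np.asarray(adjacency, dtype=bool)
    m = adj.shape[0]
    closed = adj.copy()
    for k in range(m):
        closed |= np.outer(closed[:, k], closed[k, :])
    acyclic = not bool(np.diagonal(closed).any())
    closed = closed.astype(np.int8)
    np.fill_diagonal(closed, np.diagonal(adjacency))
    return closed, acyclic


@dataclass
class SGeneNetwork:
    """Transitively closed DAG over m S-genes.

    ``adjacency[j_from, j_to] == 1`` encodes a directed edge; the diagonal
    is stored as 0 but every node implicitly reaches itself.
    """

    names: list[str]
    adjacency: np.ndarray

    def __post_init__(self):
        self.names = list(self.names)
        self.adjacency = _as_binary_matrix(self.adjacency, "adjacency")
        m = len(self.names)
        if self.adjacency.shape != (m, m):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{m} S-gene names"
            )
        if len(set(self.names)) != m:
            raise ValueError("duplicate S-gene names")
        if np.diagonal(self.adjacency).any():
            raise ValueError("self-loops must not be stored (diagonal must be 0)")
        closed, acyclic = _closure_and_acyclic(self.adjacency)
        if not acyclic:
            raise ValueError("adjacency contains a directed cycle among distinct nodes")
        if not np.array_equal(closed, self.adjacency):
            raise ValueError("adjacency is not transitively closed")

    @property
    def m(self) -> int:
        return len(self.names)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def reach_matrix(self) -> np.ndarray:
        """Reachability including self: closure plus the identity."""
        return (self.adjacency.astype(bool) | np.eye(self.m, dtype=bool)).astype(np.int8)

    def reach(self, j: int) -> set[int]:
        """Indices of S-genes reachable from j, including j itself."""
        return set(np.flatnonzero(self.reach_matrix()[j]))

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown S-gene name {name!r}") from None

    @classmethod
    def from_edges(cls, names: list[str], edges: list[tuple[str, str]]) -> "SGeneNetwork":
        """Build from an edge list; the closure is taken automatically."""
        idx = {n: i for i, n in enumerate(names)}
        adj = np.zeros((len(names), len(names)), dtype=np.int8)
        for src, tgt in edges:
            adj[idx[src], idx[tgt]] = 1
        return cls(names, transitive_closure(adj))


@dataclass
class PerturbationStates:
    """Binary patient x S-gene aberration states (the natural perturbations)."""

    patient_ids: list[str]
    sgene_names: list[str]
    states: np.ndarray

    def __post_init__(self):
        self.patient_ids = list(self.patient_ids)
        self.sgene_names = list(self.sgene_names)
        self.states = _as_binary_matrix(self.states, "states")
        if len(self.patient_ids) < 1:
            raise ValueError("need at least one patient")
        if self.states.shape != (len(self.patient_ids), len(self.sgene_names)):
            raise ValueError(
                f"states shape {self.states.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.sgene_names)} S-genes"
            )
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids")

    @property
    def l(self) -> int:  # noqa: E743 - field-standard symbol for cohort size
        return len(self.patient_ids)


@dataclass
class EGeneAttachment:
    """Assignment of each E-gene to one S-gene index or the null S-gene.

    ``attach`` holds 0-based S-gene indices; :data:`NULL_ATTACHMENT` marks
    an E-gene attached to the null S-gene (no effects predicted anywhere).
    """

    egene_names: list[str]
    attach: np.ndarray

    def __post_init__(self):
        self.egene_names = list(self.egene_names)
        self.attach = np.asarray(self.attach, dtype=np.int64)
        if self.attach.ndim != 1 or self.attach.shape[0] != len(self.egene_names):
            raise ValueError("attach must be a vector with one entry per E-gene")

    @property
    def n(self) -> int:
        return len(self.egene_names)


@dataclass
class EffectObservations:
    """Binary patient x E-gene differential-expression calls."""

    patient_ids: list[str]
    egene_names: list[str]
    data: np.ndarray

    def __post_init__(self):
        self.patient_ids = list(self.patient_ids)
        self.egene_names = list(self.egene_names)
        self.data = _as_binary_matrix(self.data, "data")
        if self.data.shape != (len(self.patient_ids), len(self.egene_names)):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.patient_ids)} patients x {len(self.egene_names)} E-genes"
            )
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids")
        if len(set(self.egene_names)) != len(self.egene_names):
            raise ValueError("duplicate E-gene names")

    @property
    def n(self) -> int:
        return len(self.egene_names)


@dataclass(frozen=True)
class NoiseRates:
    """Independent binary observation error rates.

    alpha: type-I (false alarm) probability of observing an effect where
    none is predicted.  beta: type-II probability of missing a predicted
    effect.  Rates of exactly 1 are rejected: they make every matching
    observation impossible.
    """

    alpha: float
    beta: float

    def __post_init__(self):
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if not (0.0 <= self.beta < 1.0):
            raise ValueError(f"beta must be in [0, 1), got {self.beta}")


@dataclass
class AttachmentPosterior:
    """Row-stochastic n x (m+1) posterior over E-gene attachments.

    Column order follows the network's S-genes; the last column is the
    null S-gene.
    """

    egene_names: list[str]
    sgene_names: list[str]
    posterior: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.posterior = np.asarray(self.posterior, dtype=float)
        n, cols = self.posterior.shape
        if n != len(self.egene_names) or cols != len(self.sgene_names) + 1:
            raise ValueError(
                "posterior must be n_egenes x (n_sgenes + 1) with a final null column"
            )
        if (self.posterior < 0).any():
            raise ValueError("posterior entries must be non-negative")
        if not np.allclose(self.posterior.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")

    @property
    def null_column(self) -> int:
        return len(self.sgene_names)

    def map_attachment(self) -> np.ndarray:
        """MAP attachment per E-gene; ties resolve to the lowest index.

        Returns 0-based S-gene indices, with :data:`NULL_ATTACHMENT` for
        rows whose mode is the null column.
        """
        idx = np.argmax(self.posterior, axis=1)
        return np.where(idx == self.null_column, NULL_ATTACHMENT, idx)


# ---------------------------------------------------------------------------
# Effect prediction and likelihood
# ---------------------------------------------------------------------------


def _check_alignment(network: SGeneNetwork, states: PerturbationStates) -> None:
    if states.sgene_names != network.names:
        raise ValueError(
            "PerturbationStates S-gene order does not match the network: "
            f"{states.sgene_names} vs {network.names}"
        )


def _predicted_effects_by_attachment(
    reach_with_self: np.ndarray, states: np.ndarray
) -> np.ndarray:
    """l x (m+1) binary matrix: column j is the effect pattern an E-gene
    attached to S-gene j would show; the last (null) column is all zero.

    Patient k shows an effect under attachment j iff some perturbed
    S-gene of k reaches j.
    """
    pred = (states.astype(np.float64) @ reach_with_self.astype(np.float64)) > 0
    null_col = np.zeros((states.shape[0], 1), dtype=bool)
    return np.concatenate([pred, null_col], axis=1)


def predict_effects(
    network: SGeneNetwork,
    states: PerturbationStates,
    attachment: EGeneAttachment,
) -> np.ndarray:
    """Noise-free expected observations for a fixed attachment.

    Entry (k, i) is 1 iff E-gene i is attached to a non-null S-gene that
    is reachable (including self) from at least one S-gene perturbed in
    patient k.  This is the patient-level generalization of the classic
    expected-profile product of the graph and the attachment, to which it
    reduces when every patient perturbs exactly one S-gene.
    """
    _check_alignment(network, states)
    m = network.m
    if attachment.attach.size:
        bad = (attachment.attach != NULL_ATTACHMENT) & (
            (attachment.attach < 0) | (attachment.attach >= m)
        )
        if bad.any():
            raise ValueError("attachment indices out of range")
    pred = _predicted_effects_by_attachment(network.reach_matrix(), states.states)
    cols = np.where(attachment.attach == NULL_ATTACHMENT, m, attachment.attach)
    return pred[:, cols].astype(np.int8)


def cell_loglik(e: int, effect_expected: int, rates: NoiseRates) -> float:
    """Log-probability of one observed cell given its predicted state.

    Predicted no effect: observe 1 with probability alpha, 0 with 1-alpha.
    Predicted effect: observe 1 with probability 1-beta, 0 with beta.
    A zero rate yields -inf for the impossible observation.
    """
    if e not in (0, 1) or effect_expected not in (0, 1):
        raise ValueError("e and effect_expected must be 0 or 1")
    if effect_expected:
        p = 1.0 - rates.beta if e else rates.beta
    else:
        p = rates.alpha if e else 1.0 - rates.alpha
    with np.errstate(divide="ignore"):
        return float(np.log(p))


def _log_rates(rates: NoiseRates) -> tuple[float, float, float, float]:
    with np.errstate(divide="ignore"):
        la = np.log(rates.alpha)
        l1a = np.log1p(-rates.alpha)
        lb = np.log(rates.beta)
        l1b = np.log1p(-rates.beta)
    return float(la), float(l1a), float(lb), float(l1b)


def _weighted(count: np.ndarray, logp: float) -> np.ndarray:
    # count * logp with the 0 * (-inf) = 0 convention for zero rates
    if np.isneginf(logp):
        return np.where(count > 0, -np.inf, 0.0)
    return count * logp


def attachment_logliks(
    reach_with_self: np.ndarray,
    states: np.ndarray,
    data: np.ndarray,
    rates: NoiseRates,
) -> np.ndarray:
    """n x (m+1) matrix of log P(column i of D | attachment j).

    Works on raw reachability so that quasi-order candidates (which may
    contain reciprocal edges during pairwise/triple scoring) can be scored
    with the same kernel as valid DAG networks.
    """
    if np.isnan(states).any() or np.isnan(data).any():
        raise ValueError("NaN in inputs")
    l, m = states.shape
    if l == 0:
        raise ValueError("empty patient set")
    pred = _predicted_effects_by_attachment(reach_with_self, states)
    la, l1a, lb, l1b = _log_rates(rates)
    # float64 matmul hits BLAS; the counts stay exactly representable
    E = data.astype(np.float64)
    P = pred.astype(np.float64)
    n11 = E.T @ P  # observed 1, predicted 1
    e1 = E.sum(axis=0)[:, None]
    p1 = P.sum(axis=0)[None, :]
    n10 = e1 - n11  # observed 1, predicted 0
    n01 = p1 - n11  # observed 0, predicted 1
    n00 = l - e1 - p1 + n11
    return (
        _weighted(n11, l1b)
        + _weighted(n10, la)
        + _weighted(n01, lb)
        + _weighted(n00, l1a)
    )


def marginal_loglikelihood(
    network: SGeneNetwork,
    states: PerturbationStates,
    data: EffectObservations,
    rates: NoiseRates,
) -> float:
    """Log marginal likelihood of the network, attachments integrated out.

    E-genes are independent; each carries a uniform prior 1/(m+1) over
    the m S-genes plus the null S-gene.  Computed in log space with
    log-sum-exp.
    """
    _check_alignment(network, states)
    if data.n == 0:
        raise ValueError("need at least one E-gene")
    if data.patient_ids != states.patient_ids:
        raise ValueError("patient rows of observations and states are not aligned")
    ll = attachment_logliks(
        network.reach_matrix(), states.states, data.data, rates
    )
    return _logsumexp_rows(ll).sum() - data.n * np.log(network.m + 1)


def _logsumexp_rows(ll: np.ndarray) -> np.ndarray:
    mx = ll.max(axis=1)
    out = np.full(ll.shape[0], -np.inf)
    finite = np.isfinite(mx)
    if finite.any():
        sub = ll[finite] - mx[finite, None]
        out[finite] = mx[finite] + np.log(np.exp(sub).sum(axis=1))
    return out


def attachment_posterior(
    network: SGeneNetwork,
    states: PerturbationStates,
    data: EffectObservations,
    rates: NoiseRates,
) -> AttachmentPosterior:
    """Posterior over each E-gene's attachment given the fixed network.

    Row i is proportional to the product over patients of the cell
    likelihoods under each candidate attachment; the uniform prior
    cancels in the normalization.
    """
    _check_alignment(network, states)
    if data.patient_ids != states.patient_ids:
        raise ValueError("patient rows of observations and states are not aligned")
    ll = attachment_logliks(
        network.reach_matrix(), states.states, data.data, rates
    )
    norm = _logsumexp_rows(ll)
    if not np.isfinite(norm).all():
        raise ValueError(
            "an E-gene has zero likelihood under every attachment; "
            "use strictly positive noise rates (0 < alpha, beta < 1)"
        )
    post = np.exp(ll - norm[:, None])
    post /= post.sum(axis=1, keepdims=True)
    return AttachmentPosterior(data.egene_names, network.names, post)
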