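"""Weighted Information Gain (WIG) scoring of therapeutic targets.

Given an inferred S-gene network and the posterior attachment of E-genes,
the WIG of a target (one S-gene, or an unordered pair) measures the
KL-type information gained over the uniform attachment prior, summed over
the pathway-signature E-genes inside the target's regulon:

    WIG(S_j) = sum_i  P(S_j -> E_i) * ln[(m+1) * P(S_j -> E_i)]

where P(S_j -> E_i) sums the posterior attachment mass of E-gene i over
every S-gene reachable from j (including j itself), and m+1 counts the
S-genes plus the null S-gene.  The regulon of a target is the set of
E-genes whose MAP attachment lies in the target's reach (union of reaches
for a pair).  Significance is assessed by resampling signature-sized
subsets of the regulon without replacement; p-values across targets of
the same arity are Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .model_core import NULL_ATTACHMENT, AttachmentPosterior, SGeneNetwork

__all__ = [
    "Regulon",
    "WIGResult",
    "regulon",
    "effect_probability",
    "wig",
    "wig_significance",
    "rank_targets",
]

#: Resampling defaults: 100000 draws for single targets, 50000 for pairs.
DEFAULT_RESAMPLES_SINGLE = 100_000
DEFAULT_RESAMPLES_PAIR = 50_000


@dataclass
class Regulon:
    """E-genes whose MAP attachment is reachable from the target."""

    sgenes: tuple[str, ...]
    egene_indices: np.ndarray

    @property
    def size(self) -> int:
        return int(self.egene_indices.size)


@dataclass
class WIGResult:
    targets: tuple[str, ...]
    wig: float
    n_total: int  # regulon size
    n_signature: int  # signature E-genes inside the regulon
    contributions: dict[str, float] = field(default_factory=dict)
    pvalue: float | None = None
    p_adjusted: float | None = None

    @property
    def label(self) -> str:
        return "/".join(self.targets)


def _target_indices(network: SGeneNetwork, target) -> tuple[str, ...]:
    if isinstance(target, str):
        target = (target,)
    names = tuple(target)
    if not (1 <= len(names) <= 2):
        raise ValueError("a target is one S-gene or an unordered pair")
    for name in names:
        network.index(name)  # raises KeyError for unknown names
    return names


def _reach_columns(network: SGeneNetwork, names: tuple[str, ...]) -> np.ndarray:
    reach = network.reach_matrix().astype(bool)
    cols = np.zeros(network.m, dtype=bool)
    for name in names:
        cols |= reach[network.index(name)]
    return np.flatnonzero(cols)


def regulon(
    posterior: AttachmentPosterior, network: SGeneNetwork, target
) -> Regulon:
    """E-genes MAP-attached to any S-gene reachable from the target.

    For a pair the regulon is the union of the two singleton regulons.
    Null-attached E-genes never belong to a regulon.
    """
    names = _target_indices(network, target)
    cols = set(_reach_columns(network, names).tolist())
    map_idx = posterior.map_attachment()
    members = np.flatnonzero(
        (map_idx != NULL_ATTACHMENT) & np.isin(map_idx, list(cols))
    )
    return Regulon(names, members)


def effect_probability(
    posterior: AttachmentPosterior, network: SGeneNetwork, target, egene
) -> float:
    """P(target -> E_i): posterior attachment mass over the target's reach."""
    names = _target_indices(network, target)
    cols = _reach_columns(network, names)
    if isinstance(egene, str):
        try:
            i = posterior.egene_names.index(egene)
        except ValueError:
            raise KeyError(f"unknown E-gene {egene!r}") from None
    else:
        i = int(egene)
    return float(posterior.posterior[i, cols].sum())


def _wig_terms(
    posterior: AttachmentPosterior, network: SGeneNetwork, names: tuple[str, ...]
) -> np.ndarray:
    """Per-E-gene WIG contribution P * ln[(m+1) P] for the given target."""
    cols = _reach_columns(network, names)
    p = posterior.posterior[:, cols].sum(axis=1)
    m1 = network.m + 1
    terms = np.zeros_like(p)
    pos = p > 0
    terms[pos] = p[pos] * np.log(m1 * p[pos])
    return terms


def wig(
    posterior: AttachmentPosterior,
    network: SGeneNetwork,
    target,
    signature: set[str] | list[str],
) -> WIGResult:
    """WIG of a target over the signature E-genes inside its regulon.

    Natural-log convention; an E-gene with P = 0 contributes 0.  The
    signature must be a subset of the model's E-genes.
    """
    names = _target_indices(network, target)
    sig = set(signature)
    unknown = sig - set(posterior.egene_names)
    if unknown:
        raise ValueError(f"signature genes not among the E-genes: {sorted(unknown)}")
    reg = regulon(posterior, network, names)
    egene_names = posterior.egene_names
    sig_in_reg = [i for i in reg.egene_indices if egene_names[i] in sig]
    terms = _wig_terms(posterior, network, names)
    if not sig_in_reg:
        warnings.warn(
            f"no signature E-gene inside the regulon of {'/'.join(names)}; WIG = 0",
            stacklevel=2,
        )
    contributions = {egene_names[i]: float(terms[i]) for i in sig_in_reg}
    return WIGResult(
        targets=names,
        wig=float(sum(contributions.values())),
        n_total=reg.size,
        n_signature=len(sig_in_reg),
        contributions=contributions,
    )


def wig_significance(
    posterior: AttachmentPosterior,
    network: SGeneNetwork,
    target,
    signature: set[str] | list[str],
    resamples: int | None = None,
    seed: int | None = None,
) -> tuple[WIGResult, float]:
    """Resampling p-value for the specificity of a target's WIG.

    Draws ``resamples`` subsets of the target's regulon, without
    replacement and of the same size as the signature-in-regulon set,
    recomputes the WIG on each, and reports
    p = (1 + #{resampled WIG >= observed}) / (resamples + 1).
    """
    names = _target_indices(network, target)
    if resamples is None:
        resamples = (
            DEFAULT_RESAMPLES_SINGLE if len(names) == 1 else DEFAULT_RESAMPLES_PAIR
        )
    if resamples < 1:
        raise ValueError("need at least one resample")
    result = wig(posterior, network, names, signature)
    reg = regulon(posterior, network, names)
    r = result.n_signature
    if r > reg.size:
        raise ValueError("signature-in-regulon count exceeds the regulon size")
    if r == 0 or r == reg.size:
        # every resample is the whole (or empty) set: identical WIG
        result.pvalue = 1.0
        return result, 1.0
    terms = _wig_terms(posterior, network, names)[reg.egene_indices]
    rng = np.random.default_rng(seed)
    observed = result.wig
    n_ge = 0
    chunk = max(1, min(resamples, 2_000_000 // max(reg.size, 1)))
    done = 0
    while done < resamples:
        b = min(chunk, resamples - done)
        keys = rng.random((b, reg.size))
        picks = np.argpartition(keys, r - 1, axis=1)[:, :r]
        sampled = terms[picks].sum(axis=1)
        n_ge += int((sampled >= observed - 1e-12).sum())
        done += b
    p = (1 + n_ge) / (resamples + 1)
    result.pvalue = p
    return result, p


def rank_targets(
    posterior: AttachmentPosterior,
    network: SGeneNetwork,
    signature: set[str] | list[str],
    candidates: list[str] | None = None,
    pairs: bool = False,
    resamples: int | None = None,
    seed: int | None = None,
) -> list[WIGResult]:
    """Score and rank candidate targets by WIG with BH-adjusted p-values.

    With ``pairs=True`` every unordered pair of candidates is scored
    instead of the singles.  BH adjustment runs across all targets of the
    same arity.  Sorted by WIG descending, ties by adjusted p ascending,
    then by target name.
    """
    if candidates is None:
        candidates = list(network.names)
    if not candidates:
        raise ValueError("need at least one candidate target")
    if pairs:
        targets = [tuple(sorted(p)) for p in itertools.combinations(candidates, 2)]
        if not targets:
            raise ValueError("pair ranking needs at least two candidates")
    else:
        targets = [(c,) for c in candidates]
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.spawn(len(targets))
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tgt, s in zip(targets, child_seeds):
            res, _ = wig_significance(
                posterior, network, tgt, signature,
                resamples=resamples, seed=s.generate_state(1)[0],
            )
            results.append(res)
    pvals = np.array([r.pvalue for r in results])
    adj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    for r, a in zip(results, adj):
        r.p_adjusted = float(max(a, r.pvalue))
    results.sort(key=lambda r: (-r.wig, r.p_adjusted, r.label))
    return results
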