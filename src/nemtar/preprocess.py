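"""Preprocessing of multi-omics tables into binary model inputs.

The model consumes two binary matrices: per-patient aberration states of
the selected regulators (S-genes) and per-patient differential-expression
states of the downstream reporters (E-genes).  This module implements the
selection filters for both gene sets, the assembly of the perturbation
matrix from mutation/CNV/methylation calls, the choice of positive and
negative control patients, the control-anchored discretization of
continuous expression, and the empirical estimation of the binary noise
rates from the control blocks.

Expected inputs are tidy pandas DataFrames:

* differential table — columns ``gene``, ``log2fc``, ``padj``,
  ``gene_class`` (one of TF, miRNA, kinase, other);
* perturbation evidence — columns ``gene``, ``mutation_freq``,
  ``cnv_freq``, ``delta_beta``, ``methyl_p``;
* per-patient aberration calls — columns ``patient``, ``gene`` (one row
  per qualifying event, any omics layer).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import EffectObservations, NoiseRates, PerturbationStates

__all__ = [
    "SGeneThresholds",
    "ControlSets",
    "select_egenes",
    "select_sgenes",
    "build_perturbation_matrix",
    "pick_controls",
    "discretize",
    "estimate_error_rates",
]

logger = logging.getLogger(__name__)

#: Noise-rate estimates are clamped away from {0, 1}: the likelihood is
#: undefined at exact rates of 0 or 1 whenever a single cell disagrees.
RATE_CLAMP = 1e-6


@dataclass(frozen=True)
class SGeneThresholds:
    """Cutoffs for regulator (S-gene) selection.

    Kinases/TFs qualify through upregulation plus a mutation frequency
    above ``mutation_freq`` or a copy-number-gain frequency above
    ``cnv_freq``; miRNAs qualify through downregulation plus significant
    promoter hypermethylation (delta-beta above ``delta_beta`` at
    BH-adjusted p below ``methyl_p``).  All comparisons are strict.
    """

    mutation_freq: float = 0.05
    cnv_freq: float = 0.05
    delta_beta: float = 0.1
    methyl_p: float = 0.001
    tf_lfc: float = 1.0
    mirna_lfc: float = -1.0
    fdr: float = 0.01


@dataclass
class ControlSets:
    """Patients anchoring the discretization thresholds.

    Positive controls: in-subtype patients with no S-gene aberration.
    Negative controls: out-of-subtype patients with no S-gene aberration.
    """

    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)

    def __post_init__(self):
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative controls must be disjoint")


_DIFF_COLS = {"gene", "log2fc", "padj"}


def _check_diff_table(table: pd.DataFrame) -> None:
    missing = _DIFF_COLS - set(table.columns)
    if missing:
        raise ValueError(f"differential table missing columns: {sorted(missing)}")
    if table["gene"].duplicated().any():
        dup = table.loc[table["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicated gene in differential table: {dup!r}")
    p = table["padj"]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("adjusted p-values must lie in (0, 1]")


def select_egenes(
    table: pd.DataFrame, lfc_cutoff: float = 1.0, fdr_cutoff: float = 0.01
) -> list[str]:
    """Reporter genes significantly upregulated in the target subtype.

    Keeps genes with log2 fold-change strictly above ``lfc_cutoff`` and
    BH-adjusted p strictly below ``fdr_cutoff``.  When the defaults yield
    too few genes the fold-change cutoff is customarily relaxed to 0.5.
    """
    if lfc_cutoff <= 0 or fdr_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    _check_diff_table(table)
    keep = (table["log2fc"] > lfc_cutoff) & (table["padj"] < fdr_cutoff)
    genes = table.loc[keep, "gene"].tolist()
    if not genes:
        warnings.warn("no E-gene passed the selection cutoffs", stacklevel=2)
    return genes


def select_sgenes(
    table: pd.DataFrame,
    evidence: pd.DataFrame,
    thresholds: SGeneThresholds | None = None,
    keep_list: list[str] | None = None,
) -> pd.DataFrame:
    """Regulator selection combining expression and perturbation evidence.

    Returns a DataFrame with columns ``gene``, ``gene_class`` and
    ``perturbation`` (comma-joined qualifying evidence types, or
    ``manual`` for keep-list entries that bypass the filters).
    """
    th = thresholds or SGeneThresholds()
    _check_diff_table(table)
    if "gene_class" not in table.columns:
        raise ValueError("differential table needs a gene_class column for S-genes")
    ev = evidence.set_index("gene")
    freq_cols = [c for c in ("mutation_freq", "cnv_freq") if c in ev.columns]
    for c in freq_cols:
        if ((ev[c] < 0) | (ev[c] > 1)).any():
            raise ValueError(f"{c} must lie in [0, 1]")
    if "delta_beta" in ev.columns and (ev["delta_beta"].abs() > 1).any():
        raise ValueError("delta_beta must lie in [-1, 1]")
    rows = []
    for _, rec in table.iterrows():
        gene, cls = rec["gene"], rec["gene_class"]
        e = ev.loc[gene] if gene in ev.index else None
        kinds = []
        if cls in ("TF", "kinase"):
            up = rec["log2fc"] > th.tf_lfc and rec["padj"] < th.fdr
            if e is not None and up:
                if e.get("mutation_freq", 0) > th.mutation_freq:
                    kinds.append("mutation")
                if e.get("cnv_freq", 0) > th.cnv_freq:
                    kinds.append("cnv")
        elif cls == "miRNA":
            down = rec["log2fc"] < th.mirna_lfc and rec["padj"] < th.fdr
            if (
                e is not None
                and down
                and e.get("delta_beta", 0) > th.delta_beta
                and e.get("methyl_p", 1) < th.methyl_p
            ):
                kinds.append("methylation")
        if kinds:
            rows.append({"gene": gene, "gene_class": cls, "perturbation": ",".join(kinds)})
    selected = {r["gene"] for r in rows}
    for gene in keep_list or []:
        if gene not in selected:
            cls_ser = table.loc[table["gene"] == gene, "gene_class"]
            rows.append(
                {
                    "gene": gene,
                    "gene_class": cls_ser.iloc[0] if len(cls_ser) else "other",
                    "perturbation": "manual",
                }
            )
    return pd.DataFrame(rows, columns=["gene", "gene_class", "perturbation"])


def build_perturbation_matrix(
    calls: pd.DataFrame | list[pd.DataFrame],
    sgenes: list[str],
    patient_ids: list[str] | None = None,
) -> PerturbationStates:
    """Binary patient x S-gene matrix from per-patient aberration calls.

    ``calls`` is one table (or a list of per-omics tables) with columns
    ``patient`` and ``gene``; a patient is aberrant in an S-gene iff any
    layer reports a qualifying event (logical OR).  Patients missing from
    a layer are treated as unperturbed in that layer and logged.
    """
    if isinstance(calls, pd.DataFrame):
        calls = [calls]
    for c in calls:
        missing = {"patient", "gene"} - set(c.columns)
        if missing:
            raise ValueError(f"calls table missing columns: {sorted(missing)}")
    all_patients = patient_ids or sorted(
        set().union(*(set(c["patient"]) for c in calls)) if calls else set()
    )
    if not all_patients:
        raise ValueError("no patients found in the aberration calls")
    pidx = {p: i for i, p in enumerate(all_patients)}
    gidx = {g: j for j, g in enumerate(sgenes)}
    states = np.zeros((len(all_patients), len(sgenes)), dtype=np.int8)
    for layer, c in enumerate(calls):
        seen = set(c["patient"])
        absent = set(all_patients) - seen
        if absent:
            logger.info(
                "layer %d: %d patients without records treated as unperturbed",
                layer, len(absent),
            )
        for patient, gene in zip(c["patient"], c["gene"]):
            if patient in pidx and gene in gidx:
                states[pidx[patient], gidx[gene]] = 1
    return PerturbationStates(all_patients, list(sgenes), states)


def pick_controls(
    subtype_labels: pd.Series | dict[str, bool], states: PerturbationStates
) -> ControlSets:
    """Control patients: aberration-free rows split by subtype membership.

    ``subtype_labels`` maps patient id to True for the target subtype.
    Positive controls are in-subtype patients with an all-zero state row;
    negative controls are out-of-subtype patients with an all-zero row.
    """
    labels = dict(subtype_labels)
    missing = set(states.patient_ids) - set(labels)
    if missing:
        raise ValueError(f"subtype labels missing for patients: {sorted(missing)[:5]}")
    clean = states.states.sum(axis=1) == 0
    positive = [p for p, ok in zip(states.patient_ids, clean) if ok and labels[p]]
    negative = [p for p, ok in zip(states.patient_ids, clean) if ok and not labels[p]]
    if not positive or not negative:
        raise ValueError(
            "both control sets must be non-empty for discretization "
            f"(positive={len(positive)}, negative={len(negative)})"
        )
    return ControlSets(positive, negative)


def discretize(
    expression: pd.DataFrame,
    controls: ControlSets,
    sigma: float = 0.5,
    direction: str = "below",
) -> EffectObservations:
    """Per-E-gene threshold discretization anchored on the control means.

    The threshold for E-gene i is ``sigma * mu_i_pos + (1-sigma) *
    mu_i_neg`` with plain means over the positive/negative control
    patients.  ``direction="below"`` calls an effect when expression falls
    below the threshold; ``direction="above"`` calls it when expression
    exceeds it.  The "below" default follows the printed discretization
    rule, but subtypes defined by upregulated reporters are typically
    discretized with "above" — see the methods note.
    """
    if not (0.0 <= sigma <= 1.0):
        raise ValueError("sigma must lie in [0, 1]")
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    missing = (set(controls.positive) | set(controls.negative)) - set(expression.index)
    if missing:
        raise ValueError(f"control patients absent from expression: {sorted(missing)[:5]}")
    mu_pos = expression.loc[controls.positive].mean(axis=0)
    mu_neg = expression.loc[controls.negative].mean(axis=0)
    thresholds = sigma * mu_pos + (1.0 - sigma) * mu_neg
    valid = thresholds.notna()
    if not valid.all():
        warnings.warn(
            f"dropping {int((~valid).sum())} E-genes with missing control values",
            stacklevel=2,
        )
    expr = expression.loc[:, valid]
    t = thresholds[valid]
    if direction == "below":
        binary = (expr < t).astype(np.int8)
    else:
        binary = (expr > t).astype(np.int8)
    return EffectObservations(
        list(expression.index), list(expr.columns), binary.to_numpy()
    )


def estimate_error_rates(
    observations: EffectObservations, controls: ControlSets
) -> NoiseRates:
    """Empirical noise rates from the discretized control blocks.

    alpha is the fraction of negative-control cells called 1 (false
    alarms); beta is the fraction of positive-control cells called 0
    (missed effects).  Degenerate all-identical blocks are clamped into
    [1e-6, 1-1e-6] with a warning.
    """
    if not controls.positive or not controls.negative:
        raise ValueError("both control sets must be non-empty")
    rows = {p: i for i, p in enumerate(observations.patient_ids)}
    try:
        neg = observations.data[[rows[p] for p in controls.negative]]
        pos = observations.data[[rows[p] for p in controls.positive]]
    except KeyError as exc:
        raise ValueError(f"control patient absent from observations: {exc}") from None
    alpha = float(neg.mean())
    beta = float(1.0 - pos.mean())
    lo, hi = RATE_CLAMP, 1.0 - RATE_CLAMP
    if not (lo <= alpha <= hi) or not (lo <= beta <= hi):
        warnings.warn(
            "degenerate control block; noise rates clamped away from {0, 1}",
            stacklevel=2,
        )
    return NoiseRates(min(max(alpha, lo), hi), min(max(beta, lo), hi))
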