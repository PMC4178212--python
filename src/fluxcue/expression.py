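"""Expression discretization and reaction-state assignment.

Gene expression enters the flux prediction as trinary cues: each gene is
called highly expressed (+1), moderately expressed (0) or lowly expressed
(-1) per condition, and the cues are propagated to reactions through the
GPR rules (and = min, or = max).  Reactions cued +1 form the
highly-expressed set R_H, reactions cued -1 the lowly-expressed set R_L;
these are the sets whose agreement with flux the MILP maximizes.

Two discretization modes are provided:

* quantile mode (default): genes at or below the ``q_low`` empirical
  quantile of the per-condition summary are low, genes at or above the
  ``q_high`` quantile are high.  Quantiles use linear interpolation
  between order statistics (``numpy.quantile`` with ``method="linear"``),
  pinned for reproducibility.
* explicit-threshold mode: absolute cutoffs ``t_low`` / ``t_high`` on the
  summary values, appropriate when the expression scale is known (e.g.
  synthetic data calibrated around known means).

Replicates within a condition are collapsed by the arithmetic mean before
discretization.  Whether to discretize each condition against its own
quantiles (default) or against quantiles pooled across all conditions is
selectable (``pooled=True``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gpr import evaluate_gpr
from .model import MetabolicModel

__all__ = [
    "ExpressionProfile",
    "GeneStateMap",
    "ReactionStateAssignment",
    "summarize_condition",
    "condition_summaries",
    "center_by_gene",
    "discretize_expression",
    "discretize_profile",
    "assign_reaction_states",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionProfile:
    """Genes x samples expression table plus a sample -> condition design."""

    values: pd.DataFrame          # index: gene ids, columns: sample ids
    design: pd.Series             # index: sample ids, values: condition labels

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in expression table: {dupes}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.design[s]
            if c not in seen:
                seen.append(c)
        return seen

    def condition_samples(self, condition: str) -> list[str]:
        samples = [s for s in self.values.columns if self.design[s] == condition]
        if not samples:
            raise KeyError(f"unknown condition {condition!r}")
        return samples

    @classmethod
    def from_files(cls, expression_path: str | Path, design_path: str | Path) -> "ExpressionProfile":
        """Load from a TSV table (first column gene id, header of sample ids)
        and a two-column sample/condition design TSV."""
        values = pd.read_csv(expression_path, sep="\t", index_col=0)
        design_df = pd.read_csv(design_path, sep="\t")
        if design_df.shape[1] < 2:
            raise ValueError(f"{design_path}: expected columns sample, condition")
        design = pd.Series(
            design_df.iloc[:, 1].astype(str).values,
            index=design_df.iloc[:, 0].astype(str).values,
        )
        return cls(values, design)


@dataclass
class GeneStateMap:
    """Trinary state per gene for one condition (+1 high, 0 moderate, -1 low)."""

    condition: str
    states: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.states), "state": list(self.states.values())}
        )


@dataclass
class ReactionStateAssignment:
    """Trinary cue per reaction for one condition; +1 members form R_H, -1 form R_L."""

    condition: str
    states: dict[str, int] = field(default_factory=dict)

    @property
    def r_high(self) -> list[str]:
        return [r for r, s in self.states.items() if s == 1]

    @property
    def r_low(self) -> list[str]:
        return [r for r, s in self.states.items() if s == -1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.states), "state": list(self.states.values())}
        )


def summarize_condition(profile: ExpressionProfile, condition: str) -> pd.Series:
    """Per-gene mean expression across the condition's replicate samples."""
    samples = profile.condition_samples(condition)
    return profile.values[samples].mean(axis=1)


def condition_summaries(profile: ExpressionProfile) -> pd.DataFrame:
    """Per-gene mean expression for every condition (genes x conditions)."""
    return pd.DataFrame(
        {c: summarize_condition(profile, c) for c in profile.conditions}
    )


def center_by_gene(summaries: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's cross-condition mean from its per-condition summaries.

    Centered values express how a gene behaves in a condition *relative to
    its own baseline*: a gene induced in one condition is positive there
    and negative elsewhere, while a constitutively high (or low) gene sits
    near zero everywhere.  Discretizing centered values therefore cues
    condition-specific regulation rather than basal expression level — the
    reading of "expression measured under different conditions" that a
    cross-condition flux contrast calls for.
    """
    return summaries.sub(summaries.mean(axis=1), axis=0)


def discretize_expression(
    summary: pd.Series,
    q_low: float = 0.25,
    q_high: float = 0.75,
    *,
    t_low: float | None = None,
    t_high: float | None = None,
    condition: str = "",
) -> GeneStateMap:
    """Discretize a per-gene summary vector into trinary states.

    In quantile mode (default), thresholds are the ``q_low`` / ``q_high``
    empirical quantiles of ``summary`` (linear interpolation); genes at or
    below the low threshold map to -1, at or above the high threshold to
    +1, otherwise 0.  Passing both ``t_low`` and ``t_high`` switches to
    explicit absolute thresholds.  A constant input vector yields all-zero
    states (no spread, no cues) with a logged warning.
    """
    values = summary.to_numpy(dtype=float)
    explicit = t_low is not None or t_high is not None
    if explicit:
        if t_low is None or t_high is None:
            raise ValueError("explicit mode requires both t_low and t_high")
        if not t_low < t_high:
            raise ValueError(f"t_low={t_low} must be < t_high={t_high}")
        lo, hi = float(t_low), float(t_high)
    else:
        if not 0 < q_low < q_high < 1:
            raise ValueError(f"need 0 < q_low < q_high < 1, got {q_low}, {q_high}")
        if np.ptp(values) == 0:
            log.warning(
                "condition %s: constant expression vector, no cues assigned", condition
            )
            return GeneStateMap(condition, {g: 0 for g in summary.index})
        lo = float(np.quantile(values, q_low, method="linear"))
        hi = float(np.quantile(values, q_high, method="linear"))

    states = {}
    for gene, v in zip(summary.index, values):
        if v <= lo:
            states[gene] = -1
        elif v >= hi:
            states[gene] = 1
        else:
            states[gene] = 0
    return GeneStateMap(condition, states)


def discretize_profile(
    profile: ExpressionProfile,
    q_low: float = 0.25,
    q_high: float = 0.75,
    *,
    pooled: bool = False,
    center: str = "none",
    t_low: float | None = None,
    t_high: float | None = None,
) -> dict[str, GeneStateMap]:
    """Discretize every condition of a profile in one call.

    ``center="gene"`` first subtracts each gene's cross-condition
    baseline.  ``pooled=True`` computes one pair of quantile thresholds
    from the values of all conditions jointly and applies it to each
    condition (instead of per-condition quantiles); ignored when explicit
    thresholds are given.
    """
    summaries = condition_summaries(profile)
    if center == "gene":
        summaries = center_by_gene(summaries)
    elif center != "none":
        raise ValueError(f"unknown center mode {center!r}")

    explicit = t_low is not None or t_high is not None
    if pooled and not explicit:
        if not 0 < q_low < q_high < 1:
            raise ValueError(f"need 0 < q_low < q_high < 1, got {q_low}, {q_high}")
        flat = summaries.to_numpy().ravel()
        if np.ptp(flat) == 0:
            log.warning("constant pooled expression, no cues assigned")
            return {
                c: GeneStateMap(c, {g: 0 for g in summaries.index})
                for c in summaries.columns
            }
        t_low = float(np.quantile(flat, q_low, method="linear"))
        t_high = float(np.quantile(flat, q_high, method="linear"))

    return {
        c: discretize_expression(
            summaries[c], q_low, q_high, t_low=t_low, t_high=t_high, condition=c
        )
        for c in summaries.columns
    }


def assign_reaction_states(
    model: MetabolicModel, gene_states: GeneStateMap
) -> ReactionStateAssignment:
    """Map gene states to reaction cues through the GPR rules.

    Reactions with an empty GPR get state 0; genes present in a GPR but
    absent from the profile evaluate to 0 (absence of evidence is not a
    cue).
    """
    states = {
        r.id: evaluate_gpr(r.gpr, gene_states.states) for r in model.reactions
    }
    assignment = ReactionStateAssignment(gene_states.condition, states)
    log.info(
        "condition %s: |R_H|=%d, |R_L|=%d of %d reactions",
        gene_states.condition,
        len(assignment.r_high),
        len(assignment.r_low),
        len(states),
    )
    return assignment
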