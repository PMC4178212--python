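"""Expression-cued flux prediction by mixed-integer optimization.

The central computation: given a metabolic network and trinary expression
cues per reaction (R_H highly expressed, R_L lowly expressed), find a
steady-state flux distribution ``v`` (``S @ v = 0``, ``lb <= v <= ub``)
that maximizes the number of cues it agrees with.  A highly-expressed
reaction agrees when it carries flux of magnitude at least ``epsilon``
(in either direction if reversible — expression cannot indicate
direction); a lowly-expressed reaction agrees when it carries essentially
no flux (``|v| <= zero_tol``).

Formulation: one binary indicator per satisfiable cue direction, linked
to the flux variable by big-M constraints with M derived from the
reaction's own bounds (exact for bounded fluxes):

* r in R_H, forward:  v_r + y (lb_r - eps) >= lb_r   (y=1 -> v_r >= eps)
* r in R_H, backward: v_r + y (ub_r + eps) <= ub_r   (y=1 -> v_r <= -eps)
  with y_fwd + y_bwd <= 1 when both directions exist
* r in R_L:           v_r + z (ub_r - tol) <= ub_r   (z=1 -> v_r <= tol)
                      v_r + z (lb_r + tol) >= lb_r   (z=1 -> v_r >= -tol)

maximizing the sum of indicators.  The optimum is the maximum number of
simultaneously satisfiable cues, an integer.

Because the optimum is generally degenerate, per-reaction activity is
defined by forced re-optimization, not by inspecting one optimal flux
vector: a reaction is *active* when forcing it to carry flux preserves a
strictly better objective than forcing it silent, *inactive* in the
mirrored case, and *undetermined* when both forcings achieve the same
objective.  Flux ranges are computed by optimum-preserving flux
variability (min/max v_r subject to retaining the optimal cue count).

The MILP backend is HiGHS via :func:`scipy.optimize.milp`; the
brute-force oracle enumerates indicator assignments and checks each by LP
feasibility (:func:`scipy.optimize.linprog`), and exists to certify the
MILP path on small instances.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .expression import ReactionStateAssignment
from .model import MetabolicModel

__all__ = [
    "IMATConfig",
    "IMATSolution",
    "ActivityCall",
    "FluxComparison",
    "build_milp",
    "solve_imat",
    "classify_activity",
    "compare_conditions",
    "brute_force_imat",
]

log = logging.getLogger(__name__)

#: Largest number of cue-bearing reactions the brute-force oracle accepts.
BRUTE_FORCE_LIMIT = 12


@dataclass
class IMATConfig:
    """Tunables of the cue-agreement MILP.

    epsilon
        Minimum flux magnitude (model flux units) counted as "carrying
        flux" for a highly-expressed reaction.  Default 1.0, sized for
        toy networks with bounds of order 10; scale it with the model.
    zero_tol
        Flux magnitude below which a reaction counts as silent.
    solver_time_limit
        Seconds allowed per MILP solve.
    mip_gap
        Relative optimality gap; kept tiny so integer objectives are
        certified exactly and activity verdicts never hinge on solver
        slack.
    """

    epsilon: float = 1.0
    zero_tol: float = 1e-6
    solver_time_limit: float = 60.0
    mip_gap: float = 1e-9

    def __post_init__(self) -> None:
        if not self.epsilon > self.zero_tol >= 0:
            raise ValueError(
                f"need epsilon > zero_tol >= 0, got {self.epsilon}, {self.zero_tol}"
            )


@dataclass
class _Cue:
    """One binary indicator: reaction index, cue sense, direction."""

    reaction: str
    j: int                 # column of v
    kind: str              # "high" or "low"
    direction: str         # "fwd" / "bwd" for high cues, "off" for low


@dataclass
class MILPProblem:
    """Assembled MILP: minimize c @ x s.t. constraints, integrality, bounds."""

    c: np.ndarray
    integrality: np.ndarray
    bounds: Bounds
    constraints: list[LinearConstraint]
    n_flux: int
    cues: list[_Cue]
    reaction_ids: list[str]

    @property
    def n_binary(self) -> int:
        return len(self.cues)


@dataclass
class IMATSolution:
    condition: str
    flux: dict[str, float]
    indicators: dict[str, bool]
    objective: int
    solver_status: str     # optimal / feasible-timeout / infeasible


@dataclass
class ActivityCall:
    condition: str
    reaction: str
    verdict: str           # active / inactive / undetermined
    objective_if_forced_active: float
    objective_if_forced_inactive: float
    flux_range: tuple[float, float] | None = None


@dataclass
class FluxComparison:
    reaction: str
    condition_a: str
    condition_b: str
    range_a: tuple[float, float]
    range_b: tuple[float, float]
    call: str              # higher_in_a / higher_in_b / indistinguishable


def _check_states(model: MetabolicModel, states: ReactionStateAssignment) -> None:
    known = set(model.reaction_ids)
    unknown = [r for r in states.states if r not in known]
    if unknown:
        raise ValueError(f"states reference unknown reactions: {unknown}")
    missing = [r for r in known if r not in states.states]
    if missing:
        raise ValueError(f"states missing for reactions: {missing}")


def build_milp(
    model: MetabolicModel,
    states: ReactionStateAssignment,
    config: IMATConfig,
    *,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    min_objective: int | None = None,
    flux_objective: dict[str, float] | None = None,
) -> MILPProblem:
    """Assemble the cue-agreement MILP.

    ``extra_bounds`` tightens individual flux bounds (used for forced
    activity/inactivity), ``min_objective`` adds a floor on the cue count
    (used for optimum-preserving variability), and ``flux_objective``
    replaces the cue objective by a linear function of the fluxes.
    """
    _check_states(model, states)
    n = len(model.reactions)
    eps, tol = config.epsilon, config.zero_tol

    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            j = model.reaction_ids.index(rid)
            lb[j], ub[j] = max(lb[j], lo), min(ub[j], hi)

    cues: list[_Cue] = []
    for j, rxn in enumerate(model.reactions):
        s = states.states[rxn.id]
        if s == 1:
            if ub[j] > 0:
                cues.append(_Cue(rxn.id, j, "high", "fwd"))
            if lb[j] < 0:
                cues.append(_Cue(rxn.id, j, "high", "bwd"))
        elif s == -1:
            cues.append(_Cue(rxn.id, j, "low", "off"))

    n_bin = len(cues)
    n_var = n + n_bin
    S = model.stoichiometric_matrix()

    constraints: list[LinearConstraint] = []
    if S.shape[0]:
        A_ss = np.hstack([S, np.zeros((S.shape[0], n_bin))])
        constraints.append(LinearConstraint(A_ss, 0.0, 0.0))

    rows, lower, upper = [], [], []
    for b, cue in enumerate(cues):
        j = cue.j
        row = np.zeros(n_var)
        row[j] = 1.0
        if cue.kind == "high" and cue.direction == "fwd":
            row[n + b] = lb[j] - eps
            rows.append(row); lower.append(lb[j]); upper.append(np.inf)
        elif cue.kind == "high" and cue.direction == "bwd":
            row[n + b] = ub[j] + eps
            rows.append(row); lower.append(-np.inf); upper.append(ub[j])
        else:  # low cue: two rows
            row_hi = row.copy()
            row_hi[n + b] = ub[j] - tol
            rows.append(row_hi); lower.append(-np.inf); upper.append(ub[j])
            row_lo = row.copy()
            row_lo[n + b] = lb[j] + tol
            rows.append(row_lo); lower.append(lb[j]); upper.append(np.inf)

    # a reversible highly-expressed reaction satisfies its cue in at most
    # one direction at a time
    by_reaction: dict[str, list[int]] = {}
    for b, cue in enumerate(cues):
        if cue.kind == "high":
            by_reaction.setdefault(cue.reaction, []).append(b)
    for idxs in by_reaction.values():
        if len(idxs) == 2:
            row = np.zeros(n_var)
            for b in idxs:
                row[n + b] = 1.0
            rows.append(row); lower.append(-np.inf); upper.append(1.0)

    if min_objective is not None and n_bin:
        row = np.zeros(n_var)
        row[n:] = 1.0
        rows.append(row); lower.append(min_objective - 0.5); upper.append(np.inf)

    if rows:
        constraints.append(LinearConstraint(np.array(rows), lower, upper))

    c = np.zeros(n_var)
    if flux_objective is None:
        c[n:] = -1.0  # maximize cue count
    else:
        for rid, coef in flux_objective.items():
            c[model.reaction_ids.index(rid)] = coef

    integrality = np.zeros(n_var)
    integrality[n:] = 1.0
    var_lb = np.concatenate([lb, np.zeros(n_bin)])
    var_ub = np.concatenate([ub, np.ones(n_bin)])
    return MILPProblem(
        c=c,
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        constraints=constraints,
        n_flux=n,
        cues=cues,
        reaction_ids=list(model.reaction_ids),
    )


def _run_milp(problem: MILPProblem, config: IMATConfig):
    return milp(
        c=problem.c,
        constraints=problem.constraints,
        integrality=problem.integrality,
        bounds=problem.bounds,
        options={
            "mip_rel_gap": config.mip_gap,
            "time_limit": config.solver_time_limit,
            "presolve": True,
        },
    )


def _satisfied_cues(
    problem: MILPProblem, v: np.ndarray, config: IMATConfig, slack: float = 1e-7
) -> dict[str, bool]:
    """Which cues does the flux vector itself satisfy (cue per reaction)."""
    out: dict[str, bool] = {}
    for cue in problem.cues:
        x = v[cue.j]
        if cue.kind == "high":
            ok = x >= config.epsilon - slack or x <= -config.epsilon + slack
        else:
            ok = abs(x) <= config.zero_tol + slack
        out[cue.reaction] = out.get(cue.reaction, False) or ok
    return out


def solve_imat(
    model: MetabolicModel,
    states: ReactionStateAssignment,
    config: IMATConfig | None = None,
) -> IMATSolution:
    """Solve the cue-agreement MILP.

    Returns the optimal flux distribution, the per-cued-reaction
    satisfaction indicators implied by that flux, and the integer
    objective (number of satisfied cues).  An infeasible base problem
    yields ``solver_status="infeasible"`` with empty flux, never an
    exception.
    """
    config = config or IMATConfig()
    problem = build_milp(model, states, config)
    res = _run_milp(problem, config)
    if res.status == 2 or res.x is None:
        return IMATSolution(states.condition, {}, {}, 0, "infeasible")
    status = "optimal" if res.status == 0 else "feasible-timeout"
    v = np.asarray(res.x[: problem.n_flux])
    flux = {rid: float(v[j]) for j, rid in enumerate(problem.reaction_ids)}
    indicators = _satisfied_cues(problem, v, config)
    objective = int(round(-res.fun)) if problem.n_binary else 0
    sol = IMATSolution(states.condition, flux, indicators, objective, status)
    log.info(
        "condition %s: objective %d of %d cued reactions (%s)",
        states.condition, objective, len(indicators), status,
    )
    return sol


def _forced_objective(
    model: MetabolicModel,
    states: ReactionStateAssignment,
    config: IMATConfig,
    bounds_variants: list[dict[str, tuple[float, float]]],
) -> float:
    """Best objective over the given forced-bound variants; -inf if all infeasible."""
    best = -math.inf
    for extra in bounds_variants:
        feasible = True
        for rid, (lo, hi) in extra.items():
            r = model.reaction(rid)
            if max(r.lower_bound, lo) > min(r.upper_bound, hi):
                feasible = False
        if not feasible:
            continue
        problem = build_milp(model, states, config, extra_bounds=extra)
        res = _run_milp(problem, config)
        if res.status == 2 or res.x is None:
            continue
        obj = int(round(-res.fun)) if problem.n_binary else 0
        best = max(best, obj)
    return best


def classify_activity(
    model: MetabolicModel,
    states: ReactionStateAssignment,
    config: IMATConfig | None = None,
    *,
    reactions: list[str] | None = None,
    compute_ranges: bool = False,
) -> list[ActivityCall]:
    """Classify each reaction as active / inactive / undetermined.

    For every reaction the MILP is re-solved with the reaction forced to
    carry flux (|v| >= epsilon, best over the two directions for
    reversible reactions) and forced silent (|v| <= zero_tol); the
    verdict compares the two forced optima.  ``reactions`` restricts
    classification to a subset (e.g. one subsystem of a large model);
    ``compute_ranges`` additionally runs optimum-preserving flux
    variability (two more MILPs per reaction).
    """
    config = config or IMATConfig()
    base = solve_imat(model, states, config)
    if base.solver_status == "infeasible":
        raise RuntimeError("base problem infeasible; nothing to classify")
    opt = base.objective
    eps, tol = config.epsilon, config.zero_tol

    calls = []
    targets = reactions if reactions is not None else model.reaction_ids
    for rid in targets:
        rxn = model.reaction(rid)
        active_variants = []
        if rxn.upper_bound >= eps:
            active_variants.append({rid: (eps, math.inf)})
        if rxn.lower_bound <= -eps:
            active_variants.append({rid: (-math.inf, -eps)})
        obj_active = _forced_objective(model, states, config, active_variants)
        obj_inactive = _forced_objective(model, states, config, [{rid: (-tol, tol)}])

        if obj_active > obj_inactive:
            verdict = "active"
        elif obj_inactive > obj_active:
            verdict = "inactive"
        else:
            verdict = "undetermined"

        flux_range = None
        if compute_ranges:
            flux_range = _flux_range(model, states, config, rid, opt)
        calls.append(
            ActivityCall(states.condition, rid, verdict, obj_active, obj_inactive, flux_range)
        )
    n_active = sum(1 for c in calls if c.verdict == "active")
    log.info(
        "condition %s: opt*=%d, %d/%d reactions active",
        states.condition, opt, n_active, len(calls),
    )
    return calls


def _flux_range(
    model: MetabolicModel,
    states: ReactionStateAssignment,
    config: IMATConfig,
    rid: str,
    opt: int,
) -> tuple[float, float]:
    """Optimum-preserving flux variability: min/max v_r at objective >= opt."""
    out = []
    for sense in (1.0, -1.0):
        problem = build_milp(
            model, states, config, min_objective=opt, flux_objective={rid: sense}
        )
        res = _run_milp(problem, config)
        if res.status == 2 or res.x is None:
            raise RuntimeError(f"variability subproblem infeasible for {rid}")
        out.append(sense * res.fun)
    return (float(out[0]), float(out[1]))


def compare_conditions(
    calls_a: list[ActivityCall],
    calls_b: list[ActivityCall],
    *,
    separation_tol: float = 0.0,
) -> list[FluxComparison]:
    """Compare per-reaction flux ranges between two conditions.

    A reaction is called ``higher_in_a`` only under strict interval
    separation — the smallest flux it can carry at optimum in condition A
    exceeds the largest it can carry in condition B (by more than
    ``separation_tol``); symmetrically for ``higher_in_b``; overlapping
    ranges are ``indistinguishable``.  Both call sets must come from the
    same model with flux ranges computed.
    """
    by_a = {c.reaction: c for c in calls_a}
    by_b = {c.reaction: c for c in calls_b}
    if set(by_a) != set(by_b):
        raise ValueError("mismatched reaction sets between conditions")
    out = []
    for rid in (c.reaction for c in calls_a):
        ca, cb = by_a[rid], by_b[rid]
        if ca.flux_range is None or cb.flux_range is None:
            raise ValueError(f"flux range missing for {rid}; classify with compute_ranges")
        amin, amax = ca.flux_range
        bmin, bmax = cb.flux_range
        if amin > bmax + separation_tol:
            call = "higher_in_a"
        elif bmin > amax + separation_tol:
            call = "higher_in_b"
        else:
            call = "indistinguishable"
        out.append(
            FluxComparison(rid, ca.condition, cb.condition, ca.flux_range, cb.flux_range, call)
        )
    return out


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_imat(
    model: MetabolicModel,
    states: ReactionStateAssignment,
    config: IMATConfig | None = None,
) -> IMATSolution:
    """Exhaustive reference solver for small instances.

    Enumerates, by decreasing cue count, every subset of cued reactions
    (and, for reversible highly-expressed reactions, every direction
    choice) and checks whether the implied flux restrictions admit a
    steady-state solution by LP.  The first feasible subset gives the
    maximum satisfiable cue count.  Refuses instances with more than
    ``BRUTE_FORCE_LIMIT`` cue-bearing reactions.
    """
    config = config or IMATConfig()
    _check_states(model, states)
    eps, tol = config.epsilon, config.zero_tol

    cued: list[tuple[str, list[tuple[float, float]]]] = []
    for rxn in model.reactions:
        s = states.states[rxn.id]
        if s == 1:
            options = []
            if rxn.upper_bound >= eps:
                options.append((eps, math.inf))
            if rxn.lower_bound <= -eps:
                options.append((-math.inf, -eps))
            cued.append((rxn.id, options))
        elif s == -1:
            cued.append((rxn.id, [(-tol, tol)]))
    if len(cued) > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"{len(cued)} cue-bearing reactions exceed the brute-force limit "
            f"of {BRUTE_FORCE_LIMIT}"
        )

    S = model.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    index = {rid: j for j, rid in enumerate(model.reaction_ids)}

    def feasible(assignment: dict[str, tuple[float, float]]) -> np.ndarray | None:
        lo, hi = lb.copy(), ub.copy()
        for rid, (a, b) in assignment.items():
            j = index[rid]
            lo[j], hi[j] = max(lo[j], a), min(hi[j], b)
            if lo[j] > hi[j]:
                return None
        res = linprog(
            c=np.zeros(len(lo)),
            A_eq=S if S.shape[0] else None,
            b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
            bounds=list(zip(lo, hi)),
            method="highs",
        )
        return res.x if res.status == 0 else None

    for count in range(len(cued), -1, -1):
        for subset in itertools.combinations(range(len(cued)), count):
            option_lists = [cued[i][1] for i in subset]
            if any(not opts for opts in option_lists):
                continue
            for choice in itertools.product(*option_lists):
                assignment = {cued[i][0]: c for i, c in zip(subset, choice)}
                v = feasible(assignment)
                if v is not None:
                    flux = {rid: float(v[index[rid]]) for rid in model.reaction_ids}
                    indicators = {cued[i][0]: (i in subset) for i in range(len(cued))}
                    return IMATSolution(states.condition, flux, indicators, count, "optimal")
    return IMATSolution(states.condition, {}, {}, 0, "infeasible")
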