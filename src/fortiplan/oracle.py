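"""Brute-force reference solver for the fortification MIP.

Enumerates every binary selection of food groups and solves the continuous
subproblem in closed form.  For a fixed selection S the concentrations live in
a box: c_i ∈ [activation_min, min(current_i + δ, big_m)] for i ∈ S, c_i = 0
otherwise, so the attainable aggregate supply Σ intake_i·c_i is exactly the
interval [Σ_S intake_i·lb_i, Σ_S intake_i·ub_i].  The selection is feasible
iff that interval intersects the supply window imposed by AR/RI/UL, and the
attained optimum is the window-clipped interval maximum.

Desk-scale by design (2^n enumeration): this module validates the MIP solver
and enumerates alternate optima; it is not a performant solver.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .data import CompositionMatrix, ValidationError
from .model import ModelConfig

__all__ = ["OracleResult", "enumerate_selections", "canonical_selection", "continuous_optimum"]

TOL = 1e-9


@dataclass
class OracleResult:
    best_objective: float | None  # None when no selection is feasible
    optimal_selections: list[frozenset[int]]
    feasible_count: int
    enumerated_count: int

    @property
    def feasible(self) -> bool:
        return self.best_objective is not None


def _supply_window(config: ModelConfig) -> tuple[float, float]:
    """Admissible aggregate-supply interval from the AR/RI/UL rows."""
    if config.ri_mode == "equality":
        lo = max(config.ar, config.ri)
        hi = min(config.ul, config.ri)
    else:
        lo = max(config.ar, config.ri)
        hi = config.ul
    return lo, hi


def continuous_optimum(
    selection: frozenset[int] | set[int],
    matrix: CompositionMatrix,
    config: ModelConfig,
) -> tuple[bool, float | None, dict[int, float] | None]:
    """Closed-form solve of the fixed-selection continuous subproblem.

    Returns (feasible, objective, witness).  The witness is the canonical
    greedy fill in ascending group-ID order; only objective and feasibility
    are contractual.
    """
    intakes = matrix.intakes
    currents = matrix.concentrations
    lo_w, hi_w = _supply_window(config)
    if lo_w > hi_w + TOL:
        return False, None, None
    smin = smax = 0.0
    for g in selection:
        ub = config.upper_bound(currents[g])
        if ub < config.activation_min - TOL:
            return False, None, None  # empty box for this group
        smin += intakes[g] * config.activation_min
        smax += intakes[g] * ub
    if smin > hi_w + TOL or smax < lo_w - TOL:
        return False, None, None
    objective = min(smax, hi_w)
    # canonical witness: floor everywhere, raise in ascending ID order
    conc = {g: config.activation_min for g in selection}
    total = smin
    for g in sorted(selection):
        if total >= objective - TOL:
            break
        ub = config.upper_bound(currents[g])
        room = intakes[g] * (ub - conc[g])
        step = min(room, objective - total)
        if step > 0 and intakes[g] > 0:
            conc[g] += step / intakes[g]
            total += step
    return True, objective, conc


def enumerate_selections(
    matrix: CompositionMatrix, config: ModelConfig, max_n: int = 20
) -> OracleResult:
    """Exhaustively enumerate binary selections and return all optima.

    Selections violating the cardinality cap or an either–or pair are filtered
    before the continuous solve and do not count as enumerated.
    """
    gids = sorted(matrix.group_ids)
    n = len(gids)
    if n > max_n:
        raise ValidationError(f"{n} groups exceeds enumeration guard max_n={max_n}")
    best: float | None = None
    optima: list[frozenset[int]] = []
    feasible = 0
    enumerated = 0
    for mask in itertools.product((0, 1), repeat=n):
        sel = frozenset(g for g, m in zip(gids, mask) if m)
        if config.max_groups is not None and len(sel) > config.max_groups:
            continue
        if any(a in sel and b in sel for a, b in config.preference_pairs):
            continue
        enumerated += 1
        ok, obj, _ = continuous_optimum(sel, matrix, config)
        if not ok:
            continue
        feasible += 1
        if best is None or obj > best + TOL:
            best = obj
            optima = [sel]
        elif abs(obj - best) <= TOL:
            optima.append(sel)
    return OracleResult(best, optima, feasible, enumerated)


def canonical_selection(result: OracleResult) -> frozenset[int]:
    """The optimal selection with fewest groups; ties broken by the
    lexicographically smallest sorted ID tuple.  Deterministic."""
    if not result.optimal_selections:
        raise ValidationError("no feasible selection to canonicalise")
    return min(result.optimal_selections, key=lambda s: (len(s), tuple(sorted(s))))
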