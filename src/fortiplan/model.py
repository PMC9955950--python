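"""Mixed-integer fortification optimisation.

The program decides, per food group *i*, a binary selection z_i and a new
nutrient concentration c_i (µg/g) so that the aggregate population supply
Σ intake_i · c_i meets the average requirement (AR), hits (or exceeds) the
recommended intake (RI) and stays below the tolerable upper level (UL):

    maximize    Σ intake_i · c_i
    subject to  Σ intake_i · c_i ≥ AR
                Σ intake_i · c_i = RI          (or ≥ RI, see ``ri_mode``)
                Σ intake_i · c_i ≤ UL
                c_i ≥ 0.1 · z_i                (activation floor)
                c_i ≤ 10000 · z_i              (big-M link: c_i > 0 only if chosen)
                c_i ≤ current_i + δ            (proximity to current level)
                Σ z_i ≤ K                      (optional cardinality cap)
                z_a + z_b ≤ 1                  (optional either–or preferences)

The proximity constraint (δ, ``proximity_delta``) is what spreads the
fortification over several food groups instead of loading one group.

Under the default RI equality the objective is pinned at RI, so the continuous
part of any optimal solution is degenerate; :func:`solve` therefore
canonicalises the returned concentrations with a deterministic greedy fill in
ascending group-ID order (all selected groups at the activation floor, then
raised to their proximity bound in ID order until the aggregate target is
met).  Only the objective value and feasibility are solver-contractual; the
canonical point is one optimal witness, chosen for reproducibility.

Backend: ``scipy.optimize.milp`` (HiGHS).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds

from .data import CompositionMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "FortificationPlan",
    "ConstraintReport",
    "ProblemSpec",
    "build_problem",
    "fix_selection",
    "solve",
    "verify_plan",
    "read_config",
]

TOL = 1e-6


@dataclass(frozen=True)
class ModelConfig:
    """Reference values plus all formulation constants.

    proximity_delta (µg/g)
        How far a new concentration may exceed the current one (δ).  Kept low
        (0.2 for the whole population, 1 for ages 4–10, 0.1 for ages 11–17)
        so fortification stays close to current practice.
    activation_min (µg/g)
        Minimum concentration of a chosen group (0.1 by default) — prevents
        token selections at negligible levels.
    big_m (µg/g)
        Link constant tying c_i to z_i; any value above every attainable
        concentration works (10000 by default).
    max_groups
        Optional cap on the number of chosen groups.
    preference_pairs
        Either–or pairs (a, b): at most one of the two groups may be chosen.
    ri_mode
        ``"equality"`` (aggregate supply pinned at RI — the printed
        formulation) or ``"lower_bound"`` (supply ≥ RI; the maximisation then
        pushes supply to min(UL, attainable max)).
    """

    ar: float
    ri: float
    ul: float
    proximity_delta: float
    activation_min: float = 0.1
    big_m: float = 10000.0
    max_groups: int | None = None
    preference_pairs: tuple[tuple[int, int], ...] = ()
    ri_mode: str = "equality"

    def __post_init__(self) -> None:
        if not (self.ar <= self.ri < self.ul):
            raise ValidationError(f"need AR <= RI < UL, got {self.ar}, {self.ri}, {self.ul}")
        if not (0 < self.activation_min < self.big_m):
            raise ValidationError("need 0 < activation_min < big_m")
        if self.proximity_delta < 0:
            raise ValidationError("proximity_delta must be >= 0")
        if self.max_groups is not None and self.max_groups <= 0:
            raise ValidationError("max_groups must be a positive integer")
        if self.ri_mode not in ("equality", "lower_bound"):
            raise ValidationError(f"unknown ri_mode {self.ri_mode!r}")
        pairs = tuple(tuple(sorted(map(int, p))) for p in self.preference_pairs)
        for a, b in pairs:
            if a == b:
                raise ValidationError(f"preference pair ({a}, {b}) must name distinct groups")
        object.__setattr__(self, "preference_pairs", pairs)

    def upper_bound(self, current_concentration: float) -> float:
        """Effective concentration ceiling for a chosen group."""
        return min(current_concentration + self.proximity_delta, self.big_m)


def read_config(path: str | Path) -> ModelConfig:
    """Read a ModelConfig from a TOML file mirroring the field names."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    if "preference_pairs" in raw:
        raw["preference_pairs"] = tuple(tuple(p) for p in raw["preference_pairs"])
    return ModelConfig(**raw)


@dataclass
class FortificationPlan:
    """Solved fortification: per group a binary choice and a concentration (µg/g)."""

    frame: pd.DataFrame  # columns group_id, chosen, concentration
    objective_value: float
    solver_status: str  # optimal | infeasible | error

    @classmethod
    def from_mapping(
        cls,
        concentrations: dict[int, float],
        chosen: Iterable[int],
        objective_value: float | None = None,
        solver_status: str = "optimal",
    ) -> "FortificationPlan":
        chosen = set(chosen)
        rows = [
            (gid, int(gid in chosen), float(concentrations.get(gid, 0.0)))
            for gid in sorted(concentrations)
        ]
        frame = pd.DataFrame(rows, columns=["group_id", "chosen", "concentration"])
        if objective_value is None:
            objective_value = float("nan")
        return cls(frame, float(objective_value), solver_status)

    @property
    def chosen_ids(self) -> set[int]:
        return set(self.frame.loc[self.frame["chosen"] == 1, "group_id"].astype(int))

    @property
    def concentrations(self) -> dict[int, float]:
        return dict(zip(self.frame["group_id"].astype(int), self.frame["concentration"]))

    def rounded(self, decimals: int = 3) -> "FortificationPlan":
        """Formatting helper: concentrations rounded for table display."""
        f = self.frame.copy()
        f["concentration"] = f["concentration"].round(decimals)
        return FortificationPlan(f, self.objective_value, self.solver_status)

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FortificationPlan":
        f = pd.read_csv(path)
        missing = [c for c in ("group_id", "chosen", "concentration") if c not in f.columns]
        if missing:
            raise ValidationError(f"plan file missing columns: {missing}")
        return cls(f[["group_id", "chosen", "concentration"]], float("nan"), "optimal")


@dataclass
class _Constraint:
    """One linear row a·c + b·z with bounds lb ≤ row ≤ ub."""

    name: str
    c_coeffs: dict[int, float]
    z_coeffs: dict[int, float]
    lb: float
    ub: float

    def value(self, conc: dict[int, float], chosen: dict[int, int]) -> float:
        return sum(a * conc.get(g, 0.0) for g, a in self.c_coeffs.items()) + sum(
            b * chosen.get(g, 0) for g, b in self.z_coeffs.items()
        )


@dataclass
class ProblemSpec:
    """Abstract linear program over c_i ≥ 0 continuous and z_i ∈ {0,1}."""

    group_ids: list[int]
    intakes: dict[int, float]
    currents: dict[int, float]
    config: ModelConfig
    constraints: list[_Constraint]
    z_fixed: dict[int, int] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)


def build_problem(matrix: CompositionMatrix, config: ModelConfig) -> ProblemSpec:
    """Assemble the fortification MIP for a composition matrix.

    Constraint count is 3 aggregate rows + 3 per group (activation, big-M
    link, proximity), plus one row per preference pair and an optional
    cardinality row.
    """
    if len(matrix) == 0:
        raise ValidationError("composition matrix is empty")
    gids = matrix.group_ids
    intakes = matrix.intakes
    currents = matrix.concentrations
    supply = {g: intakes[g] for g in gids}
    cons: list[_Constraint] = [
        _Constraint("aggregate_ar", supply, {}, config.ar, math.inf),
        _Constraint(
            "aggregate_ri",
            supply,
            {},
            config.ri,
            config.ri if config.ri_mode == "equality" else math.inf,
        ),
        _Constraint("aggregate_ul", supply, {}, -math.inf, config.ul),
    ]
    for g in gids:
        cons.append(
            _Constraint(f"activation[{g}]", {g: 1.0}, {g: -config.activation_min}, 0.0, math.inf)
        )
        cons.append(_Constraint(f"bigm[{g}]", {g: 1.0}, {g: -config.big_m}, -math.inf, 0.0))
        cons.append(
            _Constraint(
                f"proximity[{g}]", {g: 1.0}, {}, -math.inf, currents[g] + config.proximity_delta
            )
        )
        if config.upper_bound(currents[g]) < config.activation_min:
            logger.info(
                "group %s is unfortifiable: ceiling %.4g below activation floor %.4g",
                g, config.upper_bound(currents[g]), config.activation_min,
            )
    if config.max_groups is not None:
        cons.append(
            _Constraint("cardinality", {}, {g: 1.0 for g in gids}, -math.inf, config.max_groups)
        )
    for a, b in config.preference_pairs:
        for g in (a, b):
            if g not in intakes:
                raise ValidationError(f"preference pair ({a},{b}) references unknown group {g}")
        cons.append(_Constraint(f"either_or[{a},{b}]", {}, {a: 1.0, b: 1.0}, -math.inf, 1.0))
    return ProblemSpec(list(gids), intakes, currents, config, cons)


def fix_selection(problem: ProblemSpec, chosen_ids: Iterable[int]) -> ProblemSpec:
    """Fix the binary selection: z=1 for ``chosen_ids``, z=0 for all others.

    The continuous subproblem over the concentrations remains.
    """
    chosen = {int(g) for g in chosen_ids}
    unknown = chosen - set(problem.group_ids)
    if unknown:
        raise ValidationError(f"unknown group ids in selection: {sorted(unknown)}")
    fixed = {g: (1 if g in chosen else 0) for g in problem.group_ids}
    return replace(problem, z_fixed=fixed, constraints=list(problem.constraints))


def _canonical_fill(
    selection: Sequence[int],
    intakes: dict[int, float],
    currents: dict[int, float],
    config: ModelConfig,
    target: float,
) -> dict[int, float]:
    """Deterministic optimal witness: selected groups start at the activation
    floor and are raised to their ceiling in ascending group-ID order until
    the aggregate supply reaches ``target``."""
    conc = {g: config.activation_min for g in selection}
    total = sum(intakes[g] * conc[g] for g in selection)
    for g in sorted(selection):
        if total >= target - TOL:
            break
        ub = config.upper_bound(currents[g])
        room = intakes[g] * (ub - conc[g])
        step = min(room, target - total)
        if step > 0 and intakes[g] > 0:
            conc[g] += step / intakes[g]
            total += step
    return conc


def solve(problem: ProblemSpec) -> FortificationPlan:
    """Solve the fortification MIP; deterministic for identical input.

    Infeasibility is reported as ``solver_status="infeasible"`` with an
    all-zero plan rather than raised, so scenario scans can continue.
    """
    gids = sorted(problem.group_ids)
    n = len(gids)
    idx = {g: i for i, g in enumerate(gids)}
    ncols = 2 * n  # [c_1..c_n, z_1..z_n], ascending group id

    obj = np.zeros(ncols)
    for g in gids:
        obj[idx[g]] = -problem.intakes[g]  # milp minimises

    rows, lbs, ubs = [], [], []
    for con in problem.constraints:
        row = np.zeros(ncols)
        for g, a in con.c_coeffs.items():
            row[idx[g]] = a
        for g, b in con.z_coeffs.items():
            row[n + idx[g]] = b
        rows.append(row)
        lbs.append(con.lb)
        ubs.append(con.ub)

    lo = np.zeros(ncols)
    hi = np.full(ncols, np.inf)
    hi[n:] = 1.0
    for g, zval in problem.z_fixed.items():
        lo[n + idx[g]] = hi[n + idx[g]] = float(zval)
    integrality = np.concatenate([np.zeros(n), np.ones(n)])

    try:
        res = milp(
            c=obj,
            constraints=LinearConstraint(np.array(rows), np.array(lbs), np.array(ubs)),
            bounds=Bounds(lo, hi),
            integrality=integrality,
        )
    except Exception:  # pragma: no cover - backend failure path
        logger.exception("MILP backend failure")
        return FortificationPlan.from_mapping({g: 0.0 for g in gids}, set(), 0.0, "error")

    if res.status == 2:  # infeasible
        return FortificationPlan.from_mapping({g: 0.0 for g in gids}, set(), 0.0, "infeasible")
    if res.status != 0 or res.x is None:
        logger.error("solver returned status %s: %s", res.status, res.message)
        return FortificationPlan.from_mapping({g: 0.0 for g in gids}, set(), 0.0, "error")

    x = np.asarray(res.x)
    selection = [g for g in gids if x[n + idx[g]] > 0.5]
    target = float(sum(problem.intakes[g] * x[idx[g]] for g in gids))
    conc = _canonical_fill(selection, problem.intakes, problem.currents, problem.config, target)
    full = {g: conc.get(g, 0.0) for g in gids}
    objective = float(sum(problem.intakes[g] * full[g] for g in gids))
    return FortificationPlan.from_mapping(full, selection, objective, "optimal")


@dataclass
class ConstraintReport:
    """Per-constraint slack report for a candidate plan."""

    frame: pd.DataFrame  # columns constraint, value, slack, satisfied, binding
    tolerance: float

    @property
    def all_satisfied(self) -> bool:
        return bool(self.frame["satisfied"].all())

    def violated(self) -> pd.DataFrame:
        return self.frame[~self.frame["satisfied"]]

    def binding(self) -> pd.DataFrame:
        return self.frame[self.frame["binding"]]


def verify_plan(
    plan: FortificationPlan,
    matrix: CompositionMatrix,
    config: ModelConfig,
    tolerance: float = TOL,
) -> ConstraintReport:
    """Re-evaluate every constraint at a candidate plan and report slacks.

    Plans printed at 3 decimals need ``tolerance=0.01`` on the aggregate
    equality (rounding noise accumulates over the sum).
    """
    problem = build_problem(matrix, config)
    conc = plan.concentrations
    chosen = {int(g): int(z) for g, z in zip(plan.frame["group_id"], plan.frame["chosen"])}
    missing = set(problem.group_ids) - set(conc)
    if missing:
        raise ValidationError(f"plan does not cover groups: {sorted(missing)}")
    records = []
    for con in problem.constraints:
        value = con.value(conc, chosen)
        slacks = []
        if math.isfinite(con.lb):
            slacks.append(value - con.lb)
        if math.isfinite(con.ub):
            slacks.append(con.ub - value)
        slack = min(slacks) if slacks else math.inf
        records.append(
            {
                "constraint": con.name,
                "value": value,
                "slack": slack,
                "satisfied": slack >= -tolerance,
                "binding": abs(slack) <= tolerance,
            }
        )
    return ConstraintReport(pd.DataFrame(records), tolerance)
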