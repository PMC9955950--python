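"""Encode policy preferences: either–or pairs, cardinality caps, RI as a floor.

The formulation accepts either–or constraints (at most one of two groups may
be fortified), a cap on the number of fortified groups, and an alternative RI
mode in which the recommended intake is a lower bound rather than an equality
— the maximiser then pushes the aggregate supply up to the UL or the
attainable maximum, whichever is smaller.
"""

from fortiplan import build_problem, datasets, solve

composition = datasets.load_composition()

# fish (8) and eggs (10) may not both be fortified; at most 3 groups total
config = datasets.model_config(1, preference_pairs=((8, 10),), max_groups=3)
plan = solve(build_problem(composition, config))
print(f"either-or + cardinality: status={plan.solver_status}, "
      f"chosen={sorted(plan.chosen_ids)}, objective={plan.objective_value:.3f} µg/day")
assert not {8, 10} <= plan.chosen_ids and len(plan.chosen_ids) <= 3

# RI as a floor: supply rises to the UL of 50 µg/day
config_floor = datasets.model_config(1, ri_mode="lower_bound")
plan_floor = solve(build_problem(composition, config_floor))
print(f"RI as lower bound:      status={plan_floor.solver_status}, "
      f"chosen={sorted(plan_floor.chosen_ids)}, objective={plan_floor.objective_value:.3f} µg/day")
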