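# fortiplan

Vitamin D intake in Northern European populations is typically well below the
recommended intake, and food fortification is a population-level remedy that
does not require anyone to change what they eat. **fortiplan** is a toolkit
for planning such fortification with mixed-integer programming and for
evaluating what a plan does to the population intake distribution. It is
aimed at nutrition researchers and risk–benefit modellers who have a
group-level food-composition table and, optionally, individual-level dietary
survey data.

## The model

Given food groups *i* with average intake *a<sub>i</sub>* (g/day) and current
nutrient concentration *k<sub>i</sub>* (µg/g), the planner chooses a binary
selection *z<sub>i</sub>* ∈ {0,1} and a new concentration *c<sub>i</sub>* ≥ 0
(µg/g):

```
maximize   Σᵢ aᵢ·cᵢ
subject to Σᵢ aᵢ·cᵢ ≥ AR              (average requirement)
           Σᵢ aᵢ·cᵢ = RI              (recommended intake; optionally ≥)
           Σᵢ aᵢ·cᵢ ≤ UL              (tolerable upper level)
           cᵢ ≥ 0.1·zᵢ                (activation floor for chosen groups)
           cᵢ ≤ 10000·zᵢ              (big-M link: cᵢ > 0 only if chosen)
           cᵢ ≤ kᵢ + δ                (proximity to current concentration)
           Σᵢ zᵢ ≤ K                  (optional cardinality cap)
           z_a + z_b ≤ 1              (optional either–or preferences)
```

The proximity constraint δ is the interesting ingredient: it forbids loading
one group with a huge dose and therefore spreads the fortification over
several food groups. A brute-force oracle (closed-form solve of every binary
selection) validates the MIP solver and enumerates alternate optima, and a
dispersal/evaluation layer maps a group-level plan down to individual food
items and counts, per age band, how many people sit below the AR/RI or above
the UL. A seeded synthetic-survey generator stands in for restricted
individual-level dietary records.

## Worked example

```python
from fortiplan import build_problem, datasets, fix_selection, solve

composition = datasets.load_composition()      # 17 food groups
config = datasets.model_config(1)              # AR 7.5, RI 10, UL 50, δ 0.2
plan = solve(fix_selection(build_problem(composition, config), {3, 8, 9, 10}))
for gid in sorted(plan.chosen_ids):
    print(f"group {gid:>2}: fortify to {plan.concentrations[gid]:.3f} µg/g")
print(f"aggregate supply {plan.objective_value:.3f} µg/day")
```

prints

```
group  3: fortify to 0.201 µg/g
group  8: fortify to 0.277 µg/g
group  9: fortify to 0.202 µg/g
group 10: fortify to 0.198 µg/g
aggregate supply 10.000 µg/day
```

i.e. fortifying edible ices (3), fish (8), poultry (9) and eggs (10) — the
first three clipped at their proximity bound *k<sub>i</sub>* + 0.2, eggs
taking the remaining slack — makes the aggregate supply hit the recommended
intake of 10 µg/day exactly. The `examples/` directory has one short script
per capability (free optimisation, oracle enumeration, synthetic-survey
evaluation, policy constraints); each prints its results with a line on what
they mean.

A thin CLI wraps the same functions:

```sh
fortiplan optimize --fix-selection "3,8,9,10" --out run/
fortiplan simulate --n-persons 1000 --seed 1 --out sim/
fortiplan pipeline --composition comp.csv --survey sim/survey.csv --out run/
```

Exit codes: 0 success, 2 infeasible model, 1 error. Every output directory
gets a `manifest.json` with input digests, config, seed and version.

## Layout

- `fortiplan.data` — domain types and CSV I/O (composition matrices,
  reference values, surveys), aggregation, per-person intake
- `fortiplan.model` — the MIP: build, solve, fix selections, verify plans
- `fortiplan.oracle` — exhaustive enumeration with closed-form subproblems
- `fortiplan.dispersal` — plan→item dispersal and exposure evaluation
- `fortiplan.simulate` — seeded synthetic dietary surveys
- `fortiplan.datasets` — the packaged 17-group instance and model presets
- `fortiplan.cli` — the command-line interface

See `docs/methods.md` for modelling assumptions, calibration choices and
known limitations.
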