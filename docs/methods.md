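# Methods

## The optimisation model

The planner is a mixed-integer linear program over food groups. For group
*i* with average intake *aᵢ* (g/day) and current concentration *kᵢ* (µg/g) it
chooses a binary selector *zᵢ* and a new concentration *cᵢ* (µg/g),
maximising the aggregate supply Σ aᵢ·cᵢ subject to the AR/RI/UL rows, the
activation floor *cᵢ* ≥ 0.1·*zᵢ*, the big-M link *cᵢ* ≤ 10000·*zᵢ* and the
proximity bound *cᵢ* ≤ *kᵢ* + δ. The activation floor, big-M link and
proximity bound are per-group constraints: the realised plans clip per group
at *kᵢ* + δ and at the 0.1 floor, which is only consistent with a per-group
reading. Strict inequalities in the written formulation are implemented
non-strictly, as is standard for linear programming.

All constants are configurable with these defaults: activation floor 0.1
µg/g, big-M 10000 µg/g (any value above every attainable concentration
works), and proximity δ per model preset — 0.2 for the whole population
(ages 4–75) and for adults 18–69, 0.1 for ages 11–17, 1.0 for ages 4–10. UL
is 50 µg/day whenever the 4–10 band is covered (children are the limiting
group) and 100 µg/day otherwise; AR is 7.5 and RI 10 µg/day throughout.
A group whose ceiling *kᵢ* + δ falls below the activation floor is
unfortifiable; this is logged, not an error — the binary logic simply forces
*zᵢ* = 0.

### Degeneracy and canonicalisation

With the RI row as an equality (the default, faithful to the published
formulation) the objective is pinned at RI for every feasible point, so both
the selection and the continuous concentrations are massively degenerate: the
packaged 17-group instance has 15 848 optimal selections, and within a fixed
selection every point of a polytope is optimal. Two consequences:

- `solve` canonicalises the continuous part deterministically: all selected
  groups start at the activation floor and are raised to their proximity
  ceiling in ascending group-ID order until the aggregate target is met.
  This makes repeated solves byte-identical and, with the published 4-group
  selection fixed, reproduces the published per-group concentrations (three
  groups at the bound, the last taking the equality slack). The same fill
  builds the oracle's witness. Only feasibility and the objective value are
  contractual; the canonical point is one optimum among many.
- Which selection a solver reports is arbitrary among the optima. The free
  solve of the packaged instance returns a single-group plan (potatoes); the
  published 4-group selection is verified as *an* optimum via the oracle and
  reproduced via `fix_selection`, not claimed unique.

`ri_mode="lower_bound"` is offered because the equality makes the AR row
redundant and the maximisation vacuous; with RI as a floor the objective
becomes min(UL, attainable maximum) and the maximiser is meaningful. The
default stays with the equality.

The published whole-population fish-group value 0.278 µg/g exceeds the
proximity ceiling implied by the packaged composition chart
(0.07719 + 0.2 = 0.27719, which prints as 0.277) by 0.0008 — a rounding
artefact of the source table. Verification of printed 3-decimal plans
therefore uses tolerance 0.01, which also absorbs the aggregate rounding
noise (the printed plan supplies 10.006 µg/day against the RI of 10).

### Solver and oracle

The MIP backend is `scipy.optimize.milp` (HiGHS); infeasibility is a
reported status with an all-zero plan, not an exception, so scenario scans
continue. The independent oracle enumerates all 2^n selections (guarded at
n ≤ 20) and solves each continuous subproblem in closed form: a selection is
feasible iff its supply interval [Σ aᵢ·0.1, Σ aᵢ·(kᵢ+δ)] intersects the
AR/RI/UL window, and the optimum is the window-clipped interval maximum.
The suite checks MIP-vs-oracle agreement (objective to 1e-6, feasibility
verdicts) on 100 seeded random instances, and the closed form against a
generic LP solve on 100 random fixed selections.

## Dispersal and evaluation

A plan is group-level; fortification is item-level. Uniform dispersal
substitutes the group concentration for every item in a chosen group;
weighted dispersal rescales the items' current concentrations so their
intake-weighted mean equals the plan value (all-zero groups fall back to
uniform). Unchosen groups get zero by default (the as-modelled convention,
which understates intake) or keep their current concentrations
(`retain_current`, the realistic policy).

Evaluation counts persons strictly below AR and RI and strictly above UL per
age band, plus mean and median; boundary persons count as compliant (the
qualitative wording "below"/"above" does not fix the convention; strictness
matches it literally). The whole-sample row applies each person's own band
thresholds, so one population-wide plan is judged against children's UL 50
and adults' UL 100 simultaneously. Medians of even-sized groups are the mean
of the two central order statistics. Histogram export uses fixed 1 µg/day
bins from zero (configurable).

## The synthetic survey generator

The individual-level dietary records behind the original analysis are
restricted, so the generator emulates their structure: `n_persons` (default
3946) drawn into four age bands with weights 499 : 431 : 2750 : 266 (ages
4–10, 11–17, 18–69, 70–75); per person and food group a Bernoulli consumption
indicator; per consumed item a log-normal daily amount (log-normal is the
standard right-skew model for dietary intake). Item concentrations inherit
the group's composition-chart value times a unit-mean multiplicative
log-normal jitter (sd 0.15 by default), drawn once per item. All draws come
from one seeded generator, blocked per group for speed; identical seed and
config give byte-identical CSVs, and inserting a new group changes all
downstream draws.

Calibration: the composition chart's intake column implies a current-scenario
mean of only ~1.24 µg/day, while the surveyed population mean is 4.84 µg/day
— the chart's "average intake" is evidently not the population-mean group
consumption (its exact derivation from the survey is unstated; both
`intake_weighted` and `mean_of_item_means` aggregations are provided, neither
claimed to reproduce it). The generator therefore scales mean group grams by
4.84/1.2354 ≈ 3.92 so the simulated current-scenario mean matches the
surveyed one. Consumption probabilities and item counts per group are fixed
plausible values (e.g. beverages consumed by 98% of persons across 8 items,
fish by 45% across 6); log-sd is 0.8 throughout.

What passing tests show — and don't. The generator reproduces the *shape* of
survey data (skew, band structure, group nesting) and its aggregates recover
configured targets at n = 10 000 (concentrations within 2%, mean group grams
within 5%, jitter-free). It does not reproduce the real microdata's
correlations between foods, within-person day-to-day variance, or the
published individual-level counts (mean 19.95 µg/day fortified, 128 persons
above UL). One systematic effect carries over qualitatively: because survey
persons consume more grams than the chart's intake column, a plan whose
*aggregate* supply is calibrated to 10 µg/day yields individual fortified
intakes well above 10 — visible in the original analysis (fortified mean
19.95) and amplified in the synthetic survey (≈39 µg/day under the 3.92×
grams calibration). Synthetic evaluation results are therefore read as
invariant checks (below-AR counts fall, UL exceedances concentrate in the
low-UL child band, as-modelled ≤ realistic intake), not as predictions.

## Numerical choices

- Feasibility tolerance 1e-6 throughout; printed 3-decimal plans verified at
  0.01.
- Variable order and all tie-breaks: ascending group ID. Oracle ties on the
  objective resolved to the selection with fewest groups, then the
  lexicographically smallest ID tuple.
- Group IDs are opaque labels (the packaged grouping skips IDs 15, 16,
  18–24); all joins are by ID.
- Survey amounts are mean daily grams (multi-day recordings are assumed
  already averaged), so per-person intake is a plain Σ amount × concentration.
- Items absent from a concentration table fall back to their survey value,
  making the current scenario a no-table evaluation.
- Reference bands are half-open integer intervals and must not overlap. The
  published reference table leaves ages 70–75 uncovered (its last column
  starts at 75); the packaged *evaluation* reference set assigns 70–75 the
  adult values (AR 7.5, RI 10, UL 100) as this package's documented choice,
  while the as-published set is also shipped.

## Known limitations

- Seasonal variation of vitamin D status and sun exposure is out of scope, as
  are potency differences between vitamin D2 and D3 (D3 assumed throughout).
- The MIP constrains only the aggregate supply row, not per-individual or
  per-percentile intake; a quadratic deviation-minimising objective is not
  implemented.
- Economic costs of fortifying multiple groups are not modelled.
- The oracle is exponential by design and guarded at 20 groups.
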