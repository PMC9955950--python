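"""Dispersal of group-level fortification to food items and population
exposure evaluation.

A solved plan assigns one concentration per food *group*; real fortification
happens per food *item*.  :func:`disperse` maps the plan down to items, either
uniformly (every item in a chosen group gets the group concentration) or
weighted (item concentrations keep their current relative profile, rescaled
so the intake-weighted group mean hits the plan value).  Items of unchosen
groups get zero under the as-modelled convention, or keep their current
concentration under the realistic convention — the as-modelled default
deliberately understates intake, since in practice unfortified groups do not
lose the nutrient they already contain.

:func:`evaluate` then counts, per age band, how many people fall below the
average requirement (AR) and recommended intake (RI) and how many exceed the
tolerable upper level (UL).  All three comparisons are strict: a person
exactly at a threshold counts as compliant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import IntakeSurvey, ReferenceSet, ValidationError, person_intake
from .model import FortificationPlan

logger = logging.getLogger(__name__)

__all__ = [
    "disperse",
    "evaluate",
    "compare_scenarios",
    "ScenarioComparison",
    "histogram_table",
]

SUMMARY_COLUMNS = [
    "band", "n_below_ar", "n_below_ri", "n_above_ul", "mean", "median", "sample_size",
]


def disperse(
    plan: FortificationPlan,
    survey: IntakeSurvey,
    mode: str = "uniform",
    unchosen: str = "zero",
) -> pd.Series:
    """Map a group-level plan to an item-level concentration table (µg/g).

    mode
        ``"uniform"``: every item of a chosen group gets the group's plan
        concentration.  ``"weighted"``: items keep their current relative
        concentrations, rescaled so the intake-weighted group mean equals the
        plan concentration (groups whose current concentrations are all zero
        fall back to uniform).
    unchosen
        ``"zero"``: items of unchosen groups are assigned zero (as-modelled).
        ``"retain_current"``: they keep their survey concentration (realistic).
    """
    if mode not in ("uniform", "weighted"):
        raise ValueError(f"unknown dispersal mode {mode!r}")
    if unchosen not in ("zero", "retain_current"):
        raise ValueError(f"unknown unchosen policy {unchosen!r}")
    plan_conc = plan.concentrations
    chosen = plan.chosen_ids
    unknown = set(survey.frame["group_id"].unique()) - set(plan_conc)
    if unknown:
        raise ValidationError(f"survey references groups absent from plan: {sorted(unknown)}")

    items = (
        survey.frame.groupby("item_id")
        .agg(
            group_id=("group_id", "first"),
            current=("item_concentration", "first"),
            grams=("amount", "sum"),
        )
        .reset_index()
    )
    out = {}
    for gid, g in items.groupby("group_id"):
        if gid in chosen:
            target = plan_conc[gid]
            if mode == "uniform":
                for item in g["item_id"]:
                    out[item] = target
            else:
                mass = (g["grams"] * g["current"]).sum()
                grams = g["grams"].sum()
                current_mean = mass / grams if grams > 0 else 0.0
                if current_mean <= 0:
                    for item in g["item_id"]:
                        out[item] = target  # all-zero group: uniform fallback
                else:
                    scale = target / current_mean
                    for item, cur in zip(g["item_id"], g["current"]):
                        out[item] = cur * scale
        else:
            for item, cur in zip(g["item_id"], g["current"]):
                out[item] = 0.0 if unchosen == "zero" else float(cur)
    table = pd.Series(out, name="concentration").sort_index()
    table.index.name = "item_id"
    return table


def _band_stats(intakes: np.ndarray, ar, ri, ul) -> dict:
    """Counts with strict comparisons; thresholds may be arrays (per person)."""
    return {
        "n_below_ar": int(np.sum(intakes < ar)),
        "n_below_ri": int(np.sum(intakes < ri)),
        "n_above_ul": int(np.sum(intakes > ul)),
        "mean": float(np.mean(intakes)) if len(intakes) else float("nan"),
        "median": float(np.median(intakes)) if len(intakes) else float("nan"),
        "sample_size": int(len(intakes)),
    }


def evaluate(
    survey: IntakeSurvey,
    concentrations: pd.Series | dict | None,
    refs: ReferenceSet,
) -> pd.DataFrame:
    """Per-age-band exposure summary plus a whole-sample row.

    The ``all`` row applies each person's own band thresholds (e.g. UL 50 for
    children, 100 for adults) so a single population-wide plan is judged
    against every band's limits at once.
    """
    intake = person_intake(survey, concentrations)
    ages = survey.ages().loc[intake.index]
    bands = [refs.band_for(int(a)) for a in ages]
    unmatched = [pid for pid, b in zip(intake.index, bands) if b is None]
    if unmatched:
        raise ValidationError(
            f"persons whose age matches no reference band: {unmatched[:10]}"
            + ("..." if len(unmatched) > 10 else "")
        )
    per_person = pd.DataFrame(
        {
            "intake": intake.to_numpy(),
            "ar": [b.ar for b in bands],
            "ri": [b.ri for b in bands],
            "ul": [b.ul for b in bands],
            "band": [b.label for b in bands],
        },
        index=intake.index,
    )
    rows = []
    for band in refs.bands:
        sub = per_person[per_person["band"] == band.label]
        if sub.empty:
            continue
        stats = _band_stats(sub["intake"].to_numpy(), band.ar, band.ri, band.ul)
        rows.append({"band": band.label, **stats})
    stats = _band_stats(
        per_person["intake"].to_numpy(),
        per_person["ar"].to_numpy(),
        per_person["ri"].to_numpy(),
        per_person["ul"].to_numpy(),
    )
    rows.append({"band": "all", **stats})
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


@dataclass
class ScenarioComparison:
    """Paired exposure summaries: current survey concentrations vs a plan."""

    current: pd.DataFrame
    fortified: pd.DataFrame
    delta: pd.DataFrame  # percentage-point changes per band

    def to_csv(self, path) -> None:
        cur = self.current.assign(scenario="current")
        new = self.fortified.assign(scenario="fortified")
        pd.concat([cur, new], ignore_index=True)[["scenario"] + SUMMARY_COLUMNS].to_csv(
            path, index=False
        )


def compare_scenarios(
    survey: IntakeSurvey,
    plan: FortificationPlan,
    refs: ReferenceSet,
    mode: str = "uniform",
    unchosen: str = "zero",
) -> ScenarioComparison:
    """Evaluate the current scenario against the fortified one.

    The delta table reports percentage-point changes of the below-AR,
    below-RI and above-UL shares per band (fortified minus current).
    """
    current = evaluate(survey, None, refs)
    table = disperse(plan, survey, mode=mode, unchosen=unchosen)
    fortified = evaluate(survey, table, refs)
    delta_rows = []
    for (_, c), (_, f) in zip(current.iterrows(), fortified.iterrows()):
        n = c["sample_size"]
        delta_rows.append(
            {
                "band": c["band"],
                "pp_below_ar": 100.0 * (f["n_below_ar"] - c["n_below_ar"]) / n,
                "pp_below_ri": 100.0 * (f["n_below_ri"] - c["n_below_ri"]) / n,
                "pp_above_ul": 100.0 * (f["n_above_ul"] - c["n_above_ul"]) / n,
                "mean_change": f["mean"] - c["mean"],
            }
        )
    return ScenarioComparison(current, fortified, pd.DataFrame(delta_rows))


def histogram_table(intakes: pd.Series, bin_width: float = 1.0) -> pd.DataFrame:
    """Binned intake counts (fixed-width bins from 0) for plotting export."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(intakes, dtype=float)
    top = max(values.max(initial=0.0), bin_width)
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})
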