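"""Packaged reference datasets: the 17-group Danish vitamin D instance.

Ships the food-composition matrix (average group intake in g/day and current
vitamin D concentration in µg/g), the food-group labels, the vitamin D
reference values per age band, and the published whole-population
fortification plan, so the worked analysis can be reproduced without access
to the restricted individual-level survey.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data import (
    CompositionMatrix,
    FoodGroup,
    ReferenceSet,
    read_composition,
    read_reference_values,
)
from .model import FortificationPlan, ModelConfig

__all__ = [
    "load_composition",
    "load_food_groups",
    "load_reference_values",
    "load_evaluation_reference_values",
    "model_config",
    "published_model1_selection",
    "published_model1_plan",
]


def _path(name: str):
    return resources.files("fortiplan").joinpath("resources", name)


def load_composition() -> CompositionMatrix:
    """The 17-group vitamin D composition matrix (no fortification)."""
    with resources.as_file(_path("food_composition.csv")) as p:
        return read_composition(p)


def load_food_groups() -> list[FoodGroup]:
    """The 17 food groups considered for fortification."""
    with resources.as_file(_path("food_groups.csv")) as p:
        frame = pd.read_csv(p)
    return [FoodGroup(int(r.group_id), str(r.name)) for r in frame.itertuples()]


def load_reference_values() -> ReferenceSet:
    """Vitamin D AR/RI/UL per age band as published.

    Note the published table covers 4–10, 11–17, 18–69 and >75 years; ages
    70–75 are not assigned a band.  For evaluating a whole-population plan on
    persons aged 4–75 use :func:`load_evaluation_reference_values`.
    """
    with resources.as_file(_path("reference_values.csv")) as p:
        return read_reference_values(p)


def load_evaluation_reference_values() -> ReferenceSet:
    """Reference set covering ages 4–75 for whole-population evaluation.

    Ages 70–75 inherit the adult values (AR 7.5, RI 10, UL 100 µg/day), the
    package's own documented choice for the band the published table leaves
    uncovered.
    """
    with resources.as_file(_path("evaluation_reference_values.csv")) as p:
        return read_reference_values(p)


# Proximity delta per model: 0.2 for the whole population (model 1) and for
# adults 18-69 (model 3, whose published plan clips at current + 0.2), 0.1 for
# ages 11-17 (model 2), 1.0 for ages 4-10 (model 4).  UL is 50 µg/day when the
# 4-10 band is covered (models 1 and 4), 100 otherwise.
_MODEL_PARAMS = {
    1: {"ul": 50.0, "proximity_delta": 0.2},   # whole population, 4-75 y
    2: {"ul": 100.0, "proximity_delta": 0.1},  # 11-17 y
    3: {"ul": 100.0, "proximity_delta": 0.2},  # 18-69 y
    4: {"ul": 50.0, "proximity_delta": 1.0},   # 4-10 y
}


def model_config(model: int = 1, **overrides) -> ModelConfig:
    """The published optimisation configuration for one of the four models.

    All models share AR 7.5 and RI 10 µg/day (as an equality) and differ in UL
    and proximity delta.  Keyword overrides are passed through to
    :class:`ModelConfig`.
    """
    if model not in _MODEL_PARAMS:
        raise ValueError(f"model must be 1-4, got {model}")
    params = {"ar": 7.5, "ri": 10.0, **_MODEL_PARAMS[model]}
    params.update(overrides)
    return ModelConfig(**params)


#: Food groups chosen by the published whole-population plan:
#: edible ices (3), fish (8), poultry (9), eggs (10).
published_model1_selection = frozenset({3, 8, 9, 10})

# Published whole-population fortification concentrations (µg/g, printed at
# 3 decimals).  The fish-group value 0.278 slightly exceeds the proximity
# bound 0.07719 + 0.2 = 0.27719 implied by the composition matrix — a
# rounding artefact of the source table; verify with tolerance 0.01.
_PUBLISHED_MODEL1 = {3: 0.201, 8: 0.278, 9: 0.202, 10: 0.198}


def published_model1_plan() -> FortificationPlan:
    """The published whole-population plan as a :class:`FortificationPlan`."""
    comp = load_composition()
    conc = {g: _PUBLISHED_MODEL1.get(g, 0.0) for g in comp.group_ids}
    supply = sum(comp.intakes[g] * c for g, c in conc.items())
    return FortificationPlan.from_mapping(
        conc, set(_PUBLISHED_MODEL1), objective_value=supply, solver_status="optimal"
    )
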