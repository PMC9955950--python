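import numpy as np
import pandas as pd
import pytest

from fortiplan import (
    CompositionMatrix,
    IntakeSurvey,
    ModelConfig,
    ReferenceBand,
    ReferenceSet,
    datasets,
)


@pytest.fixture(scope="session")
def composition() -> CompositionMatrix:
    """The packaged 17-group composition matrix."""
    return datasets.load_composition()


@pytest.fixture(scope="session")
def model1_config() -> ModelConfig:
    """Whole-population configuration: AR 7.5, RI 10 (equality), UL 50, delta 0.2."""
    return datasets.model_config(1)


@pytest.fixture
def small_survey() -> IntakeSurvey:
    """3 persons x 2 items of one group, unequal grams (hand-computable)."""
    frame = pd.DataFrame(
        {
            "person_id": [1, 1, 2, 2, 3],
            "age": [30, 30, 45, 45, 60],
            "item_id": [101, 102, 101, 102, 101],
            "group_id": [1, 1, 1, 1, 1],
            "amount": [10.0, 20.0, 30.0, 5.0, 20.0],
            "item_concentration": [0.02, 0.05, 0.02, 0.05, 0.02],
        }
    )
    return IntakeSurvey(frame)


@pytest.fixture
def five_person_survey() -> IntakeSurvey:
    """5 adults whose intakes are exactly {2, 6, 9, 12, 60} ug/day."""
    amounts = [2.0, 6.0, 9.0, 12.0, 60.0]
    frame = pd.DataFrame(
        {
            "person_id": range(1, 6),
            "age": [30] * 5,
            "item_id": [1001] * 5,
            "group_id": [1] * 5,
            "amount": amounts,
            "item_concentration": [1.0] * 5,
        }
    )
    return IntakeSurvey(frame)


@pytest.fixture
def adult_refs() -> ReferenceSet:
    return ReferenceSet([ReferenceBand(18, 70, 7.5, 10.0, 50.0)])


def random_instance(rng: np.random.Generator, max_groups: int = 8):
    """A random small fortification instance (matrix + config) for
    MIP-vs-oracle equivalence checks.  Roughly half the draws are feasible."""
    n = int(rng.integers(1, max_groups + 1))
    gids = sorted(rng.choice(np.arange(1, 30), size=n, replace=False).tolist())
    intakes = rng.uniform(1.0, 100.0, size=n)
    currents = np.where(rng.random(n) < 0.4, 0.0, rng.uniform(0.0, 0.1, size=n))
    matrix = CompositionMatrix.from_records(
        [(int(g), float(i), float(c)) for g, i, c in zip(gids, intakes, currents)]
    )
    ar = float(rng.uniform(2.0, 9.0))
    ri = float(ar + rng.uniform(0.0, 4.0))
    ul = float(ri + rng.uniform(1.0, 40.0))
    kwargs = dict(
        ar=ar,
        ri=ri,
        ul=ul,
        proximity_delta=float(rng.uniform(0.05, 0.5)),
        ri_mode="equality" if rng.random() < 0.5 else "lower_bound",
    )
    if rng.random() < 0.3:
        kwargs["max_groups"] = int(rng.integers(1, n + 1))
    if n >= 2 and rng.random() < 0.3:
        a, b = rng.choice(gids, size=2, replace=False)
        kwargs["preference_pairs"] = ((int(a), int(b)),)
    return matrix, ModelConfig(**kwargs)
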