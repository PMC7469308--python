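import numpy as np
import pytest

from thyrisk.cohort import CharacteristicSpec, Cohort, NoduleRecord
from thyrisk.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort at the default study conditions, scaled down."""
    return generate_cohort(default_config(n=400, seed=20))


@pytest.fixture(scope="session")
def medium_cohort():
    return generate_cohort(default_config(n=1448, seed=21))


@pytest.fixture()
def toy_schema():
    return [
        CharacteristicSpec("component", "categorical", ("solid", "mixed"), "mixed"),
        CharacteristicSpec(
            "calcification", "categorical", ("micro", "macro", "none"), "none"
        ),
    ]


def make_record(i, outcome, component="solid", calcification="none", **kw):
    return NoduleRecord(
        nodule_id=f"N{i}",
        patient_id=f"P{i}",
        sex="female",
        age=kw.get("age", 50.0),
        size=kw.get("size", 10.0),
        er=kw.get("er", 1.0),
        characteristics={"component": component, "calcification": calcification},
        outcome=outcome,
    )


@pytest.fixture()
def toy_cohort(toy_schema):
    records = [
        make_record(0, "malignant", "solid", "micro"),
        make_record(1, "malignant", "solid", "none"),
        make_record(2, "benign", "mixed", "none"),
        make_record(3, "benign", "mixed", "macro"),
        make_record(4, "malignant", "solid", "micro", er=0.8),
        make_record(5, "benign", "solid", "none", er=2.0),
    ]
    return Cohort(toy_schema, records)


def counts_cohort(per_level: dict[str, tuple[int, int]], reference: str) -> Cohort:
    """Cohort with a single categorical characteristic realizing the given
    (benign, malignant) counts per level — an exact reconstruction of a
    printed contingency table."""
    levels = tuple(per_level)
    schema = [CharacteristicSpec("char", "categorical", levels, reference)]
    records = []
    i = 0
    for level, (n_ben, n_mal) in per_level.items():
        for outcome, k in (("benign", n_ben), ("malignant", n_mal)):
            for _ in range(k):
                records.append(
                    NoduleRecord(
                        nodule_id=f"N{i}",
                        patient_id=f"P{i}",
                        sex="female",
                        age=50.0,
                        size=10.0,
                        er=1.0,
                        characteristics={"char": level},
                        outcome=outcome,
                    )
                )
                i += 1
    return Cohort(schema, records)
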