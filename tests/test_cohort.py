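import numpy as np
import pandas as pd
import pytest

from thyrisk.cohort import (
    CharacteristicSpec,
    Cohort,
    decode_design,
    encode_design,
    read_cohort,
    stratified_split,
    write_cohort,
)
from thyrisk.datasets import study_schema
from thyrisk.synthetic import default_config, generate_cohort


class TestSpecs:
    def test_reference_must_be_a_level(self):
        with pytest.raises(ValueError):
            CharacteristicSpec("x", "categorical", ("a", "b"), "c")

    def test_continuous_spec_has_no_levels(self):
        with pytest.raises(ValueError):
            CharacteristicSpec("x", "continuous", ("a",), "a")

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValueError):
            CharacteristicSpec("x", "categorical", ("a", "a"), "a")


class TestIO:
    def test_three_row_csv_parses(self, toy_schema, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            {
                "nodule_id": ["a", "b", "c"],
                "age": [40, 50, 60],
                "size": [8, 9, 10],
                "er": [1.1, 1.2, 1.3],
                "component": ["solid", "mixed", "solid"],
                "calcification": ["micro", "none", "macro"],
                "outcome": ["malignant", "benign", "malignant"],
            }
        ).to_csv(path, index=False)
        cohort = read_cohort(path, toy_schema)
        assert len(cohort) == 3
        assert cohort.records[2].characteristics["calcification"] == "macro"

    def test_unknown_level_names_offending_row(self, toy_schema, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            {
                "nodule_id": ["a", "b"],
                "component": ["solid", "Solidd"],
                "calcification": ["none", "none"],
                "outcome": ["malignant", "benign"],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 1.*Solidd"):
            read_cohort(path, toy_schema)

    def test_duplicate_id_and_missing_outcome_rejected(self, toy_schema, tmp_path):
        path = tmp_path / "c.csv"
        pd.DataFrame(
            {
                "nodule_id": ["a", "a"],
                "component": ["solid", "solid"],
                "calcification": ["none", "none"],
                "outcome": ["malignant", "benign"],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(path, toy_schema)
        pd.DataFrame(
            {
                "nodule_id": ["a", "b"],
                "component": ["solid", "solid"],
                "calcification": ["none", "none"],
                "outcome": ["malignant", None],
            }
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="outcome"):
            read_cohort(path, toy_schema)

    def test_round_trip_preserves_every_field(self, tmp_path):
        cohort = generate_cohort(default_config(n=60, seed=5))
        path = tmp_path / "c.csv"
        write_cohort(cohort, path)
        back = read_cohort(path, cohort.schema)
        assert len(back) == len(cohort)
        for a, b in zip(cohort.records, back.records):
            assert a.nodule_id == b.nodule_id
            assert a.outcome == b.outcome
            assert a.characteristics == b.characteristics
            assert np.isclose(a.age, b.age) and np.isclose(a.er, b.er)


class TestEncoding:
    def test_dummy_coding_and_reference_row(self):
        schema = [CharacteristicSpec("g", "categorical", ("A", "B", "C"), "A")]

        records = []
        for i, level in enumerate(["B", "A", "C"]):
            from thyrisk.cohort import NoduleRecord

            records.append(
                NoduleRecord(
                    nodule_id=str(i),
                    patient_id=str(i),
                    sex="female",
                    age=1,
                    size=1,
                    er=1,
                    characteristics={"g": level},
                    outcome="malignant" if i % 2 == 0 else "benign",
                )
            )
        design = encode_design(Cohort(schema, records))
        assert design.columns == ["g=B", "g=C"]
        assert design.values.tolist() == [[1, 0], [0, 0], [0, 1]]
        assert design.y.tolist() == [1, 0, 1]

    def test_study_schema_column_count(self):
        """m = (non-reference levels over 12 categoricals) + 2 continuous = 17."""
        schema = study_schema()
        non_ref = sum(
            len(s.levels) - 1 for s in schema if s.kind == "categorical"
        )
        assert non_ref == 15
        cohort = generate_cohort(default_config(n=50, seed=1))
        assert encode_design(cohort).m == non_ref + 2

    def test_decode_inverts_encode(self, small_cohort):
        design = encode_design(small_cohort)
        decoded = decode_design(design)
        for spec in small_cohort.categorical_specs:
            assert (decoded[spec.name] == small_cohort.levels(spec.name)).all()

    def test_empty_cohort_rejected(self, toy_schema):
        with pytest.raises(ValueError):
            encode_design(Cohort(toy_schema, []))


class TestStratifiedSplit:
    def _balanced_cohort(self, n_ben, n_mal):
        from thyrisk.cohort import NoduleRecord

        schema = [CharacteristicSpec("g", "categorical", ("A", "B"), "A")]
        records = [
            NoduleRecord(
                nodule_id=str(i),
                patient_id=str(i),
                sex="female",
                age=1,
                size=1,
                er=1,
                characteristics={"g": "A"},
                outcome="benign" if i < n_ben else "malignant",
            )
            for i in range(n_ben + n_mal)
        ]
        return Cohort(schema, records)

    def test_exact_divisibility(self):
        cohort = self._balanced_cohort(10, 10)
        labels = stratified_split(cohort, (0.6, 0.2, 0.2), seed=0)
        y = cohort.outcomes()
        for stratum in (0, 1):
            sub = labels[y == stratum]
            assert sorted(np.unique(sub, return_counts=True)[1]) == [2, 2, 6]

    def test_deterministic_given_seed(self, small_cohort):
        a = stratified_split(small_cohort, seed=42)
        b = stratified_split(small_cohort, seed=42)
        assert (a == b).all()
        c = stratified_split(small_cohort, seed=43)
        assert (a != c).any()

    @pytest.mark.parametrize("n_ben,n_mal", [(7, 11), (13, 29), (50, 150)])
    def test_counts_within_one_of_target(self, n_ben, n_mal):
        cohort = self._balanced_cohort(n_ben, n_mal)
        labels = stratified_split(cohort, (0.6, 0.2, 0.2), seed=3)
        y = cohort.outcomes()
        assert len(labels) == len(cohort) and not any(l is None for l in labels)
        for stratum, total in ((0, n_ben), (1, n_mal)):
            sub = labels[y == stratum]
            for part, p in zip(("train", "validate", "test"), (0.6, 0.2, 0.2)):
                assert abs(np.sum(sub == part) - p * total) <= 1

    def test_mean_train_fraction_over_seeds(self):
        """Monte-Carlo: across 200 seeds the per-stratum train fraction
        averages 0.6 within binomial error."""
        cohort = self._balanced_cohort(50, 150)
        y = cohort.outcomes()
        fracs = {0: [], 1: []}
        for seed in range(200):
            labels = stratified_split(cohort, seed=seed)
            for s in (0, 1):
                sub = labels[y == s]
                fracs[s].append(np.mean(sub == "train"))
        # largest-remainder rounding keeps each draw within 1/n of 0.6
        for s, n in ((0, 50), (1, 150)):
            assert abs(np.mean(fracs[s]) - 0.6) < 1 / n + 1e-9

    def test_small_stratum_rejected(self):
        cohort = self._balanced_cohort(2, 18)
        with pytest.raises(ValueError, match="stratum"):
            stratified_split(cohort, seed=0)

    def test_bad_proportions_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            stratified_split(small_cohort, (0.5, 0.2, 0.2), seed=0)
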