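"""Nodule cohort data model, CSV I/O, design-matrix encoding and stratified splits.

A cohort is a list of surgically confirmed thyroid nodules, each carrying a
set of categorical ultrasonographic characteristics (margin, border,
calcification pattern, ...), continuous measurements (age in years, nodule
size in millimetres, echogenicity ratio) and the benign/malignant outcome
established by surgery.  Categorical characteristics are dummy-coded against
a per-characteristic reference level — by convention the level with the
lowest malignancy rate — so a row of all zeros within a characteristic's
indicator block means "at the reference level".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

OUTCOMES = ("benign", "malignant")
CONTINUOUS_FIELDS = ("age", "size", "er")

__all__ = [
    "CharacteristicSpec",
    "NoduleRecord",
    "Cohort",
    "DesignMatrix",
    "read_cohort",
    "write_cohort",
    "encode_design",
    "decode_design",
    "stratified_split",
]


@dataclass(frozen=True)
class CharacteristicSpec:
    """One characteristic: either categorical (with levels and a reference
    level) or continuous (no levels)."""

    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple[str, ...] = ()
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"{self.name}: kind must be categorical or continuous")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"{self.name}: categorical spec needs levels")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"{self.name}: duplicate levels")
            if self.reference not in self.levels:
                raise ValueError(f"{self.name}: reference {self.reference!r} not in levels")
        else:
            if self.levels or self.reference is not None:
                raise ValueError(f"{self.name}: continuous spec cannot have levels")

    @property
    def non_reference_levels(self) -> tuple[str, ...]:
        return tuple(lv for lv in self.levels if lv != self.reference)


@dataclass
class NoduleRecord:
    """A single nodule: identifiers, measurements, characteristic levels
    and the surgical outcome."""

    nodule_id: str
    patient_id: str
    sex: str
    age: float
    size: float
    er: float
    characteristics: dict[str, str]
    outcome: str
    group: str = "disease"

    def validate(self, schema: Sequence[CharacteristicSpec]) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"nodule {self.nodule_id}: outcome {self.outcome!r}")
        if not self.age >= 0:
            raise ValueError(f"nodule {self.nodule_id}: age must be >= 0")
        if not self.size > 0:
            raise ValueError(f"nodule {self.nodule_id}: size must be > 0")
        if not self.er > 0:
            raise ValueError(f"nodule {self.nodule_id}: er must be > 0")
        for spec in schema:
            if spec.kind != "categorical":
                continue
            if spec.name not in self.characteristics:
                raise ValueError(f"nodule {self.nodule_id}: missing {spec.name}")
            level = self.characteristics[spec.name]
            if level not in spec.levels:
                raise ValueError(
                    f"nodule {self.nodule_id}: unknown level {level!r} for {spec.name}"
                )


class Cohort:
    """Validated collection of nodules under a shared characteristic schema."""

    def __init__(self, schema: Sequence[CharacteristicSpec], records: Iterable[NoduleRecord]):
        self.schema = list(schema)
        self.records = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.nodule_id in seen:
                raise ValueError(f"duplicate nodule_id {rec.nodule_id!r}")
            seen.add(rec.nodule_id)
            rec.validate(self.schema)

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:
        n_mal = int(np.sum(self.outcomes()))
        return f"<Cohort n={len(self)} malignant={n_mal} characteristics={len(self.schema)}>"

    @property
    def categorical_specs(self) -> list[CharacteristicSpec]:
        return [s for s in self.schema if s.kind == "categorical"]

    @property
    def continuous_specs(self) -> list[CharacteristicSpec]:
        return [s for s in self.schema if s.kind == "continuous"]

    def spec(self, name: str) -> CharacteristicSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(f"no characteristic named {name!r}")

    def outcomes(self) -> np.ndarray:
        """0/1 outcome vector, 1 = malignant."""
        return np.array([1 if r.outcome == "malignant" else 0 for r in self.records])

    def continuous(self, name: str) -> np.ndarray:
        if name not in CONTINUOUS_FIELDS:
            raise KeyError(f"unknown continuous measurement {name!r}")
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    def levels(self, characteristic: str) -> np.ndarray:
        self.spec(characteristic)  # raises if unknown
        return np.array([r.characteristics[characteristic] for r in self.records])

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Cohort(self.schema, [self.records[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "nodule_id": r.nodule_id,
                "patient_id": r.patient_id,
                "sex": r.sex,
                "age": r.age,
                "size": r.size,
                "er": r.er,
                "outcome": r.outcome,
                "group": r.group,
            }
            row.update(r.characteristics)
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, schema: Sequence[CharacteristicSpec]) -> "Cohort":
        cat_names = [s.name for s in schema if s.kind == "categorical"]
        required = {"nodule_id", "outcome", *cat_names}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        records = []
        for i, row in enumerate(frame.itertuples(index=False)):
            d = row._asdict()
            if pd.isna(d["outcome"]):
                raise ValueError(f"row {i}: missing outcome")
            for name in cat_names:
                if pd.isna(d[name]):
                    raise ValueError(f"row {i}: missing value for {name}")
            records.append(
                NoduleRecord(
                    nodule_id=str(d["nodule_id"]),
                    patient_id=str(d.get("patient_id", d["nodule_id"])),
                    sex=str(d.get("sex", "female")),
                    age=float(d.get("age", 0.0)),
                    size=float(d.get("size", 1.0)),
                    er=float(d.get("er", 1.0)),
                    characteristics={name: str(d[name]) for name in cat_names},
                    outcome=str(d["outcome"]),
                )
            )
        try:
            return cls(schema, records)
        except ValueError as exc:
            raise ValueError(str(exc)) from None


def read_cohort(path, schema: Sequence[CharacteristicSpec]) -> Cohort:
    """Read a one-row-per-nodule CSV (header row, UTF-8) against *schema*.

    Rejects unknown level labels, missing outcomes and duplicate nodule ids,
    naming the offending row and field.
    """
    frame = pd.read_csv(path, dtype=str)
    for col in ("age", "size", "er"):
        if col in frame.columns:
            frame[col] = frame[col].astype(float)
    # re-raise with row index information where validation fails
    cat_names = [s.name for s in schema if s.kind == "categorical"]
    for i, row in frame.iterrows():
        for name in cat_names:
            if name in frame.columns and not pd.isna(row[name]):
                spec = next(s for s in schema if s.name == name)
                if row[name] not in spec.levels:
                    raise ValueError(
                        f"row {i}: unknown level {row[name]!r} for characteristic {name!r}"
                    )
    return Cohort.from_frame(frame, schema)


def write_cohort(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


@dataclass
class DesignMatrix:
    """Dummy-coded design: one indicator per non-reference level of each
    categorical characteristic plus one column per continuous one, with the
    0/1 malignancy outcome vector."""

    columns: list[str]
    values: np.ndarray  # (n, m)
    y: np.ndarray  # (n,)
    schema: list[CharacteristicSpec] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def subset(self, mask: np.ndarray) -> "DesignMatrix":
        mask = np.asarray(mask)
        return DesignMatrix(self.columns, self.values[mask], self.y[mask], self.schema)


def indicator_column_name(characteristic: str, level: str) -> str:
    return f"{characteristic}={level}"


def encode_design(cohort: Cohort, features: Sequence[str] | None = None) -> DesignMatrix:
    """Encode *cohort* into a dummy-coded design matrix.

    ``features`` optionally restricts to a subset of characteristic names
    (categorical blocks are kept or dropped whole).  The reference level of
    each categorical characteristic encodes as all-zero.
    """
    if len(cohort) == 0:
        raise ValueError("cannot encode an empty cohort")
    wanted = set(features) if features is not None else None
    columns: list[str] = []
    arrays: list[np.ndarray] = []
    used_specs: list[CharacteristicSpec] = []
    for spec in cohort.schema:
        if wanted is not None and spec.name not in wanted:
            continue
        used_specs.append(spec)
        if spec.kind == "categorical":
            levels = cohort.levels(spec.name)
            for lv in spec.non_reference_levels:
                columns.append(indicator_column_name(spec.name, lv))
                arrays.append((levels == lv).astype(float))
        else:
            columns.append(spec.name)
            arrays.append(cohort.continuous(spec.name))
    if wanted is not None:
        known = {s.name for s in cohort.schema}
        unknown = wanted - known
        if unknown:
            raise KeyError(f"unknown characteristics: {sorted(unknown)}")
    values = np.column_stack(arrays) if arrays else np.empty((len(cohort), 0))
    return DesignMatrix(columns, values, cohort.outcomes().astype(float), used_specs)


def decode_design(design: DesignMatrix) -> dict[str, np.ndarray]:
    """Invert the dummy coding: recover the level label per categorical
    characteristic (all-zero block -> reference level)."""
    out: dict[str, np.ndarray] = {}
    for spec in design.schema:
        if spec.kind != "categorical":
            continue
        labels = np.full(design.n, spec.reference, dtype=object)
        for lv in spec.non_reference_levels:
            j = design.columns.index(indicator_column_name(spec.name, lv))
            labels[design.values[:, j] == 1] = lv
        out[spec.name] = labels
    return out


def stratified_split(
    cohort: Cohort,
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> np.ndarray:
    """Assign each nodule to train/validate/test, stratified by outcome.

    Within each outcome stratum the three partition sizes follow
    largest-remainder rounding of ``n_stratum * proportions``, so they match
    the targets to within one record.  Deterministic given *seed*.
    """
    props = np.asarray(proportions, dtype=float)
    if props.shape != (3,) or not np.isclose(props.sum(), 1.0):
        raise ValueError("proportions must be three values summing to 1")
    y = cohort.outcomes()
    names = np.array(["train", "validate", "test"])
    labels = np.empty(len(cohort), dtype=object)
    rng = np.random.default_rng(seed)
    for stratum in (0, 1):
        idx = np.flatnonzero(y == stratum)
        if len(idx) < 3:
            raise ValueError(
                f"outcome stratum {OUTCOMES[stratum]!r} has {len(idx)} records; need >= 3"
            )
        target = props * len(idx)
        counts = np.floor(target).astype(int)
        remainder = len(idx) - counts.sum()
        # distribute leftover records by largest fractional part
        order = np.argsort(-(target - counts), kind="stable")
        for k in range(remainder):
            counts[order[k]] += 1
        perm = rng.permutation(idx)
        bounds = np.cumsum(counts)
        labels[perm[: bounds[0]]] = names[0]
        labels[perm[bounds[0] : bounds[1]]] = names[1]
        labels[perm[bounds[1] :]] = names[2]
    return labels
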