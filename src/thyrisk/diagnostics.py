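"""Contingency tables, diagnostic accuracy metrics and rank tests.

Every characteristic level is assessed one-vs-rest: a nodule is "positive"
when it shows exactly that level and "negative" otherwise, pooling the
remaining levels.  For such a dichotomous predictor the ROC curve has a
single interior vertex, so its AUC reduces to (SEN + SPE) / 2 — the same
number the rank (Mann-Whitney) AUC yields on the 0/1 indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticMetrics",
    "level_contingency",
    "diagnostic_metrics",
    "fisher_exact",
    "rank_auc",
    "mann_whitney",
    "metrics_from_counts",
    "cohort_report",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts cross-classifying a dichotomous predictor with the outcome.

    tp/fn split the malignant nodules by predictor status, fp/tn the benign.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass(frozen=True)
class DiagnosticMetrics:
    sen: float
    spe: float
    ppv: float | None
    npv: float | None
    auc: float


def level_contingency(cohort: Cohort, characteristic: str, level: str) -> ContingencyTable2x2:
    """One-vs-rest 2x2 table for *level* of *characteristic*: positive means
    the nodule shows exactly this level; all other levels pool as negative."""
    spec = cohort.spec(characteristic)
    if level not in spec.levels:
        raise ValueError(f"unknown level {level!r} for {characteristic!r}")
    labels = cohort.levels(characteristic)
    y = cohort.outcomes().astype(bool)
    pos = labels == level
    return ContingencyTable2x2(
        tp=int(np.sum(pos & y)),
        fp=int(np.sum(pos & ~y)),
        fn=int(np.sum(~pos & y)),
        tn=int(np.sum(~pos & ~y)),
    )


def diagnostic_metrics(table: ContingencyTable2x2) -> DiagnosticMetrics:
    """SEN, SPE, PPV, NPV and the dichotomous-predictor AUC = (SEN+SPE)/2.

    PPV/NPV are ``None`` when their denominator (a predicted class) is empty.
    """
    if table.n == 0:
        raise ValueError("empty contingency table")
    if table.tp + table.fn == 0 or table.fp + table.tn == 0:
        raise ValueError("both outcome classes must be present")
    sen = table.tp / (table.tp + table.fn)
    spe = table.tn / (table.tn + table.fp)
    ppv = table.tp / (table.tp + table.fp) if table.tp + table.fp > 0 else None
    npv = table.tn / (table.tn + table.fn) if table.tn + table.fn > 0 else None
    return DiagnosticMetrics(sen=sen, spe=spe, ppv=ppv, npv=npv, auc=(sen + spe) / 2)


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (probability-ordering rule)."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("Fisher exact test requires all margins > 0")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def rank_auc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC of *scores* for the 0/1 *labels*; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("rank_auc requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Mann-Whitney U of *values_a* vs *values_b* with the tie-corrected
    normal approximation; returns ``(U, two-sided p)``."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _pct(x: float | None) -> float | None:
    return None if x is None else round(100 * x, 1)


def metrics_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Diagnostic metrics for every non-reference level of a printed
    class-conditional count table (columns: characteristic, level, reference,
    benign, malignant), using one-vs-rest pooling within characteristic.

    Reference rows are kept with blank metrics, mirroring the benchmark
    table layout.  Percentages are reported at one decimal, AUC at three.
    """
    rows = []
    for char, grp in counts.groupby("characteristic", sort=False):
        ben_total = int(grp["benign"].sum())
        mal_total = int(grp["malignant"].sum())
        for _, r in grp.iterrows():
            if r["reference"]:
                rows.append(
                    {
                        "characteristic": char,
                        "level": r["level"],
                        "benign": int(r["benign"]),
                        "malignant": int(r["malignant"]),
                        "reference": True,
                    }
                )
                continue
            table = ContingencyTable2x2(
                tp=int(r["malignant"]),
                fp=int(r["benign"]),
                fn=mal_total - int(r["malignant"]),
                tn=ben_total - int(r["benign"]),
            )
            m = diagnostic_metrics(table)
            rows.append(
                {
                    "characteristic": char,
                    "level": r["level"],
                    "benign": int(r["benign"]),
                    "malignant": int(r["malignant"]),
                    "reference": False,
                    "npv_pct": _pct(m.npv),
                    "ppv_pct": _pct(m.ppv),
                    "sen_pct": _pct(m.sen),
                    "spe_pct": _pct(m.spe),
                    "auc": round(m.auc, 3),
                    "fisher_p": fisher_exact(table),
                }
            )
    return pd.DataFrame(rows)


def cohort_report(cohort: Cohort) -> pd.DataFrame:
    """Benchmark-style diagnostic report for every categorical characteristic
    level of a cohort (reference rows marked, metrics blank for them)."""
    counts_rows = []
    y = cohort.outcomes().astype(bool)
    for spec in cohort.categorical_specs:
        labels = cohort.levels(spec.name)
        for lv in spec.levels:
            pos = labels == lv
            counts_rows.append(
                {
                    "characteristic": spec.name,
                    "level": lv,
                    "reference": lv == spec.reference,
                    "benign": int(np.sum(pos & ~y)),
                    "malignant": int(np.sum(pos & y)),
                }
            )
    return metrics_from_counts(pd.DataFrame(counts_rows))
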