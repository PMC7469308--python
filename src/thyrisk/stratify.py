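"""Four-level risk stratification of nodules from their risk scores.

The score axis [0, 1] is cut at three points into the categories
benign / low suspicion / intermediate suspicion / high suspicion:

* ``l_c`` — the lower end of the 95% bootstrap-percentile confidence
  interval for the mean of the benign nodules' scores (1000 replications);
* ``0.5`` — the conventional class-probability midpoint;
* ``h_c`` — the score threshold whose ROC point lies closest to the perfect
  corner (0, 1).

Boundaries are left-closed: a score equal to ``l_c``, ``0.5`` or ``h_c``
falls in the higher category.  Each category carries a fixed management
recommendation, from watchful follow-up to biopsy or surgery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import optimal_probability_cutoff

__all__ = [
    "CATEGORIES",
    "MANAGEMENT",
    "Thresholds",
    "bootstrap_lower_limit",
    "derive_thresholds",
    "assign_category",
    "assign_categories",
    "category_report",
]

CATEGORIES = ("benign", "low_suspicion", "intermediate_suspicion", "high_suspicion")

MANAGEMENT = {
    "benign": "After a 6-month sonographic follow-up",
    "low_suspicion": "After 3-month sonographic follow-up or Fine Needle Aspiration (FNA) biopsy",
    "intermediate_suspicion": "FNA biopsy",
    "high_suspicion": "FNA biopsy or surgical treatment",
}


@dataclass
class Thresholds:
    """The category boundaries l_c < 0.5 < h_c, with provenance."""

    l_c: float
    h_c: float
    mid: float = 0.5
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.l_c < self.mid < self.h_c <= 1:
            raise ValueError(
                f"thresholds must satisfy 0 <= l_c < {self.mid} < h_c <= 1; "
                f"got l_c={self.l_c:.4f}, h_c={self.h_c:.4f}"
            )


def bootstrap_lower_limit(scores, B: int = 1000, level: float = 0.95, seed: int = 0) -> float:
    """Percentile-bootstrap lower confidence limit for the mean of *scores*:
    the (1-level)/2 quantile of *B* bootstrap resample means."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 10:
        raise ValueError("bootstrap_lower_limit needs at least 10 scores")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(scores), size=(B, len(scores)))
    means = scores[idx].mean(axis=1)
    return float(np.percentile(means, 100 * (1 - level) / 2))


def derive_thresholds(
    scores,
    labels,
    benign_only: bool = True,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> Thresholds:
    """Derive l_c (bootstrap lower limit of the mean score, by default over
    the benign nodules only) and h_c (closest-to-(0,1) ROC cutoff), and
    validate the ordering l_c < 0.5 < h_c."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes required to derive thresholds")
    pool = scores[labels == 0] if benign_only else scores
    l_c = bootstrap_lower_limit(pool, B=B, level=level, seed=seed)
    h_c = optimal_probability_cutoff(scores, labels)
    return Thresholds(
        l_c=l_c,
        h_c=h_c,
        provenance={
            "bootstrap_replications": B,
            "confidence_level": level,
            "benign_only": benign_only,
            "seed": seed,
            "n_scores": int(len(pool)),
        },
    )


def assign_category(score: float, thresholds: Thresholds) -> str:
    """Category of one score under left-closed boundaries."""
    if not 0 <= score <= 1:
        raise ValueError(f"score {score} outside [0, 1]")
    if score < thresholds.l_c:
        return "benign"
    if score < thresholds.mid:
        return "low_suspicion"
    if score < thresholds.h_c:
        return "intermediate_suspicion"
    return "high_suspicion"


def assign_categories(scores, thresholds: Thresholds) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores outside [0, 1]")
    out = np.full(scores.shape, "high_suspicion", dtype=object)
    out[scores < thresholds.h_c] = "intermediate_suspicion"
    out[scores < thresholds.mid] = "low_suspicion"
    out[scores < thresholds.l_c] = "benign"
    return out


def category_report(scores, labels, thresholds: Thresholds) -> pd.DataFrame:
    """Counts, malignancy rate and management recommendation per category."""
    labels = np.asarray(labels).astype(int)
    cats = assign_categories(scores, thresholds)
    rows = []
    for cat in CATEGORIES:
        mask = cats == cat
        n = int(mask.sum())
        n_mal = int(labels[mask].sum())
        rows.append(
            {
                "category": cat,
                "benign": n - n_mal,
                "malignant": n_mal,
                "n": n,
                "malignancy_rate": n_mal / n if n else np.nan,
                "management": MANAGEMENT[cat],
            }
        )
    return pd.DataFrame(rows)
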