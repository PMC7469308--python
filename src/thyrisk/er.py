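"""Echogenicity-ratio (ER) dichotomization and the AUC-maximizing cutoff scan.

The ER is the nodule's echogenicity divided by that of the anterior cervical
muscles; a nodule is read as hypoechoic when its ER falls at or below a
cutoff.  The best cutoff is found by scanning every observed ER value in
[0, 5] and keeping the one whose hypoechoic indicator maximizes the
dichotomous AUC = (SEN + SPE) / 2 for malignancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .diagnostics import ContingencyTable2x2, DiagnosticMetrics, diagnostic_metrics

__all__ = ["ERCutoffProfile", "dichotomize_er", "er_profile", "optimal_er_cutoff"]

DEFAULT_RANGE = (0.0, 5.0)


def dichotomize_er(er: float, cutoff: float) -> str:
    """``"hypoechoic"`` iff er <= cutoff, else ``"hyperechoic"``."""
    if not er > 0:
        raise ValueError("er must be positive")
    return "hypoechoic" if er <= cutoff else "hyperechoic"


@dataclass
class ERCutoffProfile:
    """Per-cutoff diagnostic metrics and malignancy rates on either side."""

    table: pd.DataFrame  # cutoff, sen, spe, ppv, npv, auc, rate_hypo, rate_hyper

    def __post_init__(self) -> None:
        cutoffs = self.table["cutoff"].to_numpy()
        if len(cutoffs) == 0:
            raise ValueError("empty cutoff profile")
        if not np.all(np.diff(cutoffs) > 0):
            raise ValueError("cutoffs must be strictly increasing")

    def __len__(self) -> int:
        return len(self.table)


def er_profile(
    cohort: Cohort,
    grid=None,
    er_range: tuple[float, float] = DEFAULT_RANGE,
    step: float | None = None,
) -> ERCutoffProfile:
    """Scan cutoffs and compute the hypoechoic indicator's metrics at each.

    The default grid is the sorted unique observed ER values clipped to
    ``er_range``; pass ``step`` (e.g. 0.1) for a fixed-step grid instead, or
    ``grid`` for an explicit one.
    """
    er = cohort.continuous("er")
    y = cohort.outcomes()
    if y.min() == y.max():
        raise ValueError("er_profile requires both outcomes present")
    lo, hi = er_range
    if grid is None:
        if step is not None:
            grid = np.arange(lo, hi + step / 2, step)
        else:
            grid = np.unique(er)
            grid = grid[(grid >= lo) & (grid <= hi)]
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("no cutoffs remain after clipping to the ER range")
    rows = []
    n1 = int(y.sum())
    n0 = len(y) - n1
    for c in np.sort(np.unique(grid)):
        hypo = er <= c
        table = ContingencyTable2x2(
            tp=int(np.sum(hypo & (y == 1))),
            fp=int(np.sum(hypo & (y == 0))),
            fn=int(np.sum(~hypo & (y == 1))),
            tn=int(np.sum(~hypo & (y == 0))),
        )
        m = diagnostic_metrics(table)
        n_hypo = table.tp + table.fp
        n_hyper = table.fn + table.tn
        rows.append(
            {
                "cutoff": c,
                "sen": m.sen,
                "spe": m.spe,
                "ppv": m.ppv,
                "npv": m.npv,
                "auc": m.auc,
                "rate_hypo": table.tp / n_hypo if n_hypo else np.nan,
                "rate_hyper": table.fn / n_hyper if n_hyper else np.nan,
            }
        )
    return ERCutoffProfile(pd.DataFrame(rows))


def optimal_er_cutoff(profile: ERCutoffProfile) -> tuple[float, DiagnosticMetrics]:
    """Cutoff with the maximal AUC; ties resolve to the smallest cutoff."""
    t = profile.table
    best = int(np.argmax(t["auc"].to_numpy()))  # argmax takes the first maximum
    row = t.iloc[best]
    metrics = DiagnosticMetrics(
        sen=float(row["sen"]),
        spe=float(row["spe"]),
        ppv=None if pd.isna(row["ppv"]) else float(row["ppv"]),
        npv=None if pd.isna(row["npv"]) else float(row["npv"]),
        auc=float(row["auc"]),
    )
    return float(row["cutoff"]), metrics
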