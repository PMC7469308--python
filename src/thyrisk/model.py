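"""The end-to-end risk model: selection -> scoring -> stratification.

`NoduleRiskModel` bundles the whole pipeline behind a statsmodels-style
interface: build it from a cohort (or a DataFrame plus schema), call
``fit(seed)``, and read the estimates off the returned
:class:`NoduleRiskResults` — selected characteristics with their selection
frequencies, repetition-averaged risk scores, the category thresholds
(l_c, 0.5, h_c), repetition-averaged classification metrics per split, and
the four-category reports for the train+validate and test sets.

All randomness flows from the single ``seed`` passed to ``fit`` through
per-stage derived seeds, recorded in the results' provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, stratified_split
from .scoring import (
    ClassifierSpec,
    MetricSummary,
    RiskScoreTable,
    classifier_metrics,
    ensemble_risk_scores,
    optimal_probability_cutoff,
    summarize_over_repetitions,
)
from .selection import SelectionSummary, repeated_selection
from .stratify import Thresholds, category_report, derive_thresholds

__all__ = ["NoduleRiskModel", "NoduleRiskResults"]


class NoduleRiskModel:
    """Malignancy risk-scoring model for a thyroid-nodule cohort.

    Parameters
    ----------
    cohort
        The nodules with their characteristics and surgical outcomes.
    classifier
        Backend used for scoring (default: random forest with 500 trees,
        2 candidate features per split).
    features
        Characteristic names to score on.  ``None`` runs the repeated
        LASSO-logistic selection first.
    selection_repetitions, scoring_repetitions
        Number of random 60/20/20 splits in the selection and scoring
        stages (the study design uses 100 for both).
    retention_threshold
        Minimum selection frequency for a characteristic to be retained.
    bootstrap_replications, confidence_level
        Bootstrap settings behind the lower category boundary l_c.
    """

    def __init__(
        self,
        cohort: Cohort,
        classifier: ClassifierSpec | None = None,
        features: list[str] | None = None,
        proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
        selection_repetitions: int = 100,
        scoring_repetitions: int = 100,
        retention_threshold: float = 0.5,
        bootstrap_replications: int = 1000,
        confidence_level: float = 0.95,
        scoring_mode: str = "out_of_split",
        benign_only_lower: bool = True,
    ):
        self.cohort = cohort
        self.classifier = classifier or ClassifierSpec()
        self.features = features
        self.proportions = proportions
        self.selection_repetitions = selection_repetitions
        self.scoring_repetitions = scoring_repetitions
        self.retention_threshold = retention_threshold
        self.bootstrap_replications = bootstrap_replications
        self.confidence_level = confidence_level
        self.scoring_mode = scoring_mode
        self.benign_only_lower = benign_only_lower

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, schema, **kwargs) -> "NoduleRiskModel":
        return cls(Cohort.from_frame(frame, schema), **kwargs)

    def fit(self, seed: int = 0) -> "NoduleRiskResults":
        rng = np.random.default_rng(seed)
        stage_seeds = {
            stage: int(s)
            for stage, s in zip(
                ("selection", "scoring", "reference_split", "bootstrap"),
                rng.integers(0, 2**31 - 1, size=4),
            )
        }
        selection = None
        features = self.features
        if features is None:
            selection = repeated_selection(
                self.cohort,
                R=self.selection_repetitions,
                retention_threshold=self.retention_threshold,
                seed=stage_seeds["selection"],
                proportions=self.proportions,
            )
            features = selection.retained
        score_table = ensemble_risk_scores(
            self.cohort,
            self.classifier,
            features,
            R=self.scoring_repetitions,
            seed=stage_seeds["scoring"],
            proportions=self.proportions,
            mode=self.scoring_mode,
        )
        y = score_table.y
        # frozen reference split: thresholds come from train+validate only
        ref = stratified_split(self.cohort, self.proportions, seed=stage_seeds["reference_split"])
        dev_mask = ref != "test"
        thresholds = derive_thresholds(
            score_table.scores[dev_mask],
            y[dev_mask],
            benign_only=self.benign_only_lower,
            B=self.bootstrap_replications,
            level=self.confidence_level,
            seed=stage_seeds["bootstrap"],
        )
        metrics = self._repetition_metrics(score_table)
        reports = {
            "train+validate": category_report(
                score_table.scores[dev_mask], y[dev_mask], thresholds
            ),
            "test": category_report(score_table.scores[~dev_mask], y[~dev_mask], thresholds),
        }
        return NoduleRiskResults(
            model=self,
            seed=seed,
            stage_seeds=stage_seeds,
            selection=selection,
            features=list(features),
            score_table=score_table,
            thresholds=thresholds,
            metrics=metrics,
            category_reports=reports,
            reference_partition=ref,
        )

    def _repetition_metrics(self, table: RiskScoreTable) -> dict[str, MetricSummary]:
        """Per-repetition metrics: the probability cutoff is derived on each
        repetition's validation split, then applied to validation and test."""
        per_split: dict[str, list] = {"validate": [], "test": []}
        y = table.y
        for r in range(table.probabilities.shape[0]):
            probs = table.probabilities[r]
            parts = table.partitions[r]
            val = parts == "validate"
            cutoff = optimal_probability_cutoff(probs[val], y[val])
            for split in ("validate", "test"):
                mask = parts == split
                per_split[split].append(classifier_metrics(probs[mask], y[mask], cutoff))
        return {split: summarize_over_repetitions(ms) for split, ms in per_split.items()}


@dataclass
class NoduleRiskResults:
    """Fit artefacts of :class:`NoduleRiskModel`."""

    model: NoduleRiskModel
    seed: int
    stage_seeds: dict[str, int]
    selection: SelectionSummary | None
    features: list[str]
    score_table: RiskScoreTable
    thresholds: Thresholds
    metrics: dict[str, MetricSummary]
    category_reports: dict[str, pd.DataFrame]
    reference_partition: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        lines = []
        n = len(self.score_table.scores)
        n_mal = int(self.score_table.y.sum())
        lines.append("Thyroid nodule malignancy risk model")
        lines.append("=" * 60)
        lines.append(f"Nodules: {n} ({n_mal} malignant, {n - n_mal} benign)")
        lines.append(
            f"Classifier: {self.model.classifier.name}  "
            f"repetitions: {self.score_table.probabilities.shape[0]}  seed: {self.seed}"
        )
        lines.append(f"Selected characteristics ({len(self.features)}):")
        if self.selection is not None:
            freq = self.selection.frequency
            for name in sorted(self.features, key=lambda f: -freq.get(f, 0)):
                lines.append(f"  {name:<16s} selection frequency {freq.get(name, 1.0):.2f}")
        else:
            for name in self.features:
                lines.append(f"  {name}")
        lines.append(
            f"Thresholds: l_c = {self.thresholds.l_c:.3f}, mid = 0.5, "
            f"h_c = {self.thresholds.h_c:.3f}"
        )
        for split, ms in self.metrics.items():
            vals = "  ".join(f"{k.upper()} {v:.3f}" for k, v in ms.means.items())
            lines.append(f"Metrics [{split}]: {vals}")
        for name, rep in self.category_reports.items():
            lines.append(f"Risk categories [{name}]:")
            for _, row in rep.iterrows():
                rate = row["malignancy_rate"]
                rate_s = "   --" if pd.isna(rate) else f"{100 * rate:5.1f}%"
                lines.append(
                    f"  {row['category']:<24s} benign {row['benign']:>5d}  "
                    f"malignant {row['malignant']:>5d}  malignancy {rate_s}"
                )
        return "\n".join(lines)

    def export(self, outdir) -> None:
        """Write all artefacts (CSV/JSON) under *outdir*."""
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.score_table.to_frame().to_csv(out / "risk_scores.csv", index=False)
        for name, rep in self.category_reports.items():
            rep.to_csv(out / f"categories_{name.replace('+', '_')}.csv", index=False)
        metrics = pd.DataFrame({split: ms.means for split, ms in self.metrics.items()})
        metrics.to_csv(out / "metric_summary.csv")
        if self.selection is not None:
            pd.DataFrame(
                {
                    "characteristic": list(self.selection.frequency),
                    "frequency": list(self.selection.frequency.values()),
                    "retained": [
                        name in self.selection.retained for name in self.selection.frequency
                    ],
                }
            ).to_csv(out / "selection_summary.csv", index=False)
            with open(out / "selection_repetitions.jsonl", "w") as fh:
                for entry in self.selection.per_repetition:
                    fh.write(json.dumps(entry) + "\n")
        provenance = {
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "classifier": self.model.classifier.name,
            "hyperparameters": self.model.classifier.hyperparameters,
            "features": self.features,
            "thresholds": {
                "l_c": self.thresholds.l_c,
                "mid": self.thresholds.mid,
                "h_c": self.thresholds.h_c,
                **self.thresholds.provenance,
            },
            "scoring_mode": self.score_table.mode,
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
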