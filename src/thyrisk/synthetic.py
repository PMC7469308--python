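"""Synthetic cohort generator calibrated to the published study marginals.

The raw per-nodule data behind the study are unavailable, so this module
fabricates cohorts with the same statistical skeleton: outcome prevalence
1200/1448, class-conditional level frequencies of every ultrasonographic
characteristic taken from the published counts, truncated-normal ages with
the printed per-class moments, and a log-normal echogenicity ratio (ER)
whose per-class location is pinned by the printed exceedance probabilities
P(ER <= 1.3 | malignant) = 0.767 and P(ER <= 1.3 | benign) = 0.472.

Characteristics are drawn independently given the outcome (class-conditional
independence): only marginals are published, so no dependence structure is
recoverable.  Echogenicity is *derived* by dichotomizing the simulated ER at
the calibration cutoff rather than drawn separately, which keeps the
categorical marginal and the continuous calibration automatically
consistent.  Nodule size is pure invention (log-normal, median 10 mm), as no
size distribution was published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .cohort import CharacteristicSpec, Cohort, NoduleRecord

__all__ = ["GeneratorConfig", "default_config", "abnormal_config", "generate_cohort", "marginal_report"]

ER_CUTOFF = 1.3
ER_EXCEEDANCE = {"malignant": 0.767, "benign": 0.472}


@dataclass
class GeneratorConfig:
    """Full description of the generative model for one cohort."""

    n: int
    prevalence: float
    # characteristic -> outcome -> {level: probability}
    conditional_probs: dict[str, dict[str, dict[str, float]]]
    # outcome -> (log-location mu, log-scale sigma) of the log-normal ER
    er_model: dict[str, tuple[float, float]]
    # outcome -> (mean, sd) in years, truncated to age_range
    age_model: dict[str, tuple[float, float]]
    age_range: tuple[float, float] = (10.0, 80.0)
    # outcome -> (log-median, log-sd) of the log-normal size in mm; the
    # medians differ so size carries signal, as the cohort's rank test found
    size_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "benign": (np.log(10.0), 0.6),
            "malignant": (np.log(12.5), 0.6),
        }
    )
    er_cutoff: float = ER_CUTOFF
    p_female: float = 0.79
    paired_patient_fraction: float = 78 / 1448  # nodules sharing a patient
    group: str = "disease"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            if self.prevalence not in (0.0, 1.0):  # degenerate allowed explicitly
                raise ValueError("prevalence must lie in [0, 1]")
        for char, per_outcome in self.conditional_probs.items():
            for outcome, probs in per_outcome.items():
                total = sum(probs.values())
                if not np.isclose(total, 1.0, atol=1e-8):
                    raise ValueError(
                        f"{char}/{outcome}: level probabilities sum to {total}, not 1"
                    )

    def schema(self) -> list[CharacteristicSpec]:
        """Schema implied by the config: one categorical spec per configured
        characteristic (reference = level with the lowest implied malignancy
        rate) plus derived echogenicity and the continuous size and age."""
        prev = self.prevalence
        specs = []
        for char, per_outcome in self.conditional_probs.items():
            levels = tuple(per_outcome["malignant"])
            rates = {}
            for lv in levels:
                pm = prev * per_outcome["malignant"][lv]
                pb = (1 - prev) * per_outcome["benign"][lv]
                rates[lv] = pm / (pm + pb) if pm + pb > 0 else 0.0
            reference = min(levels, key=lambda lv: rates[lv])
            specs.append(
                CharacteristicSpec(
                    name=char, kind="categorical", levels=levels, reference=reference
                )
            )
        # echogenicity derives from the ER model; the hypoechoic exceedances
        # decide which side carries the lower malignancy rate
        p_hypo = {
            cls: stats.norm.cdf((np.log(self.er_cutoff) - mu) / sigma)
            for cls, (mu, sigma) in self.er_model.items()
        }
        rate_hypo = prev * p_hypo["malignant"] / (
            prev * p_hypo["malignant"] + (1 - prev) * p_hypo["benign"]
        )
        rate_hyper = prev * (1 - p_hypo["malignant"]) / (
            prev * (1 - p_hypo["malignant"]) + (1 - prev) * (1 - p_hypo["benign"])
        )
        specs.append(
            CharacteristicSpec(
                name="echogenicity",
                kind="categorical",
                levels=("hypoechoic", "hyperechoic"),
                reference="hypoechoic" if rate_hypo < rate_hyper else "hyperechoic",
            )
        )
        specs.append(CharacteristicSpec(name="size", kind="continuous"))
        specs.append(CharacteristicSpec(name="age", kind="continuous"))
        return specs


def _er_params(sigma: float) -> dict[str, tuple[float, float]]:
    """Log-normal locations solving P(ER <= cutoff | class) = target for a
    given log-scale sigma (one free parameter per class)."""
    out = {}
    for outcome, target in ER_EXCEEDANCE.items():
        mu = np.log(ER_CUTOFF) - sigma * stats.norm.ppf(target)
        out[outcome] = (float(mu), float(sigma))
    return out


def default_config(n: int = 1448, seed: int = 0, er_sigma: float = 0.5) -> GeneratorConfig:
    """The study conditions: prevalence 1200/1448, published class-conditional
    level frequencies, printed age moments, calibrated ER model."""
    counts = datasets.characteristic_counts("disease")
    totals = datasets.DISEASE_TOTALS
    conditional: dict[str, dict[str, dict[str, float]]] = {}
    for char, grp in counts.groupby("characteristic", sort=False):
        if char == "echogenicity":
            continue  # derived from the continuous ER, not drawn
        conditional[char] = {
            outcome: {
                str(r["level"]): float(r[outcome]) / totals[outcome]
                for _, r in grp.iterrows()
            }
            for outcome in ("benign", "malignant")
        }
    return GeneratorConfig(
        n=n,
        prevalence=1200 / 1448,
        conditional_probs=conditional,
        er_model=_er_params(er_sigma),
        age_model={"benign": (57.2, 10.7), "malignant": (43.1, 11.4)},
        seed=seed,
    )


def abnormal_config(n: int = 110, seed: int = 0) -> GeneratorConfig:
    """Preset emulating the adversarial "abnormal" nodules: the strong
    malignancy signs have their class-conditional frequencies swapped, so the
    usual visual reading points the wrong way."""
    cfg = default_config(n=n, seed=seed)
    inverted = {}
    for char, per_outcome in cfg.conditional_probs.items():
        if char in ("shape", "hackly_border", "component", "calcification", "margin"):
            inverted[char] = {
                "benign": per_outcome["malignant"],
                "malignant": per_outcome["benign"],
            }
        else:
            inverted[char] = per_outcome
    return replace(
        cfg,
        conditional_probs=inverted,
        prevalence=11 / 110,
        er_model={"benign": cfg.er_model["malignant"], "malignant": cfg.er_model["benign"]},
        group="abnormal",
    )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort from *config*; byte-identical output for a given seed."""
    if config.n < 20:
        raise ValueError("n must be >= 20 (smaller cohorts break the splits downstream)")
    rng = np.random.default_rng(config.seed)
    n = config.n
    y = rng.random(n) < config.prevalence
    outcome = np.where(y, "malignant", "benign")

    levels: dict[str, np.ndarray] = {}
    for char, per_outcome in config.conditional_probs.items():
        col = np.empty(n, dtype=object)
        for cls in ("benign", "malignant"):
            mask = outcome == cls
            if not mask.any():
                continue
            labels = list(per_outcome[cls])
            probs = np.array([per_outcome[cls][lv] for lv in labels])
            col[mask] = rng.choice(labels, size=int(mask.sum()), p=probs / probs.sum())
        levels[char] = col

    er = np.empty(n)
    age = np.empty(n)
    size = np.empty(n)
    for cls in ("benign", "malignant"):
        mask = outcome == cls
        k = int(mask.sum())
        if k == 0:
            continue
        mu, sigma = config.er_model[cls]
        er[mask] = np.exp(rng.normal(mu, sigma, size=k))
        mean, sd = config.age_model[cls]
        age[mask] = _truncnorm(rng, mean, sd, *config.age_range, size=k)
        smu, ssd = config.size_model[cls]
        size[mask] = np.exp(rng.normal(smu, ssd, size=k))
    levels["echogenicity"] = np.where(er <= config.er_cutoff, "hypoechoic", "hyperechoic")

    sex = np.where(rng.random(n) < config.p_female, "female", "male")
    patient_ids = [f"P{i:05d}" for i in range(n)]
    n_pairs = int(round(config.paired_patient_fraction * n / 2))
    if n_pairs > 0 and n >= 2 * n_pairs:
        paired = rng.choice(n, size=2 * n_pairs, replace=False)
        for a, b in paired.reshape(-1, 2):
            patient_ids[b] = patient_ids[a]

    records = [
        NoduleRecord(
            nodule_id=f"N{i:05d}",
            patient_id=patient_ids[i],
            sex=str(sex[i]),
            age=float(age[i]),
            size=float(size[i]),
            er=float(er[i]),
            characteristics={char: str(levels[char][i]) for char in levels},
            outcome=str(outcome[i]),
            group=config.group,
        )
        for i in range(n)
    ]
    return Cohort(config.schema(), records)


def marginal_report(cohort: Cohort, config: GeneratorConfig) -> pd.DataFrame:
    """Absolute deviation of every empirical class-conditional level
    frequency from its configured target; one row per
    (characteristic, level, outcome)."""
    schema_names = {s.name for s in cohort.schema}
    missing = set(config.conditional_probs) - schema_names
    if missing:
        raise ValueError(f"cohort schema lacks configured characteristics: {sorted(missing)}")
    y = cohort.outcomes().astype(bool)
    rows = []
    for char, per_outcome in config.conditional_probs.items():
        labels = cohort.levels(char)
        for cls, mask in (("benign", ~y), ("malignant", y)):
            denom = int(mask.sum())
            for lv, target in per_outcome[cls].items():
                empirical = float(np.sum((labels == lv) & mask)) / denom if denom else np.nan
                rows.append(
                    {
                        "characteristic": char,
                        "level": lv,
                        "outcome": cls,
                        "target": target,
                        "empirical": empirical,
                        "deviation": abs(empirical - target),
                    }
                )
    return pd.DataFrame(rows)
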