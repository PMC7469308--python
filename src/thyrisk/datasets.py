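"""Benchmark tables from the published thyroid-nodule cohort this package models.

The source study reports, for 1448 surgically confirmed "disease" nodules
(248 benign / 1200 malignant) and for the 1558-nodule "overall" set that adds
110 adversarial ("abnormal") nodules, the class-conditional counts of every
ultrasonographic characteristic level, plus the benchmark performance of ten
classifiers.  The raw per-nodule data are not publicly deposited, so these
printed marginals are the calibration targets for the synthetic generator
and the ground truth for the diagnostics benchmarks.
"""

from __future__ import annotations

import pandas as pd

from .cohort import CharacteristicSpec

__all__ = [
    "study_schema",
    "characteristic_counts",
    "classifier_performance",
    "DISEASE_TOTALS",
    "OVERALL_TOTALS",
]

DISEASE_TOTALS = {"benign": 248, "malignant": 1200}
OVERALL_TOTALS = {"benign": 347, "malignant": 1211}

# (characteristic, level, is_reference, benign count, malignant count)
_DISEASE_COUNTS = [
    ("shape", "AP/T>=1", False, 34, 684),
    ("shape", "AP/T<1", True, 214, 516),
    ("margin", "regular", True, 174, 180),
    ("margin", "irregular", False, 74, 1020),
    ("border", "unclear", False, 55, 819),
    ("border", "clear", True, 193, 381),
    ("hackly_border", "present", False, 22, 744),
    ("hackly_border", "absent", True, 226, 456),
    ("component", "solid", False, 108, 1157),
    ("component", "mixed", True, 140, 43),
    ("calcification", "macro", False, 30, 137),
    ("calcification", "micro", False, 78, 711),
    ("calcification", "none", True, 140, 352),
    ("halo", "present", False, 209, 1123),
    ("halo", "absent", True, 39, 77),
    ("attenuation", "present", False, 12, 208),
    ("attenuation", "absent", True, 236, 992),
    ("lateral_shadow", "present", False, 5, 52),
    ("lateral_shadow", "absent", True, 243, 1148),
    ("blood_flow", "low", False, 49, 417),
    ("blood_flow", "medium", True, 116, 396),
    ("blood_flow", "high", False, 83, 387),
    ("vascularity", "peripheral", True, 78, 250),
    ("vascularity", "mixed", False, 69, 228),
    ("vascularity", "central", False, 101, 722),
    ("echogenicity", "hypoechoic", False, 117, 920),
    ("echogenicity", "hyperechoic", True, 131, 280),
]

_OVERALL_COUNTS = [
    ("shape", "AP/T>=1", False, 89, 685),
    ("shape", "AP/T<1", True, 258, 526),
    ("margin", "regular", True, 180, 189),
    ("margin", "irregular", False, 167, 1022),
    ("border", "unclear", False, 137, 820),
    ("border", "clear", True, 210, 391),
    ("hackly_border", "present", False, 91, 745),
    ("hackly_border", "absent", True, 256, 466),
    ("component", "solid", False, 207, 1158),
    ("component", "mixed", True, 140, 53),
    ("calcification", "macro", False, 46, 137),
    ("calcification", "micro", False, 139, 712),
    ("calcification", "none", True, 162, 362),
    ("halo", "present", False, 303, 1132),
    ("halo", "absent", True, 44, 79),
    ("attenuation", "present", False, 33, 208),
    ("attenuation", "absent", True, 314, 1003),
    ("lateral_shadow", "present", False, 9, 52),
    ("lateral_shadow", "absent", True, 338, 1159),
    ("blood_flow", "low", False, 80, 417),
    ("blood_flow", "medium", True, 152, 402),
    ("blood_flow", "high", False, 115, 392),
    ("vascularity", "peripheral", True, 103, 255),
    ("vascularity", "mixed", False, 88, 231),
    ("vascularity", "central", False, 156, 725),
    ("echogenicity", "hypoechoic", False, 198, 925),
    ("echogenicity", "hyperechoic", True, 149, 286),
]

# (classifier, split, auc, sen, f1, spe, ppv, npv) for the disease cohort
# ("validating"/"testing") and the overall cohort ("overall_validating").
_CLASSIFIER_PERFORMANCE = [
    ("RF", "validating", 0.960, 0.892, 0.701, 0.820, 0.960, 0.612),
    ("RF", "testing", 0.958, 0.883, 0.721, 0.880, 0.972, 0.611),
    ("LR", "validating", 0.965, 0.875, 0.720, 0.900, 0.977, 0.600),
    ("LR", "testing", 0.965, 0.875, 0.720, 0.900, 0.977, 0.600),
    ("SVM", "validating", 0.952, 0.862, 0.713, 0.920, 0.981, 0.582),
    ("SVM", "testing", 0.962, 0.896, 0.740, 0.900, 0.977, 0.643),
    ("NET", "validating", 0.965, 0.879, 0.726, 0.900, 0.977, 0.608),
    ("NET", "testing", 0.964, 0.879, 0.746, 0.920, 0.981, 0.613),
    ("ELM", "validating", 0.952, 0.833, 0.657, 0.880, 0.971, 0.524),
    ("ELM", "testing", 0.952, 0.833, 0.657, 0.880, 0.971, 0.524),
    ("KNN", "validating", 0.926, 0.825, 0.657, 0.900, 0.975, 0.517),
    ("KNN", "testing", 0.926, 0.825, 0.657, 0.900, 0.975, 0.517),
    ("NB", "validating", 0.940, 0.871, 0.672, 0.820, 0.959, 0.569),
    ("NB", "testing", 0.940, 0.871, 0.672, 0.820, 0.959, 0.569),
    ("ADAB", "validating", 0.955, 0.891, 0.733, 0.880, 0.973, 0.629),
    ("ADAB", "testing", 0.958, 0.855, 0.712, 0.940, 0.985, 0.574),
    ("LOG", "validating", 0.964, 0.846, 0.711, 0.960, 0.970, 0.565),
    ("LOG", "testing", 0.956, 0.846, 0.711, 0.960, 0.970, 0.565),
    ("LDA", "validating", 0.954, 0.850, 0.687, 0.900, 0.976, 0.556),
    ("LDA", "testing", 0.954, 0.850, 0.687, 0.900, 0.976, 0.556),
    ("RF", "overall_validating", 0.798, 0.822, 0.588, 0.672, 0.896, 0.522),
    ("LR", "overall_validating", 0.820, 0.810, 0.611, 0.729, 0.912, 0.526),
    ("SVM", "overall_validating", 0.781, 0.777, 0.558, 0.685, 0.895, 0.470),
    ("NET", "overall_validating", 0.818, 0.789, 0.601, 0.743, 0.914, 0.505),
    ("ELM", "overall_validating", 0.811, 0.806, 0.573, 0.671, 0.894, 0.500),
    ("KNN", "overall_validating", 0.738, 0.707, 0.492, 0.657, 0.877, 0.393),
    ("NB", "overall_validating", 0.796, 0.851, 0.587, 0.629, 0.888, 0.550),
    ("ADAB", "overall_validating", 0.748, 0.777, 0.506, 0.599, 0.870, 0.437),
    ("LOG", "overall_validating", 0.811, 0.810, 0.610, 0.729, 0.912, 0.526),
    ("LDA", "overall_validating", 0.820, 0.793, 0.588, 0.714, 0.906, 0.500),
]


def study_schema() -> list[CharacteristicSpec]:
    """The study's characteristic schema: 12 categorical ultrasonographic
    characteristics (reference = lowest-malignancy-rate level) plus nodule
    size and patient age as continuous predictors."""
    specs: list[CharacteristicSpec] = []
    seen: dict[str, dict] = {}
    for char, level, ref, _, _ in _DISEASE_COUNTS:
        entry = seen.setdefault(char, {"levels": [], "reference": None})
        entry["levels"].append(level)
        if ref:
            entry["reference"] = level
    for char, entry in seen.items():
        specs.append(
            CharacteristicSpec(
                name=char,
                kind="categorical",
                levels=tuple(entry["levels"]),
                reference=entry["reference"],
            )
        )
    specs.append(CharacteristicSpec(name="size", kind="continuous"))
    specs.append(CharacteristicSpec(name="age", kind="continuous"))
    return specs


def characteristic_counts(cohort: str = "disease") -> pd.DataFrame:
    """Class-conditional level counts of every characteristic.

    Parameters
    ----------
    cohort
        ``"disease"`` (1448 nodules) or ``"overall"`` (1558 nodules,
        including the 110 abnormal ones).
    """
    if cohort == "disease":
        raw = _DISEASE_COUNTS
    elif cohort == "overall":
        raw = _OVERALL_COUNTS
    else:
        raise ValueError("cohort must be 'disease' or 'overall'")
    return pd.DataFrame(
        raw, columns=["characteristic", "level", "reference", "benign", "malignant"]
    )


def classifier_performance() -> pd.DataFrame:
    """Benchmark repetition-averaged metrics of the ten classifiers."""
    return pd.DataFrame(
        _CLASSIFIER_PERFORMANCE,
        columns=["classifier", "split", "auc", "sen", "f1", "spe", "ppv", "npv"],
    )
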