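"""Dependent variables and experience-group classification.

Builds the tables the study's statistical models consume: per-trial looking
totals to the upper and lower face halves, per-subject condition-level
lower-half preference proportions, and the long fixation table (fixation
index, duration, AOI, condition, covariates). Model fitting itself (ANOVA,
linear/logistic mixed models) is deliberately not part of this package.

Also implements the three experience groupings of the cohort:
mother's race (White / Asian American / Other), diversity of face-race
experience (low / medium / high), and language exposure (monolingual English /
multilingual / other-monolingual / unreported).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import CONDITIONS
from .errors import DataError

TRIAL_KEYS = ["subject_id", "trial_number"]


# ---------------------------------------------------------------------------
# Trial- and condition-level DVs
# ---------------------------------------------------------------------------

def trial_totals(fixations: pd.DataFrame) -> pd.DataFrame:
    """Per-trial looking totals by AOI from a (kept) fixation table.

    One row per trial: subject_id, trial_number, face_race, speech_type,
    looking_upper_ms, looking_lower_ms, proportion_lower. Fixations labelled
    ``none`` count toward neither total; a trial with no in-AOI fixation time
    has an undefined (NaN) proportion.
    """
    if len(fixations) == 0:
        return pd.DataFrame(
            columns=TRIAL_KEYS
            + ["face_race", "speech_type", "looking_upper_ms", "looking_lower_ms", "proportion_lower"]
        )
    base = fixations.groupby(TRIAL_KEYS, sort=True).agg(
        face_race=("face_race", "first"), speech_type=("speech_type", "first")
    )
    for region in ("upper", "lower"):
        sub = fixations[fixations["aoi"] == region]
        base[f"looking_{region}_ms"] = sub.groupby(TRIAL_KEYS)["duration_ms"].sum()
    base = base.fillna({"looking_upper_ms": 0.0, "looking_lower_ms": 0.0}).reset_index()
    denom = base["looking_upper_ms"] + base["looking_lower_ms"]
    with np.errstate(invalid="ignore", divide="ignore"):
        base["proportion_lower"] = np.where(
            denom > 0, base["looking_lower_ms"] / denom, np.nan
        )
    return base


def condition_preference(trial_dvs: pd.DataFrame, method: str = "pooled") -> pd.DataFrame:
    """Per-subject, per-condition lower-half preference.

    ``method="pooled"`` (default) pools duration across the condition's
    trials: sum(lower) / (sum(lower) + sum(upper)); ``method="mean"`` averages
    the per-trial proportions instead. Output has one row per subject x
    condition present in the data, plus an ``all_conditions`` flag marking
    subjects with data in all four stimulus conditions (only those are
    eligible for condition-level analyses).
    """
    if method not in ("pooled", "mean"):
        raise DataError(f"unknown pooling method {method!r}")
    g = trial_dvs.groupby(["subject_id", "face_race", "speech_type"], sort=True)
    if method == "pooled":
        agg = g[["looking_lower_ms", "looking_upper_ms"]].sum()
        denom = agg["looking_lower_ms"] + agg["looking_upper_ms"]
        with np.errstate(invalid="ignore", divide="ignore"):
            agg["proportion_lower"] = np.where(
                denom > 0, agg["looking_lower_ms"] / denom, np.nan
            )
        out = agg.reset_index()
    else:
        out = g["proportion_lower"].mean().reset_index()
        sums = g[["looking_lower_ms", "looking_upper_ms"]].sum().reset_index(drop=True)
        out[["looking_lower_ms", "looking_upper_ms"]] = sums
    out["n_trials"] = g.size().to_numpy()
    counts = out.groupby("subject_id")[["face_race"]].size()
    complete = set(counts[counts >= len(CONDITIONS)].index)
    out["all_conditions"] = out["subject_id"].isin(complete)
    return out


def fixation_table(fixations: pd.DataFrame, subjects: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Long fixation table, one row per fixation on kept trials, carrying the
    within-trial fixation index, condition, and subject covariates — the exact
    input for fixation-level mixed models (fit externally)."""
    out = fixations.copy()
    if subjects is not None:
        cov_cols = [c for c in subjects.columns if c != "subject_id"]
        out = out.merge(subjects[["subject_id"] + cov_cols], on="subject_id", how="left")
    return out


# ---------------------------------------------------------------------------
# Experience classification
# ---------------------------------------------------------------------------

_RACE_ALIASES = {
    "white": "white",
    "asian american": "asian_american",
    "asian_american": "asian_american",
    "asian": "asian_american",
    "black": "black",
    "black or african american": "black",
}


def _normalize_race(token: str) -> str:
    key = token.strip().lower().replace("-", " ").replace("_", " ")
    return _RACE_ALIASES.get(key, "other") if key else ""


def classify_mother_race(races: Iterable[str], hispanic: bool = False) -> str:
    """Collapse a maternal race report into White / Asian American / Other.

    White (with or without Hispanic ethnicity) -> ``white``; Asian American,
    alone or with White -> ``asian_american``; any other race, or Hispanic
    with no race reported -> ``other``; nothing reported -> ``unclassified``.
    """
    groups = {_normalize_race(r) for r in races if str(r).strip()}
    if not groups:
        return "other" if hispanic else "unclassified"
    if groups == {"white"}:
        return "white"
    if "asian_american" in groups and groups <= {"asian_american", "white"}:
        return "asian_american"
    return "other"


def exposure_group(races: Iterable[str], hispanic: bool = False) -> str:
    """The racial-group contribution of one person to the diversity count.

    Unlike :func:`classify_mother_race`, this keeps Black as its own group
    (the diversity index counts exposure to White, Asian American, and Black
    faces; anything else, including Hispanic with no reported race, counts as
    a single ``other`` group).
    """
    groups = {_normalize_race(r) for r in races if str(r).strip()}
    if not groups:
        return "other" if hispanic else ""
    if groups == {"white"}:
        return "white"
    if "asian_american" in groups and groups <= {"asian_american", "white"}:
        return "asian_american"
    if "black" in groups:
        return "black"
    return "other"


def classify_diversity(
    mother_group: str,
    caregiver_group: Optional[str] = None,
    exposures: Iterable[str] = (),
    questionnaire_present: bool = True,
) -> Optional[str]:
    """Diversity of face-race experience: low / medium / high.

    Counts the distinct racial groups the infant regularly sees among the
    union of the mother's group, any regular caregiver's group, and the
    face-experience questionnaire (which reports exposure to White, Asian
    American, and Black women). The mother's group always counts, including
    ``other``. Three groups -> high, two -> medium, one -> low. Undefined
    (``None``) when the questionnaire was not returned.
    """
    if not questionnaire_present:
        return None
    groups = set()
    if mother_group:
        groups.add(mother_group)
    if caregiver_group:
        groups.add(caregiver_group)
    for e in exposures:
        g = _normalize_race(e)
        if g in ("white", "asian_american", "black"):
            groups.add(g)
    if not groups:
        raise DataError("diversity classification requires at least the mother's group")
    n = len(groups)
    return "high" if n >= 3 else "medium" if n == 2 else "low"


def classify_language(report: Mapping[str, float], tol: float = 1e-6) -> str:
    """Language-exposure grouping from a language -> fraction-of-time report.

    English > 0.75 -> ``monolingual_english``; another single language > 0.75
    -> ``other_monolingual``; several languages with none above 0.75 ->
    ``multilingual``; empty report -> ``unreported``.
    """
    if not report:
        return "unreported"
    fracs = {str(k).strip().lower(): float(v) for k, v in report.items()}
    for lang, f in fracs.items():
        if f < -tol:
            raise DataError(f"negative exposure fraction for {lang!r}: {f}")
    if sum(fracs.values()) > 1.0 + 1e-3:
        raise DataError("language exposure fractions sum to more than 1")
    if fracs.get("english", 0.0) > 0.75:
        return "monolingual_english"
    for lang, f in fracs.items():
        if lang != "english" and f > 0.75:
            return "other_monolingual"
    return "multilingual"


def parse_language_report(text: str) -> dict[str, float]:
    """Parse the subjects-CSV encoding ``"english:0.85;spanish:0.15"``."""
    text = str(text).strip() if text is not None and not pd.isna(text) else ""
    if not text:
        return {}
    out = {}
    for item in text.split(";"):
        lang, _, frac = item.partition(":")
        if not frac:
            raise DataError(f"malformed language report item {item!r}")
        out[lang.strip()] = float(frac)
    return out


def classify_subjects(subjects: pd.DataFrame) -> pd.DataFrame:
    """Apply all three classifications to a subjects covariate table.

    Expects the raw-report columns written by the synthetic generator
    (mother_races, mother_hispanic, caregiver_group, questionnaire_present,
    exposure_white/asian_american/black, language_report) and adds
    mother_race_group, diversity_group, language_group.
    """
    out = subjects.copy()
    mother, diversity, language = [], [], []
    for _, row in out.iterrows():
        races = [r for r in str(row.get("mother_races", "") or "").split("|") if r]
        hisp = bool(row.get("mother_hispanic", 0))
        mother.append(classify_mother_race(races, hisp))
        exposures = [
            g
            for g in ("white", "asian_american", "black")
            if row.get(f"exposure_{g}", 0)
        ]
        div = classify_diversity(
            exposure_group(races, hisp),
            str(row.get("caregiver_group", "") or "") or None,
            exposures,
            questionnaire_present=bool(row.get("questionnaire_present", 1)),
        )
        diversity.append(div if div is not None else "not_reported")
        language.append(classify_language(parse_language_report(row.get("language_report", ""))))
    out["mother_race_group"] = mother
    out["diversity_group"] = diversity
    out["language_group"] = language
    return out
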