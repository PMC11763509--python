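"""Inclusion filtering, derived variables and cohort statistics.

The modelling cohort keeps only patients with complete records, at least one
month of follow-up after TKI start, and an evaluable one-year endpoint: either
progression/death within the first 12 months, or at least 12 months of
follow-up.  Two engineered variables drive all downstream modelling:

* ``lognlr`` — natural log of the pre-treatment neutrophil-to-lymphocyte
  ratio (an inflammation biomarker; log taken because NLR is right-skewed);
* ``action_code`` — the 4-level treatment variable crossing the line of the
  first TKI (first vs second-or-later) with its generation (first vs
  second-or-higher):

  =====  ==========================================
  code   meaning
  =====  ==========================================
  0      first-line, first-generation TKI
  1      first-line, second- or higher-generation TKI
  2      second- or later-line, first-generation TKI
  3      second- or later-line, second- or higher-generation TKI
  =====  ==========================================

The binary endpoint ``progression_category`` is 1 when progression or death
occurred before 12 months and 0 when the patient was progression-free for a
year or more (the 12-month boundary is inclusive on the progression-free
side).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import RAW_COLUMNS

ACTION_LABELS = {
    0: "first-line, first-generation TKI",
    1: "first-line, second- or higher-generation TKI",
    2: "second- or later-line, first-generation TKI",
    3: "second- or later-line, second- or higher-generation TKI",
}

#: Numeric feature encodings used by the classifier and the RL state.
FEATURE_COLUMNS = [
    "logage",
    "lognlr",
    "line_treatment",
    "gender_female",
    "ecog_high",
    "mutation_other",
    "smoking_current",
    "mets_4plus",
    "bone_or_liver_met",
    "brain_met",
    "comorbidity",
]

_DEFAULT_REQUIRED = [c for c in RAW_COLUMNS if c != "patient_id"]


@dataclass
class InclusionRules:
    min_followup_months: float = 1.0
    min_followup_if_progression_free: float = 12.0
    required_fields: list[str] = field(default_factory=lambda: list(_DEFAULT_REQUIRED))

    def validate(self) -> None:
        if self.min_followup_months <= 0 or self.min_followup_if_progression_free <= 0:
            raise ValueError("inclusion thresholds must be positive")


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float


def apply_inclusion_filters(
    records: pd.DataFrame, rules: InclusionRules | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition ``records`` into kept rows and an exclusion log.

    Rules are checked in a fixed order and each excluded row is logged with
    the *first* rule it fails: ``missing_fields``, then ``min_followup``
    (follow-up shorter than one month), then ``insufficient_followup``
    (censored before the one-year endpoint could be evaluated).  Kept and
    excluded rows always partition the input.
    """
    rules = rules or InclusionRules()
    rules.validate()
    missing_cols = [c for c in rules.required_fields if c not in records.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {', '.join(missing_cols)}")

    if records.empty:
        return records.copy(), pd.DataFrame(columns=["patient_id", "rule"])

    incomplete = records[rules.required_fields].isna().any(axis=1)
    short = records["followup_months"] < rules.min_followup_months
    event = records["event"].fillna(0).astype(float) > 0
    progressed_early = event & (
        records["pfs_months"] < rules.min_followup_if_progression_free
    )
    long_enough = records["followup_months"] >= rules.min_followup_if_progression_free
    unevaluable = ~(progressed_early | long_enough)

    rule = np.select(
        [incomplete, short, unevaluable],
        ["missing_fields", "min_followup", "insufficient_followup"],
        default="",
    )
    excluded_mask = rule != ""
    ids = records["patient_id"] if "patient_id" in records.columns else records.index.astype(str)
    log = pd.DataFrame(
        {"patient_id": np.asarray(ids)[excluded_mask], "rule": rule[excluded_mask]}
    )
    kept = records.loc[~excluded_mask].copy()
    return kept, log


def derive_action_code(tki_line: int, tki_generation) -> int:
    """Treatment action code from the recorded line and TKI generation."""
    line = int(tki_line)
    if line < 1:
        raise ValueError(f"tki_line must be >= 1, got {tki_line!r}")
    gen = str(tki_generation)
    if gen in {"1", "1.0"}:
        second_gen = False
    elif gen in {"2+", "2plus", "2", "2-or-higher"}:
        second_gen = True
    else:
        raise ValueError(f"unknown tki_generation {tki_generation!r}")
    return 2 * int(line >= 2) + int(second_gen)


def action_line_group(action_code: int) -> str:
    """Line half of an action code: 'first' for 0/1, 'later' for 2/3."""
    if action_code not in (0, 1, 2, 3):
        raise ValueError(f"action code must be in 0..3, got {action_code!r}")
    return "first" if action_code < 2 else "later"


def action_generation(action_code: int) -> str:
    """Generation half of an action code: '1' for 0/2, '2plus' for 1/3."""
    if action_code not in (0, 1, 2, 3):
        raise ValueError(f"action code must be in 0..3, got {action_code!r}")
    return "2plus" if action_code % 2 else "1"


def derive_progression_category(pfs_months: float, event, followup_months: float) -> int:
    """Dichotomize PFS at one year: 0 = progression-free >= 12 months."""
    if pfs_months >= 12.0:
        return 0
    if bool(event):
        return 1
    raise ValueError(
        "unclassifiable under inclusion rules: censored before 12 months "
        f"(pfs={pfs_months}, followup={followup_months})"
    )


def engineer_features(records: pd.DataFrame) -> pd.DataFrame:
    """Add lognlr, logage, action_code and progression_category columns.

    Raw columns are left untouched and the row count is preserved; rows must
    already have passed the inclusion filters.
    """
    bad_counts = (records["neutrophils"] <= 0) | (records["lymphocytes"] <= 0)
    bad_age = records["age"] <= 0
    if bad_counts.any() or bad_age.any():
        idx = records.index[bad_counts | bad_age].tolist()
        raise ValueError(f"non-positive counts or age in rows {idx}")

    out = records.copy()
    out["lognlr"] = np.log(out["neutrophils"] / out["lymphocytes"])
    out["logage"] = np.log(out["age"].astype(float))
    out["action_code"] = [
        derive_action_code(line, gen)
        for line, gen in zip(out["tki_line"], out["tki_generation"])
    ]
    out["progression_category"] = [
        derive_progression_category(p, e, f)
        for p, e, f in zip(out["pfs_months"], out["event"], out["followup_months"])
    ]
    return out


def feature_matrix(engineered: pd.DataFrame) -> pd.DataFrame:
    """Numeric model matrix (FEATURE_COLUMNS) from an engineered table.

    The line of the first TKI enters as a quantitative feature
    (``line_treatment``); binary clinical factors are 0/1 indicators.
    """
    return pd.DataFrame(
        {
            "logage": engineered["logage"].astype(float),
            "lognlr": engineered["lognlr"].astype(float),
            "line_treatment": engineered["tki_line"].astype(float),
            "gender_female": (engineered["gender"] == "female").astype(float),
            "ecog_high": (engineered["ecog"] == "2-4").astype(float),
            "mutation_other": (engineered["mutation"] != "exon19").astype(float),
            "smoking_current": (engineered["smoking"] == "current").astype(float),
            "mets_4plus": (engineered["n_mets_cat"] == "4plus").astype(float),
            "bone_or_liver_met": engineered["bone_or_liver_met"].astype(float),
            "brain_met": engineered["brain_met"].astype(float),
            "comorbidity": engineered["comorbidity"].astype(float),
        },
        index=engineered.index,
    )[FEATURE_COLUMNS]


def percent(count: int, total: int) -> float:
    """Share of a categorical level, as a percentage rounded to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


@dataclass
class CohortSummary:
    n: int
    categorical: pd.DataFrame  # variable, level, n, pct
    numeric: pd.DataFrame  # variable, mean, sd, median, min, max


_CATEGORICAL_VARS = [
    "gender",
    "ecog",
    "mutation",
    "smoking",
    "n_mets_cat",
    "bone_or_liver_met",
    "brain_met",
    "comorbidity",
    "tki_generation",
    "action_code",
    "event",
]
_NUMERIC_VARS = ["age", "neutrophils", "lymphocytes", "tki_line", "pfs_months", "followup_months"]


def summarize_cohort(records: pd.DataFrame) -> CohortSummary:
    """Descriptive summary: level counts/percentages and numeric five-number rows."""
    if records.empty:
        raise ValueError("cannot summarize an empty table")
    total = len(records)
    cat_rows = []
    for var in _CATEGORICAL_VARS:
        if var not in records.columns:
            continue
        counts = records[var].value_counts().sort_index()
        for level, count in counts.items():
            cat_rows.append(
                {"variable": var, "level": level, "n": int(count), "pct": percent(int(count), total)}
            )
    num_rows = []
    for var in _NUMERIC_VARS + [c for c in ("lognlr", "logage") if c in records.columns]:
        if var not in records.columns:
            continue
        values = records[var].astype(float)
        num_rows.append(
            {
                "variable": var,
                "mean": values.mean(),
                "sd": values.std(ddof=1),
                "median": values.median(),
                "min": values.min(),
                "max": values.max(),
            }
        )
    nlr = records["neutrophils"] / records["lymphocytes"]
    num_rows.append(
        {
            "variable": "nlr",
            "mean": nlr.mean(),
            "sd": nlr.std(ddof=1),
            "median": nlr.median(),
            "min": nlr.min(),
            "max": nlr.max(),
        }
    )
    return CohortSummary(n=total, categorical=pd.DataFrame(cat_rows), numeric=pd.DataFrame(num_rows))


def nlr_progression_ttest(engineered: pd.DataFrame) -> TestResult:
    """Pooled-variance two-sample t-test of NLR between progression categories.

    Groups are (progression_category == 0, progression_category == 1) in that
    order; degrees of freedom are n0 + n1 - 2 as in the classical Student
    test, and the p-value is two-sided.
    """
    nlr = (engineered["neutrophils"] / engineered["lymphocytes"]).astype(float)
    g0 = nlr[engineered["progression_category"] == 0]
    g1 = nlr[engineered["progression_category"] == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each progression category needs at least 2 rows for the t-test")
    res = stats.ttest_ind(g0, g1, equal_var=True)
    return TestResult(statistic=float(res.statistic), df=len(g0) + len(g1) - 2, p_value=float(res.pvalue))
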