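"""Cohort-level agreement and association statistics.

Compares the pathologist's manual grades with automated grades (percent
match and Cohen's kappa over the four ordinal grade categories), tests
2x2 receptor-status vs positivity tables (Pearson chi-square, optional
Yates continuity correction), and tabulates subtype-stratified positivity.
A sample is *positive* when its grade is 1+ or higher.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from .exceptions import DegenerateTableError, EmptyInputError, IHCScoreError
from .scoring import GRADE_LABELS, round_half_up
from .synthetic_ihc import CohortRecord

GRADES = (0, 1, 2, 3)

COHORT_COLUMNS = [
    "sample_id", "er", "pgr", "her2", "menopause", "chemo",
    "manual_grade", "auto_grade",
]


@dataclass(frozen=True)
class AgreementStats:
    n: int
    n_match: int
    percent_match: float
    kappa: float


def percent_agreement(pairs) -> tuple[int, int, float]:
    """(n, n_match, percent) for a list of (manual, auto) grade pairs."""
    pairs = list(pairs)
    if not pairs:
        raise EmptyInputError("no grade pairs")
    if any(a is None or b is None for a, b in pairs):
        raise EmptyInputError("missing grades in pairs")
    n = len(pairs)
    n_match = sum(1 for a, b in pairs if a == b)
    return n, n_match, 100.0 * n_match / n


def cohens_kappa(pairs, weights: str | None = None) -> float:
    """Cohen's kappa over the four grade categories.

    Unweighted by default; ``weights="linear"`` gives linearly weighted
    kappa for the ordinal scale.  When both raters are constant the
    chance-expected agreement is 1 and kappa is undefined; perfect constant
    agreement returns 1.0 by convention, constant disagreement raises.
    """
    pairs = list(pairs)
    if not pairs:
        raise EmptyInputError("no grade pairs")
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    # degenerate: expected agreement 1 (each rater constant)
    if len(np.unique(a)) == 1 and len(np.unique(b)) == 1:
        if a[0] == b[0]:
            return 1.0
        raise DegenerateTableError("kappa undefined: constant raters that disagree")
    return float(cohen_kappa_score(a, b, labels=list(GRADES), weights=weights))


def agreement_stats(pairs) -> AgreementStats:
    n, n_match, pct = percent_agreement(pairs)
    return AgreementStats(n, n_match, pct, cohens_kappa(pairs))


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df=1) on a 2x2 count table -> (statistic, p).

    ``table`` is ((a, b), (c, d)); rows are groups, columns positive /
    negative.  Yates continuity correction off by default.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise DegenerateTableError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or t.sum() == 0:
        raise DegenerateTableError("table must hold non-negative counts with a positive total")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("zero marginal: expected frequencies undefined")
    res = sps.chi2_contingency(t, correction=yates)
    return float(res.statistic), float(res.pvalue)


def is_positive(grade: int | None) -> bool:
    return grade is not None and grade >= 1


def records_to_frame(records) -> pd.DataFrame:
    rows = [
        {c: getattr(r, c) for c in COHORT_COLUMNS}
        for r in records
    ]
    if not rows:
        raise EmptyInputError("no cohort records")
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _subtype_label(row) -> str:
    sign = {"positive": "+", "negative": "-"}
    return f"ER{sign[row.er]}/PgR{sign[row.pgr]}/HER2{sign[row.her2]}"


def cohort_summary(
    records,
    stratify_by: str = "subtype",
    grade_field: str = "manual_grade",
    decimals: int = 0,
) -> pd.DataFrame:
    """Per-stratum positivity summary.

    Returns one row per stratum with n, n_positive, percent_positive
    (round half up at ``decimals``; NaN for empty strata) and per-grade
    counts.  ``stratify_by`` is a record field, ``"subtype"`` (the
    ER/PgR/HER2 combination) or ``"all"``.
    """
    df = records_to_frame(records)
    if stratify_by == "subtype":
        df["stratum"] = df.apply(_subtype_label, axis=1)
    elif stratify_by == "all":
        df["stratum"] = "all"
    elif stratify_by in COHORT_COLUMNS:
        df["stratum"] = df[stratify_by]
    else:
        raise IHCScoreError(f"unknown stratification field: {stratify_by!r}")

    grades = df[grade_field]
    rows = []
    for stratum, sub in df.groupby("stratum", sort=True):
        g = grades.loc[sub.index]
        n = len(sub)
        n_pos = int((g >= 1).sum())
        if n:
            scale = 10**decimals
            pct = round_half_up(100.0 * n_pos / n * scale) / scale
        else:
            pct = float("nan")
        row = {"stratum": stratum, "n": n, "n_positive": n_pos, "percent_positive": pct}
        for grade in GRADES:
            row[f"n_grade_{GRADE_LABELS[grade]}"] = int((g == grade).sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    # self-consistency: positives always recompute from the grade counts
    assert (
        out["n_positive"]
        == out[["n_grade_1+", "n_grade_2+", "n_grade_3+"]].sum(axis=1)
    ).all()
    return out


def positivity_table(records, by: str, grade_field: str = "manual_grade"):
    """2x2 (group x positive/negative) count table for a binary field."""
    df = records_to_frame(records)
    if by not in COHORT_COLUMNS:
        raise IHCScoreError(f"unknown field: {by!r}")
    levels = sorted(df[by].unique())
    if len(levels) != 2:
        raise DegenerateTableError(f"field {by!r} has {len(levels)} levels, need 2")
    pos = df[grade_field] >= 1
    table = [
        [int((df[by].eq(lv) & pos).sum()), int((df[by].eq(lv) & ~pos).sum())]
        for lv in levels
    ]
    return np.array(table), levels


def read_cohort_csv(path) -> list[CohortRecord]:
    """Read a cohort table (documented header, see COHORT_COLUMNS)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise IHCScoreError(f"cohort CSV missing columns: {missing}")

    def _grade(v):
        if pd.isna(v):
            return None
        return int(str(v).rstrip("+"))

    return [
        CohortRecord(
            sample_id=str(r.sample_id), er=r.er, pgr=r.pgr, her2=r.her2,
            menopause=r.menopause, chemo=r.chemo,
            manual_grade=_grade(r.manual_grade), auto_grade=_grade(r.auto_grade),
        )
        for r in df.itertuples()
    ]


def write_cohort_csv(path, records) -> None:
    records_to_frame(records).to_csv(path, index=False)
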