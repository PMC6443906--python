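"""Questionnaire scoring and model covariates.

Scores the interview-administered leisure-time activity questionnaire
into weekly minutes of moderate-to-vigorous physical activity (MVPA) and
the 0-3 ordinal activity code used as the exposure in the per-protein
models, and computes the myosin fiber-type ratio covariate from the
normalized protein matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import FIBER_TYPE_I, FIBER_TYPE_II

#: Activity types recorded by the questionnaire.  Brisk walking, weight or
#: circuit training, and up to four vigorous activities count toward MVPA;
#: casual walking is recorded but tabulated separately.
MVPA_TYPES: tuple[str, ...] = (
    "brisk_walking",
    "weight_circuit",
    "vigorous_1",
    "vigorous_2",
    "vigorous_3",
    "vigorous_4",
)
ALL_ACTIVITY_TYPES: tuple[str, ...] = MVPA_TYPES + ("casual_walking",)

#: Lower edges (min/week, inclusive) of the ordinal activity categories
#: 1 ("moderately active"), 2 ("active"), 3 ("highly active"); below the
#: first edge is 0 ("not active").
CATEGORY_EDGES: tuple[float, float, float] = (30.0, 75.0, 150.0)


@dataclass(frozen=True)
class ActivityRecord:
    """One questionnaire line: an activity over the past 2 weeks.

    ``frequency`` is sessions per 2 weeks; ``duration`` is average
    minutes per session.  When ``performed`` is false the frequency and
    duration are ignored.
    """

    activity_type: str
    performed: bool = False
    frequency: float = 0.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.activity_type not in ALL_ACTIVITY_TYPES:
            raise ValueError(
                f"unknown activity_type {self.activity_type!r}; "
                f"expected one of {ALL_ACTIVITY_TYPES}"
            )
        if self.frequency < 0 or self.duration < 0:
            raise ValueError("frequency and duration must be nonnegative")


@dataclass(frozen=True)
class ActivityScore:
    """Scored questionnaire: weekly MVPA minutes and the ordinal code."""

    mvpa_minutes: float
    pa_code: int
    casual_walking_minutes: float


def compute_mvpa_minutes(records: Iterable[ActivityRecord]) -> float:
    """Weekly MVPA minutes from 2-week activity records.

    For each MVPA activity performed, frequency (sessions per 2 weeks)
    is multiplied by minutes per session; the activities are summed and
    the total halved to give minutes per week.  Casual walking is
    excluded.
    """
    total = 0.0
    for rec in records:
        if rec.activity_type in MVPA_TYPES and rec.performed:
            total += rec.frequency * rec.duration
    return total / 2.0


def compute_casual_walking_minutes(records: Iterable[ActivityRecord]) -> float:
    """Weekly casual-walking minutes, scored like MVPA but kept separate."""
    total = 0.0
    for rec in records:
        if rec.activity_type == "casual_walking" and rec.performed:
            total += rec.frequency * rec.duration
    return total / 2.0


def categorize_activity(mvpa_minutes: float) -> int:
    """Ordinal activity code from weekly MVPA minutes.

    <30 -> 0 (not active); [30, 75) -> 1 (moderately active);
    [75, 150) -> 2 (active); >=150 -> 3 (highly active).
    """
    if mvpa_minutes < 0:
        raise ValueError(f"mvpa_minutes must be nonnegative, got {mvpa_minutes}")
    code = 0
    for edge in CATEGORY_EDGES:
        if mvpa_minutes >= edge:
            code += 1
    return code


def score_activity(records: Sequence[ActivityRecord]) -> ActivityScore:
    """Score a donor's full questionnaire into an :class:`ActivityScore`."""
    mvpa = compute_mvpa_minutes(records)
    return ActivityScore(
        mvpa_minutes=mvpa,
        pa_code=categorize_activity(mvpa),
        casual_walking_minutes=compute_casual_walking_minutes(records),
    )


# --- wide TSV encoding of questionnaire records -------------------------

def activity_columns() -> list[str]:
    cols: list[str] = []
    for t in ALL_ACTIVITY_TYPES:
        cols += [f"{t}_performed", f"{t}_sessions_2wk", f"{t}_min_session"]
    return cols


def records_to_row(records: Sequence[ActivityRecord]) -> dict[str, float]:
    """Encode records as the wide per-donor columns used in samples.tsv."""
    row = {}
    by_type = {r.activity_type: r for r in records}
    for t in ALL_ACTIVITY_TYPES:
        r = by_type.get(t)
        row[f"{t}_performed"] = int(r.performed) if r else 0
        row[f"{t}_sessions_2wk"] = r.frequency if r and r.performed else 0.0
        row[f"{t}_min_session"] = r.duration if r and r.performed else 0.0
    return row


def records_from_row(row: pd.Series) -> list[ActivityRecord]:
    """Decode the wide per-donor questionnaire columns into records."""
    records = []
    for t in ALL_ACTIVITY_TYPES:
        performed = bool(int(row.get(f"{t}_performed", 0)))
        records.append(
            ActivityRecord(
                activity_type=t,
                performed=performed,
                frequency=float(row.get(f"{t}_sessions_2wk", 0.0)) if performed else 0.0,
                duration=float(row.get(f"{t}_min_session", 0.0)) if performed else 0.0,
            )
        )
    return records


# --- fiber-type ratio ----------------------------------------------------

def compute_fiber_ratio(matrix, literal_log2: bool = False) -> pd.Series:
    """Per-sample type I / type II myosin fiber ratio.

    Computed from the normalized abundances of MYH7 (type I) and MYH1,
    MYH2, MYH4 (type II) as ``2**a7 / (2**a1 + 2**a2 + 2**a4)``, i.e. on
    the linear intensity scale.  ``literal_log2=True`` instead forms the
    ratio of the log2 values directly; this reading is sign-unstable
    once abundances are median-centered around 0 and is off by default.

    Parameters
    ----------
    matrix:
        A :class:`~actiprot.quantify.ProteinQuantMatrix` or a DataFrame
        of log2 abundances indexed by accession with sample columns.
    """
    values = getattr(matrix, "values_df", matrix)
    needed = [FIBER_TYPE_I, *FIBER_TYPE_II]
    missing = [acc for acc in needed if acc not in values.index]
    if missing:
        raise KeyError(
            "fiber-ratio proteins missing from the quantification matrix: "
            + ", ".join(missing)
        )
    a7 = values.loc[FIBER_TYPE_I]
    type2 = values.loc[list(FIBER_TYPE_II)]
    if literal_log2:
        ratio = a7 / type2.sum(axis=0)
    else:
        ratio = np.exp2(a7) / np.exp2(type2).sum(axis=0)
    ratio.name = "fiber_ratio"
    return ratio


def build_covariates(
    samples: pd.DataFrame,
    matrix=None,
    literal_log2_ratio: bool = False,
) -> pd.DataFrame:
    """Assemble the per-sample covariate table for the mixed models.

    Scores each non-reference sample's questionnaire into MVPA minutes
    and the ordinal code, carries age/sex/race/BMI and the TMT set, and
    (when a protein matrix is given) merges the fiber-type ratio.
    Reference channels are excluded: they carry no donor.
    """
    non_ref = samples.loc[samples["is_reference"] == 0].copy()
    rows = []
    for _, row in non_ref.iterrows():
        score = score_activity(records_from_row(row))
        rows.append(
            {
                "sample_id": row["sample_id"],
                "donor_id": row["donor_id"],
                "tmt_set": row["tmt_set"],
                "age": float(row["age"]),
                "sex": row["sex"],
                "race": row["race"],
                "bmi": float(row["bmi"]),
                "mvpa_minutes": score.mvpa_minutes,
                "pa_code": score.pa_code,
                "casual_walking_minutes": score.casual_walking_minutes,
            }
        )
    cov = pd.DataFrame(rows).set_index("sample_id")
    if matrix is not None:
        ratio = compute_fiber_ratio(matrix, literal_log2=literal_log2_ratio)
        cov = cov.join(ratio, how="left")
    return cov
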