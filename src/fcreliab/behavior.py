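"""Post-session survey scoring: attention (recall accuracy) and drowsiness.

After each scan session, participants answer recall questions about the videos
from each run and report drowsiness (none / felt tired / sleepy / difficulty
staying awake). Attention is the percent of correct recall responses over a
condition's two runs; drowsiness codes the item 0-3 per run and sums the two
runs, giving an integer 0-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

DROWSINESS_CODES = {
    "none": 0,
    "tired": 1,
    "sleepy": 2,
    "difficulty_staying_awake": 3,
}


@dataclass(frozen=True)
class RunResponse:
    """One run's survey answers: recall tally plus the drowsiness item."""

    correct: int
    asked: int
    drowsiness: str = "none"

    def __post_init__(self) -> None:
        if self.correct < 0 or self.asked < 0 or self.correct > self.asked:
            raise ValueError("need 0 <= correct <= asked")
        if self.drowsiness not in DROWSINESS_CODES:
            raise ValueError(
                f"unknown drowsiness item {self.drowsiness!r}; "
                f"expected one of {sorted(DROWSINESS_CODES)}"
            )


@dataclass(frozen=True)
class SurveyRecord:
    """One subject/session/condition's responses (exactly two runs)."""

    subject_id: str
    session: int
    condition: str
    runs: tuple

    def __post_init__(self) -> None:
        if len(self.runs) != 2:
            raise ValueError("a survey record covers exactly two runs")


def attention_score(record: SurveyRecord) -> float:
    """Percent correct recall over the condition's two runs; NaN if none asked."""
    total_correct = sum(r.correct for r in record.runs)
    total_asked = sum(r.asked for r in record.runs)
    if total_asked == 0:
        return math.nan
    return 100.0 * total_correct / total_asked


def drowsiness_score(record: SurveyRecord) -> int:
    """Sum of the two runs' drowsiness codes (0-6)."""
    return sum(DROWSINESS_CODES[r.drowsiness] for r in record.runs)


def score_survey_table(surveys: pd.DataFrame) -> pd.DataFrame:
    """Score a long-format survey table into per-condition rows.

    Input columns: subject_id, session, condition, run, correct, asked,
    drowsiness (one row per run). Output: one row per subject/session/
    condition with ``attention_pct`` and ``drowsiness`` columns, joinable to
    reliability tables.
    """
    rows = []
    for (sid, ses, cond), grp in surveys.groupby(
        ["subject_id", "session", "condition"], sort=True
    ):
        grp = grp.sort_values("run")
        rec = SurveyRecord(
            sid,
            int(ses),
            cond,
            tuple(
                RunResponse(int(r.correct), int(r.asked), r.drowsiness)
                for r in grp.itertuples()
            ),
        )
        rows.append(
            {
                "subject_id": sid,
                "session": int(ses),
                "condition": cond,
                "attention_pct": attention_score(rec),
                "drowsiness": drowsiness_score(rec),
            }
        )
    return pd.DataFrame(rows)
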