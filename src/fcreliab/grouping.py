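"""Motion-group classification from post-censored volume counts.

Subjects who retain fewer volumes after FD censoring moved more. The cutoff
between low- and high-motion subjects is data-driven: normal probability
density functions are fitted to each age group's retained-volume counts and
the threshold is the densities' intersection between the two group means.
Subjects with counts below the threshold are high-motion, at-or-above are
low-motion, and the final label crosses that with the age group
(low/high-motion adult/child).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GroupPDF:
    """Normal density over post-censored volume counts for one age group."""

    label: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("SD must be positive")

    def density(self, x):
        return stats.norm.pdf(x, loc=self.mean, scale=self.sd)


def postcensored_counts(masks_by_subject: Mapping[str, Sequence]) -> pd.Series:
    """Total retained volumes per subject, summed over all runs."""
    counts = {}
    for sid, masks in masks_by_subject.items():
        if not masks:
            warnings.warn(f"subject {sid!r} has no runs; count set to 0", UserWarning)
            counts[sid] = 0
        else:
            counts[sid] = int(sum(m.n_retained for m in masks))
    return pd.Series(counts, name="retained_volumes")


def group_pdf(label: str, counts: Sequence[float]) -> GroupPDF:
    """Fit a normal density to one age group's retained-volume counts."""
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 subjects to fit a group density")
    return GroupPDF(label, float(x.mean()), float(x.std(ddof=1)))


def pdf_intersection(
    group_a: GroupPDF, group_b: GroupPDF, fallback_midpoint: bool = False
) -> float:
    """Volume count where the two group densities are equal, between the means.

    Solves the quadratic obtained from equating the normal log-densities. With
    equal SDs the intersection is the midpoint of the means. If no root falls
    between the means (pathological SDs), raises unless ``fallback_midpoint``.
    """
    ma, sa = group_a.mean, group_a.sd
    mb, sb = group_b.mean, group_b.sd
    if ma == mb:
        raise ValueError("group means must be distinct")
    if math.isclose(sa, sb, rel_tol=1e-12):
        return (ma + mb) / 2.0
    # (x-ma)^2/(2 sa^2) + ln sa = (x-mb)^2/(2 sb^2) + ln sb
    a = 1.0 / (2 * sa**2) - 1.0 / (2 * sb**2)
    b = mb / sb**2 - ma / sa**2
    c = ma**2 / (2 * sa**2) - mb**2 / (2 * sb**2) + math.log(sa / sb)
    disc = b * b - 4 * a * c
    roots = []
    if disc >= 0:
        roots = [(-b + s * math.sqrt(disc)) / (2 * a) for s in (+1, -1)]
    lo, hi = min(ma, mb), max(ma, mb)
    between = [r for r in roots if lo <= r <= hi]
    if between:
        return float(between[0])
    if fallback_midpoint:
        warnings.warn("no density intersection between means; using midpoint")
        return (ma + mb) / 2.0
    raise ValueError("no density intersection between the group means")


def classify(
    counts: pd.Series,
    threshold: float,
    age_labels: Mapping[str, str],
    min_minutes: float | None = None,
    tr_seconds: float = 2.0,
) -> pd.DataFrame:
    """Assign motion groups by retained-volume count versus threshold.

    Counts *below* the threshold mean heavy censoring, hence high motion;
    counts at or above go to low motion (ties favour low motion). Labels are
    ``{low,high}_motion_{adult,child}``. ``min_minutes`` optionally excludes
    subjects retaining less than that much post-censored data before
    classification (flagged, not dropped silently).
    """
    obs_lo, obs_hi = float(counts.min()), float(counts.max())
    if not obs_lo <= threshold <= obs_hi:
        warnings.warn(
            f"threshold {threshold:.0f} lies outside the observed count range "
            f"[{obs_lo:.0f}, {obs_hi:.0f}]",
            UserWarning,
        )
    rows = []
    min_volumes = (
        None if min_minutes is None else 60.0 * min_minutes / tr_seconds
    )
    for sid, n in counts.items():
        age = age_labels[sid]
        motion = "high" if n < threshold else "low"
        excluded = min_volumes is not None and n < min_volumes
        rows.append(
            {
                "subject_id": sid,
                "age_group": age,
                "retained_volumes": int(n),
                "group": f"{motion}_motion_{age}",
                "excluded": bool(excluded),
            }
        )
    return pd.DataFrame(rows)


def group_summary(assignment: pd.DataFrame) -> pd.DataFrame:
    """Group sizes (excluded subjects left out), sorted by group name."""
    kept = assignment[~assignment["excluded"]]
    return (
        kept.groupby("group")
        .agg(n=("subject_id", "size"), mean_retained=("retained_volumes", "mean"))
        .reset_index()
        .sort_values("group", ignore_index=True)
    )
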