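"""Whole-connectome test-retest correlation (TRC) as a function of scan duration.

Two estimators are provided. The *split-session* approach partitions sessions
into two halves (e.g., sessions 1+4 vs 2+3), truncates each half to the first
T post-censored minutes in acquisition order, builds a Fisher-z connectome per
half, and Pearson-correlates the two flattened edge vectors; the per-split
correlations are averaged. The *iterative* approach samples 1-minute chunks of
post-censored data without replacement to form a fixed "true" reference
connectome and correlates it with connectomes built from T minutes of the
residual chunks, averaged over random iterations.

Both produce a :class:`ReliabilityCurve`; time-to-threshold with linear
interpolation, per-step incremental benefit, and Cohen's d group effect sizes
operate on those curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import connectivity as conn
from .motion import CensorMask, minutes_to_volumes

UNREACHABLE = math.inf


@dataclass(frozen=True)
class SplitScheme:
    """Pairs of disjoint session sets that jointly cover all sessions."""

    pairs: tuple

    def __post_init__(self) -> None:
        norm = []
        for a, b in self.pairs:
            sa, sb = frozenset(a), frozenset(b)
            if sa & sb:
                raise ValueError(f"split halves overlap: {sorted(sa & sb)}")
            norm.append((sa, sb))
        cover = set().union(*(sa | sb for sa, sb in norm)) if norm else set()
        for sa, sb in norm:
            if sa | sb != cover:
                raise ValueError("each split pair must jointly cover all sessions")
        object.__setattr__(self, "pairs", tuple(norm))


def default_split_scheme(n_sessions: int = 4) -> SplitScheme:
    """The three balanced two-vs-two splits of a four-session design."""
    if n_sessions == 4:
        return SplitScheme((((1, 4), (2, 3)), ((1, 2), (3, 4)), ((1, 3), (2, 4))))
    if n_sessions == 2:
        return SplitScheme((((1,), (2,)),))
    raise ValueError("no default scheme for this session count; supply one")


@dataclass
class ReliabilityCurve:
    """TRC per post-censored duration for one subject and estimation method."""

    subject_id: str
    method: str  # "split_session" | "iterative"
    grid_minutes: tuple
    trc: np.ndarray  # NaN where the duration was infeasible
    condition_scope: str = "all"
    n_iterations: int | None = None
    splits_used: int | None = None

    def __post_init__(self) -> None:
        g = tuple(float(t) for t in self.grid_minutes)
        if any(b <= a for a, b in zip(g, g[1:])) or (g and g[0] <= 0):
            raise ValueError("duration grid must be strictly increasing and positive")
        t = np.asarray(self.trc, dtype=float)
        if t.shape != (len(g),):
            raise ValueError("trc length must equal grid length")
        self.grid_minutes = g
        self.trc = t

    @property
    def feasible(self) -> np.ndarray:
        return ~np.isnan(self.trc)


def duration_grid(start: float, stop: float, step: float) -> tuple:
    """Inclusive arithmetic grid of durations in minutes, e.g. 5..80 by 5."""
    if step <= 0 or start <= 0 or stop < start:
        raise ValueError("need 0 < start <= stop and step > 0")
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    return tuple(round(start + k * step, 10) for k in range(n))


def _ordered(runs, sessions, condition=None):
    """Runs of the given sessions in acquisition order (session, condition, run)."""
    cond_order = {}
    for r in runs:
        cond_order.setdefault(r.condition, len(cond_order))
    sel = [
        r
        for r in runs
        if r.session in sessions and (condition is None or r.condition == condition)
    ]
    return sorted(sel, key=lambda r: (r.session, cond_order[r.condition], r.run))


def _half_data(runs, masks, sessions, condition=None):
    """Concatenated post-censored node x volume matrix for one session half."""
    by_id = {id(r): m for r, m in zip(runs, masks)} if masks is not None else None
    sel = _ordered(runs, sessions, condition)
    if not sel:
        return None
    sel_masks = [by_id[id(r)] for r in sel] if by_id is not None else None
    return conn.concat_censored(sel, sel_masks)


def _edge_vector(data: np.ndarray) -> np.ndarray:
    # vectorize before transforming so the unit diagonal never hits atanh
    return conn.fisher_z(conn.vectorize_upper(conn.pearson_fc(data)))


def split_session_trc(
    runs: Sequence,
    scheme: SplitScheme,
    grid: Sequence[float],
    masks: Sequence[CensorMask] | None = None,
    condition: str | None = None,
) -> ReliabilityCurve:
    """Split-session TRC curve for one subject.

    For each duration T and each split pair, both halves are truncated to their
    first T post-censored minutes (temporal sequencing maintained); the TRC at
    T is the mean over splits of the edge-vector Pearson correlation. Durations
    that any half cannot supply for a split are skipped for that split; if no
    split is feasible the grid entry is NaN.
    """
    if not runs:
        raise ValueError("no runs supplied")
    tr = runs[0].tr_seconds
    grid = tuple(float(t) for t in grid)
    per_split = []
    for sess_a, sess_b in scheme.pairs:
        a = _half_data(runs, masks, sess_a, condition)
        b = _half_data(runs, masks, sess_b, condition)
        vals = np.full(len(grid), np.nan)
        if a is None or b is None:
            per_split.append(vals)
            continue
        for gi, t_min in enumerate(grid):
            v = minutes_to_volumes(t_min, tr)
            if v < 3 or a.shape[1] < v or b.shape[1] < v:
                continue
            try:
                ea = _edge_vector(a[:, :v])
                eb = _edge_vector(b[:, :v])
            except ValueError:
                continue  # zero-variance node in a short truncation
            vals[gi] = float(np.corrcoef(ea, eb)[0, 1])
        per_split.append(vals)
    stacked = np.vstack(per_split)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice", RuntimeWarning)
        trc = np.nanmean(stacked, axis=0)
    return ReliabilityCurve(
        subject_id=runs[0].subject_id,
        method="split_session",
        grid_minutes=grid,
        trc=trc,
        condition_scope=condition or "all",
        splits_used=len(scheme.pairs),
    )


def iterative_trc(
    data: np.ndarray,
    tr_seconds: float,
    grid: Sequence[float],
    reference_minutes: float = 60.0,
    chunk_minutes: float = 1.0,
    n_iterations: int = 1000,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sub",
) -> ReliabilityCurve:
    """Iterative TRC curve against a randomly sampled "true" reference.

    ``data`` is the subject's censored, concatenated node x volume matrix
    (all sessions and conditions). It is tiled into chunks of
    ``chunk_minutes`` from its start (the final partial chunk is dropped).
    Per iteration, reference chunks are sampled without replacement; for each
    duration T, T minutes of chunks are sampled from the residual, and TRC is
    the edge-vector correlation between the reference and residual-subset
    connectomes. Curves are averaged over iterations and are reproducible
    under a fixed seed. Grid entries the residual cannot supply are NaN; if
    even the reference is infeasible the whole curve is NaN.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    data = np.asarray(data, dtype=float)
    grid = tuple(float(t) for t in grid)
    chunk_vols = minutes_to_volumes(chunk_minutes, tr_seconds)
    if chunk_vols < 1:
        raise ValueError("chunk shorter than one volume")
    n_chunks = data.shape[1] // chunk_vols
    ref_chunks = int(round(reference_minutes / chunk_minutes))
    trc = np.full(len(grid), np.nan)
    if n_chunks <= ref_chunks:
        return ReliabilityCurve(
            subject_id, "iterative", grid, trc, n_iterations=n_iterations
        )
    chunks = [
        data[:, i * chunk_vols : (i + 1) * chunk_vols] for i in range(n_chunks)
    ]
    need = [int(round(t / chunk_minutes)) for t in grid]
    sums = np.zeros(len(grid))
    counts = np.zeros(len(grid), dtype=int)
    all_idx = np.arange(n_chunks)
    for _ in range(n_iterations):
        ref_idx = rng.choice(all_idx, size=ref_chunks, replace=False)
        residual = np.setdiff1d(all_idx, ref_idx)
        ref_vec = _edge_vector(np.concatenate([chunks[i] for i in ref_idx], axis=1))
        for gi, k in enumerate(need):
            if k < 1 or k > residual.size:
                continue
            sub = rng.choice(residual, size=k, replace=False)
            sub_vec = _edge_vector(
                np.concatenate([chunks[i] for i in sub], axis=1)
            )
            sums[gi] += float(np.corrcoef(ref_vec, sub_vec)[0, 1])
            counts[gi] += 1
    ok = counts > 0
    trc[ok] = sums[ok] / counts[ok]
    return ReliabilityCurve(
        subject_id, "iterative", grid, trc, n_iterations=n_iterations
    )


def condition_trc(
    runs: Sequence,
    scheme: SplitScheme,
    condition: str,
    grid: Sequence[float] | None = None,
    masks: Sequence[CensorMask] | None = None,
) -> ReliabilityCurve:
    """Split-session TRC restricted to one viewing condition's runs.

    Default grid: 1 to 22 minutes in 1-minute increments, the feasible range
    when a single condition contributes two runs per session.
    """
    grid = grid if grid is not None else duration_grid(1, 22, 1)
    return split_session_trc(runs, scheme, grid, masks=masks, condition=condition)


def time_to_threshold(curve: ReliabilityCurve, threshold: float = 0.8) -> float:
    """Smallest duration at which the curve reaches the TRC threshold.

    Linear interpolation between the bracketing grid points gives off-grid
    answers; returns the first grid duration directly if it already meets the
    threshold, and :data:`UNREACHABLE` (``inf``) if the curve never does.
    """
    pts = [
        (t, v)
        for t, v in zip(curve.grid_minutes, curve.trc)
        if not math.isnan(v)
    ]
    if not pts:
        return UNREACHABLE
    prev_t, prev_v = pts[0]
    if prev_v >= threshold:
        return prev_t
    for t, v in pts[1:]:
        if v >= threshold:
            if v == prev_v:
                return t
            frac = (threshold - prev_v) / (v - prev_v)
            return prev_t + frac * (t - prev_t)
        prev_t, prev_v = t, v
    return UNREACHABLE


def incremental_benefit(curve: ReliabilityCurve) -> dict:
    """First differences of TRC along the grid, keyed by the later duration."""
    pts = [
        (t, v) for t, v in zip(curve.grid_minutes, curve.trc) if not math.isnan(v)
    ]
    if len(pts) < 2:
        raise ValueError("need >= 2 feasible grid points")
    return {
        t1: v1 - v0 for (t0, v0), (t1, v1) in zip(pts, pts[1:])
    }


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Cohen's d with the (n-1)-weighted pooled standard deviation.

    Positive when group A's mean exceeds group B's. Returns NaN when the
    pooled SD is zero (both groups constant).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    na, nb = a.size, b.size
    pooled = math.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return math.nan
    return float((a.mean() - b.mean()) / pooled)


def group_mean_curve(curves: Sequence[ReliabilityCurve]) -> np.ndarray:
    """Mean TRC across subjects at each grid point (NaN-aware)."""
    if not curves:
        raise ValueError("no curves supplied")
    grid = curves[0].grid_minutes
    for c in curves[1:]:
        if c.grid_minutes != grid:
            raise ValueError("curves must share a duration grid")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice", RuntimeWarning)
        return np.nanmean(np.vstack([c.trc for c in curves]), axis=0)
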