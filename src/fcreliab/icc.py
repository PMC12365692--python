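"""ICC(2,1) reliability of connectome features across subjects.

ICC(2,1) is the two-way random-effects, absolute-agreement, single-measure
intraclass correlation. For an n-subjects x k-measurements table with
between-subject mean square MSR, between-measurement mean square MSC, and
residual mean square MSE:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

Here the k = 2 measurements are a subject's two split-half connectomes built
from disjoint session sets at a matched post-censored duration. ICC is
computed per edge, then optionally averaged within network-pair blocks either
*after* the edge-level computation (post-averaging) or by first averaging
Fisher-z edges within blocks per subject and half (pre-averaging), which
suppresses edge-level measurement noise before the variance decomposition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import devectorize_upper, vectorize_upper

ICC_BIN_LABELS = ("poor", "fair", "good", "excellent")


@dataclass
class SplitHalfDataset:
    """Per-subject split-half Fisher-z connectomes at one matched duration.

    ``half_a`` and ``half_b`` are (n_subjects, n_nodes, n_nodes) stacks built
    from disjoint session sets, each from exactly ``t_minutes`` of
    post-censored data. ``groups`` carries one label per subject.
    """

    half_a: np.ndarray
    half_b: np.ndarray
    t_minutes: float
    subject_ids: tuple
    groups: tuple
    node_ids: tuple
    network_labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.half_a, dtype=float)
        b = np.asarray(self.half_b, dtype=float)
        if a.shape != b.shape or a.ndim != 3 or a.shape[1] != a.shape[2]:
            raise ValueError("halves must be matching (subjects, nodes, nodes) stacks")
        if len(self.subject_ids) != a.shape[0] or len(self.groups) != a.shape[0]:
            raise ValueError("subject_ids/groups must match the subject axis")
        if len(self.node_ids) != a.shape[1]:
            raise ValueError("node_ids must match the node axis")
        self.half_a, self.half_b = a, b

    @property
    def n_subjects(self) -> int:
        return self.half_a.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.half_a.shape[1]

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(subjects, edges) upper-triangle views of the two halves."""
        ea = np.vstack([vectorize_upper(m) for m in self.half_a])
        eb = np.vstack([vectorize_upper(m) for m in self.half_b])
        return ea, eb

    def subset(self, keep: Sequence[bool]) -> "SplitHalfDataset":
        keep = np.asarray(keep, dtype=bool)
        return SplitHalfDataset(
            self.half_a[keep],
            self.half_b[keep],
            self.t_minutes,
            tuple(np.array(self.subject_ids)[keep]),
            tuple(np.array(self.groups)[keep]),
            self.node_ids,
            self.network_labels,
        )


def icc_2_1(table: np.ndarray) -> float:
    """ICC(2,1) of an n-subjects x k-measurements table.

    Degenerate tables (no variance anywhere) return NaN.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an (n >= 2) x (k >= 2) table")
    if not np.all(np.isfinite(x)):
        raise ValueError("table contains missing or non-finite cells")
    return float(_icc_2_1_stack(x[None, :, :])[0])


def _icc_2_1_stack(tables: np.ndarray) -> np.ndarray:
    """Vectorized ICC(2,1) over a (m, n, k) stack of tables."""
    m, n, k = tables.shape
    grand = tables.mean(axis=(1, 2), keepdims=True)
    row = tables.mean(axis=2, keepdims=True)
    col = tables.mean(axis=1, keepdims=True)
    ssr = k * ((row - grand) ** 2).sum(axis=(1, 2))
    ssc = n * ((col - grand) ** 2).sum(axis=(1, 2))
    sse = ((tables - row - col + grand) ** 2).sum(axis=(1, 2))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    out = np.full(m, np.nan)
    ok = np.abs(denom) > 1e-30
    out[ok] = (msr[ok] - mse[ok]) / denom[ok]
    return out


def edgewise_icc(dataset: SplitHalfDataset) -> np.ndarray:
    """Edge-level ICC(2,1) matrix (nodes x nodes, NaN diagonal).

    Each edge contributes an n_subjects x 2 table (half A, half B).
    """
    if dataset.n_subjects < 2:
        raise ValueError("need >= 2 subjects for ICC")
    ea, eb = dataset.edges()
    tables = np.stack([ea.T, eb.T], axis=2)  # (edges, subjects, 2)
    vals = _icc_2_1_stack(tables)
    return devectorize_upper(vals, dataset.n_nodes)


def _network_blocks(node_ids: Sequence, labels: Mapping[str, str], min_nodes: int = 2):
    """Network order plus per-network node indices; small networks dropped."""
    order = []
    for nid in node_ids:
        lab = labels[nid]
        if lab not in order:
            order.append(lab)
    idx = {
        lab: np.array([i for i, nid in enumerate(node_ids) if labels[nid] == lab])
        for lab in order
    }
    kept = [lab for lab in order if idx[lab].size >= min_nodes]
    dropped = [lab for lab in order if idx[lab].size < min_nodes]
    if dropped:
        warnings.warn(
            f"networks with < {min_nodes} nodes excluded: {dropped}", UserWarning
        )
    return kept, idx


def _block_mask(n_nodes: int, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
    mask = np.zeros((n_nodes, n_nodes), dtype=bool)
    mask[np.ix_(ia, ib)] = True
    mask[np.ix_(ib, ia)] = True
    np.fill_diagonal(mask, False)
    return np.triu(mask, k=1)


def network_icc_pre_average(
    dataset: SplitHalfDataset, labels: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """ICC of network-block-averaged edges (averaging *before* ICC).

    Per subject and half, Fisher-z edges are averaged within each network-pair
    block; the ICC across subjects of those block means is returned as a
    networks x networks DataFrame. Networks with fewer than two nodes are
    excluded (their diagonal block has no edge).
    """
    labels = labels or dataset.network_labels
    if labels is None:
        raise ValueError("network labels required")
    nets, idx = _network_blocks(dataset.node_ids, labels)
    n = dataset.n_nodes
    out = pd.DataFrame(np.nan, index=nets, columns=nets)
    iu = np.triu_indices(n, k=1)
    ea, eb = dataset.edges()
    for i, na in enumerate(nets):
        for nb in nets[i:]:
            sel = _block_mask(n, idx[na], idx[nb])[iu]
            if not sel.any():
                continue
            table = np.stack([ea[:, sel].mean(axis=1), eb[:, sel].mean(axis=1)], axis=1)
            val = _icc_2_1_stack(table[None, :, :])[0]
            out.loc[na, nb] = out.loc[nb, na] = val
    return out


def network_icc_post_average(
    edge_icc: np.ndarray,
    node_ids: Sequence,
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Mean of edge-level ICC values within each network-pair block."""
    nets, idx = _network_blocks(node_ids, labels)
    n = len(node_ids)
    iu = np.triu_indices(n, k=1)
    edge_vals = np.asarray(edge_icc, dtype=float)[iu]
    out = pd.DataFrame(np.nan, index=nets, columns=nets)
    for i, na in enumerate(nets):
        for nb in nets[i:]:
            sel = _block_mask(n, idx[na], idx[nb])[iu]
            if not sel.any():
                continue
            out.loc[na, nb] = out.loc[nb, na] = float(edge_vals[sel].mean())
    return out


def parcelwise_mean_icc(edge_icc: np.ndarray) -> np.ndarray:
    """Per-node mean of edge ICC over the node's N-1 connections."""
    m = np.asarray(edge_icc, dtype=float)
    off = ~np.eye(m.shape[0], dtype=bool)
    with np.errstate(invalid="ignore"):
        return np.array([np.nanmean(m[i, off[i]]) for i in range(m.shape[0])])


def parcelwise_trc(dataset: SplitHalfDataset) -> pd.DataFrame:
    """Per-node split-half test-retest correlation, averaged within groups.

    For each subject and node, the node's half-A connectivity row (self-
    connection excluded) is Pearson-correlated with its half-B row; rows of
    the result are nodes, columns are group means. Group-difference maps are
    column subtractions and are antisymmetric under swapping the groups.
    """
    n_sub, n = dataset.n_subjects, dataset.n_nodes
    per_subject = np.zeros((n_sub, n))
    off = ~np.eye(n, dtype=bool)
    for s in range(n_sub):
        a, b = dataset.half_a[s], dataset.half_b[s]
        for i in range(n):
            ra, rb = a[i, off[i]], b[i, off[i]]
            sa, sb = ra.std(), rb.std()
            per_subject[s, i] = (
                np.corrcoef(ra, rb)[0, 1] if sa > 0 and sb > 0 else np.nan
            )
    groups = np.array(dataset.groups)
    cols = {}
    for g in dict.fromkeys(dataset.groups):
        cols[g] = np.nanmean(per_subject[groups == g], axis=0)
    return pd.DataFrame(cols, index=list(dataset.node_ids))


def bin_icc(value: float) -> str:
    """Categorize an ICC value: poor / fair / good / excellent.

    Contiguous bins covering the whole line: poor (ICC <= 0.4, including
    negatives), fair (0.4, 0.6), good [0.6, 0.75), excellent [0.75, ...).
    """
    v = float(value)
    if math.isnan(v):
        raise ValueError("cannot bin a NaN ICC value")
    if v <= 0.4:
        return "poor"
    if v < 0.6:
        return "fair"
    if v < 0.75:
        return "good"
    return "excellent"


def bin_icc_matrix(m: np.ndarray) -> np.ndarray:
    """Elementwise :func:`bin_icc`; NaN entries (the diagonal) map to ''."""
    m = np.asarray(m, dtype=float)
    out = np.empty(m.shape, dtype=object)
    it = np.nditer(m, flags=["multi_index"])
    for v in it:
        out[it.multi_index] = "" if math.isnan(float(v)) else bin_icc(float(v))
    return out


def network_icc_by_duration(
    datasets: Mapping[tuple, SplitHalfDataset],
    networks: Sequence[str],
    durations: Sequence[float] = (5, 10, 24, 54),
    labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mean within-network ICC per group and split-half duration.

    ``datasets`` maps (group, duration_minutes) to a split-half dataset for
    that group; (group, duration) combinations missing from the mapping (e.g.
    a high-motion group lacking long-duration data) are skipped with a
    warning. Returns a long-format table (group, network, duration_min,
    mean_icc) where mean_icc averages the edge ICC values of the network's
    diagonal block.
    """
    rows = []
    groups = sorted({g for g, _ in datasets})
    for g in groups:
        for t in durations:
            ds = datasets.get((g, t))
            if ds is None:
                warnings.warn(
                    f"no split-half data for group {g!r} at {t} min; skipped",
                    UserWarning,
                )
                continue
            labs = labels or ds.network_labels
            post = network_icc_post_average(edgewise_icc(ds), ds.node_ids, labs)
            for net in networks:
                if net in post.index:
                    rows.append(
                        {
                            "group": g,
                            "network": net,
                            "duration_min": t,
                            "mean_icc": float(post.loc[net, net]),
                        }
                    )
    return pd.DataFrame(rows)
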