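"""Fisher-z Pearson connectomes from parcellated BOLD time series.

A connectome here is the node-by-node matrix of Fisher-z-transformed Pearson
correlations computed over the retained (post-censored) volumes of one or more
concatenated runs. Edge vectors are the canonical row-major upper-triangle
flattening, which every reliability statistic downstream consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .motion import CensorMask, FDTrace

_CLIP = 1.0 - 1e-7


@dataclass
class ParcellatedTimeseries:
    """One run's node x volume signal matrix plus its FD trace and identifiers."""

    subject_id: str
    session: int
    condition: str
    run: int
    signal: np.ndarray  # (nodes, volumes)
    node_ids: tuple
    tr_seconds: float
    fd: FDTrace

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a (nodes, volumes) matrix")
        if len(self.node_ids) != self.signal.shape[0]:
            raise ValueError("node_ids length must match signal rows")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        if self.fd.n_volumes != self.signal.shape[1]:
            raise ValueError("FD trace length must match volume count")

    @property
    def n_nodes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectome; the diagonal is excluded (NaN)."""

    z: np.ndarray
    node_ids: tuple
    n_volumes_used: int
    network_labels: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("connectome must be square")
        off = ~np.eye(z.shape[0], dtype=bool)
        if not np.all(np.isfinite(z[off])):
            raise ValueError("off-diagonal entries must be finite")
        if not np.allclose(z[off], z.T[off], atol=1e-10):
            raise ValueError("connectome must be symmetric")
        self.z = z

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]


def concat_censored(
    runs: Sequence[ParcellatedTimeseries],
    masks: Sequence[CensorMask] | None = None,
) -> np.ndarray:
    """Concatenate retained volumes of several runs into one node x volume matrix.

    Volumes keep their acquisition order within each run, and runs keep the
    order given. ``masks=None`` retains everything. An all-censored input
    yields a 0-column matrix (callers must check before correlating).
    """
    if not runs:
        raise ValueError("no runs supplied")
    node_ids = runs[0].node_ids
    for r in runs[1:]:
        if r.node_ids != node_ids:
            raise ValueError(
                f"node set mismatch between runs ({r.subject_id} ses {r.session})"
            )
    if masks is None:
        pieces = [r.signal for r in runs]
    else:
        if len(masks) != len(runs):
            raise ValueError("one mask per run required")
        pieces = []
        for r, m in zip(runs, masks):
            if m.n_volumes != r.n_volumes:
                raise ValueError("mask length must match run volume count")
            pieces.append(r.signal[:, m.kept])
    return np.concatenate(pieces, axis=1)


def pearson_fc(data: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix over volumes (columns) of a node x volume matrix."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("need a (nodes, volumes) matrix with >= 3 volumes")
    flat = np.nonzero(np.ptp(data, axis=1) == 0)[0]
    if flat.size:
        raise ValueError(f"zero-variance node(s) at index: {flat.tolist()}")
    r = np.corrcoef(data)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def fisher_z(r):
    """Fisher z-transform, ``z = atanh(r)``.

    Correlations at exactly +/-1 (possible on tiny inputs) are clipped to
    +/-(1 - 1e-7) with a warning rather than raising, so that toy examples run.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn(
            "correlation magnitude >= 1 clipped before Fisher z", RuntimeWarning
        )
        r = np.clip(r, -_CLIP, _CLIP)
    return np.arctanh(r)


def fc_matrix(
    data: np.ndarray,
    node_ids: Sequence | None = None,
    network_labels: Mapping | None = None,
) -> ConnectivityMatrix:
    """Fisher-z connectome of a node x volume matrix (diagonal set to NaN)."""
    r = pearson_fc(data)
    off = ~np.eye(r.shape[0], dtype=bool)
    z = np.full_like(r, np.nan)
    z[off] = fisher_z(r[off])
    if node_ids is None:
        node_ids = tuple(range(r.shape[0]))
    return ConnectivityMatrix(
        z, tuple(node_ids), n_volumes_used=data.shape[1], network_labels=network_labels
    )


def vectorize_upper(m: np.ndarray | ConnectivityMatrix) -> np.ndarray:
    """Row-major upper-triangle (i < j) edge vector of a symmetric matrix."""
    z = m.z if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("matrix must be square")
    iu = np.triu_indices(z.shape[0], k=1)
    if not np.allclose(
        np.nan_to_num(z[iu]), np.nan_to_num(z.T[iu]), atol=1e-8
    ):
        raise ValueError("matrix is not symmetric")
    return z[iu]


def devectorize_upper(edges: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; the diagonal comes back as NaN."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape[0] != n_nodes * (n_nodes - 1) // 2:
        raise ValueError("edge vector length does not match node count")
    m = np.full((n_nodes, n_nodes), np.nan)
    iu = np.triu_indices(n_nodes, k=1)
    m[iu] = edges
    m[(iu[1], iu[0])] = edges
    return m


def edge_index_map(n_nodes: int) -> list[tuple[int, int]]:
    """Edge position -> (i, j) node pair, matching :func:`vectorize_upper` order."""
    iu = np.triu_indices(n_nodes, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def tmean(data: np.ndarray) -> np.ndarray:
    """Per-node temporal mean signal (the numerator of tSNR)."""
    data = np.asarray(data, dtype=float)
    return data.mean(axis=1)


def tsd(data: np.ndarray) -> np.ndarray:
    """Per-node temporal standard deviation (sample SD; the denominator of tSNR)."""
    data = np.asarray(data, dtype=float)
    if data.shape[1] < 2:
        raise ValueError("need >= 2 volumes for a temporal SD")
    return data.std(axis=1, ddof=1)


def nodewise_regression(y: np.ndarray, x: np.ndarray):
    """OLS of a per-node outcome on a per-node predictor.

    Descriptive utility for relating regional reliability differences to signal
    quality (e.g., delta test-retest correlation vs delta temporal mean).
    Returns the scipy ``LinregressResult`` (slope, intercept, rvalue, pvalue, ...).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("x and y must be the same length")
    return stats.linregress(x, y)
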