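"""Template matching of nodes to canonical functional networks.

Each node's connectivity profile (its Fisher-z connectome row, self-connection
excluded) is compared against binary network-membership templates; the node is
assigned the best-matching network. Group-consensus maps keep only nodes whose
assignment agrees across a threshold fraction of subjects (66% or 75%), and an
analysis filter drops unlabeled nodes and networks left with fewer than two
nodes (network averages need at least two members).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix


@dataclass(frozen=True)
class NetworkTemplate:
    """Binary node-membership vectors, one per canonical network name."""

    membership: Mapping[str, np.ndarray]
    node_ids: tuple

    def __post_init__(self) -> None:
        for name, vec in self.membership.items():
            v = np.asarray(vec)
            if v.shape != (len(self.node_ids),):
                raise ValueError(f"template {name!r} length mismatch")
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"template {name!r} must be binary")

    @property
    def names(self) -> tuple:
        return tuple(self.membership)


def templates_from_labels(
    labels: Mapping[str, str], node_ids: Sequence | None = None
) -> NetworkTemplate:
    """One binary template per network in a node -> network label map."""
    node_ids = tuple(node_ids if node_ids is not None else labels.keys())
    names = list(dict.fromkeys(labels[n] for n in node_ids))
    membership = {
        name: np.array([1 if labels[n] == name else 0 for n in node_ids])
        for name in names
    }
    return NetworkTemplate(membership, node_ids)


def _eta_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's eta^2 similarity between two profiles (1 = identical)."""
    m = (a + b) / 2.0
    grand = m.mean()
    ss_within = ((a - m) ** 2).sum() + ((b - m) ** 2).sum()
    ss_total = ((a - grand) ** 2).sum() + ((b - grand) ** 2).sum()
    if ss_total == 0:
        return np.nan
    return 1.0 - ss_within / ss_total


def template_match(
    fc: ConnectivityMatrix,
    templates: NetworkTemplate,
    metric: str = "correlation",
) -> pd.DataFrame:
    """Assign each node to its best-matching network template.

    Similarity is the Pearson correlation (default) or eta^2 between the
    node's connectivity row and each binary membership vector, both with the
    self-connection excluded. Ties go to the first network in template order
    (warned); nodes with no scorable template are unassigned, unless a single
    template exists, in which case it wins by default. Returns a DataFrame
    indexed by node with columns ``network`` and ``score``.
    """
    if tuple(fc.node_ids) != tuple(templates.node_ids):
        raise ValueError("FC node set must match the template node set")
    if metric not in ("correlation", "eta2"):
        raise ValueError("metric must be 'correlation' or 'eta2'")
    n = fc.n_nodes
    names = templates.names
    assigned, scores = [], []
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        profile = fc.z[i, off[i]]
        best_name, best_score = None, -np.inf
        tie = False
        for name in names:
            vec = np.asarray(templates.membership[name], dtype=float)[off[i]]
            if metric == "correlation":
                s = (
                    np.corrcoef(profile, vec)[0, 1]
                    if profile.std() > 0 and vec.std() > 0
                    else np.nan
                )
            else:
                zvec = (vec - vec.mean()) / vec.std() if vec.std() > 0 else None
                zprof = (
                    (profile - profile.mean()) / profile.std()
                    if profile.std() > 0
                    else None
                )
                s = (
                    _eta_squared(zprof, zvec)
                    if zvec is not None and zprof is not None
                    else np.nan
                )
            if np.isnan(s):
                continue
            if s > best_score:
                best_name, best_score, tie = name, s, False
            elif s == best_score:
                tie = True
        if best_name is None:
            if len(names) == 1:
                best_name, best_score = names[0], np.nan
            else:
                warnings.warn(
                    f"node {fc.node_ids[i]!r} has no scorable template; unassigned",
                    UserWarning,
                )
        if tie:
            warnings.warn(
                f"tie at node {fc.node_ids[i]!r}; first network in order kept",
                UserWarning,
            )
        assigned.append(best_name)
        scores.append(best_score if best_name is not None else np.nan)
    return pd.DataFrame(
        {"network": assigned, "score": scores}, index=list(fc.node_ids)
    )


def group_overlap(
    assignments: Sequence[pd.DataFrame], threshold: float = 0.66
) -> pd.DataFrame:
    """Consensus node -> network map across subjects.

    A node receives a network label iff at least ``threshold`` of subjects
    assigned it that network; otherwise it is unassigned (None). The winning
    fraction is reported per node.
    """
    if len(assignments) < 2:
        raise ValueError("need >= 2 subjects for a consensus map")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    index = assignments[0].index
    for a in assignments[1:]:
        if not a.index.equals(index):
            raise ValueError("assignments must share a node set")
    n_sub = len(assignments)
    labels, fracs = [], []
    for node in index:
        votes = pd.Series(
            [a.loc[node, "network"] for a in assignments]
        ).dropna()
        if votes.empty:
            labels.append(None)
            fracs.append(0.0)
            continue
        top = votes.value_counts()
        frac = top.iloc[0] / n_sub
        labels.append(top.index[0] if frac >= threshold else None)
        fracs.append(float(frac))
    return pd.DataFrame({"network": labels, "overlap": fracs}, index=index)


def filter_networks_for_analysis(
    consensus: pd.DataFrame, min_nodes_per_network: int = 2
) -> tuple[list, list, dict]:
    """Final analysis node and network sets from a consensus map.

    Drops unlabeled nodes, then drops networks with fewer than
    ``min_nodes_per_network`` surviving nodes (and their nodes from the
    network-level set). Returns (kept nodes, kept networks, exclusion log).
    """
    labeled = consensus[consensus["network"].notna()]
    dropped_nodes = [n for n in consensus.index if n not in labeled.index]
    sizes = labeled["network"].value_counts()
    kept_networks = [
        n for n in dict.fromkeys(labeled["network"]) if sizes[n] >= min_nodes_per_network
    ]
    dropped_networks = [n for n in sizes.index if n not in kept_networks]
    kept_nodes = [
        n for n in labeled.index if labeled.loc[n, "network"] in kept_networks
    ]
    log = {
        "nodes_dropped_no_consensus": dropped_nodes,
        "networks_dropped_undersized": dropped_networks,
        "nodes_dropped_with_network": [
            n for n in labeled.index if n not in kept_nodes
        ],
    }
    return kept_nodes, kept_networks, log
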