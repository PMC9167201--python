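"""Shortest-path subnetworks and per-sample branch sums.

A subnetwork summarises how signal travels from one receptor to its most
discriminative TFs.  Path topology is computed once from *reference* node
weights — the per-gene t50 averaged over a chosen sample subset — and then
held fixed, so that per-sample branch sums are comparable across patients.
The cost of a path is the sum of the node weights over its non-source
nodes (the receptor is the injection point and is excluded); Dijkstra runs
on the equivalent edge cost (w_u + w_v) / 2 with endpoint halves corrected,
and ties are broken by the lexicographically smallest node sequence.

For each sample, the branch sum is the sum of that sample's gene t50 values
over a branch's non-source nodes; the per-sample mean over branches is the
patient-level pathway-speed summary compared between response groups
(non-responders, whose signalling is faster, show lower branch sums).
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .diffusion import DiffusionProfile
from .exceptions import UnknownGeneError
from .stratify import wilcoxon_groups

logger = logging.getLogger(__name__)


@dataclass
class Subnetwork:
    """Shortest-path branches from one receptor to its top TFs."""

    receptor: str
    branches: list[tuple[str, tuple[str, ...]]]  # (tf, node path receptor -> tf)
    node_weights: dict[str, float]

    @property
    def nodes(self) -> set[str]:
        return {n for _, path in self.branches for n in path}

    def to_graph(self, network: nx.Graph) -> nx.Graph:
        """Subgraph induced by the branches, annotated for GraphML export."""
        g = nx.Graph()
        for tf, path in self.branches:
            for node in path:
                g.add_node(node, role=network.nodes[node].get("role", ""),
                           reference_weight=float(self.node_weights[node]))
            for u, v in zip(path, path[1:]):
                g.add_edge(u, v)
                g.edges[u, v].setdefault("branches", "")
            for u, v in zip(path, path[1:]):
                tag = g.edges[u, v]["branches"]
                g.edges[u, v]["branches"] = f"{tag},{tf}" if tag else tf
        return g


def reference_node_weights(
    profile: DiffusionProfile,
    receptor: str,
    samples: list[str] | None = None,
) -> dict[str, float]:
    """Per-gene mean t50 over a sample subset for one source receptor.

    Sentinel (unreached) values are excluded from the mean; a gene at the
    sentinel in every selected sample keeps the sentinel as its weight, so
    it can never undercut a finite path.
    """
    if receptor not in profile.receptors:
        raise UnknownGeneError(f"{receptor!r} is not a profiled receptor")
    frame = profile.gene_frame(receptor)
    if samples is not None:
        if len(samples) == 0:
            raise ValueError("sample subset is empty")
        frame = frame.loc[list(samples)]
    values = frame.to_numpy(dtype=float)
    finite = values < profile.sentinel
    with np.errstate(invalid="ignore"):
        means = np.where(finite.any(axis=0),
                         np.nansum(np.where(finite, values, np.nan), axis=0)
                         / np.maximum(finite.sum(axis=0), 1),
                         float(profile.sentinel))
    return dict(zip(frame.columns, means))


def _edge_transform_cost(path: tuple[str, ...], weights: dict[str, float]) -> float:
    """Path cost via the half-weight edge transformation: each edge costs
    (w_u + w_v)/2; adding half the terminal weight and removing half the
    source weight makes the total equal the plain node sum over non-source
    nodes."""
    edge_total = sum((weights[u] + weights[v]) / 2.0 for u, v in zip(path, path[1:]))
    return edge_total - weights[path[0]] / 2.0 + weights[path[-1]] / 2.0


def shortest_path_subnetwork(
    network: nx.Graph,
    weights: dict[str, float],
    receptor: str,
    tfs: list[str],
) -> Subnetwork:
    """Node-weighted shortest path from the receptor to each TF.

    Path cost is the sum of node weights over non-source nodes; equal-cost
    paths resolve to the lexicographically smallest node sequence.  TFs that
    cannot be reached are omitted (logged).
    """
    if not tfs:
        raise ValueError("empty TF list")
    if receptor not in network:
        raise UnknownGeneError(f"receptor {receptor!r} not in network")
    if receptor in tfs:
        raise ValueError("receptor and TF coincide; zero-length branch")
    missing = sorted(n for n in network.nodes if n not in weights)
    if missing:
        raise KeyError(f"node weights missing for: {missing}")

    # Dijkstra over (cost, path) so the heap's tuple order breaks cost ties
    # lexicographically by node sequence.
    best: dict[str, tuple[float, tuple[str, ...]]] = {}
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (receptor,))]
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node in best:
            continue
        best[node] = (cost, path)
        for nbr in sorted(network.neighbors(node)):
            if nbr not in best:
                heapq.heappush(heap, (cost + float(weights[nbr]), path + (nbr,)))

    branches = []
    for tf in tfs:
        if tf not in best:
            logger.warning("TF %s unreachable from %s; branch omitted", tf, receptor)
            continue
        cost, path = best[tf]
        transformed = _edge_transform_cost(path, weights)
        node_sum = sum(float(weights[n]) for n in path[1:])
        if not np.isclose(transformed, node_sum, rtol=1e-9, atol=1e-9) or \
           not np.isclose(cost, node_sum, rtol=1e-9, atol=1e-9):
            raise RuntimeError(
                f"path-cost bookkeeping mismatch on branch {receptor}->{tf}")
        branches.append((tf, path))
    return Subnetwork(receptor=receptor, branches=branches,
                      node_weights={n: float(weights[n]) for n in network.nodes})


def branch_sums(
    subnetwork: Subnetwork,
    profile: DiffusionProfile,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample, per-branch sum of gene t50 values over the branch's
    non-source nodes.  Branches containing only sentinel values for a sample
    yield ``len(branch) * sentinel`` and are flagged in the ``all_sentinel``
    column."""
    frame = profile.gene_frame(subnetwork.receptor)
    if samples is not None:
        frame = frame.loc[list(samples)]
    rows = []
    for tf, path in subnetwork.branches:
        missing = [n for n in path[1:] if n not in frame.columns]
        if missing:
            raise UnknownGeneError(f"branch genes absent from profile: {missing}")
        sub = frame[list(path[1:])].to_numpy(dtype=float)
        sums = sub.sum(axis=1)
        all_sentinel = (sub >= profile.sentinel).all(axis=1)
        for sample, total, flag in zip(frame.index, sums, all_sentinel):
            rows.append({"sample_id": sample, "tf": tf,
                         "branch_sum": float(total), "all_sentinel": bool(flag)})
    return pd.DataFrame(rows)


def mean_branch_sums(table: pd.DataFrame) -> pd.Series:
    """Per-sample mean branch sum across branches."""
    return table.groupby("sample_id", sort=True)["branch_sum"].mean()


def compare_branch_sums(table: pd.DataFrame, labels: pd.Series) -> dict:
    """Compare per-sample mean branch sums between two groups.

    ``labels`` maps sample_id -> group; exactly two groups must be present
    among the table's samples.  Returns the per-group medians and the
    two-sided Wilcoxon p-value.
    """
    means = mean_branch_sums(table)
    groups = labels.loc[means.index]
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValueError(f"need >= 2 groups, got {names}")
    if len(names) > 2:
        raise ValueError(f"expected two groups for comparison, got {names}")
    a = means[groups == names[0]].to_numpy()
    b = means[groups == names[1]].to_numpy()
    return {
        "groups": names,
        "medians": {names[0]: float(np.median(a)), names[1]: float(np.median(b))},
        "p_value": wilcoxon_groups(a, b),
        "n": {names[0]: int(a.size), names[1]: int(b.size)},
    }
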