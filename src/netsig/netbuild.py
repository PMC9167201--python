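"""Assembly of the role-annotated signalling network.

The signalling network is an undirected graph whose nodes are genes with one
of three mutually exclusive roles: ``receptor`` (cell-surface signal source),
``transducer`` (intermediate signalling protein) and ``tf`` (transcription
factor, the absorbing sink of the diffusion model).  The graph is cut out of
a generic protein-protein interaction (PPI) edge list by restricting to a
gene universe (typically GO-term derived gene sets plus the declared
receptors and TFs), removing promiscuous hub genes (TP53, UBC, heat-shock
proteins and the like), and pruning receptors/TFs that cannot reach the
opposite role.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import networkx as nx
import pandas as pd

from .exceptions import NetworkBuildError

logger = logging.getLogger(__name__)

#: Node-role attribute values used throughout the package.
RECEPTOR = "receptor"
TRANSDUCER = "transducer"
TF = "tf"
ROLES = (RECEPTOR, TRANSDUCER, TF)


def _edge_pairs(ppi) -> list[tuple[str, str]]:
    """Normalise a PPI input (DataFrame with >=2 columns, or an iterable of
    pairs) to a list of string 2-tuples."""
    if isinstance(ppi, pd.DataFrame):
        return [(str(u), str(v)) for u, v in ppi.iloc[:, :2].itertuples(index=False)]
    return [(str(u), str(v)) for u, v in ppi]


def assemble_network(
    ppi,
    receptors: Iterable[str],
    tfs: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]] | None = None,
    blacklist: Iterable[str] = (),
    *,
    prefer_receptor: bool = False,
) -> nx.Graph:
    """Build the role-annotated signalling network.

    Parameters
    ----------
    ppi
        Protein-protein interaction edges: a DataFrame whose first two
        columns are gene identifiers, or an iterable of ``(u, v)`` pairs.
        Edges are undirected; duplicates are collapsed, self-loops dropped.
    receptors, tfs
        Declared role gene lists.  A gene in both lists raises ``ValueError``
        unless ``prefer_receptor`` is set, in which case the receptor role
        wins.
    gene_sets
        Optional mapping of set name -> member genes (e.g. parsed GMT).  When
        given, the node universe is the union of all sets plus the receptor
        and TF lists; when ``None``, no restriction is applied and the
        universe is every PPI gene plus receptors and TFs.
    blacklist
        Hub genes removed from the universe together with their edges.

    Returns
    -------
    networkx.Graph
        Nodes carry a ``role`` attribute; edges carry ``source="ppi"``.
        Receptors with no path to any TF (and vice versa) are dropped; the
        per-stage accounting is stored in ``G.graph["prune_report"]``.
    """
    receptors = {str(g) for g in receptors}
    tfs = {str(g) for g in tfs}
    blacklist = {str(g) for g in blacklist}

    overlap = receptors & tfs
    if overlap:
        if prefer_receptor:
            logger.warning("genes in both receptor and TF lists kept as receptors: %s",
                           sorted(overlap))
            tfs -= overlap
        else:
            raise ValueError(
                f"genes declared both receptor and TF: {sorted(overlap)}; "
                "pass prefer_receptor=True to resolve")

    pairs = _edge_pairs(ppi)
    if gene_sets is None:
        universe = {g for uv in pairs for g in uv} | receptors | tfs
    else:
        universe = set().union(*(set(map(str, s)) for s in gene_sets.values())) \
            if gene_sets else set()
        universe |= receptors | tfs
    universe -= blacklist

    g = nx.Graph()
    g.add_nodes_from(universe)
    n_edges_in = len(pairs)
    for u, v in pairs:
        if u == v or u not in universe or v not in universe:
            continue
        g.add_edge(u, v, source="ppi")

    for node in g.nodes:
        if node in receptors:
            g.nodes[node]["role"] = RECEPTOR
        elif node in tfs:
            g.nodes[node]["role"] = TF
        else:
            g.nodes[node]["role"] = TRANSDUCER

    # A receptor is useful only if some TF shares its connected component,
    # and symmetrically for TFs (edges are undirected, so component
    # membership is exactly finite hop distance).
    comp_id: dict[str, int] = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_id[node] = i
    comp_has_tf = {comp_id[n] for n in g.nodes if g.nodes[n]["role"] == TF and g.degree[n] > 0}
    comp_has_rec = {comp_id[n] for n in g.nodes if g.nodes[n]["role"] == RECEPTOR and g.degree[n] > 0}
    dropped_receptors = sorted(
        n for n in g.nodes
        if g.nodes[n]["role"] == RECEPTOR and comp_id[n] not in comp_has_tf)
    dropped_tfs = sorted(
        n for n in g.nodes
        if g.nodes[n]["role"] == TF and comp_id[n] not in comp_has_rec)
    if dropped_receptors:
        logger.warning("receptors with no path to any TF dropped: %s", dropped_receptors)
    if dropped_tfs:
        logger.warning("TFs with no path from any receptor dropped: %s", dropped_tfs)
    g.remove_nodes_from(dropped_receptors + dropped_tfs)

    g.graph["prune_report"] = {
        "ppi_edges_in": n_edges_in,
        "universe_size": len(universe),
        "blacklisted": sorted(blacklist),
        "dropped_receptors": dropped_receptors,
        "dropped_tfs": dropped_tfs,
        "nodes": g.number_of_nodes(),
        "edges": g.number_of_edges(),
    }
    if g.number_of_edges() == 0:
        raise NetworkBuildError(
            f"network empty after filtering; diagnostics: {g.graph['prune_report']}")
    return g


def nodes_with_role(network: nx.Graph, role: str) -> list[str]:
    """Sorted node ids carrying the given role."""
    return sorted(n for n, r in network.nodes(data="role") if r == role)


def network_report(network: nx.Graph) -> dict:
    """Summary counts: nodes, edges, per-role counts and the receptor x TF
    pair count (product over retained role nodes)."""
    n_rec = len(nodes_with_role(network, RECEPTOR))
    n_tf = len(nodes_with_role(network, TF))
    return {
        "nodes": network.number_of_nodes(),
        "edges": network.number_of_edges(),
        "receptors": n_rec,
        "transducers": len(nodes_with_role(network, TRANSDUCER)),
        "tfs": n_tf,
        "receptor_tf_pairs": n_rec * n_tf,
    }
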