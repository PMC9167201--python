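"""Per-sample signal diffusion and the t50 connectivity statistic.

The model quantifies how quickly signal injected at a cell-surface receptor
reaches each transcription factor through a patient's signalling network.
For one sample, every network edge (u, v) is weighted by the product of the
two genes' expression values, x_u * x_v.  A unit of signal mass is placed on
the source receptor and propagated as a discrete-time random walk: at each
step the mass sitting on a node moves to its neighbours in proportion to
edge weight (row-stochastic transition), transcription factors absorb
arriving mass permanently, and dead ends (nodes whose incident weights are
all zero, or isolated nodes) simply retain it.  The cumulative amount of
mass that has *arrived* at a gene by step t is a nondecreasing curve A_g(t)
with a finite limit; t50 is the first step at which this curve reaches half
of its final value:

    t50(g) = min { t >= 1 : A_g(t) >= 0.5 * A_g(t_stop) }

A lower t50 means faster connectivity from the receptor to the gene.  Genes
that never receive mass get a sentinel value of ``t_max + 1`` so that
"lower = faster" stays a total order.  Because the transition matrix is
row-normalised, multiplying all expression values by a positive constant
leaves every t50 unchanged.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import UnknownGeneError
from .netbuild import RECEPTOR, TF, nodes_with_role

logger = logging.getLogger(__name__)

#: Absolute slack when testing the half-maximum crossing; guards against
#: summation-order float noise flipping an exact boundary.
_CROSS_EPS = 1e-12


@dataclass(frozen=True)
class DiffusionConfig:
    """Parameters of the diffusion run.

    t_max
        Horizon, in steps.  With absorbing TFs the circulating mass decays
        geometrically, so 100 steps resolve any reachable t50 on networks of
        the sizes used here.
    mass_tol
        Early-stop threshold on the circulating (still moving) mass.
    """

    t_max: int = 100
    mass_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.mass_tol < 0:
            raise ValueError("mass_tol must be >= 0")

    @property
    def sentinel(self) -> int:
        """Unreachability marker, strictly larger than any finite t50."""
        return self.t_max + 1


def sample_edge_weights(network: nx.Graph, expression: Mapping[str, float]) -> nx.Graph:
    """Weight the network's edges with one sample's expression.

    ``w_uv = x_u * x_v`` for every edge.  Expression must cover every network
    gene and be nonnegative (normalised intensities; log-scale data must be
    shifted to a positive scale upstream).
    """
    missing = sorted(g for g in network.nodes if g not in expression)
    if missing:
        raise UnknownGeneError(f"expression missing for network genes: {missing}")
    negative = sorted(g for g in network.nodes if float(expression[g]) < 0)
    if negative:
        raise ValueError(f"negative expression for genes: {negative}")
    weighted = nx.Graph()
    weighted.add_nodes_from(network.nodes(data=True))
    for u, v in network.edges:
        weighted.add_edge(u, v, weight=float(expression[u]) * float(expression[v]))
    return weighted


@dataclass
class DiffusionResult:
    """Arrival curves of one diffusion run.

    arrivals[t, i] is the cumulative mass that has arrived at node
    ``nodes[i]`` by step t (t = 0 .. t_stop); the initial injection at the
    source does not count as an arrival.  ``mass_balance[t]`` is the total
    accounted mass (circulating + absorbed at TFs + held at dead ends),
    identically 1 up to float roundoff.
    """

    nodes: list[str]
    arrivals: np.ndarray
    t_stop: int
    mass_balance: np.ndarray

    def curve(self, node: str) -> np.ndarray:
        return self.arrivals[:, self.nodes.index(node)]


def _transition(weighted: nx.Graph, nodes: list[str]):
    """Row-stochastic transition matrix over non-absorbing, non-dead-end
    nodes, plus the movable mask."""
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    w = np.zeros((n, n))
    for u, v, d in weighted.edges(data=True):
        w[index[u], index[v]] = w[index[v], index[u]] = float(d.get("weight", 1.0))
    absorbing = np.array([weighted.nodes[g].get("role") == TF for g in nodes])
    out = w.sum(axis=1)
    movable = ~absorbing & (out > 0)
    p = np.zeros_like(w)
    p[movable] = w[movable] / out[movable, None]
    return p, movable


def diffuse(weighted: nx.Graph, source: str, cfg: DiffusionConfig | None = None) -> DiffusionResult:
    """Run one absorbing random walk from ``source`` and record per-node
    cumulative arrival curves.

    ``source`` must be a receptor node of the weighted graph.  If every edge
    at the source has zero weight the walk cannot start: all curves stay at
    zero (logged as a warning) and every t50 downstream is the sentinel.
    """
    cfg = cfg or DiffusionConfig()
    if source not in weighted:
        raise UnknownGeneError(f"source {source!r} not in network")
    if weighted.nodes[source].get("role") != RECEPTOR:
        raise ValueError(f"source {source!r} is not a receptor")

    nodes = sorted(weighted.nodes)
    n = len(nodes)
    p, movable = _transition(weighted, nodes)
    src = nodes.index(source)

    mass = np.zeros(n)
    mass[src] = 1.0
    stuck = np.zeros(n)  # absorbed at TFs or held at dead ends
    if not movable[src]:
        logger.warning("source %r has no positive-weight edge; all curves zero", source)
        stuck[src] = 1.0
        return DiffusionResult(nodes, np.zeros((1, n)), 0, np.ones(1))

    cumulative = np.zeros(n)
    arrivals = [cumulative.copy()]
    balance = [mass.sum() + stuck.sum()]
    t_stop = 0
    for t in range(1, cfg.t_max + 1):
        incoming = p.T @ mass  # mass is nonzero only on movable nodes
        cumulative = cumulative + incoming
        arrivals.append(cumulative.copy())
        stuck = stuck + np.where(movable, 0.0, incoming)
        mass = np.where(movable, incoming, 0.0)
        balance.append(mass.sum() + stuck.sum())
        t_stop = t
        if mass.sum() < cfg.mass_tol:
            break
    return DiffusionResult(nodes, np.asarray(arrivals), t_stop, np.asarray(balance))


def t50_from_curve(curve: np.ndarray, cfg: DiffusionConfig | None = None) -> int:
    """First step at which a cumulative arrival curve reaches half of its
    value at the stopping time; the sentinel when nothing ever arrived."""
    cfg = cfg or DiffusionConfig()
    curve = np.asarray(curve, dtype=float)
    if np.any(np.diff(curve) < -1e-9):
        raise RuntimeError("cumulative arrival curve is decreasing")
    total = curve[-1]
    if total <= 0.0:
        return cfg.sentinel
    crossed = np.nonzero(curve >= 0.5 * total - _CROSS_EPS)[0]
    t = int(crossed[0])
    return max(t, 1)


@dataclass
class DiffusionProfile:
    """t50 scores for a cohort: one diffusion run per (sample, receptor).

    gene_t50 has shape (n_samples, n_receptors, n_genes); pair_t50 is its
    restriction to TF target genes, kept as a separate array so the two
    views can be cross-checked.
    """

    sample_ids: list[str]
    receptors: list[str]
    tfs: list[str]
    genes: list[str]
    gene_t50: np.ndarray
    pair_t50: np.ndarray  # (n_samples, n_receptors * n_tfs), pair-major by (receptor, tf)
    sentinel: int
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairs:
            self.pairs = [(r, f) for r in self.receptors for f in self.tfs]

    @property
    def pair_frame(self) -> pd.DataFrame:
        """samples x pairs DataFrame with ``RECEPTOR__TF`` column names."""
        cols = [f"{r}__{f}" for r, f in self.pairs]
        return pd.DataFrame(self.pair_t50, index=self.sample_ids, columns=cols)

    def gene_frame(self, receptor: str) -> pd.DataFrame:
        """samples x genes t50 values for one source receptor."""
        i = self.receptors.index(receptor)
        return pd.DataFrame(self.gene_t50[:, i, :], index=self.sample_ids,
                            columns=self.genes)


def compute_t50_profile(
    network: nx.Graph,
    expression: pd.DataFrame,
    cfg: DiffusionConfig | None = None,
) -> DiffusionProfile:
    """Diffuse from every receptor in every sample and extract t50.

    ``expression`` is genes x samples and must cover all network genes.
    The result is independent of sample and receptor iteration order.
    """
    cfg = cfg or DiffusionConfig()
    receptors = nodes_with_role(network, RECEPTOR)
    tfs = nodes_with_role(network, TF)
    genes = sorted(network.nodes)
    samples = list(expression.columns)
    tf_pos = [genes.index(f) for f in tfs]

    gene_t50 = np.full((len(samples), len(receptors), len(genes)), cfg.sentinel,
                       dtype=np.int64)
    for si, sample in enumerate(samples):
        weighted = sample_edge_weights(network, expression[sample])
        for ri, receptor in enumerate(receptors):
            result = diffuse(weighted, receptor, cfg)
            # result.nodes is sorted(network.nodes) == genes
            for gi in range(len(genes)):
                gene_t50[si, ri, gi] = t50_from_curve(result.arrivals[:, gi], cfg)
    pair_t50 = gene_t50[:, :, tf_pos].reshape(len(samples), -1)
    return DiffusionProfile(
        sample_ids=samples, receptors=receptors, tfs=tfs, genes=genes,
        gene_t50=gene_t50, pair_t50=pair_t50, sentinel=cfg.sentinel)
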