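"""End-to-end synthetic run: simulate -> preprocess -> diffuse -> rank ->
subnetwork -> group comparison.

This is the reference composition of the library modules and the backbone of
the command-line ``pipeline`` command.  The comparison cohort defaults to
week-0 biopsies, the setting in which therapy response is to be predicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .diffusion import DiffusionConfig, DiffusionProfile, compute_t50_profile
from .preprocess import NON_RESPONDER, RESPONDER, classify_samples, quantile_normalize
from .stratify import pair_auc, select_top_pairs
from .subnet import (Subnetwork, branch_sums, compare_branch_sums,
                     reference_node_weights, shortest_path_subnetwork)
from .synthetic import SyntheticDesign, generate_expression, generate_toy_network


@dataclass
class PipelineResult:
    network: nx.Graph
    expression: pd.DataFrame
    samples: pd.DataFrame
    profile: DiffusionProfile
    pair_table: pd.DataFrame
    receptor: str
    subnetwork: Subnetwork
    branch_table: pd.DataFrame
    comparison: dict


def run_pipeline(
    design: SyntheticDesign,
    *,
    cohort_seed: int | None = None,
    cfg: DiffusionConfig | None = None,
    quantile: bool = True,
    subset: str = "pre",
    receptor: str | None = None,
    top_tfs: int = 10,
) -> PipelineResult:
    """Run the full analysis on one synthetic cohort.

    Pair ranking uses the ``subset`` cohort (default week-0, the
    prediction-before-treatment setting).  The subnetwork receptor defaults
    to the receptor of the best-AUC pair; its branches go to the (up to)
    ``top_tfs`` highest-AUC TFs for that receptor.  Branch sums are computed
    and compared between responders and non-responders over *all* treated
    biopsies, the way the study presents per-group branch statistics.
    """
    cfg = cfg or DiffusionConfig()
    network = generate_toy_network(design)
    expression, samples = generate_expression(network, design, cohort_seed)
    if quantile:
        expression = quantile_normalize(expression)
    samples = classify_samples(samples)

    profile = compute_t50_profile(network, expression, cfg)
    pair_table = pair_auc(profile, samples, subset=subset)

    ranked = select_top_pairs(pair_table)
    if receptor is None:
        receptor = str(ranked.iloc[0]["receptor"])
    top = select_top_pairs(pair_table[pair_table["receptor"] == receptor], k=top_tfs)
    tfs = top["tf"].tolist()

    indexed = samples.set_index("sample_id")
    treated = indexed["response"].isin([RESPONDER, NON_RESPONDER])
    cohort = indexed.index[treated].tolist()

    weights = reference_node_weights(profile, receptor, samples=cohort)
    subnetwork = shortest_path_subnetwork(network, weights, receptor, tfs)
    branch_table = branch_sums(subnetwork, profile, samples=cohort)
    comparison = compare_branch_sums(branch_table, indexed["response"])
    return PipelineResult(
        network=network, expression=expression, samples=samples, profile=profile,
        pair_table=pair_table, receptor=receptor, subnetwork=subnetwork,
        branch_table=branch_table, comparison=comparison)
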