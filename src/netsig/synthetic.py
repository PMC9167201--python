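"""Synthetic cohorts with a planted fast-signalling pathway.

The generator emulates the statistical structure the downstream analysis
assumes: a layered receptor -> transducer -> TF signalling network, strictly
positive log-normal expression with sample-to-sample noise, a two-group
responder / non-responder design in which one receptor->TF path is
multiplicatively up-regulated in non-responders (making their signalling
faster, i.e. lower t50), a biopsy schedule with a week-0 sample plus
follow-ups per treated patient, and a pandaR-style TF -> target edge-score
table with a few designated strong regulators.

Node naming: receptors ``REC1..``, transducers ``SIG1..``, transcription
factors ``TF1..``.  A single integer seed drives independent hierarchical
substreams (network / expression / schedule) so each generator is
reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import GenerationError, InvalidDesignError, UnknownGeneError
from .netbuild import RECEPTOR, TF, TRANSDUCER
from .preprocess import CONTROL, NON_RESPONDER, RESPONDER

_STREAM_NETWORK, _STREAM_EXPRESSION, _STREAM_SCHEDULE = 0, 1, 2


@dataclass(frozen=True)
class SyntheticDesign:
    """Study conditions for one synthetic cohort.

    ``seed`` fixes the *biological system* — network geometry and per-gene
    baseline expression; a separate cohort seed (see
    :func:`generate_expression`) resamples patients, so replicate cohorts can
    be drawn from one fixed system the way a study would re-recruit patients.

    Defaults encode the package's reference conditions: a 3/30/3 layered
    network at edge density 0.1, a planted 4-gene cascade
    REC1-SIG1-SIG2-TF1 up-regulated 1.5-fold in non-responders, log-scale
    noise sd 0.1, and 20 + 20 treated patients.  Planted-path genes' baseline
    log-expression is anchored at ``planted_baseline`` (default 6.5, near
    the top of the U(2, 8) baseline range): the planted cascade must be a
    high-expression conduit, because a timing statistic cannot register an
    activity change on a pathway that carries no flux.
    ``schedule="table2"`` switches to the fixed biopsy schedule with
    27/14/12 patients and per-group biopsy totals 32/49/9/22/12.
    """

    n_receptors: int = 3
    n_transducers: int = 30
    n_tfs: int = 3
    edge_density: float = 0.1
    n_responders: int = 20
    n_nonresponders: int = 20
    n_controls: int = 0
    planted_path_genes: tuple[str, ...] = ("REC1", "SIG1", "SIG2", "TF1")
    effect_size: float = 1.5
    noise_sd: float = 0.1
    baseline_range: tuple[float, float] = (2.0, 8.0)
    planted_baseline: float | None = 6.5
    seed: int = 0
    schedule: str = "random"  # "random" | "table2"
    followup_weeks: tuple[int, ...] = (6, 12, 52)
    max_followups: int = 3
    max_attempts: int = 100

    def validate(self) -> None:
        if min(self.n_receptors, self.n_transducers, self.n_tfs) < 1:
            raise InvalidDesignError("network layer counts must all be >= 1")
        if not 0.0 < self.edge_density <= 1.0:
            raise InvalidDesignError("edge_density must be in (0, 1]")
        if self.effect_size < 1.0:
            raise InvalidDesignError("effect_size must be >= 1")
        if self.noise_sd < 0.0:
            raise InvalidDesignError("noise_sd must be >= 0")
        if self.baseline_range[0] >= self.baseline_range[1]:
            raise InvalidDesignError("baseline_range must be increasing")
        if self.schedule not in ("random", "table2"):
            raise InvalidDesignError(f"unknown schedule {self.schedule!r}")


def planted_preset(seed: int = 0, effect_size: float = 1.5) -> SyntheticDesign:
    """Reference planted-path design (effect 1.5, noise 0.1, n = 20 + 20)."""
    return SyntheticDesign(seed=seed, effect_size=effect_size)


def null_preset(seed: int = 0) -> SyntheticDesign:
    """Same design with no planted effect (effect_size = 1)."""
    return planted_preset(seed=seed, effect_size=1.0)


def table2_preset(seed: int = 0) -> SyntheticDesign:
    """Cohort matching the study's biopsy bookkeeping: 27 non-responders,
    14 responders, 12 controls, with fixed per-group biopsy totals."""
    return SyntheticDesign(seed=seed, n_responders=14, n_nonresponders=27,
                           n_controls=12, schedule="table2")


def _node_names(design: SyntheticDesign):
    receptors = [f"REC{i + 1}" for i in range(design.n_receptors)]
    transducers = [f"SIG{i + 1}" for i in range(design.n_transducers)]
    tfs = [f"TF{i + 1}" for i in range(design.n_tfs)]
    return receptors, transducers, tfs


def generate_toy_network(design: SyntheticDesign) -> nx.Graph:
    """Layered random signalling network.

    Candidate edges are receptor-transducer, transducer-transducer and
    transducer-TF pairs, each kept with probability ``edge_density``; the
    planted path's consecutive edges are always present.  Generation is
    retried with fresh substreams until the graph is connected (bounded by
    ``max_attempts``).
    """
    design.validate()
    receptors, transducers, tfs = _node_names(design)
    nodes = set(receptors + transducers + tfs)
    for g in design.planted_path_genes:
        if g not in nodes:
            raise InvalidDesignError(
                f"planted gene {g!r} not among generated node names")

    candidates = (
        [(r, s) for r in receptors for s in transducers]
        + [(a, b) for i, a in enumerate(transducers) for b in transducers[i + 1:]]
        + [(s, f) for s in transducers for f in tfs]
    )
    seed_seq = np.random.SeedSequence([int(design.seed), _STREAM_NETWORK])
    for child in seed_seq.spawn(design.max_attempts):
        rng = np.random.default_rng(child)
        keep = rng.random(len(candidates)) < design.edge_density
        g = nx.Graph()
        for name in receptors:
            g.add_node(name, role=RECEPTOR)
        for name in transducers:
            g.add_node(name, role=TRANSDUCER)
        for name in tfs:
            g.add_node(name, role=TF)
        g.add_edges_from(e for e, k in zip(candidates, keep) if k)
        g.add_edges_from(zip(design.planted_path_genes, design.planted_path_genes[1:]))
        if nx.is_connected(g):
            return g
    raise GenerationError(
        f"no connected network in {design.max_attempts} attempts at "
        f"density {design.edge_density}")


def _random_schedule(design: SyntheticDesign, rng: np.random.Generator):
    """One week-0 biopsy per patient; treated patients add 1..max_followups
    follow-up biopsies at distinct weeks."""
    rows = []
    groups = [(RESPONDER, "RESP", design.n_responders),
              (NON_RESPONDER, "NR", design.n_nonresponders),
              (CONTROL, "CTRL", design.n_controls)]
    for response, prefix, count in groups:
        for i in range(count):
            patient = f"{prefix}{i + 1:02d}"
            rows.append((f"{patient}_W0", patient, 0, response))
            if response == CONTROL:
                continue
            k = int(rng.integers(1, design.max_followups + 1))
            k = min(k, len(design.followup_weeks))
            weeks = sorted(rng.choice(design.followup_weeks, size=k, replace=False))
            rows.extend((f"{patient}_W{w}", patient, int(w), response) for w in weeks)
    return rows


def _table2_schedule(design: SyntheticDesign):
    """Fixed biopsy schedule reproducing the per-group totals 32 pre- and 49
    post-treatment non-responder biopsies (27 patients), 9 pre- and 22
    post-treatment responder biopsies (14 patients) and 12 control biopsies.
    Requires the 27/14/12 patient counts of :func:`table2_preset`."""
    if (design.n_nonresponders, design.n_responders, design.n_controls) != (27, 14, 12):
        raise InvalidDesignError("table2 schedule requires 27/14/12 patients")
    weeks = [6, 12, 52]
    rows = []
    for i in range(27):  # non-responders: 32 W0 biopsies, 49 follow-ups
        patient = f"NR{i + 1:02d}"
        rows.append((f"{patient}_W0", patient, 0, NON_RESPONDER))
        if i < 32 - 27:
            rows.append((f"{patient}_W0b", patient, 0, NON_RESPONDER))
        w = weeks[i % 3]
        rows.append((f"{patient}_W{w}", patient, w, NON_RESPONDER))
        if i < 49 - 27:
            w2 = weeks[(i + 1) % 3]
            rows.append((f"{patient}_W{w2}", patient, w2, NON_RESPONDER))
    for i in range(14):  # responders: 9 W0 biopsies, 22 follow-ups
        patient = f"RESP{i + 1:02d}"
        if i < 9:
            rows.append((f"{patient}_W0", patient, 0, RESPONDER))
        w = weeks[i % 3]
        rows.append((f"{patient}_W{w}", patient, w, RESPONDER))
        if i < 22 - 14:
            w2 = weeks[(i + 1) % 3]
            rows.append((f"{patient}_W{w2}", patient, w2, RESPONDER))
    for i in range(12):
        patient = f"CTRL{i + 1:02d}"
        rows.append((f"{patient}_W0", patient, 0, CONTROL))
    return rows


def gene_baselines(network: nx.Graph, design: SyntheticDesign) -> pd.Series:
    """Per-gene baseline log-expression mu_g of the synthetic system.

    Baselines are drawn once per ``design.seed`` from
    U(*baseline_range*); planted-path genes are then anchored at
    ``planted_baseline`` so the planted cascade is a high-expression
    conduit.
    """
    genes = sorted(network.nodes)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(design.seed), _STREAM_EXPRESSION]))
    mu = rng.uniform(*design.baseline_range, size=len(genes))
    if design.planted_baseline is not None:
        planted = np.array([g in design.planted_path_genes for g in genes])
        mu[planted] = design.planted_baseline
    return pd.Series(mu, index=genes)


def generate_expression(network: nx.Graph, design: SyntheticDesign,
                        cohort_seed: int | None = None):
    """Log-normal expression matrix plus the matching sample table.

    Gene g in sample s takes the value ``exp(mu_g + delta_gs + eps)`` with
    baselines mu_g from :func:`gene_baselines`, eps ~ Normal(0, noise_sd),
    and ``delta_gs = log(effect_size)`` exactly when g lies on the planted
    path and s belongs to a non-responder.  All values are strictly
    positive.

    ``cohort_seed`` (default: ``design.seed``) drives the patient-level
    randomness — biopsy schedule and noise — so replicate cohorts can be
    drawn from the same fixed network and baselines.

    Returns ``(expression, samples)``: a genes x samples DataFrame and a
    DataFrame with columns sample_id, patient_id, week, response.
    """
    design.validate()
    genes = sorted(network.nodes)
    missing = [g for g in design.planted_path_genes if g not in network]
    if missing:
        raise UnknownGeneError(f"planted genes absent from network: {missing}")
    if cohort_seed is None:
        cohort_seed = design.seed

    cohort_rng = np.random.default_rng(
        np.random.SeedSequence([int(cohort_seed), _STREAM_SCHEDULE]))
    rows = (_table2_schedule(design) if design.schedule == "table2"
            else _random_schedule(design, cohort_rng))
    samples = pd.DataFrame(rows, columns=["sample_id", "patient_id", "week", "response"])

    mu = gene_baselines(network, design).to_numpy()
    noise = cohort_rng.normal(0.0, design.noise_sd, size=(len(genes), len(samples)))
    log_values = mu[:, None] + noise
    planted = np.array([g in design.planted_path_genes for g in genes])
    nonresp = (samples["response"] == NON_RESPONDER).to_numpy()
    log_values[np.ix_(planted, nonresp)] += math.log(design.effect_size)
    expression = pd.DataFrame(np.exp(log_values), index=genes,
                              columns=samples["sample_id"].tolist())
    return expression, samples


def generate_regulatory_table(
    n_tfs: int,
    n_targets: int,
    n_strong_tfs: int = 0,
    strong_scale: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """pandaR-style TF -> target edge-score table.

    Every TF gets one edge per target with score ~ Exponential(1); the first
    ``n_strong_tfs`` TFs have their scores multiplied by ``strong_scale``,
    emulating genuinely regulating factors whose edge-weight sums stand out
    from the exchangeable null.
    """
    if n_strong_tfs > n_tfs:
        raise InvalidDesignError("n_strong_tfs must be <= n_tfs")
    if n_strong_tfs > 0 and strong_scale <= 1.0:
        raise InvalidDesignError("strong_scale must be > 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    tfs = [f"TF{i + 1}" for i in range(n_tfs)]
    targets = [f"G{i + 1}" for i in range(n_targets)]
    scores = rng.exponential(1.0, size=(n_tfs, n_targets))
    scores[:n_strong_tfs] *= strong_scale
    return pd.DataFrame({
        "tf": np.repeat(tfs, n_targets),
        "target": np.tile(targets, n_tfs),
        "score": scores.ravel(),
    })
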