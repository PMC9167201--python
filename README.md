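# netsig

Diffusion-based receptor-to-TF signalling connectivity for therapy-response
stratification.

`netsig` is for computational biologists who want to ask, per patient, *how
fast does signal travel from a cell-surface receptor to each transcription
factor* — and whether that speed predicts response to a therapy.  It was
built around anti-integrin treatment of ulcerative colitis, where
non-responders show faster receptor→TF signalling in mucosal biopsies, but
the machinery is generic: any expression matrix, PPI network, receptor
list and TF set will do.

## The statistic

For one sample with expression x, every edge (u, v) of a role-annotated
signalling network (receptor / transducer / TF) is weighted
w<sub>uv</sub> = x<sub>u</sub>·x<sub>v</sub>.  Unit signal mass injected at
a receptor performs a discrete-time random walk with row-stochastic
transitions; TFs absorb arriving mass.  Writing A<sub>g</sub>(t) for the
cumulative mass arrived at gene g by step t,

> t₅₀(g) = min { t ≥ 1 : A<sub>g</sub>(t) ≥ ½·A<sub>g</sub>(t_stop) }

is the half-arrival time — lower t₅₀ = faster connectivity.  The
samples × (receptor, TF) matrix of t₅₀ values is then mined three ways:

- **Pair ranking** — each receptor–TF pair's t₅₀ is scored as a
  responder/non-responder discriminator with the rank-sum AUC, oriented so
  AUC > 0.5 means non-responders are faster; pairs are ranked by the
  folded AUC max(AUC, 1 − AUC).
- **TF selection** — upstream TF→target edge scores (pandaR-style) are
  reduced to per-TF weight sums and tested with add-one empirical p-values
  against 512 score-column shuffles.
- **Subnetworks** — per receptor, shortest paths (node cost = mean gene
  t₅₀) to its top TFs; per-sample branch sums summarise each patient's
  pathway speed and are compared between response groups.

A first-class synthetic module generates the whole study — layered
network, log-normal two-group expression with a planted fast cascade in
non-responders, biopsy schedules — so every stage runs and calibrates with
no downloads.

## Worked example

```python
from netsig import run_pipeline
from netsig.synthetic import planted_preset

result = run_pipeline(planted_preset(seed=0))
top = result.pair_table.sort_values("auc_oriented", ascending=False).head(3)
print(top[["receptor", "tf", "auc_oriented", "direction", "wilcoxon_p"]])
print(result.comparison)
```

prints (week-0 ranking, then the all-biopsy branch-sum comparison):

```
receptor  tf  auc_oriented           direction  wilcoxon_p
    REC1 TF2       0.87750 nonresponder_faster    0.000025
    REC2 TF1       0.86625 nonresponder_faster    0.000063
    REC2 TF3       0.86250 nonresponder_faster    0.000070
{'groups': ['non-responder', 'responder'],
 'medians': {'non-responder': 46.67, 'responder': 51.67},
 'p_value': 1.45e-07, 'n': {'non-responder': 56, 'responder': 56}}
```

Reading this: several receptor–TF pairs separate the groups before
treatment with oriented AUC ≈ 0.87, always in the direction "non-responder
faster"; the mean branch sum over the best receptor's subnetwork is ~5 t₅₀
steps lower in non-responders (46.7 vs 51.7), a difference the Wilcoxon
test calls highly significant — the planted fast cascade is recovered end
to end.

The same stages are available from the shell:

```sh
netsig simulate --seed 1 --outdir cohort/
netsig preprocess --expr cohort/expression.tsv --meta cohort/samples.csv --outdir norm/
netsig rank-pairs --net cohort/network.graphml --expr norm/expression.norm.tsv \
    --meta norm/samples.labelled.csv --out pairs.tsv
netsig subnet --net cohort/network.graphml --expr norm/expression.norm.tsv \
    --meta norm/samples.labelled.csv --receptor REC1 --out-prefix subnet
```

`build-net` assembles a network from real inputs (PPI TSV, receptor/TF
lists, GMT gene sets, hub blacklist), and `tf-select` runs the permutation
test on a regulatory edge table.

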