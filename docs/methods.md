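# Methods

## The model

`netsig` scores how quickly signal travels from a cell-surface receptor to
each transcription factor (TF) through a patient-specific weighted
signalling network, and uses those speeds to stratify therapy response.

The signalling network is an undirected graph whose nodes carry one of
three roles: *receptor* (signal source), *transducer* (intermediate
signalling protein) or *TF* (absorbing sink).  For one sample with
expression vector x, every edge (u, v) gets weight

    w_uv = x_u · x_v

so edges between highly expressed genes conduct more signal.  Diffusion is
a discrete-time random walk: unit mass is injected at the source receptor;
at each step the mass on a non-TF node moves to its neighbours in
proportion to edge weight (row-stochastic transition); TF nodes absorb
arriving mass permanently; dead ends — nodes whose incident weights are all
zero, or isolated nodes — retain it.  The cumulative mass that has arrived
at gene g by step t, A_g(t), is nondecreasing with a finite limit because
absorption guarantees convergence.  The connectivity score is

    t50(g) = min { t ≥ 1 : A_g(t) ≥ ½ · A_g(t_stop) },

the half-arrival time: lower t50 means faster receptor-to-gene
connectivity.  Unreached genes get the sentinel `t_max + 1`, which keeps
"lower = faster" a total order.  Because transition rows are normalised,
t50 is invariant under global rescaling of expression, and the engine
conserves mass (circulating + absorbed + held = 1) to ~1e-15 at every step.

Design choices in the engine, and why:

- **Absorbing TFs.**  "Maximum signal received over time" is well defined
  only if the arrival curves converge; absorption guarantees that without
  introducing a restart parameter.
- **Dead ends retain mass** rather than teleporting — there is no restart
  distribution in the model, and a zero-expression gene genuinely blocks
  signal through itself.
- **Horizon** `t_max = 100` with early stop when circulating mass falls
  below `mass_tol = 1e-6`.  With absorbing sinks, circulating mass decays
  geometrically, so 100 steps resolve every reachable t50 at the network
  sizes used here; the sentinel is `t_max + 1`.
- **Half-crossing slack** of 1e-12 absolute when testing
  A(t) ≥ ½·A(t_stop), so summation-order roundoff cannot flip an exact
  boundary; an independent plain-loop reference implementation reproduces
  the engine's integer t50 exactly on random graphs.
- **Other receptors act as ordinary transducers** when they are not the
  injection source.

Per sample and receptor, one walk produces t50 for every gene; the
receptor-TF restriction is the *pair* matrix (samples × receptor-TF pairs)
used for stratification, and the full per-gene values feed the subnetwork
stage.

## Pair ranking and statistics

Each pair's per-sample t50 is scored with the rank-sum AUC, oriented as
P(t50_non-responder < t50_responder) + ½ P(equal), so values above 0.5
mean non-responders signal faster; the folded value
max(AUC, 1 − AUC) ranks pairs irrespective of direction.  Group
comparisons use the two-sided Wilcoxon rank-sum test (exact enumeration
when both groups have ≤ 8 untied values, tie-corrected normal
approximation otherwise, p = 1 for constant input).  Per-gene group
effects use OLS with a Benjamini–Hochberg step-up across exactly the
supplied gene list.  PCA is column-centred SVD with the sign of each
component fixed by its largest-magnitude loading.  The baseline classifier
is a single-hidden-layer feed-forward network (standardised inputs,
hidden size chosen from {2, 5, 10} by average out-of-fold accuracy) under
stratified 10-fold cross-validation repeated 20 times; it reports pooled
out-of-fold AUC per repeat.  Cross-dataset consistency of two pair-AUC
tables is Pearson correlation over shared pairs (≥ 3 required).

The default comparison cohort for pair ranking is week-0 biopsies — the
clinically interesting setting is prediction before treatment — with an
all-biopsies mode available, since group differences persist after
treatment.

## TF selection

The TF → target regulatory table (a pandaR-style upstream product) is
thresholded at score > 0.01 (strict), each TF summarised by the sum of its
retained edge scores, and tested against an exchangeable null obtained by
shuffling the score column over rows.  This preserves each TF's edge count
and the global score multiset while destroying any TF-score association.
The one-sided, add-one empirical p-value

    p = (1 + #{permuted sum ≥ observed}) / (1 + n_perm)

is floored at 1/(n_perm+1) (512 permutations by default cannot support
smaller p); TFs with p < 0.05 are selected.  Permuted sums are compared
with a relative slack of 1e-9 so reassignments of an identical multiset
are not ranked by roundoff.

## Network assembly

The node universe is the union of the supplied gene sets (e.g. GO-derived,
parsed from GMT) plus the declared receptors and TFs, minus the hub
blacklist (TP53, UBC, HSPs and similar promiscuous interactors); edges are
the PPI edges with both endpoints inside the universe, deduplicated and
self-loop-free.  Receptors whose connected component contains no TF — and
TFs with no receptor — are pruned and reported.  The final node set is
invariant to the order of blacklisting and restriction, and adding a gene
set can only grow the network.

## Subnetworks and branch sums

Path topology is computed once, from *reference* node weights — the
per-gene t50 averaged over the comparison cohort (sentinels excluded; an
all-sentinel gene keeps the sentinel) — and held fixed across samples so
branch sums are comparable.  The cost of a receptor→TF path is the sum of
node weights over its non-source nodes; Dijkstra uses the equivalent edge
cost (w_u + w_v)/2 with endpoint halves corrected, and the implementation
asserts the transformed cost equals the node sum on every branch.  Cost
ties resolve to the lexicographically smallest node sequence, making the
subnetwork fully deterministic.  For each sample, the branch sum adds that
sample's gene t50 over a branch's non-source nodes; the per-sample mean
over branches is the patient-level pathway-speed summary compared between
groups (non-responders, with faster signalling, show lower sums).

## Preprocessing

Quantile normalisation replaces each column's sorted values with the
row-wise mean of all sorted columns; tied values within a column receive
the mean of the reference values at their tied ranks, which keeps the map
deterministic.  (This tie rule coincides with R limma's for pairs but
differs for ties of three or more, where limma interpolates at the average
rank; the cross-check test against limma therefore uses tie-free input.
On tie-free input the operation is idempotent; with ties it is only
approximately so.)  Gene filtering keeps protein-coding genes whose IQR
across samples (linear-interpolation quartiles, computed on log2 values by
default — the natural scale for normalised intensities) strictly exceeds
the threshold, 0.30 by default.  Sample classification crosses biopsy week
(0 vs later) with eventual response: pre/post-resistant for
non-responders, pre/post-response for responders, `control` for controls
at any week, `unassigned` (logged) for unknown response.

## The synthetic study

The generator emulates the structure the analysis assumes, not any
particular dataset: a layered receptor–transducer–TF network, strictly
positive log-normal expression, a two-group responder/non-responder design
with a planted expression increase along one receptor→TF cascade in
non-responders (making their signalling faster), and a biopsy schedule of
one week-0 sample plus 1–3 follow-ups per treated patient.

The reference design is 3 receptors, 30 transducers and 3 TFs at edge
density 0.1 (candidate edges: receptor–transducer, transducer–transducer,
transducer–TF; regeneration until connected), with the 4-gene planted
cascade REC1–SIG1–SIG2–TF1 — the length of the receptor→TNF→CAV1→TRAF2→TF
routes that dominate real subnetworks of this kind.  Expression is
exp(μ_g + ε), ε ~ N(0, 0.1), with baselines μ_g ~ U(2, 8) except that
planted-path genes are anchored at μ = 6.5; the planted effect multiplies
the planted genes by 1.5 in every non-responder sample, before noise.

Two generator choices deserve explanation because they were forced by the
mathematics of the statistic rather than convenience:

- **The planted cascade is high-expression.**  Under a row-normalised
  walk, a uniform multiplicative boost cancels *inside* the boosted path
  (transition ratios between boosted neighbours are unchanged); the
  observable effect acts only where unboosted nodes hand mass to boosted
  ones — entry into the path, retention against side leaks, and absorption
  at the TF.  A timing statistic therefore cannot register an activity
  change on a pathway that carries negligible flux, so the planted cascade
  must be a major conduit, as the cytokine and fatty-acid pathways of real
  mucosal biopsies are.
- **The system/cohort seed split.**  One hierarchical seed stream fixes
  the biological system (network geometry and gene baselines); a separate
  cohort seed resamples patients (schedule and noise).  Replicates in the
  calibration checks re-recruit patients from the same fixed system, which
  is what a replicate of a clinical study means; it also separates
  sampling noise from geometric variability.

The preset with `schedule="table2"` reproduces the study-style bookkeeping
exactly: 27 non-responder, 14 responder and 12 control patients with
32/49/9/22/12 biopsies across the five groups.

What the generator does *not* emulate: probe-level microarray artifacts,
batch effects, RNA-seq count noise, correlated gene-gene expression beyond
the planted path, dropout or missingness.  Passing tests therefore show
that the machinery recovers a planted connectivity difference under clean
log-normal noise — not that any particular biological claim holds in real
cohorts.

## Calibration facts worth knowing

- The folded (oriented) AUC is positively biased under the null: its mean
  is 0.5 + sd·√(2/π) for a continuous statistic, ≈ 0.57 at 20 + 20
  samples.  Integer t50 ties shrink the dispersion, and evaluating over all
  biopsies (≈ 112 samples) shrinks it further; the null mean of the planted
  pair lands near 0.54 in the reference design.  Raw (unfolded) AUC is the
  unbiased quantity, mean ≈ 0.5.
- The end-to-end pipeline run uses quantile normalisation and an IQR
  threshold of 0 on synthetic cohorts: with noise sd 0.1 every synthetic
  gene's log-scale IQR is ≈ 0.13, so the default 0.30 cutoff — meant for
  genome-wide microarray matrices — would delete the whole toy network.
  The threshold remains exposed for real data.
- Problem sizes in the shipped checks (36-node networks, ≈ 112-sample
  cohorts, 50 replicate cohorts, 512 permutations, 10×20 CV) were chosen so
  the full suite and the acceptance script each run in a few minutes on one
  CPU while keeping every calibration band comfortably resolved.

## Known limitations

- The diffusion update rule is one defensible reading of "time steps to
  50% of maximum signal"; alternatives (non-absorbing TFs, continuous-time
  kernels, restart walks) would give different t50 values.  The update
  rule is isolated behind `diffuse()` so variants can be added.
- Quantile normalisation attenuates multiplicative group effects on small
  gene panels (rank quantisation); with genome-scale inputs this is
  negligible.
- Branch sums inherit the reference-path topology; a sample whose own
  shortest paths differ is still summarised along the cohort's paths.
- AUCs computed over all biopsies treat repeated biopsies of one patient
  as independent, as the source analyses do.
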