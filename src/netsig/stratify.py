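"""Receptor-TF pair ranking and comparative statistics.

Each receptor-TF pair's per-sample t50 is scored as a response predictor
with the rank-sum AUC.  The raw orientation is fixed as

    auc_raw = P(t50_nonresponder < t50_responder) + 1/2 P(equal)

so values above 0.5 mean non-responders signal faster; the oriented AUC
``max(auc_raw, 1 - auc_raw)`` is the direction-free discrimination used for
ranking.  The module also provides the surrounding comparative statistics:
two-sided Wilcoxon rank-sum tests, per-gene OLS group tests with
Benjamini-Hochberg adjustment, PCA scores, a repeated cross-validated
feed-forward network baseline, and Pearson correlation between two AUC
tables (cross-dataset consistency).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .diffusion import DiffusionProfile
from .preprocess import NON_RESPONDER, RESPONDER

logger = logging.getLogger(__name__)

NONRESPONDER_FASTER = "nonresponder_faster"
RESPONDER_FASTER = "responder_faster"

#: Largest per-group size at which the Wilcoxon p-value is computed by exact
#: enumeration (ties force the asymptotic path regardless).
_EXACT_WILCOXON_MAX_N = 8


def rank_auc(positive: np.ndarray, negative: np.ndarray) -> float:
    """AUC via the rank-sum identity, ties counted one half.

    Equals ``(#{pos < neg} + 0.5 #{pos == neg}) / (n_pos * n_neg)`` — the
    probability that a positive-class value ranks below a negative-class
    one.
    """
    positive = np.asarray(positive, dtype=float)
    negative = np.asarray(negative, dtype=float)
    if positive.size == 0 or negative.size == 0:
        raise ValueError("both classes must be non-empty")
    pooled = np.concatenate([positive, negative])
    ranks = stats.rankdata(pooled)
    u_neg = ranks[positive.size:].sum() - negative.size * (negative.size + 1) / 2
    return float(u_neg) / (positive.size * negative.size)


def wilcoxon_groups(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two groups.

    Exact enumeration when both groups have at most 8 untied values,
    tie-corrected normal approximation otherwise; a constant pooled vector
    gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = ("exact" if max(x.size, y.size) <= _EXACT_WILCOXON_MAX_N
              and not has_ties else "asymptotic")
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _comparison_mask(samples: pd.DataFrame, subset: str) -> pd.Series:
    treated = samples["response"].isin([RESPONDER, NON_RESPONDER])
    if subset == "pre":
        return treated & (samples["week"] == 0)
    if subset == "all":
        return treated
    raise ValueError(f"unknown subset {subset!r} (expected 'pre' or 'all')")


def pair_auc(
    profile: DiffusionProfile,
    samples: pd.DataFrame,
    *,
    subset: str = "pre",
) -> pd.DataFrame:
    """Score every receptor-TF pair as a responder / non-responder
    discriminator.

    ``subset="pre"`` (default) restricts to week-0 biopsies — the setting of
    interest being prediction before treatment; ``"all"`` uses every treated
    sample.  Returns one row per pair: receptor, tf, auc_raw, auc_oriented,
    direction, n_pos (non-responders), n_neg (responders), group medians and
    the two-sided Wilcoxon p-value.
    """
    table = samples.set_index("sample_id").loc[profile.sample_ids]
    mask = _comparison_mask(table.reset_index(), subset).to_numpy()
    response = table["response"].to_numpy()
    pos = mask & (response == NON_RESPONDER)
    neg = mask & (response == RESPONDER)
    if not pos.any() or not neg.any():
        raise ValueError(f"subset {subset!r} lacks one of the two response classes")

    rows = []
    for j, (receptor, tf) in enumerate(profile.pairs):
        t50 = profile.pair_t50[:, j].astype(float)
        auc_raw = rank_auc(t50[pos], t50[neg])
        rows.append({
            "receptor": receptor,
            "tf": tf,
            "auc_raw": auc_raw,
            "auc_oriented": max(auc_raw, 1.0 - auc_raw),
            "direction": NONRESPONDER_FASTER if auc_raw >= 0.5 else RESPONDER_FASTER,
            "n_pos": int(pos.sum()),
            "n_neg": int(neg.sum()),
            "median_nonresponder": float(np.median(t50[pos])),
            "median_responder": float(np.median(t50[neg])),
            "wilcoxon_p": wilcoxon_groups(t50[pos], t50[neg]),
        })
    return pd.DataFrame(rows)


def select_top_pairs(table: pd.DataFrame, min_auc: float = 0.0,
                     k: int | None = None) -> pd.DataFrame:
    """Rows with oriented AUC >= ``min_auc``, sorted descending (ties broken
    by receptor then TF name), truncated to the top ``k``."""
    out = table.loc[table["auc_oriented"] >= min_auc].copy()
    out = out.sort_values(["auc_oriented", "receptor", "tf"],
                          ascending=[False, True, True], kind="stable")
    if k is not None:
        out = out.head(k)
    return out.reset_index(drop=True)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of a p-value vector."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def de_linear_model(
    matrix: pd.DataFrame,
    labels,
    genes: list[str],
) -> pd.DataFrame:
    """Per-gene OLS group-effect test with BH adjustment.

    ``labels`` is a binary per-sample grouping aligned with the matrix
    columns (any two-level encoding).  The p-value is the two-sided t-test
    on the group coefficient of ``expression ~ 1 + group``; adjustment is
    Benjamini-Hochberg across exactly the supplied gene list.
    """
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError(f"labels must have exactly two levels, got {list(levels)}")
    design = sm.add_constant((labels == levels[1]).astype(float))

    rows = []
    for gene in genes:
        fit = sm.OLS(matrix.loc[gene].to_numpy(dtype=float), design).fit()
        rows.append({"gene": gene, "estimate": float(fit.params[1]),
                     "p_value": float(fit.pvalues[1])})
    out = pd.DataFrame(rows)
    out["adjusted_p"] = benjamini_hochberg(out["p_value"])
    return out


def pca_scores(matrix, n_components: int = 2):
    """Column-centred SVD scores for a samples x features matrix.

    Constant features are dropped with a warning.  The sign of each
    component is fixed by making its largest-magnitude loading positive, so
    scores are fully deterministic.  Returns ``(scores, variance_fractions)``
    where fractions are of the total variance and nonincreasing.
    """
    frame = pd.DataFrame(matrix)
    values = frame.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("PCA needs >= 2 samples")
    constant = np.ptp(values, axis=0) == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant feature(s)")
        values = values[:, ~constant]
    if values.shape[1] == 0:
        raise ValueError("no non-constant features left")
    centred = values - values.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, s.size)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = pd.DataFrame(u * s, index=frame.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
    total_var = (centred ** 2).sum()
    fractions = (s ** 2) / total_var if total_var > 0 else np.zeros(k)
    return scores, fractions


def baseline_classifier_cv(
    matrix,
    labels,
    folds: int = 10,
    repeats: int = 20,
    seed: int = 0,
    hidden_sizes: tuple[int, ...] = (2, 5, 10),
    max_iter: int = 500,
) -> dict:
    """Repeated stratified k-fold CV of a one-hidden-layer feed-forward
    network baseline.

    The hidden-layer size is picked from ``hidden_sizes`` by average
    out-of-fold accuracy over all repeats; the report carries that size's
    pooled out-of-fold AUC per repeat.  Folds are reduced (with a warning)
    when the smaller class cannot fill them.  Deterministic given the seed.
    """
    x = pd.DataFrame(matrix).to_numpy(dtype=float)
    y = np.asarray(labels)
    levels = np.unique(y)
    if levels.size != 2:
        raise ValueError("baseline classifier needs exactly two classes")
    y = (y == levels[1]).astype(int)
    min_class = int(np.bincount(y).min())
    if folds > min_class:
        logger.warning("reducing folds from %d to %d (smallest class size)",
                       folds, max(2, min_class))
        folds = max(2, min_class)

    results = {}
    for hidden in hidden_sizes:
        accs, aucs = [], []
        for rep in range(repeats):
            split_seed = (int(seed) * 1_000_003 + rep * 9_973 + hidden) % (2**31 - 1)
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=split_seed)
            oof = np.empty(len(y))
            for train, test in skf.split(x, y):
                clf = make_pipeline(
                    StandardScaler(),
                    MLPClassifier(hidden_layer_sizes=(hidden,), max_iter=max_iter,
                                  random_state=split_seed))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # MLP convergence chatter
                    clf.fit(x[train], y[train])
                oof[test] = clf.predict_proba(x[test])[:, 1]
            accs.append(float(np.mean((oof >= 0.5) == y)))
            aucs.append(float(roc_auc_score(y, oof)))
        results[hidden] = (float(np.mean(accs)), aucs)

    best_hidden = max(sorted(results), key=lambda h: results[h][0])
    per_repeat = results[best_hidden][1]
    return {
        "hidden_size": best_hidden,
        "mean_accuracy": results[best_hidden][0],
        "per_repeat_auc": per_repeat,
        "mean_auc": float(np.mean(per_repeat)),
        "folds": folds,
        "repeats": repeats,
    }


def auc_correlation(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between two pair-AUC tables over their shared
    (receptor, tf) pairs; errors with fewer than 3 shared pairs."""
    merged = a.merge(b, on=["receptor", "tf"], suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} shared pairs; need >= 3")
    r, p = stats.pearsonr(merged["auc_oriented_a"], merged["auc_oriented_b"])
    return float(r), float(p)
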