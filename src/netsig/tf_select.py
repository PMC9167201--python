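"""Permutation-based selection of significantly regulating TFs.

Input is an upstream regulatory-network inference table (pandaR-style) of
(tf, target, score) rows, where the score is the confidence that the TF
regulates the target.  After a confidence cutoff, each TF is summarised by
the sum of its retained edge scores.  Significance is assessed against an
exchangeable null built by shuffling the score column over rows — this
keeps each TF's edge count and the overall score multiset fixed while
destroying any association between TF identity and score magnitude.  The
one-sided (upper tail) add-one empirical p-value

    p = (1 + #{permuted sum >= observed sum}) / (1 + n_perm)

is bounded below by 1/(n_perm + 1), so 512 permutations can never report
p = 0; TFs with p < alpha are selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("tf", "target", "score")


@dataclass(frozen=True)
class TFSelection:
    tf_id: str
    weight_sum: float
    empirical_p: float
    selected: bool


def _check_table(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"regulatory table missing columns: {sorted(missing)}")
    if table.duplicated(subset=["tf", "target"]).any():
        raise ValueError("duplicate (tf, target) pairs in regulatory table")


def threshold_edges(table: pd.DataFrame, cutoff: float = 0.01) -> pd.DataFrame:
    """Retain rows with score strictly greater than the cutoff."""
    _check_table(table)
    out = table.loc[table["score"] > cutoff].reset_index(drop=True)
    if out.empty:
        warnings.warn(f"no regulatory edges above cutoff {cutoff}")
    return out


def tf_weight_sums(table: pd.DataFrame) -> pd.Series:
    """Sum of edge scores per TF (TFs absent from the table are absent
    from the result)."""
    _check_table(table)
    return table.groupby("tf", sort=True)["score"].sum()


def _iter_permutations(scores: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Yield ``n_perm`` random reassignments of the score column to rows."""
    for _ in range(n_perm):
        yield rng.permutation(scores)


def empirical_tf_pvalues(
    table: pd.DataFrame,
    n_perm: int = 512,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-TF add-one empirical p-values under score-column shuffling.

    Returns a DataFrame with columns tf_id, weight_sum, empirical_p,
    selected, sorted by tf_id.  Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_table(table)
    if table.empty:
        warnings.warn("empty regulatory table; no TFs to test")
        return pd.DataFrame(columns=["tf_id", "weight_sum", "empirical_p", "selected"])

    codes, tfs = pd.factorize(table["tf"], sort=True)
    scores = table["score"].to_numpy(dtype=float)
    observed = np.bincount(codes, weights=scores, minlength=len(tfs))
    # small relative slack so permutations of the identical multiset are not
    # ranked by summation-order roundoff
    threshold = observed - 1e-9 * np.maximum(np.abs(observed), 1.0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(tfs))
    for permuted in _iter_permutations(scores, n_perm, rng):
        sums = np.bincount(codes, weights=permuted, minlength=len(tfs))
        exceed += sums >= threshold
    pvalues = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({
        "tf_id": list(tfs),
        "weight_sum": observed,
        "empirical_p": pvalues,
        "selected": pvalues < alpha,
    })


def select_tfs(
    table: pd.DataFrame,
    cutoff: float = 0.01,
    n_perm: int = 512,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Convenience wrapper: threshold edges, then permutation-test TFs."""
    return empirical_tf_pvalues(threshold_edges(table, cutoff),
                                n_perm=n_perm, alpha=alpha, seed=seed)
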