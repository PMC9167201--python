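"""Expression normalisation, gene filtering and treatment-group labelling.

Quantile normalisation forces every sample (column) onto a common reference
distribution — the row-wise mean of the column-sorted matrix — so that
between-sample intensity differences cannot masquerade as biology.  Gene
filtering keeps protein-coding genes whose interquartile range across
samples exceeds a threshold (low-variance genes carry no group signal).
Sample classification crosses biopsy week (week 0 vs later) with the
patient's eventual response to produce the four pre/post response/resistant
groups; controls are never given a pre/post label.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NON_RESPONDER = "non-responder"
CONTROL = "control"

PRE_RESPONSE = "preResponse"
POST_RESPONSE = "postResponse"
PRE_RESISTANT = "preResistant"
POST_RESISTANT = "postResistant"
UNASSIGNED = "unassigned"

GROUP_LABELS = (PRE_RESPONSE, POST_RESPONSE, PRE_RESISTANT, POST_RESISTANT,
                CONTROL, UNASSIGNED)

#: Biotypes counted as protein-coding when filtering.
CODING_BIOTYPES = frozenset({"protein_coding"})


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise a genes x samples matrix.

    Every column's sorted values are replaced by the reference distribution
    (row-wise mean of all sorted columns).  Ties within a column receive the
    mean of the reference values at their tied ranks, which keeps the result
    deterministic and permutation-equivariant.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalisation needs >= 2 samples; returning input")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values present; impute or drop before normalising")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        uniq, inverse = np.unique(col, return_inverse=True)
        group_mean = np.bincount(inverse, weights=assigned) / np.bincount(inverse)
        out[:, j] = group_mean[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def gene_iqr(matrix: pd.DataFrame, *, log_scale: bool = True) -> pd.Series:
    """Per-gene interquartile range across samples, linear-interpolation
    quartiles.  With ``log_scale`` the IQR is taken on log2 values, the
    conventional scale for normalised intensities."""
    values = matrix.to_numpy(dtype=float)
    if log_scale:
        if (values <= 0).any():
            raise ValueError("log-scale IQR requires strictly positive values")
        values = np.log2(values)
    q75, q25 = np.percentile(values, [75, 25], axis=1)
    return pd.Series(q75 - q25, index=matrix.index)


def filter_genes(
    matrix: pd.DataFrame,
    annotations: Mapping[str, str],
    iqr_threshold: float = 0.30,
    *,
    log_scale: bool = True,
    coding_biotypes: frozenset[str] = CODING_BIOTYPES,
    keep_unannotated: bool = False,
) -> pd.DataFrame:
    """Keep protein-coding genes with IQR strictly above the threshold.

    Non-coding biotypes (lncRNA, miRNA, pseudogene, ...) are removed
    regardless of variance.  Genes missing from ``annotations`` are dropped
    by default (logged); ``keep_unannotated`` retains them instead.
    """
    if iqr_threshold < 0:
        raise ValueError("iqr_threshold must be >= 0")
    unannotated = [g for g in matrix.index if g not in annotations]
    if unannotated:
        action = "kept" if keep_unannotated else "dropped"
        logger.warning("%d genes without biotype annotation %s (e.g. %s)",
                       len(unannotated), action, unannotated[:5])
    coding = matrix.index.to_series().map(
        lambda g: (annotations[g] in coding_biotypes) if g in annotations
        else keep_unannotated)
    iqr = gene_iqr(matrix, log_scale=log_scale)
    keep = coding.to_numpy(dtype=bool) & (iqr > iqr_threshold).to_numpy()
    return matrix.loc[keep]


def classify_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Attach the treatment-group label to each sample row.

    Week-0 biopsies from eventual non-responders are pre-resistant and from
    responders pre-response; later biopsies are post-resistant /
    post-response; controls stay ``control`` whatever the week.  Treated
    samples with an unknown response flag become ``unassigned`` (logged).
    """
    required = {"sample_id", "week", "response"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dup}")

    def label(row) -> str:
        if row.response == CONTROL:
            return CONTROL
        if row.response == RESPONDER:
            return PRE_RESPONSE if row.week == 0 else POST_RESPONSE
        if row.response == NON_RESPONDER:
            return PRE_RESISTANT if row.week == 0 else POST_RESISTANT
        logger.warning("sample %s has unknown response %r; left unassigned",
                       row.sample_id, row.response)
        return UNASSIGNED

    out = samples.copy()
    out["group_label"] = [label(row) for row in samples.itertuples()]
    return out
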