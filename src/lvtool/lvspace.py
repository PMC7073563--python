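"""Latent-variable space: projection, deduplication, variability, batch check.

A PLIER-style model factorizes a large reference compendium as
``Y ~ Z B`` with non-negative sparse loadings ``Z`` (genes x LVs) and an
L2 penalty ``lambda2`` on the LV scores ``B``.  Transferring the model to
a new cohort therefore amounts to the ridge projection

    B = (Z'Z + lambda2 I)^-1 Z' Y

applied to the gene-standardized expression of the new samples.  The
remaining operations curate the latent space: drop LVs whose loading
vectors are strongly intercorrelated, report the most variable LVs, and
quantify how much study-of-origin (batch) structure survives the move
from gene space to LV space.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ParameterError, PlierModel

log = logging.getLogger(__name__)


def zscore_genes(Y: pd.DataFrame, ddof: int = 1):
    """Standardize each gene row to mean 0, sample SD 1.

    Rows with zero variance cannot be standardized; they are set to all
    zero and reported in the second return value.

    Returns
    -------
    (standardized DataFrame, list of zero-variance gene ids)
    """
    if Y.shape[1] < 2:
        raise ParameterError("z-scoring needs >= 2 samples (sample SD undefined)")
    vals = Y.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    sd[flat] = 1.0
    out = (vals - mean) / sd
    out[flat] = 0.0
    flagged = list(Y.index[flat])
    if flagged:
        log.info("zscore_genes: %d zero-variance gene(s) set to 0", len(flagged))
    return pd.DataFrame(out, index=Y.index, columns=Y.columns), flagged


def project_lv(
    model: PlierModel, Y: pd.DataFrame, min_overlap: float = 0.2
) -> pd.DataFrame:
    """Ridge-project expression into the model's latent space.

    ``Y`` should already be gene-standardized.  Genes in the model but
    absent from ``Y`` are filled with 0 (the post-standardization mean);
    genes in ``Y`` but not the model are ignored.

    Returns an LVs x samples score matrix B solving
    ``(Z'Z + lambda2 I) B = Z' Y``.
    """
    shared = model.genes.intersection(Y.index)
    overlap = len(shared) / len(model.genes)
    if overlap < min_overlap:
        raise ParameterError(
            f"gene overlap with model is {overlap:.3f}, below minimum {min_overlap}"
        )
    Yp = Y.reindex(model.genes).fillna(0.0)
    Z = model.loadings.to_numpy(dtype=float)
    G = Z.T @ Z + model.lambda2 * np.eye(model.n_lvs)
    B = np.linalg.solve(G, Z.T @ Yp.to_numpy(dtype=float))
    return pd.DataFrame(B, index=model.lv_ids, columns=Y.columns)


def dedup_lvs(model: PlierModel, threshold: float = 0.5) -> list:
    """Drop LVs whose loading columns correlate above ``threshold``.

    Scans LVs in ascending column order; an LV is dropped when its
    loading vector has Pearson correlation > threshold with any
    earlier retained LV, so the earlier-indexed member of each
    offending pair survives.  Returned ids keep the model's order.
    """
    if not (0 < threshold <= 1):
        raise ParameterError("threshold must lie in (0, 1]")
    Z = model.loadings.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(Z, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)  # constant columns correlate with nothing
    retained: list[int] = []
    for j in range(Z.shape[1]):
        if all(corr[j, i] <= threshold for i in retained):
            retained.append(j)
    return [model.lv_ids[i] for i in retained]


def top_variable_lvs(B: pd.DataFrame, fraction: float = 0.05) -> list:
    """LVs in the top ``fraction`` by across-sample standard deviation.

    Returns ``ceil(fraction * n_lvs)`` ids, ties broken in favor of the
    earlier LV.
    """
    if not (0 < fraction <= 1):
        raise ParameterError("fraction must lie in (0, 1]")
    if B.shape[1] < 2:
        raise ParameterError("need >= 2 samples to rank variability")
    n = math.ceil(fraction * B.shape[0])
    sd = B.to_numpy(dtype=float).std(axis=1, ddof=1)
    order = np.lexsort((np.arange(len(sd)), -sd))  # descending SD, stable in id
    return [B.index[i] for i in order[:n]]


def _within_study_distances(
    mat: pd.DataFrame, meta: pd.DataFrame, n_pcs: int
) -> np.ndarray:
    """Normalized within-study pairwise PC distances for one space.

    ``mat`` is features x samples.  Samples are the observations of a
    centered (unscaled) PCA; distances over the first ``n_pcs`` scores
    are divided by the mean of all pairwise distances in that space so
    the two spaces become comparable.
    """
    from scipy.spatial.distance import pdist, squareform
    from sklearn.decomposition import PCA

    X = mat.to_numpy(dtype=float).T  # samples x features
    k = min(n_pcs, X.shape[0] - 1, X.shape[1])
    scores = PCA(n_components=k).fit_transform(X)
    dmat = squareform(pdist(scores))
    overall = pdist(scores)
    norm = overall.mean()
    if norm == 0:
        norm = 1.0
    sample_pos = {s: i for i, s in enumerate(mat.columns)}
    out = []
    for study, grp in meta.groupby("study_id"):
        ids = [s for s in grp["sample_id"] if s in sample_pos]
        if len(ids) < 2:
            log.warning("study %s has < 2 samples; skipped in batch check", study)
            continue
        idx = [sample_pos[s] for s in ids]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                out.append(dmat[idx[a], idx[b]] / norm)
    if not out:
        raise ParameterError("no study with >= 2 samples; batch check impossible")
    return np.asarray(out)


def pca_batch_assessment(
    Y: pd.DataFrame, B: pd.DataFrame, meta: pd.DataFrame, n_pcs: int = 2
) -> dict:
    """Compare within-study PC distances in gene space vs LV space.

    Smaller normalized within-study distances in LV space mean the
    projection attenuated the study (batch) structure visible in
    gene-space PCA.  Significance is a two-sided Wilcoxon rank-sum
    (normal approximation with tie correction) between the two distance
    multisets.
    """
    d_gene = _within_study_distances(Y, meta, n_pcs)
    d_lv = _within_study_distances(B, meta, n_pcs)
    res = stats.mannwhitneyu(
        d_gene, d_lv, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return {
        "distances_gene": d_gene,
        "distances_lv": d_lv,
        "median_gene": float(np.median(d_gene)),
        "median_lv": float(np.median(d_lv)),
        "p_value": float(res.pvalue),
    }
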