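"""Rank-based regulon activity inference and LV-activity correlation.

A regulon is a regulator protein with signed, weighted target genes.
Per sample, expression is reduced to a rank-normal *signature* (gene
ranks mapped through the standard-normal quantile function), and a
regulon's enrichment is the likelihood-weighted, mode-signed mean of
its targets' signature values — a one-tail analytic rank enrichment.
The score is scaled by its analytic null SD so that, for an i.i.d.
standard-normal signature, the normalized enrichment score (NES) is
standard normal.  Inferences from several networks are combined into a
consensus activity matrix, and activities are related to LV scores by
Spearman correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ParameterError, Regulon

log = logging.getLogger(__name__)


def rank_signature(Y: pd.DataFrame) -> pd.DataFrame:
    """Per-sample rank-normal gene signature.

    Genes are ranked within each sample (ties get the average rank),
    ranks are mapped to (0, 1) via ``(rank - 0.5) / n`` and then to
    standard-normal quantiles.  An all-equal sample yields an all-zero
    signature with a warning.
    """
    if Y.shape[0] < 3:
        raise ParameterError("signatures need >= 3 genes")
    vals = Y.to_numpy(dtype=float)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        col = vals[:, j]
        if np.all(col == col[0]):
            log.warning("sample %s: constant expression; zero signature", Y.columns[j])
            out[:, j] = 0.0
            continue
        ranks = stats.rankdata(col)
        out[:, j] = stats.norm.ppf((ranks - 0.5) / n)
    return pd.DataFrame(out, index=Y.index, columns=Y.columns)


def area_nes(signature: pd.DataFrame, regulon: Regulon) -> pd.Series | None:
    """Normalized enrichment of one regulon in each sample's signature.

    ES(sample) = sum_i w_i m_i s_i(target_i) with likelihoods w
    normalized to sum 1; NES = ES / sqrt(sum_i (w_i m_i)^2), the exact
    null SD of ES when signature values are independent standard
    normals.  Returns None (protein skipped) when fewer than two
    targets are present in the signature.
    """
    present = [i for i, t in enumerate(regulon.targets) if t in signature.index]
    if len(present) < 2:
        log.info("regulon %s: < 2 targets present; skipped", regulon.regulator)
        return None
    w = regulon.likelihoods[present]
    m = regulon.modes[present]
    w = w / w.sum()
    null_sd = np.sqrt(np.sum((w * m) ** 2))
    if null_sd == 0:
        log.info("regulon %s: all-zero modes; skipped", regulon.regulator)
        return None
    tgt = signature.loc[[regulon.targets[i] for i in present]].to_numpy(dtype=float)
    es = (w * m) @ tgt
    return pd.Series(es / null_sd, index=signature.columns, name=regulon.regulator)


def activity_matrix(Y: pd.DataFrame, regulons: list) -> pd.DataFrame:
    """Proteins x samples NES matrix for one regulon network."""
    sig = rank_signature(Y)
    rows = [r for r in (area_nes(sig, reg) for reg in regulons) if r is not None]
    if not rows:
        raise ParameterError("no regulon had >= 2 targets in the expression matrix")
    return pd.DataFrame(rows)


def metaviper_consensus(activities: list, rule: str = "max_abs"):
    """Combine per-network activity matrices into one consensus matrix.

    Per (protein, sample), ``max_abs`` keeps the NES with the largest
    magnitude across the networks containing that protein (magnitude
    ties resolved toward the larger signed value, so the result does
    not depend on network order); ``weighted_mean`` averages the NES
    values weighted by their magnitudes.  Returns ``(consensus,
    provenance)`` where provenance counts contributing networks per
    protein.
    """
    if not activities:
        raise ParameterError("need >= 1 activity matrix")
    if rule not in ("max_abs", "weighted_mean"):
        raise ParameterError(f"unknown consensus rule {rule!r}")
    samples = activities[0].columns
    for a in activities[1:]:
        samples = samples.intersection(a.columns)
    if len(samples) == 0:
        raise ParameterError("activity matrices share no samples")
    proteins = sorted(set().union(*(set(a.index) for a in activities)))
    stacked = np.full((len(activities), len(proteins), len(samples)), np.nan)
    for k, a in enumerate(activities):
        idx = [i for i, p in enumerate(proteins) if p in set(a.index)]
        stacked[k, idx, :] = a.loc[[proteins[i] for i in idx], samples].to_numpy()

    n_nets = np.sum(~np.isnan(stacked[:, :, 0]), axis=0)
    with np.errstate(invalid="ignore"):
        if rule == "max_abs":
            score = np.abs(stacked) + 1e-12 * stacked  # break |NES| ties upward
            best = np.nanargmax(np.where(np.isnan(stacked), -np.inf, score), axis=0)
            consensus = np.take_along_axis(stacked, best[None], axis=0)[0]
        else:
            wts = np.abs(stacked)
            wsum = np.nansum(wts, axis=0)
            consensus = np.where(
                wsum > 0,
                np.nansum(wts * stacked, axis=0) / np.where(wsum > 0, wsum, 1.0),
                np.nanmean(stacked, axis=0),
            )
    out = pd.DataFrame(consensus, index=proteins, columns=samples)
    provenance = pd.Series(n_nets, index=proteins, name="n_networks")
    return out, provenance


def correlate_activity_lv(
    activity: pd.DataFrame, B: pd.DataFrame, threshold: float = 0.65
):
    """Spearman correlation of every (LV, protein) pair, plus tail counts.

    Returns ``(corr, counts)``: the LVs x proteins Spearman matrix over
    shared samples, and the per-LV count of proteins with r above
    ``threshold`` (constant vectors give NaN and are not counted).
    """
    shared = [s for s in B.columns if s in set(activity.columns)]
    if len(shared) < 3:
        raise ParameterError("fewer than 3 shared samples")
    bv = B[shared].to_numpy(dtype=float)
    av = activity[shared].to_numpy(dtype=float)

    def rank_rows(x):
        ranked = np.apply_along_axis(stats.rankdata, 1, x)
        sd = ranked.std(axis=1, keepdims=True)
        const = sd[:, 0] == 0
        sd[const] = 1.0
        ranked = (ranked - ranked.mean(axis=1, keepdims=True)) / sd
        ranked[const] = np.nan
        return ranked

    rb, ra = rank_rows(bv), rank_rows(av)
    corr = (rb @ ra.T) / len(shared)
    corr_df = pd.DataFrame(corr, index=B.index, columns=activity.index)
    counts = (corr_df > threshold).sum(axis=1)
    counts.name = f"n_proteins_r_gt_{threshold}"
    return corr_df, counts
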