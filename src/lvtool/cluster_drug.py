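"""LV clustering by protein-activity profile, and drug-target enrichment.

LVs whose protein-activity correlation profiles look alike are grouped
by agglomerative hierarchical clustering (Euclidean distance, complete
linkage, tree cut into k groups).  Each cluster's profile is condensed
into a consensus protein ranking (mean correlation over the cluster's
LVs), which is then tested for enrichment of drug target sets with a
preranked, weighted Kolmogorov-Smirnov running-sum statistic and a
protein-label permutation null (one-sided for positive enrichment,
Benjamini-Hochberg corrected across drugs).
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .containers import ClusterAssignment, ParameterError

log = logging.getLogger(__name__)


def cluster_lvs(corr: pd.DataFrame, k: int = 5) -> ClusterAssignment:
    """Cut a complete-linkage tree over LV correlation profiles at k.

    Rows of ``corr`` (LVs x proteins) are the observations; NaN
    correlations are imputed to 0 with a log message.
    """
    if k > corr.shape[0]:
        raise ParameterError(f"k={k} exceeds {corr.shape[0]} LVs")
    X = corr.to_numpy(dtype=float)
    n_na = int(np.isnan(X).sum())
    if n_na:
        log.info("cluster_lvs: imputing %d NaN correlation(s) to 0", n_na)
        X = np.nan_to_num(X, nan=0.0)
    Z = linkage(pdist(X), method="complete")
    labels = cut_tree(Z, n_clusters=k)[:, 0] + 1  # 1-based, exactly k groups
    return ClusterAssignment(
        labels=pd.Series(labels, index=corr.index, name="cluster"), linkage=Z, k=k
    )


def consensus_protein_ranking(
    corr: pd.DataFrame, clusters: ClusterAssignment
) -> dict:
    """Per cluster: mean correlation of each protein over the cluster's LVs.

    Returns ``{cluster label: Series}`` with proteins sorted by
    descending mean correlation (ties by protein id).
    """
    extra = set(clusters.labels.index) - set(corr.index)
    if extra:
        raise ParameterError(f"cluster LVs missing from corr: {sorted(extra)[:5]}")
    out = {}
    for cl in sorted(clusters.labels.unique()):
        members = clusters.members(cl)
        mean = corr.loc[members].mean(axis=0)
        mean = mean.iloc[np.lexsort((mean.index.astype(str), -mean.to_numpy()))]
        out[int(cl)] = mean
    return out


def _es_from_positions(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    """Signed max-deviation ES for hits at sorted 0-based ``positions``.

    ``weights`` are the |score| values at those positions.  Candidate
    extrema occur just before and just after each hit; the running sum
    returns to 0 at the end.
    """
    m = len(positions)
    total_w = weights.sum()
    if total_w == 0:
        hit_steps = np.full(m, 1.0 / m)
    else:
        hit_steps = weights / total_w
    cum_hit = np.cumsum(hit_steps)
    miss_denom = n - m
    misses_before = (positions - np.arange(m)) / miss_denom if miss_denom else 0.0
    before = np.concatenate(([0.0], cum_hit[:-1])) - misses_before
    after = cum_hit - misses_before
    candidates = np.concatenate((before, after))
    return float(candidates[np.argmax(np.abs(candidates))])


def drug_enrichment(
    ranking: pd.Series,
    drug_sets: dict,
    n_perm: int = 10000,
    seed: int = 0,
    exhaustive: bool = False,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Preranked enrichment of each drug's target set in a protein ranking.

    Proteins are sorted by descending score; the running sum increments
    by |score| (weight exponent 1, normalized) at targets and decrements
    uniformly elsewhere; ES is the signed maximum deviation.  The
    one-sided p-value is the probability, under random placement of the
    target set (protein-label permutation), of an ES at least as large;
    ``exhaustive=True`` enumerates every placement instead of sampling.
    Significance is positive ES with BH q below ``q_threshold``.
    """
    if len(ranking) < 2:
        raise ParameterError("ranking needs >= 2 proteins")
    order = np.lexsort((ranking.index.astype(str), -ranking.to_numpy(dtype=float)))
    proteins = ranking.index.to_numpy()[order]
    scores = ranking.to_numpy(dtype=float)[order]
    absw = np.abs(scores)
    n = len(proteins)
    pos_of = {p: i for i, p in enumerate(proteins)}
    rng = np.random.default_rng(seed)

    rows = []
    for drug, targets in drug_sets.items():
        hit_pos = np.array(sorted(pos_of[t] for t in set(targets) if t in pos_of))
        if len(hit_pos) == 0:
            log.info("drug %s: no target in ranking universe; dropped", drug)
            continue
        if len(hit_pos) == n:
            log.warning("drug %s: targets cover the whole universe; skipped", drug)
            continue
        m = len(hit_pos)
        es = _es_from_positions(hit_pos, absw[hit_pos], n)
        if exhaustive:
            if comb(n, m) > 2_000_000:
                raise ParameterError(
                    f"exhaustive enumeration infeasible: C({n},{m}) placements"
                )
            hits = 0
            total = 0
            for combo in combinations(range(n), m):
                pos = np.array(combo)
                if _es_from_positions(pos, absw[pos], n) >= es:
                    hits += 1
                total += 1
            p = hits / total
        else:
            null = np.empty(n_perm)
            for b in range(n_perm):
                pos = np.sort(rng.choice(n, size=m, replace=False))
                null[b] = _es_from_positions(pos, absw[pos], n)
            p = (1 + np.sum(null >= es)) / (1 + n_perm)
        rows.append({"drug": drug, "es": es, "n_targets": m, "p": float(p)})

    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=[], significant=[])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = (out["es"] > 0) & (out["q"] < q_threshold)
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def cluster_expression_by_type(
    B: pd.DataFrame, clusters: ClusterAssignment, meta: pd.DataFrame
) -> pd.DataFrame:
    """Mean LV score per (cluster, sample), joined with tumor type."""
    extra = set(clusters.labels.index) - set(B.index)
    if extra:
        raise ParameterError(f"cluster LVs missing from B: {sorted(extra)[:5]}")
    type_of = dict(zip(meta["sample_id"], meta["tumor_type"]))
    unknown = [s for s in B.columns if s not in type_of]
    if unknown:
        log.warning("%d sample(s) missing from metadata; dropped", len(unknown))
    samples = [s for s in B.columns if s in type_of]
    rows = []
    for cl in sorted(clusters.labels.unique()):
        means = B.loc[clusters.members(cl), samples].mean(axis=0)
        for s in samples:
            rows.append(
                {
                    "cluster": int(cl),
                    "sample_id": s,
                    "tumor_type": type_of[s],
                    "mean_lv_expression": float(means[s]),
                }
            )
    return pd.DataFrame(rows)
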