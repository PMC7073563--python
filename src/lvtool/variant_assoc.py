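"""Gene-variant vs latent-variable expression association.

For every gene carrying non-silent variants in enough assayed samples,
each LV's scores are compared between carrier and non-carrier samples
(only samples with variant data enter the wild-type group) with a
two-sided Wilcoxon rank-sum test, Benjamini-Hochberg corrected across
all (gene, LV) pairs tested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ParameterError

log = logging.getLogger(__name__)

#: variant classes treated as silent / non-coding by default
DEFAULT_EXCLUDED_CLASSES = frozenset({"Silent", "Intron", "3'UTR", "5'UTR"})


def filter_variants(
    variants: pd.DataFrame, excluded_classes=DEFAULT_EXCLUDED_CLASSES
) -> pd.DataFrame:
    """Drop silent / non-coding variant rows."""
    keep = ~variants["Variant_Classification"].isin(set(excluded_classes))
    return variants.loc[keep]


def rank_sum_test(x, y, exact_max_n: int = 25):
    """Two-sided Wilcoxon rank-sum: exact for small groups, else asymptotic
    with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = (
        "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n and not ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def lv_variant_association(
    B: pd.DataFrame,
    variants: pd.DataFrame,
    meta: pd.DataFrame,
    assayed=None,
    min_mutated: int = 3,
    q_threshold: float = 0.01,
    excluded_classes=DEFAULT_EXCLUDED_CLASSES,
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """Test every (gene, LV) pair for a carrier vs wild-type score shift.

    Parameters
    ----------
    assayed
        sample ids with variant data; non-carriers outside this set are
        excluded from the wild-type group.  Default: every sample shared
        between ``B`` and ``meta``.
    min_mutated
        minimum carriers for a gene to be tested (1 allows
        single-sample-driven hits).
    test
        ``"wilcoxon"`` (rank-sum, default) or ``"ttest"`` (Welch).

    Returns a table with one row per tested pair: carrier counts, the
    statistic, p, BH q, significance at ``q_threshold`` and the sign of
    the carrier-vs-wild-type median difference.
    """
    known = set(meta["sample_id"]) & set(B.columns)
    if assayed is None:
        assayed = sorted(known)
    else:
        assayed = sorted(set(assayed) & known)
    if len(assayed) < min_mutated + 2:
        raise ParameterError(
            f"only {len(assayed)} assayed samples; need >= {min_mutated + 2}"
        )
    var = filter_variants(variants, excluded_classes)
    outside = set(var["Tumor_Sample_Barcode"]) - set(assayed)
    if outside:
        log.info("%d variant sample(s) outside assayed cohort; ignored", len(outside))
    var = var[var["Tumor_Sample_Barcode"].isin(set(assayed))]

    rows = []
    carriers_by_gene = var.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].agg(set)
    for gene, carriers in sorted(carriers_by_gene.items()):
        mut_ids = sorted(carriers)
        if len(mut_ids) < min_mutated:
            continue
        wt_ids = [s for s in assayed if s not in carriers]
        if not wt_ids:
            continue
        mut = B[mut_ids].to_numpy(dtype=float)
        wt = B[wt_ids].to_numpy(dtype=float)
        for li, lv in enumerate(B.index):
            if test == "wilcoxon":
                stat, p = rank_sum_test(mut[li], wt[li])
            elif test == "ttest":
                res = stats.ttest_ind(mut[li], wt[li], equal_var=False)
                stat, p = float(res.statistic), float(res.pvalue)
            else:
                raise ParameterError(f"unknown test {test!r}")
            diff = float(np.median(mut[li]) - np.median(wt[li]))
            rows.append(
                {
                    "gene": gene,
                    "lv": lv,
                    "n_mut": len(mut_ids),
                    "n_wt": len(wt_ids),
                    "statistic": stat,
                    "p": p,
                    "direction": int(np.sign(diff)),
                }
            )
    out = pd.DataFrame(
        rows, columns=["gene", "lv", "n_mut", "n_wt", "statistic", "p", "direction"]
    )
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
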