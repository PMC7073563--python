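"""Tumor-microenvironment scoring and LV-immune correlation.

Two complementary views of immune infiltration in bulk expression:

* marker scores — the MCP-counter-style abundance estimator: the
  arithmetic mean of log2 expression over a cell population's marker
  genes, one score per (cell type, sample);
* mixture fractions — signature-based deconvolution: per sample,
  non-negative least squares of linear-scale expression against a
  genes x cell-types signature matrix, normalized to the simplex.

Either score table can then be correlated against LV scores, with
Benjamini-Hochberg control across all (LV, cell type) pairs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .containers import ImmuneScoreTable, ParameterError

log = logging.getLogger(__name__)


def marker_scores(Y: pd.DataFrame, markers: dict) -> ImmuneScoreTable:
    """Mean log2 marker expression per cell type and sample.

    ``Y`` is log2-scale genes x samples; ``markers`` maps cell type to
    marker gene symbols.  Markers absent from ``Y`` are logged; a cell
    type with no marker present is omitted with a warning.
    """
    rows, kept = [], []
    for cell_type, genes in markers.items():
        present = [g for g in genes if g in Y.index]
        absent = set(genes) - set(present)
        if absent:
            log.info("%s: %d marker(s) absent from expression", cell_type, len(absent))
        if not present:
            log.warning("%s: no marker present; cell type omitted", cell_type)
            continue
        rows.append(Y.loc[present].to_numpy(dtype=float).mean(axis=0))
        kept.append(cell_type)
    if not kept:
        raise ParameterError("no marker set had any gene in the expression matrix")
    scores = pd.DataFrame(np.vstack(rows), index=kept, columns=Y.columns)
    return ImmuneScoreTable(scores=scores, method="marker")


def deconvolve_fractions(
    Y: pd.DataFrame,
    S: pd.DataFrame,
    expr_is_log2: bool = True,
    min_overlap: float = 0.5,
) -> ImmuneScoreTable:
    """Constrained least-squares mixture deconvolution.

    Solves, per sample, ``min ||S f - y||_2  s.t.  f >= 0`` over the
    genes shared between expression and signature, then normalizes
    ``f`` to sum 1 (an all-zero solution stays zero).  ``Y`` is
    un-logged first when ``expr_is_log2`` (signatures are linear scale).
    Per-sample RMSE of the unnormalized fit is reported.
    """
    shared = S.index.intersection(Y.index)
    overlap = len(shared) / len(S.index)
    if overlap < min_overlap:
        raise ParameterError(
            f"signature gene overlap {overlap:.3f} below minimum {min_overlap}"
        )
    Smat = S.loc[shared].to_numpy(dtype=float)
    expr = Y.loc[shared].to_numpy(dtype=float)
    if expr_is_log2:
        expr = np.power(2.0, expr) - 1.0
    fracs = np.zeros((S.shape[1], Y.shape[1]))
    rmse = np.zeros(Y.shape[1])
    for j in range(Y.shape[1]):
        f, resid = nnls(Smat, expr[:, j])
        rmse[j] = resid / np.sqrt(len(shared))
        total = f.sum()
        fracs[:, j] = f / total if total > 0 else f
    return ImmuneScoreTable(
        scores=pd.DataFrame(fracs, index=S.columns, columns=Y.columns),
        method="fractions",
        rmse=pd.Series(rmse, index=Y.columns, name="rmse"),
    )


def _corr(x: np.ndarray, y: np.ndarray, method: str):
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def correlate_immune_lv(
    scores: ImmuneScoreTable,
    B: pd.DataFrame,
    method: str = "pearson",
    meta: pd.DataFrame | None = None,
    group_by_tumor_type: bool = False,
) -> pd.DataFrame:
    """Correlate every (LV, cell type) pair across shared samples.

    Optionally computed within each tumor type (requires ``meta``).
    Benjamini-Hochberg q-values are assigned across every pair with a
    defined correlation; constant vectors yield ``r = NaN`` and are
    left out of the correction.
    """
    shared = [s for s in B.columns if s in set(scores.scores.columns)]
    if group_by_tumor_type:
        if meta is None:
            raise ParameterError("grouped correlation needs sample metadata")
        groups = [
            (cls, [s for s in shared if s in set(grp["sample_id"])])
            for cls, grp in meta.groupby("tumor_type")
        ]
    else:
        groups = [(None, shared)]

    rows = []
    for group, ids in groups:
        if len(ids) < 3:
            if group is not None:
                log.warning("group %s has < 3 shared samples; skipped", group)
                continue
            raise ParameterError("fewer than 3 shared samples")
        sc = scores.scores[ids].to_numpy(dtype=float)
        bv = B[ids].to_numpy(dtype=float)
        for li, lv in enumerate(B.index):
            for ci, cell_type in enumerate(scores.scores.index):
                r, p = _corr(bv[li], sc[ci], method)
                rows.append(
                    {"lv": lv, "cell_type": cell_type, "group": group, "r": r, "p": p}
                )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
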