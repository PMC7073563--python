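"""Ensemble-of-random-forests feature selection over LV scores.

The procedure, designed for small cohorts with many features:

1. split the cohort into a *model* set (80%) and an *independent test*
   set (20%), stratified by tumor type;
2. tune ``mtry`` (features per split) and ``ntrees`` by stratified
   cross-validated macro-F1 on the model set;
3. draw many stratified 75/25 train/holdout resamples of the model set
   (without replacement), train one forest per resample, and record
   per-class F1 together with per-class permutation importance and Gini
   importance for every feature — yielding *distributions* of
   performance and importance rather than point estimates;
4. take each class's top-k features by median importance, pool the
   union, retrain the ensemble on that restricted feature set, and
   evaluate on the untouched independent test set;
5. compare full vs restricted per-class F1 distributions with Mood's
   median test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score, recall_score
from sklearn.model_selection import StratifiedKFold

from .containers import (
    ForestEnsembleResult,
    ParameterError,
    SelectedFeatures,
)

log = logging.getLogger(__name__)


@dataclass
class EnsembleConfig:
    """Knobs of the resampling ensemble.

    Defaults mirror the full-cohort protocol (500 resamples, 75/25
    splits, mtry grid 1..100, tree grid {250, 500, 1000, 2000}, 5-fold
    CV, top 40 features per class); synthetic studies typically scale
    ``n_iterations`` and the grids down.
    """

    n_iterations: int = 500
    train_fraction: float = 0.75
    model_fraction: float = 0.8
    mtry_grid: tuple = tuple(range(1, 101))
    ntree_grid: tuple = (250, 500, 1000, 2000)
    cv_folds: int = 5
    top_k: int = 40
    seed: int = 0
    compute_permutation: bool = True
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1 and 0 < self.model_fraction < 1):
            raise ParameterError("fractions must lie in (0, 1)")
        if not self.mtry_grid or not self.ntree_grid:
            raise ParameterError("hyperparameter grids must be non-empty")

    def with_(self, **kw) -> "EnsembleConfig":
        return replace(self, **kw)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_model_test(meta: pd.DataFrame, model_fraction: float = 0.8, seed: int = 0):
    """Stratified model / independent-test split of the cohort.

    Per tumor type, ``round((1 - model_fraction) * n)`` samples (at
    least 1) go to the test set.  Returns ``(model_ids, test_ids)``,
    each sorted, together forming a partition of the samples.
    """
    rng = np.random.default_rng(seed)
    model_ids, test_ids = [], []
    for cls in sorted(meta["tumor_type"].unique()):
        ids = list(meta.loc[meta["tumor_type"] == cls, "sample_id"])
        if len(ids) < 2:
            raise ParameterError(f"class {cls} has fewer than 2 samples")
        n_test = max(1, _round_half_up((1 - model_fraction) * len(ids)))
        perm = rng.permutation(len(ids))
        test_ids += [ids[i] for i in perm[:n_test]]
        model_ids += [ids[i] for i in perm[n_test:]]
    return sorted(model_ids), sorted(test_ids)


def _forest(mtry: int, ntrees: int, random_state: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntrees,
        max_features=mtry,
        random_state=random_state,
        n_jobs=1,
    )


def tune_hyperparams(B: pd.DataFrame, labels: pd.Series, config: EnsembleConfig):
    """Grid-search (mtry, ntrees) by stratified k-fold macro-F1.

    Ties go to the smallest ``ntrees``, then the smallest ``mtry``.
    Grid points with ``mtry > n_features`` are skipped.  Returns
    ``(mtry, ntrees, cv_table)`` where ``cv_table`` holds the per-point
    mean CV macro-F1.
    """
    X = B.T.loc[labels.index].to_numpy(dtype=float)
    y = labels.to_numpy()
    n_features = X.shape[1]
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    folds = list(skf.split(X, y))
    rows = []
    best = None
    for ntrees in sorted(config.ntree_grid):
        for mtry in sorted(config.mtry_grid):
            if mtry > n_features:
                continue
            scores = []
            for tr, te in folds:
                clf = _forest(mtry, ntrees, config.seed)
                clf.fit(X[tr], y[tr])
                scores.append(
                    f1_score(y[te], clf.predict(X[te]), average="macro", zero_division=0)
                )
            mean_f1 = float(np.mean(scores))
            rows.append({"mtry": mtry, "ntrees": ntrees, "cv_macro_f1": mean_f1})
            if best is None or mean_f1 > best[0]:  # strict: first (=smallest) wins ties
                best = (mean_f1, mtry, ntrees)
    if best is None:
        raise ParameterError("every grid point had mtry > n_features")
    return best[1], best[2], pd.DataFrame(rows)


def _stratified_resample(labels: np.ndarray, train_fraction: float, rng):
    """Per-class train/holdout split without replacement; both sides non-empty."""
    train_idx, hold_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_train = min(len(idx) - 1, max(1, _round_half_up(train_fraction * len(idx))))
        perm = rng.permutation(idx)
        train_idx += list(perm[:n_train])
        hold_idx += list(perm[n_train:])
    return np.array(train_idx), np.array(hold_idx)


def run_ensemble(
    B: pd.DataFrame,
    labels: pd.Series,
    config: EnsembleConfig,
    mtry: int,
    ntrees: int,
    features=None,
    samples=None,
    eval_samples=None,
) -> ForestEnsembleResult:
    """Train ``config.n_iterations`` forests on stratified 75/25 resamples.

    Parameters
    ----------
    B
        LVs x samples score matrix.
    labels
        tumor type per sample (indexed by sample id).
    mtry, ntrees
        forest hyperparameters (tuned or fixed); ``mtry`` is clipped to
        the feature count with a warning.
    features
        feature subset (rows of ``B``) to train on; default all.
    samples
        pool the resamples are drawn from (the *model* set); default
        every labelled sample present in ``B``.
    eval_samples
        when given, every forest is evaluated on these samples (the
        *independent test* set) instead of its own 25% holdout.

    Records per-class one-vs-rest F1, per-class permutation importance
    (decrease in class recall when one feature is permuted in the
    evaluation split) and Gini importance, per iteration.
    """
    if features is None:
        features = list(B.index)
    missing = set(features) - set(B.index)
    if missing:
        raise ParameterError(f"features not in B: {sorted(missing)[:5]}")
    if samples is None:
        samples = [s for s in labels.index if s in set(B.columns)]
    classes = sorted(pd.unique(labels))
    n_feat = len(features)
    if mtry > n_feat:
        log.warning("mtry=%d > %d features; clipping", mtry, n_feat)
        mtry = n_feat

    X_pool = B.loc[features, samples].T.to_numpy(dtype=float)
    y_pool = labels.loc[samples].to_numpy()
    if eval_samples is not None:
        X_ind = B.loc[features, eval_samples].T.to_numpy(dtype=float)
        y_ind = labels.loc[eval_samples].to_numpy()

    n_iter = config.n_iterations
    f1 = np.zeros((n_iter, len(classes)))
    gini = np.zeros((n_iter, n_feat))
    perm = (
        np.zeros((n_iter, len(classes), n_feat)) if config.compute_permutation else None
    )

    for it in range(n_iter):
        ss = np.random.SeedSequence([config.seed, it])
        rng = np.random.default_rng(ss)
        rf_state = int(ss.generate_state(1)[0] % (2**31))
        for attempt in range(config.max_redraws + 1):
            tr, ho = _stratified_resample(y_pool, config.train_fraction, rng)
            y_eval = y_ind if eval_samples is not None else y_pool[ho]
            if set(np.unique(y_pool[tr])) == set(classes) and set(
                np.unique(y_eval)
            ) == set(classes):
                break
            log.info("iteration %d: resample missing a class, redrawn", it)
        else:
            raise ParameterError("could not draw a resample containing every class")

        clf = _forest(mtry, ntrees, rf_state)
        clf.fit(X_pool[tr], y_pool[tr])
        X_eval = X_ind if eval_samples is not None else X_pool[ho]
        pred = clf.predict(X_eval)
        f1[it] = f1_score(y_eval, pred, labels=classes, average=None, zero_division=0)
        gini[it] = clf.feature_importances_
        if config.compute_permutation:
            base_recall = recall_score(
                y_eval, pred, labels=classes, average=None, zero_division=0
            )
            n_eval = X_eval.shape[0]
            # one stacked predict call: block j is X_eval with feature j permuted
            stacked = np.tile(X_eval, (n_feat, 1))
            for j in range(n_feat):
                blk = slice(j * n_eval, (j + 1) * n_eval)
                stacked[blk, j] = X_eval[rng.permutation(n_eval), j]
            pred_perm = clf.predict(stacked).reshape(n_feat, n_eval)
            for j in range(n_feat):
                rec = recall_score(
                    y_eval,
                    pred_perm[j],
                    labels=classes,
                    average=None,
                    zero_division=0,
                )
                perm[it, :, j] = base_recall - rec

    return ForestEnsembleResult(
        f1_scores=pd.DataFrame(f1, columns=classes),
        gini_importance=gini,
        perm_importance=perm,
        classes=classes,
        features=list(features),
        mtry=mtry,
        ntrees=ntrees,
    )


def select_top_features(
    result: ForestEnsembleResult, top_k: int = 40, metric: str = "gini"
) -> SelectedFeatures:
    """Per-class top-k features by median importance, plus their union.

    ``metric`` is ``"gini"`` (mean decrease in impurity — class-agnostic,
    so every class sees the same ranking) or ``"permutation"`` (per-class
    decrease in recall).  Ties are broken in favor of the
    earlier-listed feature; the union keeps the input feature order.
    """
    n_feat = len(result.features)
    if top_k > n_feat:
        log.warning("top_k=%d exceeds %d features; capped", top_k, n_feat)
        top_k = n_feat
    if metric not in ("gini", "permutation"):
        raise ParameterError(f"unknown importance metric {metric!r}")
    if metric == "permutation" and result.perm_importance is None:
        raise ParameterError("permutation importances were not computed")

    per_class = {}
    for ci, cls in enumerate(result.classes):
        med = (
            np.median(result.gini_importance, axis=0)
            if metric == "gini"
            else np.median(result.perm_importance[:, ci, :], axis=0)
        )
        order = np.lexsort((np.arange(n_feat), -med))
        per_class[cls] = [result.features[i] for i in order[:top_k]]
    chosen = set().union(*per_class.values())
    union = [f for f in result.features if f in chosen]
    return SelectedFeatures(per_class=per_class, union=union, metric=metric, top_k=top_k)


def moods_median_test(x, y):
    """Mood's median test: 2x2 chi-square on counts above vs <= pooled median.

    Ties with the pooled median count as "below"; no continuity
    correction.  A degenerate pooled table (all values identical) is
    reported as p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ParameterError("both samples must be non-empty")
    try:
        stat, p, _med, _tbl = stats.median_test(
            x, y, ties="below", correction=False
        )
    except ValueError:  # all values equal the grand median
        return 0.0, 1.0
    return float(stat), float(p)


def compare_restricted(
    f1_full: pd.DataFrame, f1_restricted: pd.DataFrame
) -> pd.DataFrame:
    """Per-class Mood's median test of restricted vs full F1 distributions."""
    rows = []
    for cls in f1_full.columns:
        stat, p = moods_median_test(f1_full[cls], f1_restricted[cls])
        rows.append(
            {
                "class": cls,
                "median_full": float(f1_full[cls].median()),
                "median_restricted": float(f1_restricted[cls].median()),
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
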