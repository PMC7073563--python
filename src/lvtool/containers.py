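"""Core data containers shared across analysis stages.

Matrix-like quantities (expression, LV scores, activity, correlations) are
plain :class:`pandas.DataFrame` objects following the bulk-transcriptomics
convention of features in rows and samples in columns.  Structured results
that bundle several arrays get small dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

TUMOR_TYPES = ("cNF", "pNF", "NF", "MPNST")


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


@dataclass
class PlierModel:
    """A transferred PLIER-style factor model.

    Parameters
    ----------
    loadings
        Non-negative genes x LVs weight matrix Z.  Row index holds HUGO
        gene symbols, column index holds LV identifiers.
    lambda2
        Ridge constant used when projecting new samples into the latent
        space (the L2 penalty on LV scores during training).
    lv_annotations
        Optional map from LV id to a pathway label for LVs that align
        with a curated gene set.
    """

    loadings: pd.DataFrame
    lambda2: float
    lv_annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        Z = self.loadings
        if not isinstance(Z, pd.DataFrame):
            raise ParameterError("loadings must be a DataFrame (genes x LVs)")
        if Z.index.duplicated().any():
            raise ParameterError("duplicate gene symbols in loading matrix")
        vals = Z.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ParameterError("non-finite entries in loading matrix")
        if (vals < 0).any():
            raise ParameterError("loading matrix must be non-negative")
        if (vals.sum(axis=0) == 0).any():
            raise ParameterError("loading matrix has an all-zero LV column")
        if self.lambda2 < 0:
            raise ParameterError("lambda2 must be >= 0")

    @property
    def genes(self) -> pd.Index:
        return self.loadings.index

    @property
    def lv_ids(self) -> pd.Index:
        return self.loadings.columns

    @property
    def n_lvs(self) -> int:
        return self.loadings.shape[1]

    def subset(self, lv_ids) -> "PlierModel":
        """Restrict the model to a subset of LVs, preserving column order."""
        keep = [lv for lv in self.lv_ids if lv in set(lv_ids)]
        ann = {k: v for k, v in self.lv_annotations.items() if k in set(keep)}
        return PlierModel(self.loadings[keep], self.lambda2, ann)


@dataclass
class Regulon:
    """A transcriptional regulator with signed, weighted targets.

    ``modes`` lie in [-1, 1] (activation vs repression); ``likelihoods``
    are non-negative interaction confidences, normalized internally when
    computing enrichment.
    """

    regulator: str
    targets: list
    modes: np.ndarray
    likelihoods: np.ndarray

    def __post_init__(self) -> None:
        self.modes = np.asarray(self.modes, dtype=float)
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if len(self.targets) < 2:
            raise ParameterError(f"regulon {self.regulator}: needs >= 2 targets")
        if not (len(self.targets) == len(self.modes) == len(self.likelihoods)):
            raise ParameterError(f"regulon {self.regulator}: ragged fields")
        if (np.abs(self.modes) > 1).any():
            raise ParameterError(f"regulon {self.regulator}: modes outside [-1, 1]")
        if (self.likelihoods < 0).any() or self.likelihoods.sum() == 0:
            raise ParameterError(
                f"regulon {self.regulator}: likelihoods must be >= 0, not all zero"
            )


@dataclass
class ImmuneScoreTable:
    """Cell-type x sample immune scores.

    ``method`` is ``"marker"`` (mean log2 marker expression) or
    ``"fractions"`` (constrained least-squares mixture estimates, which
    are non-negative and sum to at most one per sample).  ``rmse`` holds
    the per-sample fit residual for the fractions variant.
    """

    scores: pd.DataFrame
    method: str
    rmse: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.method not in ("marker", "fractions"):
            raise ParameterError(f"unknown immune score method {self.method!r}")
        if self.method == "fractions":
            vals = self.scores.to_numpy(dtype=float)
            if (vals < -1e-9).any():
                raise ParameterError("fractions must be non-negative")
            if (vals.sum(axis=0) > 1 + 1e-9).any():
                raise ParameterError("fraction columns must sum to <= 1")


@dataclass
class ForestEnsembleResult:
    """Evidence from an ensemble of random forests.

    ``f1_scores`` is iterations x classes; ``perm_importance`` is
    iterations x classes x features (decrease in class recall under
    feature permutation, may be None if not computed); ``gini_importance``
    is iterations x features (mean decrease in impurity).
    """

    f1_scores: pd.DataFrame
    gini_importance: np.ndarray
    perm_importance: Optional[np.ndarray]
    classes: list
    features: list
    mtry: int
    ntrees: int

    def __post_init__(self) -> None:
        f1 = self.f1_scores.to_numpy(dtype=float)
        if ((f1 < -1e-12) | (f1 > 1 + 1e-12)).any():
            raise ParameterError("F1 scores must lie in [0, 1]")
        n_iter = f1.shape[0]
        if self.gini_importance.shape != (n_iter, len(self.features)):
            raise ParameterError("gini importance shape mismatch")
        if self.perm_importance is not None and self.perm_importance.shape != (
            n_iter,
            len(self.classes),
            len(self.features),
        ):
            raise ParameterError("permutation importance shape mismatch")


@dataclass
class SelectedFeatures:
    """Top-k feature selection output: per-class ranked lists and the union."""

    per_class: dict
    union: list
    metric: str
    top_k: int


@dataclass
class ClusterAssignment:
    """LV cluster labels (1..k) plus the agglomerative linkage tree."""

    labels: pd.Series
    linkage: np.ndarray
    k: int

    def __post_init__(self) -> None:
        present = set(self.labels.unique())
        if len(present) != self.k:
            raise ParameterError(
                f"expected {self.k} non-empty clusters, found {len(present)}"
            )

    def members(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])


@dataclass
class SyntheticTruth:
    """Recorded ground truth for a generated cohort.

    Keeps everything a test needs to check recovery: which LVs were
    shifted in which class, the unprojected LV score matrix B, the genes
    carrying the study batch offset, cell-type mixing fractions, planted
    variant carriers, and the planted enriched drug(s).
    """

    seed: int
    planted_lvs_per_class: dict = field(default_factory=dict)
    lv_scores: Optional[pd.DataFrame] = None
    batch_shift_genes: frozenset = frozenset()
    batch_shift: float = 0.0
    mixing_fractions: Optional[pd.DataFrame] = None
    effect_gene_lv_pairs: list = field(default_factory=list)
    variant_carriers: dict = field(default_factory=dict)
    enriched_drugs: frozenset = frozenset()

    def __post_init__(self) -> None:
        seen = set()
        for cls, lvs in self.planted_lvs_per_class.items():
            lvs = set(lvs)
            if lvs & seen:
                raise ParameterError("planted LV sets overlap across classes")
            seen |= lvs
        if self.mixing_fractions is not None:
            col_sums = self.mixing_fractions.to_numpy(dtype=float).sum(axis=0)
            if (self.mixing_fractions.to_numpy() < 0).any():
                raise ParameterError("mixing fractions must be non-negative")
            if np.abs(col_sums - 1).max() > 1e-9:
                raise ParameterError("mixing fractions must sum to 1 per sample")
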