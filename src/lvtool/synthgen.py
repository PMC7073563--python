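"""Synthetic data with the statistical structure the analysis assumes.

Every generator is a pure function of its arguments including the seed,
and records its ground truth in a :class:`~lvtool.containers.SyntheticTruth`
so downstream recovery can be checked exactly:

* a non-negative sparse loading matrix (half-normal magnitudes masked
  by Bernoulli sparsity, the qualitative shape of PLIER loadings);
* a cohort whose LV scores are unit-normal noise plus class-specific
  shifts on a few *planted* LVs, observed through the loading matrix
  with additive gene-level noise and, optionally, study-specific batch
  offsets in gene space;
* regulon networks with signed modes, variant tables whose effect genes
  mark the samples to be shifted, immune-cell mixtures over marker
  genes, and drug target sets with one planted enriched drug.

Class labels use the four nerve-sheath-tumor type names (cNF, pNF, NF,
MPNST) so that reports read like the real cohort's.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .containers import ParameterError, PlierModel, Regulon, SyntheticTruth


def gen_model(
    n_genes: int,
    n_lvs: int,
    sparsity: float,
    seed: int,
    lambda2: float = 1e-6,
) -> PlierModel:
    """Random non-negative sparse loading matrix.

    Entries are |N(0, 1)| masked by Bernoulli(``sparsity``); every LV
    column is guaranteed at least one nonzero entry.
    """
    if n_genes < n_lvs or n_lvs < 2:
        raise ParameterError("need n_genes >= n_lvs >= 2")
    if not (0 < sparsity < 1):
        raise ParameterError("sparsity must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_genes, n_lvs)) < sparsity
    Z = np.abs(rng.standard_normal((n_genes, n_lvs))) * mask
    empty = np.flatnonzero(Z.sum(axis=0) == 0)
    for j in empty:
        Z[rng.integers(n_genes), j] = np.abs(rng.standard_normal())
    genes = [f"G{i:05d}" for i in range(n_genes)]
    lvs = [f"LV{j + 1}" for j in range(n_lvs)]
    return PlierModel(pd.DataFrame(Z, index=genes, columns=lvs), lambda2=lambda2)


def gen_cohort(
    model: PlierModel,
    n_per_class: dict,
    planted_per_class: int = 5,
    effect_size: float = 3.0,
    noise_sd: float = 0.5,
    batch_map: dict | None = None,
    batch_shift: float = 0.0,
    batch_gene_frac: float = 0.1,
    seed: int = 0,
):
    """Generate (expression, metadata, truth) for a multi-class cohort.

    LV scores ``B`` are i.i.d. N(0, 1); for each class,
    ``planted_per_class`` disjoint LVs get ``+effect_size`` (SD units of
    the unit-variance baseline) in that class's samples.  Expression is
    ``Y = Z B + Normal(0, noise_sd)``; when ``batch_shift > 0`` a random
    ``batch_gene_frac`` of genes receives an additive study-specific
    offset (``batch_shift`` times a standard-normal draw per gene and
    study) in gene space, the place batch structure shows up in PCA of
    real cohorts.  ``batch_map`` assigns each class to a study id
    (default: one study for everyone).
    """
    if len(n_per_class) < 2:
        raise ParameterError("need >= 2 classes")
    if any(n < 1 for n in n_per_class.values()):
        raise ParameterError("every class needs >= 1 sample")
    n_lvs = model.n_lvs
    if planted_per_class * len(n_per_class) > n_lvs:
        raise ParameterError("not enough LVs for disjoint planted sets")
    rng = np.random.default_rng(seed)

    samples, types = [], []
    for cls, n in n_per_class.items():
        samples += [f"{cls}_{i:02d}" for i in range(n)]
        types += [cls] * n
    studies = [
        (batch_map or {}).get(cls, "study1") for cls in types
    ]
    meta = pd.DataFrame(
        {"sample_id": samples, "tumor_type": types, "study_id": studies}
    )

    B = rng.standard_normal((n_lvs, len(samples)))
    lv_pool = rng.permutation(n_lvs)
    planted: dict[str, set] = {}
    offset = 0
    for cls in n_per_class:
        chosen = lv_pool[offset : offset + planted_per_class]
        offset += planted_per_class
        cols = [i for i, t in enumerate(types) if t == cls]
        B[np.ix_(chosen, cols)] += effect_size
        planted[cls] = {model.lv_ids[j] for j in chosen}

    Z = model.loadings.to_numpy(dtype=float)
    Y = Z @ B
    if noise_sd > 0:
        Y = Y + noise_sd * rng.standard_normal(Y.shape)

    batch_genes: frozenset = frozenset()
    if batch_shift > 0:
        n_batch = max(1, math.ceil(batch_gene_frac * len(model.genes)))
        rows = rng.choice(len(model.genes), size=n_batch, replace=False)
        batch_genes = frozenset(model.genes[i] for i in rows)
        for study in sorted(set(studies)):
            delta = batch_shift * rng.standard_normal(n_batch)
            cols = [i for i, s in enumerate(studies) if s == study]
            Y[np.ix_(rows, cols)] += delta[:, None]

    expr = pd.DataFrame(Y, index=model.genes, columns=samples)
    truth = SyntheticTruth(
        seed=seed,
        planted_lvs_per_class=planted,
        lv_scores=pd.DataFrame(B, index=model.lv_ids, columns=samples),
        batch_shift_genes=batch_genes,
        batch_shift=batch_shift,
    )
    return expr, meta, truth


def gen_regulons(
    n_regulators: int, targets_per_regulon: int, gene_universe, seed: int
) -> list:
    """Random signed, weighted regulons over a gene universe."""
    genes = list(gene_universe)
    if targets_per_regulon > len(genes):
        raise ParameterError("gene universe smaller than requested regulon size")
    rng = np.random.default_rng(seed)
    regulons = []
    for i in range(n_regulators):
        targets = [genes[j] for j in rng.choice(len(genes), targets_per_regulon, replace=False)]
        modes = rng.choice([-1.0, 1.0], size=targets_per_regulon)
        likelihoods = rng.uniform(0.5, 1.0, size=targets_per_regulon)
        regulons.append(Regulon(f"TF{i + 1}", targets, modes, likelihoods))
    return regulons


def gen_variants(
    meta: pd.DataFrame,
    effect_pairs: list,
    background_rate: float,
    seed: int,
    carrier_fraction: float = 0.5,
    background_genes=None,
    assayed=None,
):
    """MAF-style variant table with planted effect genes.

    Each ``(gene, lv, shift)`` effect pair gets a random
    ``carrier_fraction`` of the assayed samples as carriers; apply the
    matching LV shift to a cohort's score matrix with
    :func:`plant_variant_effect`.  Background variants hit every
    (sample, background gene) combination independently at
    ``background_rate``.  Returns ``(VariantTable, carriers)`` with
    carriers mapping gene -> set of sample ids.
    """
    if not (0 <= background_rate < 1):
        raise ParameterError("background_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    assayed = list(assayed) if assayed is not None else list(meta["sample_id"])
    if background_genes is None:
        background_genes = [f"BGGENE{i + 1}" for i in range(20)]
    rows = []
    carriers: dict[str, set] = {}
    for gene, _lv, _shift in effect_pairs:
        n_carr = max(1, int(np.floor(carrier_fraction * len(assayed) + 0.5)))
        picked = {assayed[i] for i in rng.choice(len(assayed), n_carr, replace=False)}
        carriers[gene] = picked
        for s in sorted(picked):
            rows.append((s, gene, "Missense_Mutation"))
    if background_rate > 0:
        classes = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del"]
        for gene in background_genes:
            hits = rng.random(len(assayed)) < background_rate
            for s, hit in zip(assayed, hits):
                if hit:
                    rows.append((s, gene, classes[rng.integers(len(classes))]))
    table = pd.DataFrame(
        rows, columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    )
    return table, carriers


def plant_variant_effect(
    B: pd.DataFrame, carriers: dict, effect_pairs: list
) -> pd.DataFrame:
    """Shift LV scores in carrier samples; returns a modified copy of B.

    Shifts are in SD units of each LV's across-sample scores.
    """
    out = B.copy()
    for gene, lv, shift in effect_pairs:
        ids = [s for s in carriers.get(gene, ()) if s in out.columns]
        sd = float(out.loc[lv].std(ddof=1))
        out.loc[lv, ids] += shift * (sd if sd > 0 else 1.0)
    return out


def gen_immune_mixture(
    n_cell_types: int = 4,
    markers_per_type: int = 5,
    n_samples: int = 60,
    n_extra_genes: int = 50,
    noise_sd: float = 0.1,
    seed: int = 0,
    marker_high: float = 50.0,
    basal: float = 1.0,
):
    """Bulk expression of known cell-type mixtures over marker genes.

    Cell-type fractions are Dirichlet(1) per sample; each type's
    markers are expressed at ``marker_high`` in that type and ``basal``
    elsewhere, so linear bulk expression is the signature-weighted
    mixture.  Log2(x+1) expression receives Normal(0, ``noise_sd``)
    noise (log2 units).  Returns ``(Y_log2, marker_sets, signature,
    truth)`` with mixing fractions recorded in the truth.
    """
    rng = np.random.default_rng(seed)
    cell_types = [f"CT{i + 1}" for i in range(n_cell_types)]
    marker_sets = {
        ct: [f"MK_{ct}_{j + 1}" for j in range(markers_per_type)] for ct in cell_types
    }
    genes = [g for ms in marker_sets.values() for g in ms]
    genes += [f"XG{i + 1}" for i in range(n_extra_genes)]
    S = np.full((len(genes), n_cell_types), basal)
    for ci, ct in enumerate(cell_types):
        for g in marker_sets[ct]:
            S[genes.index(g), ci] = marker_high
    # extra genes: random moderate expression shared across types
    S[len(genes) - n_extra_genes :, :] = rng.uniform(
        basal, 10.0, size=(n_extra_genes, 1)
    )
    F = rng.dirichlet(np.ones(n_cell_types), size=n_samples).T  # types x samples
    bulk = S @ F
    Y = np.log2(bulk + 1.0) + noise_sd * rng.standard_normal(bulk.shape)
    samples = [f"MIX_{i:02d}" for i in range(n_samples)]
    signature = pd.DataFrame(S, index=genes, columns=cell_types)
    expr = pd.DataFrame(Y, index=genes, columns=samples)
    truth = SyntheticTruth(
        seed=seed,
        mixing_fractions=pd.DataFrame(F, index=cell_types, columns=samples),
    )
    return expr, marker_sets, signature, truth


def gen_drug_sets(
    n_drugs: int,
    targets_per_drug: int,
    protein_universe,
    planted_drug_top_k: int,
    seed: int,
):
    """Drug -> target sets with one planted positively enriched drug.

    The first drug's targets are drawn from the top ``planted_drug_top_k``
    stratum of the (already ranked) protein universe; the rest are drawn
    uniformly.  Returns ``(drug_sets, truth)``.
    """
    proteins = list(protein_universe)
    if targets_per_drug > len(proteins) or planted_drug_top_k > len(proteins):
        raise ParameterError("protein universe smaller than requested set sizes")
    if targets_per_drug > planted_drug_top_k:
        raise ParameterError("planted stratum smaller than the target set")
    rng = np.random.default_rng(seed)
    sets = {}
    planted = "DRUG001"
    top = proteins[:planted_drug_top_k]
    sets[planted] = sorted(
        top[i] for i in rng.choice(len(top), targets_per_drug, replace=False)
    )
    for d in range(1, n_drugs):
        sets[f"DRUG{d + 1:03d}"] = sorted(
            proteins[i]
            for i in rng.choice(len(proteins), targets_per_drug, replace=False)
        )
    truth = SyntheticTruth(seed=seed, enriched_drugs=frozenset({planted}))
    return sets, truth
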