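"""A self-contained synthetic demo study: inputs, config, ground truth.

Writes every input file the pipeline consumes (expression, model,
metadata, variants, markers, signature, regulon networks, drug sets)
for a small four-class cohort with known planted structure, plus a YAML
config pointing at them.  Used by the worked example, the end-to-end
tests, and the reproducibility script.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, synthgen


def write_demo_inputs(
    directory,
    seed: int = 7,
    n_genes: int = 300,
    n_lvs: int = 60,
    n_per_class: int = 8,
    planted_per_class: int = 3,
    effect_size: float = 3.0,
    noise_sd: float = 0.5,
    n_iterations: int = 20,
    ntrees: int = 100,
    n_perm: int = 1000,
) -> dict:
    """Generate and write a complete demo study; return its config dict."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    model = synthgen.gen_model(n_genes, n_lvs, sparsity=0.12, seed=seed)
    classes = {"cNF": n_per_class, "pNF": n_per_class, "NF": n_per_class,
               "MPNST": n_per_class}
    expr, meta, truth = synthgen.gen_cohort(
        model,
        classes,
        planted_per_class=planted_per_class,
        effect_size=effect_size,
        noise_sd=noise_sd,
        batch_map={"cNF": "studyA", "pNF": "studyB", "NF": "studyB",
                   "MPNST": "studyC"},
        batch_shift=1.0,
        seed=seed + 1,
    )

    # variant table: one effect gene shifting a planted MPNST LV, light background
    target_lv = sorted(truth.planted_lvs_per_class["MPNST"])[0]
    pairs = [("NF1", target_lv, 2.0)]
    assayed = list(meta["sample_id"][: 3 * n_per_class])
    maf, carriers = synthgen.gen_variants(
        meta, pairs, background_rate=0.05, seed=seed + 2, assayed=assayed
    )
    B_shifted = synthgen.plant_variant_effect(truth.lv_scores, carriers, pairs)
    expr = pd.DataFrame(
        model.loadings.to_numpy() @ B_shifted.to_numpy()
        + (expr.to_numpy() - model.loadings.to_numpy() @ truth.lv_scores.to_numpy()),
        index=expr.index,
        columns=expr.columns,
    )

    # immune markers drawn from the model's gene universe
    genes = list(model.genes)
    marker_sets = {
        ct: genes[i * 5 : (i + 1) * 5]
        for i, ct in enumerate(["Tcell", "Bcell", "Macrophage", "Mast"])
    }
    sig = pd.DataFrame(
        1.0, index=[g for ms in marker_sets.values() for g in ms],
        columns=list(marker_sets),
    )
    for ct, ms in marker_sets.items():
        sig.loc[ms, ct] = 25.0

    regulons = [
        synthgen.gen_regulons(8, 10, genes, seed=seed + 3),
        synthgen.gen_regulons(8, 10, genes, seed=seed + 4),
    ]
    drug_sets, _ = synthgen.gen_drug_sets(
        12, 4, [f"TF{i + 1}" for i in range(8)], planted_drug_top_k=5, seed=seed + 5
    )

    io.write_matrix(expr, d / "expression.tsv", index_label="gene")
    io.write_model(model, d / "model.tsv", d / "model.json")
    io.write_metadata(meta, d / "metadata.tsv")
    io.write_maf(maf, d / "variants.maf")
    io.write_gmt(marker_sets, d / "markers.gmt")
    io.write_matrix(sig, d / "signature.tsv", index_label="gene")
    io.write_regulons(regulons[0], d / "regulons_net1.json")
    io.write_regulons(regulons[1], d / "regulons_net2.json")
    io.write_gmt(drug_sets, d / "drugs.gmt")

    cfg = {
        "expression": str(d / "expression.tsv"),
        "model": str(d / "model.tsv"),
        "model_meta": str(d / "model.json"),
        "metadata": str(d / "metadata.tsv"),
        "variants": str(d / "variants.maf"),
        "markers": str(d / "markers.gmt"),
        "signature": str(d / "signature.tsv"),
        "regulons": [str(d / "regulons_net1.json"), str(d / "regulons_net2.json")],
        "drug_sets": str(d / "drugs.gmt"),
        "assayed_samples": assayed,
        "outdir": str(d / "out"),
        "seed": seed,
        "params": {
            "min_mutated": 3,
            "n_perm": n_perm,
            "ensemble": {
                "n_iterations": n_iterations,
                "mtry": 8,
                "ntrees": ntrees,
                "top_k": 10,
            },
        },
    }
    (d / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return cfg
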