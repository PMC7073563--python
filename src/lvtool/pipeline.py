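"""End-to-end orchestration from a single YAML config.

Stage order: project -> dedup -> forest selection -> {immune, regulon
activity, variants} -> cluster/drugs.  Every stage reads and writes
plain-text files under the configured output directory; stages whose
inputs are absent are skipped with an explicit notice.  A manifest with
content hashes of every output makes reruns verifiable: the same config
and seed reproduce the manifest byte for byte.

The global seed fans out to per-stage seeds by fixed offsets, so any
stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import cluster_drug, forest_select, io, lvspace, microenv, regulon_activity
from . import variant_assoc as va
from .containers import ParameterError

log = logging.getLogger(__name__)

SEED_OFFSETS = {
    "split": 1,
    "ensemble": 2,
    "restricted": 3,
    "drugs": 4,
}

DEFAULT_PARAMS = {
    "dedup_threshold": 0.5,
    "min_overlap": 0.2,
    "top_variable_fraction": 0.05,
    "n_pcs": 2,
    "importance_metric": "gini",
    "k_clusters": 5,
    "corr_threshold": 0.65,
    "variant_q": 0.01,
    "min_mutated": 3,
    "drug_q": 0.05,
    "n_perm": 10000,
    "ensemble": {},
}


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    cfg.setdefault("params", {})
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _params(cfg: dict) -> dict:
    p = dict(DEFAULT_PARAMS)
    p.update(cfg.get("params", {}))
    return p


def run_all(cfg: dict, outdir=None) -> dict:
    """Execute every stage whose inputs are configured; return the manifest."""
    params = _params(cfg)
    seed = int(cfg.get("seed", 0))
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    skipped: list[str] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        outputs.append(path)
        log.info("stage output: %s", name)
        return path

    def have(key: str) -> bool:
        return bool(cfg.get(key))

    for key in ("expression", "model", "model_meta", "metadata"):
        if not have(key):
            raise ParameterError(f"config is missing required input {key!r}")

    # ---- projection ------------------------------------------------------
    model = io.read_model(cfg["model"], cfg["model_meta"])
    expr = io.read_matrix(cfg["expression"])
    meta = io.read_metadata(cfg["metadata"])
    retained = lvspace.dedup_lvs(model, params["dedup_threshold"])
    model_d = model.subset(retained)
    Yz, flagged = lvspace.zscore_genes(expr)
    B = lvspace.project_lv(model_d, Yz, params["min_overlap"])
    emit("B.tsv", lambda p: io.write_matrix(B, p, index_label="lv"))
    emit(
        "dedup.json",
        lambda p: p.write_text(
            json.dumps(
                {"retained": list(retained), "n_dropped": model.n_lvs - len(retained)},
                sort_keys=True,
                indent=1,
            )
        ),
    )
    top_vars = lvspace.top_variable_lvs(B, params["top_variable_fraction"])
    emit(
        "top_variable_lvs.json",
        lambda p: p.write_text(json.dumps({"top_variable": top_vars}, indent=1)),
    )

    # ---- batch assessment ------------------------------------------------
    if meta["study_id"].nunique() >= 2:
        batch = lvspace.pca_batch_assessment(expr, B, meta, params["n_pcs"])
        emit(
            "batch_check.json",
            lambda p: p.write_text(
                json.dumps(
                    {
                        k: batch[k]
                        for k in ("median_gene", "median_lv", "p_value")
                    },
                    sort_keys=True,
                    indent=1,
                )
            ),
        )
    else:
        skipped.append("batch_check: fewer than 2 studies")

    # ---- forest selection ------------------------------------------------
    labels = pd.Series(
        meta["tumor_type"].to_numpy(), index=meta["sample_id"], name="tumor_type"
    )
    labels = labels[[s for s in labels.index if s in set(B.columns)]]
    ens_kw = dict(params["ensemble"])
    mtry = ens_kw.pop("mtry", None)
    ntrees = ens_kw.pop("ntrees", None)
    config = forest_select.EnsembleConfig(**ens_kw, seed=seed + SEED_OFFSETS["ensemble"])
    model_ids, test_ids = forest_select.split_model_test(
        meta[meta["sample_id"].isin(labels.index)],
        config.model_fraction,
        seed + SEED_OFFSETS["split"],
    )
    if mtry is None or ntrees is None:
        mtry, ntrees, _cv = forest_select.tune_hyperparams(
            B[model_ids], labels.loc[model_ids], config
        )
        log.info("tuned hyperparameters: mtry=%d ntrees=%d", mtry, ntrees)
    full = forest_select.run_ensemble(
        B, labels, config, mtry, ntrees, samples=model_ids
    )
    selected = forest_select.select_top_features(
        full, config.top_k, params["importance_metric"]
    )
    restricted = forest_select.run_ensemble(
        B,
        labels,
        config.with_(seed=seed + SEED_OFFSETS["restricted"]),
        mtry,
        ntrees,
        features=selected.union,
        samples=model_ids,
        eval_samples=test_ids,
    )
    moods = forest_select.compare_restricted(full.f1_scores, restricted.f1_scores)
    emit(
        "selected.json",
        lambda p: p.write_text(
            json.dumps(
                {
                    "union": selected.union,
                    "per_class": {k: list(v) for k, v in selected.per_class.items()},
                    "metric": selected.metric,
                    "mtry": mtry,
                    "ntrees": ntrees,
                },
                sort_keys=True,
                indent=1,
            )
        ),
    )
    emit("f1_full.tsv", lambda p: full.f1_scores.to_csv(p, sep="\t", index_label="iteration"))
    emit(
        "f1_restricted.tsv",
        lambda p: restricted.f1_scores.to_csv(p, sep="\t", index_label="iteration"),
    )
    emit("moods_test.tsv", lambda p: moods.to_csv(p, sep="\t", index=False))
    B_sel = B.loc[selected.union]

    # ---- immune ----------------------------------------------------------
    if have("markers"):
        markers = io.read_gmt(cfg["markers"])
        mscores = microenv.marker_scores(expr, markers)
        emit(
            "immune_marker_scores.tsv",
            lambda p: io.write_matrix(mscores.scores, p, index_label="cell_type"),
        )
        mcorr = microenv.correlate_immune_lv(mscores, B_sel)
        emit("immune_lv_corr_marker.tsv", lambda p: mcorr.to_csv(p, sep="\t", index=False))
    else:
        skipped.append("immune_markers: no marker GMT configured")
    if have("signature"):
        sig = io.read_matrix(cfg["signature"])
        fracs = microenv.deconvolve_fractions(expr, sig)
        emit(
            "immune_fractions.tsv",
            lambda p: io.write_matrix(fracs.scores, p, index_label="cell_type"),
        )
        fcorr = microenv.correlate_immune_lv(fracs, B_sel)
        emit(
            "immune_lv_corr_fractions.tsv",
            lambda p: fcorr.to_csv(p, sep="\t", index=False),
        )
    else:
        skipped.append("immune_fractions: no signature matrix configured")

    # ---- regulon activity + clustering + drugs ---------------------------
    if have("regulons"):
        nets = [io.read_regulons(path) for path in cfg["regulons"]]
        acts = [regulon_activity.activity_matrix(expr, net) for net in nets]
        consensus, provenance = regulon_activity.metaviper_consensus(acts)
        emit(
            "activity.tsv", lambda p: io.write_matrix(consensus, p, index_label="protein")
        )
        emit(
            "activity_provenance.tsv",
            lambda p: provenance.to_csv(p, sep="\t", index_label="protein"),
        )
        corr, counts = regulon_activity.correlate_activity_lv(
            consensus, B_sel, params["corr_threshold"]
        )
        emit("activity_lv_corr.tsv", lambda p: io.write_matrix(corr, p, index_label="lv"))
        emit(
            "activity_corr_counts.tsv",
            lambda p: counts.to_csv(p, sep="\t", index_label="lv"),
        )

        k = min(params["k_clusters"], corr.shape[0])
        clusters = cluster_drug.cluster_lvs(corr, k)
        emit(
            "clusters.tsv",
            lambda p: clusters.labels.to_csv(p, sep="\t", index_label="lv"),
        )
        rankings = cluster_drug.consensus_protein_ranking(corr, clusters)
        long = pd.concat(
            [
                pd.DataFrame(
                    {"cluster": cl, "protein": r.index, "mean_correlation": r.values}
                )
                for cl, r in rankings.items()
            ]
        )
        emit(
            "consensus_rankings.tsv", lambda p: long.to_csv(p, sep="\t", index=False)
        )
        expr_by_type = cluster_drug.cluster_expression_by_type(B_sel, clusters, meta)
        emit(
            "cluster_expression.tsv",
            lambda p: expr_by_type.to_csv(p, sep="\t", index=False),
        )
        if have("drug_sets"):
            drug_sets = io.read_gmt(cfg["drug_sets"])
            tables = []
            for cl, ranking in rankings.items():
                tab = cluster_drug.drug_enrichment(
                    ranking,
                    drug_sets,
                    n_perm=params["n_perm"],
                    seed=seed + SEED_OFFSETS["drugs"] + cl,
                    q_threshold=params["drug_q"],
                )
                tab.insert(0, "cluster", cl)
                tables.append(tab)
            emit(
                "drug_enrichment.tsv",
                lambda p: pd.concat(tables).to_csv(p, sep="\t", index=False),
            )
        else:
            skipped.append("drug_enrichment: no drug-target GMT configured")
    else:
        skipped.append("regulon_activity: no regulon networks configured")
        skipped.append("cluster_drug: requires regulon activity")

    # ---- variants --------------------------------------------------------
    if have("variants"):
        variants = io.read_maf(cfg["variants"])
        assayed = cfg.get("assayed_samples")
        assoc = va.lv_variant_association(
            B_sel,
            variants,
            meta,
            assayed=assayed,
            min_mutated=params["min_mutated"],
            q_threshold=params["variant_q"],
        )
        emit("variant_assoc.tsv", lambda p: assoc.to_csv(p, sep="\t", index=False))
    else:
        skipped.append("variant_assoc: no variant table configured")

    manifest = {
        "seed": seed,
        "params": params,
        "n_samples": int(B.shape[1]),
        "n_lvs_retained": int(B.shape[0]),
        "n_zero_variance_genes": len(flagged),
        "outputs": {p.name: _sha256(p) for p in outputs},
        "skipped": sorted(skipped),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest
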