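"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions:

* matrices (expression, LV scores, activity, correlations) are TSV with
  the feature identifier in the first column and samples in the header;
* sample metadata is TSV with ``sample_id``, ``tumor_type``, ``study_id``;
* variant calls are MAF-derived TSV with ``Tumor_Sample_Barcode``,
  ``Hugo_Symbol``, ``Variant_Classification``;
* gene / marker / drug-target sets use GMT;
* regulon networks are JSON mapping regulator -> list of
  ``{"target", "mode", "likelihood"}`` records;
* the loading matrix is TSV (gene rows, LV columns) with a JSON sidecar
  carrying the ridge constant and LV annotations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ParameterError, PlierModel, Regulon

MAF_COLUMNS = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")


# ---------------------------------------------------------------- matrices

def read_matrix(path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = identifier)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return df


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


# ---------------------------------------------------------------- metadata

def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "tumor_type", "study_id"} - set(meta.columns)
    if missing:
        raise ParameterError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ParameterError("duplicate sample ids in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- model

def write_model(model: PlierModel, tsv_path, sidecar_path) -> None:
    write_matrix(model.loadings, tsv_path, index_label="gene")
    payload = {"lambda2": model.lambda2, "lv_annotations": model.lv_annotations}
    Path(sidecar_path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_model(tsv_path, sidecar_path) -> PlierModel:
    Z = read_matrix(tsv_path)
    meta = json.loads(Path(sidecar_path).read_text())
    return PlierModel(Z, float(meta["lambda2"]), dict(meta.get("lv_annotations", {})))


# --------------------------------------------------------------------- GMT

def read_gmt(path) -> dict:
    """Read a GMT file into an ordered ``{set name: [members]}`` map."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParameterError(f"malformed GMT line: {line[:80]!r}")
        name, _desc, *members = parts
        sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- regulons

def write_regulons(regulons: list, path) -> None:
    payload = {
        r.regulator: [
            {"target": t, "mode": float(m), "likelihood": float(l)}
            for t, m, l in zip(r.targets, r.modes, r.likelihoods)
        ]
        for r in regulons
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_regulons(path) -> list:
    payload = json.loads(Path(path).read_text())
    regulons = []
    for regulator, records in payload.items():
        regulons.append(
            Regulon(
                regulator=regulator,
                targets=[rec["target"] for rec in records],
                modes=np.array([rec["mode"] for rec in records], dtype=float),
                likelihoods=np.array(
                    [rec.get("likelihood", 1.0) for rec in records], dtype=float
                ),
            )
        )
    return regulons


def regulons_from_gmt(path) -> list:
    """Import regulons from GMT: modes default to +1, equal likelihoods."""
    return [
        Regulon(name, members, np.ones(len(members)), np.ones(len(members)))
        for name, members in read_gmt(path).items()
    ]


# --------------------------------------------------------------------- MAF

def read_maf(path) -> pd.DataFrame:
    maf = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = set(MAF_COLUMNS) - set(maf.columns)
    if missing:
        raise ParameterError(f"MAF missing columns: {sorted(missing)}")
    return maf


def write_maf(maf: pd.DataFrame, path) -> None:
    maf.to_csv(path, sep="\t", index=False)
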