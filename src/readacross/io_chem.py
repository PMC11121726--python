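"""Reading compound/descriptor data and serializing models and reports.

Supported inputs: CSV (header row; id/smiles/ec50/docking metadata columns
recognised case-insensitively, every remaining numeric column treated as a
descriptor), SDF (V2000, via RDKit), and SMILES lists (one per line,
optional tab-separated id).  Model bundles are stored as a single JSON
document with an embedded schema version; Python's JSON float handling is
``repr``-based, so round-trips are bit-exact.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

if TYPE_CHECKING:  # pragma: no cover
    from .readacross_model import ModelBundle, Prediction

RDLogger.DisableLog("rdApp.error")

ID_ALIASES = ("id", "compound_id", "name")
SMILES_ALIASES = ("smiles",)
EC50_ALIASES = ("ec50", "ec50_um")
DOCKING_ALIASES = ("docking", "docking_score")

__all__ = [
    "CompoundRecord",
    "read_compounds",
    "save_model_bundle",
    "load_model_bundle",
    "write_prediction_report",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One molecule: id, SMILES, optional potency and docking score."""

    compound_id: str
    smiles: str
    ec50_uM: float | None = None
    docking_score: float | None = None
    canonical_smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if self.ec50_uM is not None and not self.ec50_uM > 0:
            raise ValueError(f"ec50_uM must be > 0 (compound {self.compound_id})")


def _canonicalize(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Validate and canonicalize SMILES; collect all failures into one error."""
    out, bad = [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            bad.append(rec.compound_id)
        else:
            out.append(
                CompoundRecord(
                    compound_id=rec.compound_id,
                    smiles=rec.smiles,
                    ec50_uM=rec.ec50_uM,
                    docking_score=rec.docking_score,
                    canonical_smiles=Chem.MolToSmiles(mol),
                )
            )
    if bad:
        raise ValueError(f"unparsable SMILES for compound(s): {', '.join(bad)}")
    return out


def _check_unique(ids: Sequence[str]) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate compound id(s): {', '.join(sorted(set(dups)))}")


def _find_column(columns, aliases) -> str | None:
    lowered = {str(c).strip().lower(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def _read_csv(path: Path) -> tuple[list[CompoundRecord], pd.DataFrame | None]:
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"empty file: {path}")
    id_col = _find_column(frame.columns, ID_ALIASES)
    smiles_col = _find_column(frame.columns, SMILES_ALIASES)
    if id_col is None or smiles_col is None:
        raise ValueError("CSV must contain an id column and a smiles column")
    ec50_col = _find_column(frame.columns, EC50_ALIASES)
    docking_col = _find_column(frame.columns, DOCKING_ALIASES)

    ids = [str(v) for v in frame[id_col]]
    _check_unique(ids)

    records = []
    for i, row in frame.iterrows():
        ec50 = row[ec50_col] if ec50_col else None
        dock = row[docking_col] if docking_col else None
        records.append(
            CompoundRecord(
                compound_id=str(row[id_col]),
                smiles=str(row[smiles_col]),
                ec50_uM=None if ec50 is None or pd.isna(ec50) else float(ec50),
                docking_score=None if dock is None or pd.isna(dock) else float(dock),
            )
        )
    records = _canonicalize(records)

    meta = {c for c in (id_col, smiles_col, ec50_col, docking_col) if c is not None}
    desc_cols = [
        c
        for c in frame.columns
        if c not in meta and pd.api.types.is_numeric_dtype(frame[c])
    ]
    table = None
    if desc_cols:
        table = frame[desc_cols].copy()
        table.index = pd.Index(ids)
        if table.isna().any().any():
            raise ValueError("descriptor columns contain missing values")
    return records, table


def _read_sdf(path: Path) -> tuple[list[CompoundRecord], None]:
    supplier = Chem.SDMolSupplier(str(path))
    records, bad = [], []
    count = 0
    for k, mol in enumerate(supplier):
        count += 1
        if mol is None:
            bad.append(f"record_{k + 1}")
            continue
        mol_id = None
        for prop in ("ID", "id", "_Name"):
            if mol.HasProp(prop) and mol.GetProp(prop).strip():
                mol_id = mol.GetProp(prop).strip()
                break
        if mol_id is None:
            mol_id = f"mol_{k + 1}"
        ec50 = None
        for prop in ("ec50_uM", "EC50", "ec50"):
            if mol.HasProp(prop):
                ec50 = float(mol.GetProp(prop))
                break
        smi = Chem.MolToSmiles(mol)
        records.append(
            CompoundRecord(
                compound_id=mol_id, smiles=smi, ec50_uM=ec50, canonical_smiles=smi
            )
        )
    if count == 0:
        raise ValueError(f"empty file: {path}")
    if bad:
        raise ValueError(f"unparsable SDF record(s): {', '.join(bad)}")
    _check_unique([r.compound_id for r in records])
    return records, None


def _read_smiles_list(path: Path) -> tuple[list[CompoundRecord], None]:
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty file: {path}")
    records = []
    for k, line in enumerate(lines):
        parts = line.split("\t")
        smi = parts[0].strip()
        mol_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"mol_{k + 1}"
        records.append(CompoundRecord(compound_id=mol_id, smiles=smi))
    _check_unique([r.compound_id for r in records])
    return _canonicalize(records), None


def read_compounds(
    path, format: str = "csv"
) -> tuple[list[CompoundRecord], pd.DataFrame | None]:
    """Read molecules (and any accompanying descriptor columns).

    Returns records in input order and, for CSV inputs with numeric
    non-metadata columns, a descriptor table (DataFrame indexed by
    compound id, columns in file order); otherwise ``None``.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if format == "csv":
        return _read_csv(p)
    if format == "sdf":
        return _read_sdf(p)
    if format == "smiles":
        return _read_smiles_list(p)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# model bundle serialization


def save_model_bundle(bundle: "ModelBundle", path) -> None:
    """Write a bundle as a single versioned JSON document (row-major
    nested arrays for matrices; full-precision floats)."""
    from .readacross_model import BUNDLE_SCHEMA_VERSION

    doc = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "selected_features": list(bundle.selected_features),
        "standardization": {
            "column_names": list(bundle.standardization.column_names),
            "mean": list(bundle.standardization.mean),
            "sd": list(bundle.standardization.sd),
        },
        "train_matrix": [list(map(float, row)) for row in bundle.train_matrix],
        "train_ids": list(bundle.train_ids),
        "train_labels": list(bundle.train_labels),
        "knn_config": {
            "k": bundle.knn_config.k,
            "weighting": bundle.knn_config.weighting,
            "report_extra_neighbor": bundle.knn_config.report_extra_neighbor,
        },
        "apd": {
            "z": bundle.apd.z,
            "d_bar": bundle.apd.d_bar,
            "sigma": bundle.apd.sigma,
            "threshold": bundle.apd.threshold,
        },
        "provenance": bundle.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model_bundle(path) -> "ModelBundle":
    """Inverse of :func:`save_model_bundle`; errors on schema-version
    mismatch or structurally incomplete documents."""
    import numpy as np

    from .readacross_model import (
        BUNDLE_SCHEMA_VERSION,
        ApdModel,
        KnnConfig,
        ModelBundle,
    )
    from .preprocess import StandardizationParams

    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != BUNDLE_SCHEMA_VERSION:
        raise ValueError(
            f"model bundle schema version mismatch: got {version!r}, "
            f"expected {BUNDLE_SCHEMA_VERSION!r}"
        )
    required = (
        "selected_features",
        "standardization",
        "train_matrix",
        "train_ids",
        "train_labels",
        "knn_config",
        "apd",
    )
    missing = [k for k in required if k not in doc]
    if missing:
        raise ValueError(f"model bundle missing block(s): {', '.join(missing)}")
    std = doc["standardization"]
    return ModelBundle(
        selected_features=tuple(doc["selected_features"]),
        standardization=StandardizationParams(
            column_names=tuple(std["column_names"]),
            mean=tuple(std["mean"]),
            sd=tuple(std["sd"]),
        ),
        train_matrix=np.asarray(doc["train_matrix"], dtype=float),
        train_ids=tuple(doc["train_ids"]),
        train_labels=tuple(doc["train_labels"]),
        knn_config=KnnConfig(**doc["knn_config"]),
        apd=ApdModel(**doc["apd"]),
        provenance=doc.get("provenance", {}),
    )


# ---------------------------------------------------------------------------
# prediction reports


def _compat_row(p: "Prediction") -> dict:
    # legacy field names reproduced verbatim, including the misspelled
    # "predictionReliablility" some downstream consumers key on
    row: dict = {"id": p.query_id}
    for i, (nn_id, dist) in enumerate(p.neighbors, start=1):
        row[f"idNN{i}"] = nn_id
        row[f"distNN{i}"] = dist
    row["domain"] = p.domain_distance
    row["apd"] = p.apd_threshold
    row["predictionReliablility"] = "reliable" if p.reliable else "not reliable"
    row["knnprediction"] = p.predicted_class
    return row


def _plain_row(p: "Prediction") -> dict:
    weights = {
        cls: (None if math.isinf(w) else w) for cls, w in p.vote_weights.items()
    }
    return {
        "query_id": p.query_id,
        "predicted_class": p.predicted_class,
        "neighbors": [{"id": nn_id, "distance": d} for nn_id, d in p.neighbors],
        "vote_weights": weights,
        "domain_distance": p.domain_distance,
        "apd_threshold": p.apd_threshold,
        "reliable": p.reliable,
    }


def write_prediction_report(
    predictions: Sequence["Prediction"],
    path,
    format: str = "json",
    compat_mode: bool = False,
) -> None:
    """Write predictions as JSON (array of objects) or CSV.

    ``compat_mode`` reproduces the legacy flat schema (id, idNN1...,
    distNN1..., domain, apd, predictionReliablility, knnprediction).
    Neighbour distances are emitted in ascending order.
    """
    rows = [(_compat_row if compat_mode else _plain_row)(p) for p in predictions]
    p = Path(path)
    if format == "json":
        p.write_text(json.dumps(rows, indent=1))
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    flat = []
    for row in rows:
        if compat_mode:
            flat.append(row)
        else:
            f = {
                "query_id": row["query_id"],
                "predicted_class": row["predicted_class"],
                "domain_distance": row["domain_distance"],
                "apd_threshold": row["apd_threshold"],
                "reliable": row["reliable"],
            }
            for i, nn in enumerate(row["neighbors"], start=1):
                f[f"nn{i}_id"] = nn["id"]
                f[f"nn{i}_distance"] = nn["distance"]
            flat.append(f)
    fieldnames: list[str] = []
    for row in flat:
        for key in row:
            if key not in fieldnames:
                fieldnames.append(key)
    with p.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(flat)
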