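"""Dataset and artifact I/O.

Datasets travel as plain CSV with header
``aw,temperature_c,method,branch,replicate,xe`` (UTF-8, LF line endings,
full float precision).  Synthetic datasets carry a JSON sidecar
(``<stem>.truth.json``) holding the ground-truth model, parameters, noise
descriptor and seed.  Moisture is decimal dry basis internally; a percent
convention flag converts at the boundary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .synthetic import BRANCHES, COLUMNS, METHODS, IsothermDataset

__all__ = ["read_dataset", "write_dataset", "sidecar_path"]


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".truth.json")


def write_dataset(dataset: IsothermDataset, path) -> Path:
    """Write a dataset CSV (and its truth sidecar when synthetic)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = dataset.frame[list(COLUMNS)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.aw!r},{row.temperature_c!r},{row.method},{row.branch},"
                f"{int(row.replicate)},{row.xe!r}\n"
            )
    if dataset.provenance == "synthetic":
        meta = {"seed": dataset.seed, "provenance": dataset.provenance,
                "truth": dataset.truth}
        sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n",
                                      encoding="utf-8")
    return path


def read_dataset(path, percent: bool = False,
                 column_map: dict[str, str] | None = None) -> IsothermDataset:
    """Read and validate a dataset CSV.

    Parameters
    ----------
    percent
        Set when the file stores moisture in % dry basis; values are divided
        by 100 on ingest (internal convention is decimal dry basis).
    column_map
        Optional ``{file_column: canonical_column}`` renaming for ingesting
        third-party spreadsheets.

    Errors name the offending column or row.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    if "replicate" not in df.columns:
        df["replicate"] = 1
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    df = df[list(COLUMNS)].copy()
    for col in ("aw", "temperature_c", "xe"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if len(bad):
            raise SchemaError(f"{path.name}: non-numeric {col} at row {bad[0] + 2}")
        df[col] = vals
    if percent:
        df["xe"] = df["xe"] / 100.0
    bad = np.flatnonzero(((df["aw"] <= 0) | (df["aw"] >= 1)).to_numpy())
    if len(bad):
        raise SchemaError(
            f"{path.name}: aw={df['aw'].iloc[bad[0]]} outside (0, 1) at row {bad[0] + 2}")
    bad = np.flatnonzero((df["xe"] < 0).to_numpy())
    if len(bad):
        raise SchemaError(f"{path.name}: negative xe at row {bad[0] + 2}")
    bad = np.flatnonzero((~df["method"].isin(METHODS)).to_numpy())
    if len(bad):
        raise SchemaError(
            f"{path.name}: unknown method {df['method'].iloc[bad[0]]!r} at row "
            f"{bad[0] + 2}; valid: {METHODS}")
    bad = np.flatnonzero((~df["branch"].isin(BRANCHES)).to_numpy())
    if len(bad):
        raise SchemaError(
            f"{path.name}: unknown branch {df['branch'].iloc[bad[0]]!r} at row "
            f"{bad[0] + 2}; valid: {BRANCHES}")

    side = sidecar_path(path)
    truth = seed = None
    provenance = "measured"
    if side.exists():
        meta = json.loads(side.read_text(encoding="utf-8"))
        truth = meta.get("truth")
        seed = meta.get("seed")
        provenance = meta.get("provenance", "synthetic")
    return IsothermDataset(df, provenance=provenance, truth=truth, seed=seed)
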