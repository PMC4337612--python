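"""File formats: BIDS-style events TSV, NIfTI volumes, config snapshots."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .config import ParseError, PipelineConfig, config_from_dict, to_dict

EVENTS_COLUMNS = [
    "onset",
    "duration",
    "item",
    "list",
    "room",
    "response",
    "rt",
    "memory_status",
]

_NUMERIC = {"onset": float, "duration": float, "rt": float, "response": int, "run": int, "trial": int}


def write_events_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as a BIDS-style events TSV (missing -> 'n/a')."""

    table.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.4f")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    """Read an events TSV, validating column counts line by line.

    'n/a' becomes a missing value (never 0); malformed rows raise a parse
    error carrying the 1-based line number.
    """

    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty events file", line=1)
    header = lines[0].split("\t")
    n_cols = len(header)
    records = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if raw == "":
            continue
        fields = raw.split("\t")
        if len(fields) != n_cols:
            raise ParseError(
                f"expected {n_cols} tab-separated fields, found {len(fields)}",
                line=lineno,
            )
        records.append(fields)
    df = pd.DataFrame(records, columns=header)
    df = df.replace("n/a", np.nan)
    for col, dtype in _NUMERIC.items():
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if dtype is int and not df[col].isna().any():
                df[col] = df[col].astype(int)
    return df


def ras_affine(voxel_size_mm: float = 3.0) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size_mm
    return aff


def write_nifti(
    data: np.ndarray, path: str | Path, voxel_size_mm: float = 3.0
) -> None:
    """Write a 3D mask or 4D run as NIfTI-1 with an RAS+ affine."""

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), ras_affine(voxel_size_mm))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_config(config: PipelineConfig, path: str | Path) -> None:
    path = Path(path)
    payload = to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return config_from_dict(payload)
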