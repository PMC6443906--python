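"""TSV input/output and manifest helpers.

All tables are UTF-8 TSV with a header row and '.' decimal; absent
reporter intensities are empty fields (a literal 0 is also treated as
absent on read, since a detected reporter ion is never truly zero).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import INTENSITY_COLUMNS


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="")


def read_psm_table(path: str | Path) -> pd.DataFrame:
    psm = pd.read_csv(path, sep="\t", dtype={"proteins": str, "tmt_set": str})
    for col in INTENSITY_COLUMNS:
        vals = pd.to_numeric(psm[col], errors="coerce")
        psm[col] = vals.where(vals != 0.0)
    return psm


def read_samples_table(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(
        path,
        sep="\t",
        dtype={"sample_id": str, "donor_id": str, "tmt_set": str, "channel": str},
    )
    samples["donor_id"] = samples["donor_id"].fillna("")
    return samples


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_purity_matrix(path: str | Path) -> np.ndarray:
    mat = np.loadtxt(path, delimiter="\t")
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"purity matrix in {path} must be square")
    return mat


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
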