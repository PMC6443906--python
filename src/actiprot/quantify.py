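"""Normalization and protein roll-up.

Implements the quantification arithmetic: log2 transform of reporter
intensities, median-centering of each protein's spectra within a TMT
set, roll-up to a protein x sample matrix by the median over all of a
protein's spectrum-level values, and sample-loading correction by
subtracting each sample column's median so every column has zero
median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CHANNELS
from .simulate import INTENSITY_COLUMNS

#: Tolerance on the zero-median invariants.
MEDIAN_TOL = 1e-9


@dataclass
class ProteinQuantMatrix:
    """Proteins x non-reference samples, log2 relative abundance.

    ``values_df`` is indexed by accession with sample-id columns;
    ``provenance`` records the number of spectra and distinct peptides
    backing each (protein, sample) cell.
    """

    values_df: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def accessions(self) -> list[str]:
        return list(self.values_df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values_df.columns)


def log2_transform(psms: pd.DataFrame) -> pd.DataFrame:
    """Replace each reporter intensity by its base-2 logarithm."""
    out = psms.copy()
    values = out.loc[:, list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
    bad = np.nonzero(~(values > 0))
    if bad[0].size:
        row = int(bad[0][0])
        sid = out.iloc[row].get("spectrum_id", f"row {row}")
        raise ValueError(
            f"nonpositive intensity in record {sid!r}; "
            "filter for complete channels before transforming"
        )
    out[list(INTENSITY_COLUMNS)] = np.log2(values)
    return out


def normalize_within_protein(psms: pd.DataFrame, per_set: bool = False) -> pd.DataFrame:
    """Center each protein's spectra by median subtraction.

    The median over all of a protein's spectrum-by-channel log2 values
    across all channels (reference included) is subtracted, leaving a
    zero median per protein.  Centering is global by default: set-to-set
    intensity offsets deliberately remain in the data, to be absorbed by
    the TMT-experiment adjustment in the downstream model.  With
    ``per_set=True`` the median is instead taken within each (protein,
    TMT set); that variant also removes the genuine batch effects the
    model is meant to adjust for, and its subtracted median tracks the
    set's activity levels, attenuating between-set effect information.
    """
    out = psms.copy()
    cols = list(INTENSITY_COLUMNS)
    values = out.loc[:, cols].to_numpy(dtype=float)
    if per_set:
        key_series = out["proteins"] + "\x00" + out["tmt_set"]
    else:
        key_series = out["proteins"]
    flat = pd.DataFrame(
        {
            "key": np.repeat(key_series.to_numpy(), len(cols)),
            "value": values.ravel(),
        }
    )
    medians = flat.groupby("key", sort=False)["value"].median()
    keys = key_series.map(medians).to_numpy()
    out[cols] = values - keys[:, None]
    return out


def rollup_protein(
    psms: pd.DataFrame, samples: pd.DataFrame
) -> ProteinQuantMatrix:
    """Roll centered spectra up to a protein x sample matrix.

    Each cell is the median over all retained spectrum-level values of
    all the protein's peptides in that sample's channel ("combined
    together": one pooled median, not a median of peptide medians).
    Even counts use the mean-of-middle convention.  Reference channels
    are excluded from the output columns.
    """
    non_ref = samples.loc[samples["is_reference"] == 0]
    channel_col = {
        (row["tmt_set"], row["channel"]): row["sample_id"]
        for _, row in non_ref.iterrows()
    }
    long_parts = []
    for ch, col in zip(CHANNELS, INTENSITY_COLUMNS):
        part = psms.loc[:, ["proteins", "peptide_seq", "tmt_set"]].copy()
        part["channel"] = ch
        part["value"] = psms[col].to_numpy(dtype=float)
        long_parts.append(part)
    long = pd.concat(long_parts, ignore_index=True)
    long["sample_id"] = [
        channel_col.get((s, c)) for s, c in zip(long["tmt_set"], long["channel"])
    ]
    long = long.dropna(subset=["sample_id"])

    grouped = long.groupby(["proteins", "sample_id"], sort=True)
    agg = grouped.agg(
        value=("value", "median"),
        n_spectra=("value", "size"),
        n_peptides=("peptide_seq", "nunique"),
    ).reset_index()
    values = agg.pivot(index="proteins", columns="sample_id", values="value")
    values.index.name = "accession"
    sample_order = [s for s in non_ref["sample_id"] if s in values.columns]
    values = values.loc[:, sample_order]
    provenance = agg.rename(columns={"proteins": "accession"})[
        ["accession", "sample_id", "n_spectra", "n_peptides"]
    ]
    if values.isna().any().any():
        missing = values.index[values.isna().any(axis=1)]
        raise ValueError(
            "matrix has absent cells for protein(s) "
            + ", ".join(map(str, missing[:5]))
            + "; apply the retention filters first"
        )
    return ProteinQuantMatrix(values_df=values, provenance=provenance)


def median_polish_loading(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Correct sample-loading differences by column-median subtraction.

    Subtracts each sample column's median across proteins, leaving every
    column with zero median.  This is the single-pass channel-median
    centering that defines the loading correction here, not Tukey's
    iterative row/column polish.
    """
    values = matrix.values_df - matrix.values_df.median(axis=0)
    col_med = values.median(axis=0).abs()
    assert (col_med < MEDIAN_TOL).all(), "column medians nonzero after polish"
    return ProteinQuantMatrix(values_df=values, provenance=matrix.provenance)


def quantify(psms: pd.DataFrame, samples: pd.DataFrame) -> ProteinQuantMatrix:
    """Full quantification chain on a filtered PSM table."""
    transformed = log2_transform(psms)
    centered = normalize_within_protein(transformed)
    matrix = rollup_protein(centered, samples)
    return median_polish_loading(matrix)
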