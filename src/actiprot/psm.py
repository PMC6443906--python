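"""Isotopic purity correction and PSM retention filters.

The retention rules mirror standard TMT quantification practice: decoy
and contaminant spectra are discarded, peptide/protein FDR thresholds
applied, spectra shared between proteins or missing reporter channels
dropped, quantifiable peptides restricted to those detected in every
sample, and single-peptide proteins kept only when confirmed by more
than one search engine.  Every rule's effect is recorded in an
auditable :class:`FilterReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CHANNELS, FilterThresholds
from .simulate import INTENSITY_COLUMNS

#: Condition number above which purity correction warns about instability.
CONDITION_WARN_THRESHOLD = 1e6


class NoQuantifiableProteinsError(RuntimeError):
    """Raised when the retention filters empty the PSM table."""


@dataclass
class FilterReport:
    """Ordered per-rule record counts; counts telescope rule to rule."""

    rules: list[dict] = field(default_factory=list)
    n_proteins_in: int = 0
    n_proteins_out: int = 0

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.rules.append(
            {"rule": name, "records_in": n_in, "records_removed": n_in - n_out,
             "records_out": n_out}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rules,
            columns=["rule", "records_in", "records_removed", "records_out"],
        )


def correct_isotopic_purity(
    intensities: np.ndarray, purity_matrix: np.ndarray
) -> np.ndarray:
    """Invert reporter-channel crosstalk for one spectrum.

    Solves ``purity_matrix @ x = observed`` and clamps negative
    components to 0.  Vectors with absent (NaN) channels are returned
    unchanged — correction is only defined on complete spectra.
    """
    observed = np.asarray(intensities, dtype=float)
    p = np.asarray(purity_matrix, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] != observed.shape[-1]:
        raise ValueError(
            f"purity matrix shape {p.shape} does not match {observed.shape[-1]} channels"
        )
    cond = np.linalg.cond(p)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("purity matrix is singular; cannot correct isotopic impurity")
    if cond > CONDITION_WARN_THRESHOLD:
        warnings.warn(
            f"purity matrix condition number {cond:.3g} exceeds "
            f"{CONDITION_WARN_THRESHOLD:.0e}; corrected intensities may be unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    single = observed.ndim == 1
    obs2 = np.atleast_2d(observed)
    complete = ~np.isnan(obs2).any(axis=1)
    out = obs2.copy()
    if complete.any():
        solved = np.linalg.solve(p, obs2[complete].T).T
        out[complete] = np.clip(solved, 0.0, None)
    return out[0] if single else out


def apply_purity_correction(
    psms: pd.DataFrame, purity_matrix: np.ndarray
) -> pd.DataFrame:
    """Purity-correct all complete spectra in a PSM table.

    Records with absent channels are passed through unchanged and
    flagged in the ``purity_corrected`` column.
    """
    out = psms.copy()
    values = out.loc[:, list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
    corrected = correct_isotopic_purity(values, purity_matrix)
    out[list(INTENSITY_COLUMNS)] = corrected
    out["purity_corrected"] = (~np.isnan(values).any(axis=1)).astype(int)
    return out


def _protein_count(psms: pd.DataFrame) -> int:
    if len(psms) == 0:
        return 0
    return psms["proteins"].str.split(";").explode().nunique()


def filter_psm_table(
    psms: pd.DataFrame,
    samples: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the retention rules in a fixed, auditable order.

    Rules, in order: (1) drop decoys; (2) drop contaminants;
    (3) peptide FDR <= threshold; (4) protein FDR <= threshold;
    (5) spectra exclusive to one protein; (6) spectra identified in all
    6 channels (absent or zero intensity counts as missing);
    (7) peptides detected in every non-reference sample, i.e. with at
    least one retained spectrum in every TMT set holding donors;
    (8) drop proteins whose entire evidence is a single peptide
    confirmed by fewer than two search engines.

    Raises :class:`NoQuantifiableProteinsError` naming the first rule
    that emptied the table.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    report = FilterReport(n_proteins_in=_protein_count(psms))
    current = psms

    def apply(name: str, mask: pd.Series) -> None:
        nonlocal current
        n_in = len(current)
        current = current.loc[mask]
        report.add(name, n_in, len(current))
        if n_in > 0 and len(current) == 0:
            raise NoQuantifiableProteinsError(
                f"no quantifiable proteins: rule '{name}' removed all remaining records"
            )

    apply("decoy", current["is_decoy"] == 0)
    apply("contaminant", current["is_contaminant"] == 0)
    apply("peptide_fdr", current["peptide_fdr"] <= thresholds.peptide_fdr)
    apply("protein_fdr", current["protein_fdr"] <= thresholds.protein_fdr)
    apply("shared_spectrum", ~current["proteins"].str.contains(";"))

    inten = current.loc[:, list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
    complete = ~(np.isnan(inten) | (inten == 0.0)).any(axis=1)
    apply("complete_channels", pd.Series(complete, index=current.index))

    # rule 7: a peptide must be observed in every TMT set holding a
    # non-reference sample (a complete spectrum covers all of its set's
    # donors at once)
    donor_sets = set(samples.loc[samples["is_reference"] == 0, "tmt_set"].unique())
    sets_per_peptide = current.groupby("peptide_seq")["tmt_set"].agg(set)
    full_coverage = sets_per_peptide[
        sets_per_peptide.map(lambda s: donor_sets.issubset(s))
    ].index
    apply("peptide_in_all_samples", current["peptide_seq"].isin(full_coverage))

    # rule 8: single-peptide proteins need >1 confirming engine
    per_protein = current.groupby("proteins").agg(
        n_peptides=("peptide_seq", "nunique"),
        max_engines=("engines_confirming", "max"),
    )
    bad = per_protein.index[
        (per_protein["n_peptides"] == 1) & (per_protein["max_engines"] < 2)
    ]
    apply("single_peptide_engines", ~current["proteins"].isin(bad))

    report.n_proteins_out = _protein_count(current)
    return current.reset_index(drop=True), report
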