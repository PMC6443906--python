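"""Configuration objects for the cohort generator and the pipeline.

All configs are plain dataclasses with eager validation; ``from_dict``
constructors reject unknown keys so that a typo in a YAML file fails
before any stage runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Any, Mapping, Sequence

import numpy as np

#: TMT 6-plex reporter channels, in mass order.
CHANNELS: tuple[str, ...] = ("126", "127", "128", "129", "130", "131")

#: Reporter channel carrying the pooled reference sample in every set.
REFERENCE_CHANNEL: str = "131"

#: Age strata; each TMT set holds one donor from each stratum.
AGE_STRATA: tuple[tuple[int, int], ...] = (
    (20, 34),
    (35, 49),
    (50, 64),
    (65, 79),
    (80, 95),
)

#: Accessions used for the fiber-type ratio covariate
#: (type I myosin over the sum of type II myosins).
FIBER_TYPE_I: str = "MYH7"
FIBER_TYPE_II: tuple[str, ...] = ("MYH1", "MYH2", "MYH4")


def default_purity_matrix(n_channels: int = 6) -> np.ndarray:
    """Default reporter-ion isotopic impurity matrix.

    ``P[i, j]`` is the fraction of channel ``i``'s true signal observed in
    channel ``j``; observed intensities are ``P.T @ true`` is not used —
    the convention throughout is ``observed = P @ true`` with a dominant
    diagonal, mimicking the lot-specific crosstalk tables shipped with
    TMT kits (a few percent of signal spilling into the -1/+1 channels).
    """
    p = np.eye(n_channels) * 0.9
    for i in range(n_channels):
        if i > 0:
            p[i, i - 1] = 0.05
        if i < n_channels - 1:
            p[i, i + 1] = 0.05
    return p


def _reject_unknown(cls: type, data: Mapping[str, Any]) -> None:
    known = {f.name for f in dc_fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {', '.join(unknown)}; "
            f"known keys: {', '.join(sorted(known))}"
        )


@dataclass
class CohortConfig:
    """Design constants and variance components of a synthetic TMT cohort.

    Defaults are the study conditions: 60 donors in twelve 6-plex sets
    (five donors, one per age stratum, plus one reference channel per
    set), activity-effect magnitudes spanning the observed per-activity-
    point log2 effect range, and reporter-level noise typical of TMT
    spectra.

    Parameters
    ----------
    n_donors:
        Number of donors; sets are filled five at a time.
    n_proteins:
        Proteins to simulate; the first four accessions are always the
        myosin heavy chains MYH7/MYH1/MYH2/MYH4 so the fiber-type ratio
        covariate is computable.
    frac_nonnull:
        Fraction of non-myosin proteins with a nonzero activity effect.
    beta_range:
        (low, high) magnitude bounds, log2-units per activity point, for
        nonzero activity effects; the sign is drawn separately.
    sigma_spectrum:
        SD of spectrum-by-channel measurement noise, log2 units.
    tau_batch:
        SD of the per-(protein, TMT set) random batch intercept.
    loading_sd:
        SD of per-(set, channel) sample-loading offsets, log2 units.
    peptide_offset_sd:
        SD of per-peptide ionization-efficiency offsets, log2 units.
    fiber_donor_sd:
        SD of per-(myosin, donor) abundance shifts emulating fiber-type
        composition differences between donors.
    frac_*:
        Nuisance-record rates (decoys, contaminants, shared spectra,
        spectra with blanked channels, peptides absent from some sets,
        high-FDR records, single-search-engine identifications).
    """

    n_donors: int = 60
    donors_per_set: int = 5
    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (1, 4)
    spectra_per_peptide: tuple[int, int] = (1, 3)
    frac_nonnull: float = 0.25
    beta_range: tuple[float, float] = (0.02, 0.22)
    beta_age_sd: float = 0.002
    beta_bmi_sd: float = 0.004
    sigma_spectrum: float = 0.20
    tau_batch: float = 0.05
    loading_sd: float = 0.10
    peptide_offset_sd: float = 0.30
    fiber_donor_sd: float = 0.40
    baseline_log2_mean: float = 18.0
    baseline_log2_sd: float = 2.0
    frac_decoy: float = 0.05
    frac_contaminant: float = 0.02
    frac_shared: float = 0.03
    frac_missing_channel: float = 0.03
    frac_incomplete_peptide: float = 0.05
    frac_high_peptide_fdr: float = 0.02
    frac_high_protein_fdr: float = 0.02
    frac_single_engine: float = 0.20
    purity_matrix: np.ndarray = field(default_factory=default_purity_matrix)
    seed: int = 0

    @property
    def n_sets(self) -> int:
        return math.ceil(self.n_donors / self.donors_per_set)

    def __post_init__(self) -> None:
        self.purity_matrix = np.asarray(self.purity_matrix, dtype=float)
        if isinstance(self.peptides_per_protein, Sequence):
            self.peptides_per_protein = tuple(self.peptides_per_protein)
        if isinstance(self.spectra_per_peptide, Sequence):
            self.spectra_per_peptide = tuple(self.spectra_per_peptide)
        self.beta_range = tuple(self.beta_range)
        self.validate()

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ValueError("n_donors must be positive")
        if self.donors_per_set < 1:
            raise ValueError("donors_per_set must be positive")
        if self.donors_per_set * self.n_sets < self.n_donors:
            raise ValueError("donors_per_set * n_sets must cover n_donors")
        if self.n_donors % self.donors_per_set != 0:
            raise ValueError(
                "n_donors must fill TMT sets completely "
                f"(multiple of {self.donors_per_set})"
            )
        if self.n_proteins < 8:
            raise ValueError("n_proteins must be at least 8 (4 myosins + others)")
        for name in (
            "frac_nonnull",
            "frac_decoy",
            "frac_contaminant",
            "frac_shared",
            "frac_missing_channel",
            "frac_incomplete_peptide",
            "frac_high_peptide_fdr",
            "frac_high_protein_fdr",
            "frac_single_engine",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "sigma_spectrum",
            "tau_batch",
            "loading_sd",
            "peptide_offset_sd",
            "fiber_donor_sd",
            "beta_age_sd",
            "beta_bmi_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein must be an increasing range >= 1")
        lo, hi = self.spectra_per_peptide
        if not (1 <= lo <= hi):
            raise ValueError("spectra_per_peptide must be an increasing range >= 1")
        lo, hi = self.beta_range
        if not (0 < lo <= hi):
            raise ValueError("beta_range must be positive and increasing")
        p = self.purity_matrix
        if p.shape != (len(CHANNELS), len(CHANNELS)):
            raise ValueError(f"purity_matrix must be {len(CHANNELS)}x{len(CHANNELS)}")
        if (p < 0).any():
            raise ValueError("purity_matrix entries must be nonnegative")
        diag = np.diag(p)
        off = p - np.diag(diag)
        if (diag <= off.sum(axis=1)).any():
            raise ValueError("purity_matrix must be diagonally dominant by rows")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "CohortConfig":
        _reject_unknown(cls, data)
        return cls(**dict(data))


@dataclass
class FilterThresholds:
    """FDR thresholds for PSM retention."""

    peptide_fdr: float = 0.001
    protein_fdr: float = 0.01

    def __post_init__(self) -> None:
        for name in ("peptide_fdr", "protein_fdr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "FilterThresholds":
        _reject_unknown(cls, data)
        return cls(**dict(data))


@dataclass
class PipelineConfig:
    """Top-level pipeline configuration (YAML-serializable)."""

    out_dir: str = "actiprot_out"
    #: optional pre-existing inputs; when unset the cohort is simulated
    psm_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    purity_path: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    model: "Any" = None  # ModelSpec; late import to avoid a cycle
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        from .models import ModelSpec

        if self.model is None:
            self.model = ModelSpec()
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if (self.psm_path is None) != (self.samples_path is None):
            raise ValueError(
                "psm_path and samples_path must be given together "
                "(or both omitted to simulate a cohort)"
            )

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        from .models import ModelSpec

        _reject_unknown(cls, data)
        data = dict(data)
        if "cohort" in data and isinstance(data["cohort"], Mapping):
            data["cohort"] = CohortConfig.from_dict(data["cohort"])
        if "filters" in data and isinstance(data["filters"], Mapping):
            data["filters"] = FilterThresholds.from_dict(data["filters"])
        if "model" in data and isinstance(data["model"], Mapping):
            data["model"] = ModelSpec.from_dict(data["model"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, Mapping):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(raw)
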