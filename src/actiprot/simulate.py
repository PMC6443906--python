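"""Synthetic TMT cohort generator with ground truth.

Emulates the data-generating process the downstream analysis assumes:
6-plex TMT sets each holding five donors (one per age stratum) plus a
pooled reference channel, per-protein linear effects of activity, age
and BMI on log2 abundance, per-(protein, set) random batch intercepts,
per-(set, channel) loading offsets, per-peptide ionization offsets and
spectrum-level noise.  Emitted reporter intensities are linear-scale and
mixed through the isotopic-impurity matrix, and the PSM table carries
realistic nuisance records: decoys, contaminants, spectra shared between
proteins, spectra with blanked channels, peptides missing from some
sets, high-FDR records and single-engine identifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import AGE_STRATA, CHANNELS, REFERENCE_CHANNEL, CohortConfig
from .covariates import (
    ActivityRecord,
    MVPA_TYPES,
    activity_columns,
    categorize_activity,
    records_to_row,
)

_RACE_LEVELS = ("white", "black", "other")
_RACE_PROBS = (0.55, 0.35, 0.10)
#: Marginal distribution of ordinal activity codes in the cohort.
_PA_CODE_PROBS = (0.35, 0.20, 0.20, 0.25)
_SESSION_MINUTES = (20, 30, 40, 60)
_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_CONTAMINANTS = ("CONT_KRT1", "CONT_KRT10", "CONT_TRYP", "CONT_ALB")

INTENSITY_COLUMNS = tuple(f"intensity_{c}" for c in CHANNELS)

PSM_COLUMNS = (
    "spectrum_id",
    "peptide_seq",
    "proteins",
    "tmt_set",
    *INTENSITY_COLUMNS,
    "is_decoy",
    "is_contaminant",
    "peptide_fdr",
    "protein_fdr",
    "engines_confirming",
)


@dataclass
class CohortTruth:
    """Generator ground truth for a synthetic cohort.

    ``protein_effects`` holds each protein's true regression coefficients
    (log2-units per activity point / year / kg/m²); null proteins have
    ``beta_pa`` exactly 0.  ``sample_truth`` holds each donor's true MVPA
    minutes and ordinal code alongside demographics; ``loading_offsets``
    the per-(set, channel) log2 loading shifts; ``report`` realized
    nuisance counts and generation warnings.
    """

    protein_effects: pd.DataFrame
    sample_truth: pd.DataFrame
    loading_offsets: pd.DataFrame
    report: dict[str, Any] = field(default_factory=dict)


def simulate_activity_records(
    pa_minutes_target: float,
    rng: np.random.Generator,
    casual_walking_prob: float = 0.7,
) -> list[ActivityRecord]:
    """Build questionnaire records realizing a target of weekly MVPA minutes.

    Splits ``2 * pa_minutes_target`` minutes over the past 2 weeks across
    one to three MVPA activities (whole sessions of typical durations,
    with the final activity absorbing the exact remainder so that scoring
    the records reproduces the target exactly).  A casual-walking record
    is generated independently and never contributes to MVPA.
    """
    if pa_minutes_target < 0:
        raise ValueError(
            f"pa_minutes_target must be nonnegative, got {pa_minutes_target}"
        )
    records: list[ActivityRecord] = []
    remaining = 2.0 * pa_minutes_target
    if remaining > 0:
        n_act = int(rng.integers(1, 4))
        pool = list(rng.permutation(MVPA_TYPES)[:n_act])
        for act in pool[:-1]:
            duration = int(rng.choice(_SESSION_MINUTES))
            max_freq = min(14, int(remaining // duration) - 1)
            if max_freq < 1:
                continue
            freq = int(rng.integers(1, max_freq + 1))
            records.append(
                ActivityRecord(act, performed=True, frequency=freq, duration=duration)
            )
            remaining -= freq * duration
        if remaining > 0:
            # powers of two keep frequency * (remaining / frequency) exact;
            # grow the session count so single sessions stay under ~90 min
            freq = int(rng.choice((1, 2)))
            while remaining / freq > 90 and freq < 16:
                freq *= 2
            records.append(
                ActivityRecord(
                    pool[-1], performed=True, frequency=freq,
                    duration=remaining / freq,
                )
            )
    if rng.random() < casual_walking_prob:
        records.append(
            ActivityRecord(
                "casual_walking",
                performed=True,
                frequency=int(rng.integers(2, 15)),
                duration=int(rng.integers(10, 61)),
            )
        )
    return records


def _simulate_donors(config: CohortConfig, rng: np.random.Generator):
    """Per-set donors (one per age stratum) with demographics and activity."""
    set_ids = [f"set{b + 1:02d}" for b in range(config.n_sets)]
    donor_rows = []
    donor_records = {}
    donor_counter = 0
    for set_id in set_ids:
        strata = rng.permutation(len(AGE_STRATA))
        channels = [c for c in CHANNELS if c != REFERENCE_CHANNEL]
        for channel, stratum in zip(channels, strata):
            donor_counter += 1
            donor_id = f"D{donor_counter:03d}"
            lo, hi = AGE_STRATA[stratum]
            code = int(rng.choice(4, p=_PA_CODE_PROBS))
            if code == 0:
                target = 0.0 if rng.random() < 0.5 else float(rng.uniform(1, 30))
            elif code == 1:
                target = float(rng.uniform(30, 75))
            elif code == 2:
                target = float(rng.uniform(75, 150))
            else:
                target = float(rng.uniform(150, 360))
            records = simulate_activity_records(target, rng)
            donor_records[donor_id] = records
            donor_rows.append(
                {
                    "donor_id": donor_id,
                    "tmt_set": set_id,
                    "channel": channel,
                    "age": int(rng.integers(lo, hi + 1)),
                    "sex": str(rng.choice(("F", "M"))),
                    "race": str(rng.choice(_RACE_LEVELS, p=_RACE_PROBS)),
                    "bmi": float(np.round(np.clip(rng.normal(27.0, 4.0), 18.0, 42.0), 1)),
                    "pa_minutes": target,
                    "pa_code": categorize_activity(target),
                }
            )
    return set_ids, pd.DataFrame(donor_rows), donor_records


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 16))
    return "".join(rng.choice(_AMINO_ACIDS, size=length)) + "K"


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate a synthetic cohort: PSM table, sample metadata and truth.

    The log2 intensity of spectrum ``s`` (peptide ``j`` of protein ``p``)
    in the channel of donor ``i``, set ``b``, is::

        m_p + e_j + beta_pa,p * PA_i + beta_age,p * age_i
            + beta_bmi,p * BMI_i + u_{p,b} + L_{b,c} + eps

    with ``u ~ N(0, tau_batch^2)`` and ``eps ~ N(0, sigma_spectrum^2)``;
    the reference channel carries the covariate-free pooled profile.
    Intensities are exponentiated to the linear scale and mixed through
    the isotopic-impurity matrix.  Bit-reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ch = len(CHANNELS)
    ref_idx = CHANNELS.index(REFERENCE_CHANNEL)

    set_ids, donors, donor_records = _simulate_donors(config, rng)
    set_index = {s: b for b, s in enumerate(set_ids)}
    ch_index = {c: k for k, c in enumerate(CHANNELS)}

    # per-(set, channel) covariate design: PA code, age, BMI (0 for reference)
    cov = np.zeros((config.n_sets, n_ch, 3))
    donor_of = np.full((config.n_sets, n_ch), -1, dtype=int)
    for d_i, row in donors.iterrows():
        b, k = set_index[row["tmt_set"]], ch_index[row["channel"]]
        cov[b, k] = (row["pa_code"], row["age"], row["bmi"])
        donor_of[b, k] = d_i

    # protein truth -------------------------------------------------------
    accessions = ["MYH7", "MYH1", "MYH2", "MYH4"] + [
        f"P{i:04d}" for i in range(5, config.n_proteins + 1)
    ]
    n_prot = len(accessions)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_prot)
    beta_pa = np.zeros(n_prot)
    beta_age = np.zeros(n_prot)
    beta_bmi = np.zeros(n_prot)
    nonnull = np.zeros(n_prot, dtype=bool)
    for p in range(4, n_prot):  # myosins stay null: fiber ratio is exogenous
        beta_age[p] = rng.normal(0.0, config.beta_age_sd)
        beta_bmi[p] = rng.normal(0.0, config.beta_bmi_sd)
        if rng.random() < config.frac_nonnull:
            nonnull[p] = True
            lo, hi = config.beta_range
            beta_pa[p] = rng.choice((-1.0, 1.0)) * rng.uniform(lo, hi)

    u_batch = rng.normal(0.0, config.tau_batch, (n_prot, config.n_sets))
    loading = rng.normal(0.0, config.loading_sd, (config.n_sets, n_ch))
    # donor-level fiber-composition shifts, applied to the four myosins
    fiber_shift = rng.normal(0.0, config.fiber_donor_sd, (4, len(donors)))

    # per-protein covariate effect per (set, channel)
    betas = np.column_stack([beta_pa, beta_age, beta_bmi])
    eff = np.einsum("pk,bck->pbc", betas, cov)
    for m in range(4):
        mask = donor_of >= 0
        eff[m][mask] += fiber_shift[m, donor_of[mask]]

    # peptide / spectrum layout ------------------------------------------
    pep_lo, pep_hi = config.peptides_per_protein
    spec_lo, spec_hi = config.spectra_per_peptide
    pep_protein: list[int] = []
    pep_seqs: list[str] = []
    pep_sets: list[np.ndarray] = []
    n_incomplete = 0
    for p in range(n_prot):
        # myosin heavy chains dominate muscle lysates: deep, complete
        # peptide coverage so the fiber-ratio covariate always survives
        is_myosin = p < 4
        n_pep = (
            max(4, pep_hi)
            if is_myosin
            else int(rng.integers(pep_lo, pep_hi + 1))
        )
        for _ in range(n_pep):
            pep_protein.append(p)
            pep_seqs.append(_random_peptide(rng))
            if (
                not is_myosin
                and config.frac_incomplete_peptide > 0
                and rng.random() < config.frac_incomplete_peptide
            ):
                n_incomplete += 1
                size = int(rng.integers(1, config.n_sets)) if config.n_sets > 1 else 1
                pep_sets.append(np.sort(rng.choice(config.n_sets, size=size, replace=False)))
            else:
                pep_sets.append(np.arange(config.n_sets))
    n_pep_total = len(pep_protein)
    pep_protein_arr = np.asarray(pep_protein, dtype=int)
    pep_offsets = rng.normal(0.0, config.peptide_offset_sd, n_pep_total)
    engines = np.where(rng.random(n_pep_total) < config.frac_single_engine, 1, 2)
    engines[pep_protein_arr < 4] = 2

    spec_pep: list[int] = []
    spec_set: list[int] = []
    for j in range(n_pep_total):
        deep = pep_protein[j] < 4  # myosins: abundant, consistently sampled
        for b in pep_sets[j]:
            n_s = spec_hi if deep else int(rng.integers(spec_lo, spec_hi + 1))
            for _ in range(n_s):
                spec_pep.append(j)
                spec_set.append(int(b))
    spec_pep_arr = np.asarray(spec_pep, dtype=int)
    spec_set_arr = np.asarray(spec_set, dtype=int)
    spec_prot = np.asarray([pep_protein[j] for j in spec_pep], dtype=int)
    n_spec = len(spec_pep_arr)

    # log2 intensities ----------------------------------------------------
    log2_int = (
        baseline[spec_prot][:, None]
        + pep_offsets[spec_pep_arr][:, None]
        + u_batch[spec_prot, spec_set_arr][:, None]
        + loading[spec_set_arr]
        + eff[spec_prot, spec_set_arr]
    )
    log2_int += rng.normal(0.0, config.sigma_spectrum, (n_spec, n_ch))
    linear = np.exp2(log2_int)
    observed = linear @ config.purity_matrix.T  # observed = P @ true, row-wise

    # nuisance: blanked channels and shared accessions --------------------
    missing_mask = rng.random(n_spec) < config.frac_missing_channel
    for s in np.flatnonzero(missing_mask):
        k = int(rng.integers(1, 3))
        blank = rng.choice(n_ch, size=k, replace=False)
        observed[s, blank] = np.nan
    shared_mask = rng.random(n_spec) < config.frac_shared
    proteins_field = np.asarray([accessions[p] for p in spec_prot], dtype=object)
    for s in np.flatnonzero(shared_mask):
        other = int(rng.integers(0, n_prot - 1))
        if other >= spec_prot[s]:
            other += 1
        proteins_field[s] = proteins_field[s] + ";" + accessions[other]

    pep_fdr = np.where(
        rng.random(n_spec) < config.frac_high_peptide_fdr,
        rng.uniform(0.002, 0.05, n_spec),
        rng.uniform(0.0, 0.0009, n_spec),
    )
    pep_fdr[spec_prot < 4] = np.minimum(pep_fdr[spec_prot < 4], 0.0009)
    prot_fdr_by_protein = np.where(
        rng.random(n_prot) < config.frac_high_protein_fdr,
        rng.uniform(0.011, 0.10, n_prot),
        rng.uniform(0.0, 0.009, n_prot),
    )
    prot_fdr_by_protein[:4] = np.minimum(prot_fdr_by_protein[:4], 0.009)

    psm = pd.DataFrame(
        {
            "peptide_seq": [pep_seqs[j] for j in spec_pep],
            "proteins": proteins_field,
            "tmt_set": [set_ids[b] for b in spec_set],
            **{
                col: observed[:, k]
                for k, col in enumerate(INTENSITY_COLUMNS)
            },
            "is_decoy": 0,
            "is_contaminant": 0,
            "peptide_fdr": pep_fdr,
            "protein_fdr": prot_fdr_by_protein[spec_prot],
            "engines_confirming": engines[spec_pep_arr],
        }
    )

    # nuisance: decoy and contaminant records ------------------------------
    extra_frames = []
    for flag, frac, namer in (
        ("is_decoy", config.frac_decoy, lambda i: f"DECOY_P{i + 1:04d}"),
        (
            "is_contaminant",
            config.frac_contaminant,
            lambda i: _CONTAMINANTS[i % len(_CONTAMINANTS)],
        ),
    ):
        n_extra = int(rng.binomial(n_spec, frac)) if n_spec else 0
        if n_extra == 0:
            continue
        lvals = np.exp2(
            rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, (n_extra, 1))
            + rng.normal(0.0, 0.5, (n_extra, n_ch))
        )
        frame = pd.DataFrame(
            {
                "peptide_seq": [_random_peptide(rng) for _ in range(n_extra)],
                "proteins": [namer(i) for i in range(n_extra)],
                "tmt_set": rng.choice(set_ids, size=n_extra),
                **{col: lvals[:, k] for k, col in enumerate(INTENSITY_COLUMNS)},
                "is_decoy": 0,
                "is_contaminant": 0,
                "peptide_fdr": rng.uniform(0.0, 0.5, n_extra),
                "protein_fdr": rng.uniform(0.0, 0.5, n_extra),
                "engines_confirming": rng.integers(1, 3, n_extra),
            }
        )
        frame[flag] = 1
        extra_frames.append(frame)
    if extra_frames:
        psm = pd.concat([psm, *extra_frames], ignore_index=True)

    order = rng.permutation(len(psm))
    psm = psm.iloc[order].reset_index(drop=True)
    psm.insert(0, "spectrum_id", [f"sp{i + 1:06d}" for i in range(len(psm))])
    psm = psm[list(PSM_COLUMNS)]

    # sample metadata ------------------------------------------------------
    act_cols = activity_columns()
    sample_rows = []
    for _, row in donors.iterrows():
        rec_row = records_to_row(donor_records[row["donor_id"]])
        sample_rows.append(
            {
                "sample_id": row["donor_id"],
                "donor_id": row["donor_id"],
                "tmt_set": row["tmt_set"],
                "channel": row["channel"],
                "is_reference": 0,
                "age": row["age"],
                "sex": row["sex"],
                "race": row["race"],
                "bmi": row["bmi"],
                **rec_row,
            }
        )
    for set_id in set_ids:
        sample_rows.append(
            {
                "sample_id": f"REF_{set_id}",
                "donor_id": "",
                "tmt_set": set_id,
                "channel": REFERENCE_CHANNEL,
                "is_reference": 1,
                "age": "",
                "sex": "",
                "race": "",
                "bmi": "",
                **{c: 0 for c in act_cols},
            }
        )
    samples = pd.DataFrame(sample_rows)
    samples = samples.sort_values(["tmt_set", "channel"]).reset_index(drop=True)

    report: dict[str, Any] = {
        "n_spectra_signal": int(n_spec),
        "n_decoy": int((psm["is_decoy"] == 1).sum()),
        "n_contaminant": int((psm["is_contaminant"] == 1).sum()),
        "n_shared": int(shared_mask.sum()),
        "n_missing_channel": int(missing_mask.sum()),
        "n_incomplete_peptides": int(n_incomplete),
        "n_peptides": int(n_pep_total),
        "warnings": [],
    }
    if config.frac_incomplete_peptide >= 1.0 or config.frac_missing_channel >= 1.0:
        report["warnings"].append(
            "nuisance fractions of 1.0: retention filters would eliminate all proteins"
        )

    truth = CohortTruth(
        protein_effects=pd.DataFrame(
            {
                "accession": accessions,
                "beta_pa": beta_pa,
                "beta_age": beta_age,
                "beta_bmi": beta_bmi,
                "is_null": (~nonnull).astype(int),
                "baseline_log2": baseline,
                "tau_batch": config.tau_batch,
            }
        ),
        sample_truth=donors.copy(),
        loading_offsets=pd.DataFrame(
            [
                {"tmt_set": set_ids[b], "channel": CHANNELS[k], "offset": loading[b, k]}
                for b in range(config.n_sets)
                for k in range(n_ch)
            ]
        ),
        report=report,
    )
    return psm, samples, truth
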