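import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import actiprot as ap
from actiprot.config import CHANNELS, REFERENCE_CHANNEL
from actiprot.covariates import activity_columns
from actiprot.psm import apply_purity_correction, filter_psm_table
from actiprot.quantify import quantify
from actiprot.simulate import INTENSITY_COLUMNS, PSM_COLUMNS

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def clean_kwargs(**overrides):
    """Cohort config with every nuisance mechanism switched off."""
    kw = dict(
        frac_decoy=0.0,
        frac_contaminant=0.0,
        frac_shared=0.0,
        frac_missing_channel=0.0,
        frac_incomplete_peptide=0.0,
        frac_high_peptide_fdr=0.0,
        frac_high_protein_fdr=0.0,
        frac_single_engine=0.0,
    )
    kw.update(overrides)
    return kw


def noise_free_kwargs(**overrides):
    """Clean cohort with all variance components and crosstalk removed."""
    kw = clean_kwargs(
        sigma_spectrum=0.0,
        tau_batch=0.0,
        loading_sd=0.0,
        peptide_offset_sd=0.0,
        fiber_donor_sd=0.0,
        beta_age_sd=0.0,
        beta_bmi_sd=0.0,
        purity_matrix=np.eye(len(CHANNELS)),
    )
    kw.update(overrides)
    return kw


def run_chain(cfg):
    """simulate -> correct -> filter -> quantify -> covariates."""
    psm, samples, truth = ap.simulate_cohort(cfg)
    corrected = apply_purity_correction(psm, cfg.purity_matrix)
    filtered, report = filter_psm_table(corrected, samples)
    matrix = quantify(filtered, samples)
    covariates = ap.build_covariates(samples, matrix)
    return matrix, covariates, truth, report


@pytest.fixture(scope="session")
def small_cohort():
    cfg = ap.CohortConfig(n_donors=30, n_proteins=60, seed=3)
    psm, samples, truth = ap.simulate_cohort(cfg)
    return cfg, psm, samples, truth


def make_samples_table(set_donors: dict[str, int]) -> pd.DataFrame:
    """Minimal sample metadata: per set, n donors plus one reference."""
    rows = []
    donor = 0
    for set_id, n in set_donors.items():
        for k in range(n):
            donor += 1
            rows.append(
                {
                    "sample_id": f"D{donor:03d}",
                    "donor_id": f"D{donor:03d}",
                    "tmt_set": set_id,
                    "channel": CHANNELS[k],
                    "is_reference": 0,
                    "age": 50,
                    "sex": "F",
                    "race": "white",
                    "bmi": 25.0,
                    **{c: 0 for c in activity_columns()},
                }
            )
        rows.append(
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
                **{c: 0 for c in activity_columns()},
            }
        )
    return pd.DataFrame(rows)


def make_psm_record(
    spectrum_id,
    peptide="AAAAAAAK",
    proteins="P1",
    tmt_set="set01",
    intensities=(100.0,) * 6,
    is_decoy=0,
    is_contaminant=0,
    peptide_fdr=0.0005,
    protein_fdr=0.005,
    engines=2,
):
    row = {
        "spectrum_id": spectrum_id,
        "peptide_seq": peptide,
        "proteins": proteins,
        "tmt_set": tmt_set,
        "is_decoy": is_decoy,
        "is_contaminant": is_contaminant,
        "peptide_fdr": peptide_fdr,
        "protein_fdr": protein_fdr,
        "engines_confirming": engines,
    }
    for col, v in zip(INTENSITY_COLUMNS, intensities):
        row[col] = v
    return row


def rule_fixture():
    """12 hand-built records exercising each retention rule exactly once.

    set01 holds five donors plus the reference; set02 exists but holds
    only a reference channel, so a peptide seen only there fails the
    detected-in-all-samples rule.
    """
    samples = make_samples_table({"set01": 5, "set02": 0})
    records = [
        # four clean records that survive everything
        make_psm_record("r01", peptide="PEPA", proteins="PA"),
        make_psm_record("r02", peptide="PEPA2", proteins="PA"),
        make_psm_record("r03", peptide="PEPB", proteins="PB", engines=2),
        make_psm_record("r04", peptide="PEPE", proteins="PE"),
        # one violation per rule, in rule order
        make_psm_record("r05", peptide="PEPA", proteins="PA", is_decoy=1),
        make_psm_record("r06", peptide="PEPA", proteins="PA", is_contaminant=1),
        make_psm_record("r07", peptide="PEPA", proteins="PA", peptide_fdr=0.01),
        make_psm_record("r08", peptide="PEPA", proteins="PA", protein_fdr=0.05),
        make_psm_record("r09", peptide="PEPA", proteins="PA;PX"),
        make_psm_record(
            "r10", peptide="PEPA", proteins="PA",
            intensities=(100.0, 100.0, np.nan, 100.0, 100.0, 100.0),
        ),
        make_psm_record("r11", peptide="PEPC", proteins="PC", tmt_set="set02"),
        make_psm_record("r12", peptide="PEPD", proteins="PD", engines=1),
    ]
    psm = pd.DataFrame(records)[list(PSM_COLUMNS)]
    return psm, samples
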