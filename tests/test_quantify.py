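import numpy as np
import pandas as pd
import pytest

import actiprot as ap
from actiprot.quantify import (
    ProteinQuantMatrix,
    log2_transform,
    median_polish_loading,
    normalize_within_protein,
    rollup_protein,
    quantify,
)
from actiprot.simulate import INTENSITY_COLUMNS, simulate_cohort
from actiprot.psm import filter_psm_table

from conftest import clean_kwargs, make_psm_record, make_samples_table


def psm_frame(records):
    return pd.DataFrame(records)


class TestLog2:
    def test_powers_of_two(self):
        psm = psm_frame([make_psm_record("a", intensities=(8, 1, 2**0.5, 4, 2, 16))])
        out = log2_transform(psm)
        vals = out.loc[0, list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
        assert np.allclose(vals, [3.0, 0.0, 0.5, 2.0, 1.0, 4.0])

    def test_nonpositive_names_record(self):
        psm = psm_frame([make_psm_record("bad1", intensities=(0, 1, 1, 1, 1, 1))])
        with pytest.raises(ValueError, match="bad1"):
            log2_transform(psm)


class TestWithinProteinCentering:
    def test_single_spectrum_hand_median(self):
        psm = log2_transform(
            psm_frame([make_psm_record("a", intensities=(2, 4, 8, 16, 32, 64))])
        )
        out = normalize_within_protein(psm)
        vals = out.loc[0, list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
        assert np.allclose(vals, [-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])

    def test_constant_protein_zeroed(self):
        psm = psm_frame(
            [make_psm_record(s, intensities=(7.0,) * 6) for s in "ab"]
        )
        out = normalize_within_protein(psm)
        assert (out.loc[:, list(INTENSITY_COLUMNS)] == 0.0).all().all()

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        psm = psm_frame(
            [
                make_psm_record(f"s{i}", intensities=tuple(rng.uniform(1, 5, 6)))
                for i in range(5)
            ]
        )
        once = normalize_within_protein(psm)
        twice = normalize_within_protein(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_global_median_zero_per_protein(self):
        rng = np.random.default_rng(1)
        psm = psm_frame(
            [
                make_psm_record(
                    f"s{i}", proteins="P1" if i < 3 else "P2",
                    tmt_set=f"set0{1 + i % 2}",
                    intensities=tuple(rng.uniform(1, 5, 6)),
                )
                for i in range(6)
            ]
        )
        out = normalize_within_protein(psm)
        for _, grp in out.groupby("proteins"):
            vals = grp.loc[:, list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
            assert abs(np.median(vals)) < 1e-12

    def test_per_set_variant_median_zero_per_protein_set(self):
        rng = np.random.default_rng(2)
        psm = psm_frame(
            [
                make_psm_record(
                    f"s{i}", proteins="P1", tmt_set=f"set0{1 + i % 2}",
                    intensities=tuple(rng.uniform(1, 5, 6)),
                )
                for i in range(6)
            ]
        )
        out = normalize_within_protein(psm, per_set=True)
        for _, grp in out.groupby(["proteins", "tmt_set"]):
            vals = grp.loc[:, list(INTENSITY_COLUMNS)].to_numpy(dtype=float)
            assert abs(np.median(vals)) < 1e-12


class TestRollup:
    samples = make_samples_table({"set01": 5})

    def records(self, values_by_spectrum, protein="P1", peptides=None):
        recs = []
        for i, v in enumerate(values_by_spectrum):
            recs.append(
                make_psm_record(
                    f"s{i}",
                    peptide=(peptides or ["PEP1"] * len(values_by_spectrum))[i],
                    proteins=protein,
                    intensities=(v,) * 6,
                )
            )
        return psm_frame(recs)

    def test_median_of_three(self):
        m = rollup_protein(self.records([0.1, 0.3, 0.2]), self.samples)
        assert np.allclose(m.values_df.loc["P1"], 0.2)

    def test_singleton_passthrough(self):
        m = rollup_protein(self.records([0.7]), self.samples)
        assert np.allclose(m.values_df.loc["P1"], 0.7)

    def test_even_count_mean_of_middle(self):
        m = rollup_protein(self.records([0.1, 0.3]), self.samples)
        assert np.allclose(m.values_df.loc["P1"], 0.2)

    def test_pooled_not_per_peptide_median(self):
        # 3 spectra of pep1 at 0.1 and 1 of pep2 at 0.5: pooled median 0.1,
        # a median-of-peptide-medians would give 0.3
        m = rollup_protein(
            self.records([0.1, 0.1, 0.1, 0.5], peptides=["p1", "p1", "p1", "p2"]),
            self.samples,
        )
        assert np.allclose(m.values_df.loc["P1"], 0.1)

    def test_reference_excluded_and_provenance(self):
        m = rollup_protein(
            self.records([0.1, 0.2], peptides=["p1", "p2"]), self.samples
        )
        assert "REF_set01" not in m.sample_ids
        assert len(m.sample_ids) == 5
        prov = m.provenance.set_index("sample_id")
        assert (prov["n_spectra"] == 2).all()
        assert (prov["n_peptides"] == 2).all()


class TestMedianPolish:
    def wrap(self, arr, samples=None):
        df = pd.DataFrame(
            arr,
            index=[f"P{i}" for i in range(arr.shape[0])],
            columns=[f"S{j}" for j in range(arr.shape[1])],
        )
        return ProteinQuantMatrix(df, provenance=pd.DataFrame())

    def test_column_centering(self):
        out = median_polish_loading(self.wrap(np.array([[1.0], [2.0], [3.0]])))
        assert np.allclose(out.values_df.to_numpy().ravel(), [-1, 0, 1])

    def test_fixed_point(self):
        arr = np.array([[1.0, -1.0], [0.0, 0.0], [-1.0, 1.0]])
        out = median_polish_loading(self.wrap(arr))
        assert np.allclose(out.values_df.to_numpy(), arr)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(9, 4))
        shifted = arr.copy()
        shifted[:, 2] += 3.7
        a = median_polish_loading(self.wrap(arr)).values_df.to_numpy()
        b = median_polish_loading(self.wrap(shifted)).values_df.to_numpy()
        assert np.allclose(a, b)

    def test_column_medians_zero(self):
        rng = np.random.default_rng(4)
        out = median_polish_loading(self.wrap(rng.normal(size=(15, 6))))
        assert np.allclose(out.values_df.median(axis=0), 0.0, atol=1e-12)


class TestChainProperties:
    def test_sample_ranking_preserved(self):
        """Centering steps are shifts: within-protein sample order survives."""
        cfg = ap.CohortConfig(n_donors=10, n_proteins=30, seed=8, **clean_kwargs())
        psm, samples, _ = simulate_cohort(cfg)
        filtered, _ = filter_psm_table(psm, samples)
        logged = log2_transform(filtered)
        m_raw = rollup_protein(logged, samples)
        m_final = quantify(filtered, samples)
        common = m_final.values_df.index
        for acc in common[:10]:
            raw_rank = m_raw.values_df.loc[acc].rank()
            # polish shifts columns; compare ranks after removing column shifts
            # only the within-protein centering must preserve order
            cent_rank = (
                rollup_protein(normalize_within_protein(logged), samples)
                .values_df.loc[acc]
                .rank()
            )
            assert (raw_rank == cent_rank).all()

    def test_loading_offsets_removed_exactly(self):
        """With loading offsets the only active variance component and
        uniform spectra counts, the final matrix is identical to the
        offset-free run: the injected offsets are removed exactly."""
        from conftest import noise_free_kwargs

        base = dict(
            n_donors=10, n_proteins=21, peptides_per_protein=(2, 2),
            spectra_per_peptide=(2, 2), frac_nonnull=0.0, seed=31,
        )
        cfg_l = ap.CohortConfig(**base, **noise_free_kwargs(loading_sd=0.3))
        cfg_0 = ap.CohortConfig(**base, **noise_free_kwargs())
        m_l = quantify(*_sim_filter(cfg_l))
        m_0 = quantify(*_sim_filter(cfg_0))
        diff = (m_l.values_df - m_0.values_df).abs()
        assert float(diff.to_numpy().max()) < 1e-9


def _sim_filter(cfg):
    psm, samples, _ = simulate_cohort(cfg)
    filtered, _ = filter_psm_table(psm, samples)
    return filtered, samples
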