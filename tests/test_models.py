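import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import actiprot as ap
from actiprot.models import (
    MixedDesign,
    ModelSpec,
    adjust_bh,
    build_design,
    classify_direction,
    fit_all,
    fit_protein_mixed_model,
)
from actiprot.psm import filter_psm_table
from actiprot.quantify import quantify

from conftest import run_chain


def random_design(rng, n_groups=6, per_group=6):
    n = n_groups * per_group
    groups = np.repeat(np.arange(n_groups), per_group)
    X = np.column_stack(
        [
            np.ones(n),
            rng.integers(0, 4, n).astype(float),
            rng.normal(55, 18, n),
            rng.normal(27, 4, n),
        ]
    )
    return X, groups


class TestMixedModelOracles:
    def test_boundary_fits_match_closed_form_ols(self):
        """Data with zero batch variance: whenever the variance estimate
        hits the zero boundary, beta/se must equal the normal-equations
        OLS solution to 1e-6."""
        rng = np.random.default_rng(99)
        n_checked = 0
        trials = 0
        while n_checked < 100 and trials < 400:
            trials += 1
            X, groups = random_design(rng)
            y = X @ [1.0, 0.1, 0.01, -0.02] + rng.normal(0, 0.5, len(X))
            fit = MixedDesign(X, groups, 1).fit(y)
            if fit.method != "ols_boundary":
                continue
            n_checked += 1
            xtx_inv = np.linalg.inv(X.T @ X)
            beta = xtx_inv @ X.T @ y
            resid = y - X @ beta
            sig2 = resid @ resid / (len(y) - X.shape[1])
            se = np.sqrt(sig2 * xtx_inv[1, 1])
            assert abs(fit.beta - beta[1]) < 1e-6
            assert abs(fit.se - se) < 1e-6
        assert n_checked >= 100

    def test_matches_statsmodels_mixedlm(self):
        """Independent REML cross-check on data with real batch effects
        (statsmodels stops at its own optimizer tolerance, hence the
        looser bound on the standard error)."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(12):
            X, groups = random_design(rng, n_groups=8)
            y = (
                X @ [0.1, 0.08, 0.002, 0.0]
                + rng.normal(0, 0.3, 8)[groups]
                + rng.normal(0, 0.25, len(X))
            )
            fit = MixedDesign(X, groups, 1).fit(y)
            if fit.method != "reml":
                continue
            import statsmodels.formula.api as smf

            df = pd.DataFrame(
                {"y": y, "pa": X[:, 1], "age": X[:, 2], "bmi": X[:, 3], "g": groups}
            )
            sm_fit = smf.mixedlm("y ~ pa + age + bmi", df, groups="g").fit(reml=True)
            assert abs(sm_fit.params["pa"] - fit.beta) < 1e-5
            assert abs(sm_fit.bse["pa"] - fit.se) / fit.se < 0.05
            checked += 1
        assert checked >= 5

    def test_matches_lmertest_frozen_fixture(self):
        """Frozen R lmerTest (lme4 REML + Satterthwaite) reference values
        for five proteins of a deterministic synthetic cohort."""
        cfg = ap.CohortConfig(n_donors=30, n_proteins=60, seed=11)
        matrix, cov, _, _ = run_chain(cfg)
        expected = {
            # accession: (beta, se, df, p) from lmerTest 3.1-3 / lme4 1.1-37
            "P0005": (-0.011651, 0.017480, 19.4117, 0.512905),
            "P0006": (-0.014812, 0.020969, 19.4148, 0.488349),
            "P0007": (-0.001434, 0.022637, 22.9081, 0.950048),
            "P0008": (0.050543, 0.017361, 20.7360, 0.0084211),
            "P0009": (-0.024943, 0.026269, 19.7606, 0.353820),
        }
        for acc, (beta, se, df, p) in expected.items():
            y = matrix.values_df.loc[acc].reindex(cov.index)
            fit = fit_protein_mixed_model(y, cov)
            assert abs(fit.beta - beta) < 1e-5
            assert abs(fit.se - se) < 1e-5
            assert abs(fit.df - df) < 0.2
            assert fit.p_value == pytest.approx(p, rel=1e-2, abs=1e-5)

    def test_null_response(self):
        rng = np.random.default_rng(1)
        X, groups = random_design(rng)
        fit = MixedDesign(X, groups, 1).fit(np.zeros(len(X)))
        assert fit.beta == 0.0
        assert fit.p_value == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        X, groups = random_design(rng)
        y = X @ [0.5, 0.1, 0.0, 0.01] + rng.normal(0, 0.3, len(X))
        ref = MixedDesign(X, groups, 1).fit(y)
        perm = rng.permutation(len(X))
        alt = MixedDesign(X[perm], groups[perm], 1).fit(y[perm])
        assert alt.beta == pytest.approx(ref.beta, abs=1e-8)
        assert alt.se == pytest.approx(ref.se, abs=1e-8)
        assert alt.p_value == pytest.approx(ref.p_value, rel=1e-6)


class TestBenjaminiHochberg:
    @staticmethod
    def brute_force(p):
        """Literal step-up rule: q_i = min_{j: p_j >= p_i} p_j * m / rank_j."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        q = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m, 0, -1):
            idx = order[rank_from_top - 1]
            prev = min(prev, p[idx] * m / rank_from_top)
            q[idx] = prev
        return q

    def test_hand_example(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert np.allclose(adjust_bh([0.2]), [0.2])

    def test_ties_preserved(self):
        assert np.allclose(adjust_bh([0.04, 0.04, 0.04]), [0.04] * 3)

    @given(
        st.lists(
            st.floats(0, 1, allow_nan=False, allow_infinity=False),
            min_size=1, max_size=20,
        )
    )
    def test_matches_brute_force(self, p):
        assert np.allclose(adjust_bh(p), self.brute_force(p), atol=1e-12)

    def test_exhaustive_small_vectors(self):
        from itertools import product

        grid = [0.001, 0.02, 0.05, 0.5, 1.0]
        for n in (1, 2, 3):
            for p in product(grid, repeat=n):
                assert np.allclose(adjust_bh(list(p)), self.brute_force(p))

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [float("nan")]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            adjust_bh(bad)


class TestDirection:
    @pytest.mark.parametrize(
        "beta, p, expected",
        [
            (0.05, 0.001, "up"),
            (-0.0281, 6.61e-7, "down"),  # strongest negatively associated protein
            (0.1, 0.2, "ns"),
            (0.0, 0.001, "ns"),  # exact-zero tie-break
            (-0.3, 0.05, "ns"),  # alpha is strict
        ],
    )
    def test_calls(self, beta, p, expected):
        assert classify_direction(beta, p, alpha=0.05) == expected


class TestFitAll:
    def test_complete_results(self, small_cohort):
        cfg, psm, samples, _ = small_cohort
        from actiprot.psm import apply_purity_correction

        filtered, _ = filter_psm_table(
            apply_purity_correction(psm, cfg.purity_matrix), samples
        )
        matrix = quantify(filtered, samples)
        cov = ap.build_covariates(samples, matrix)
        results, meta = fit_all(matrix, cov)
        assert len(results) == len(matrix.values_df)
        for col in ("beta", "se", "df", "p_value", "q_value"):
            assert results[col].notna().all()
        assert set(results["direction"]) <= {"up", "down", "ns"}
        assert meta["race_reference"] in {"white", "black", "other"}
        # deterministic given inputs
        again, _ = fit_all(matrix, cov)
        pd.testing.assert_frame_equal(results, again)

    def test_rank_deficiency_names_column(self):
        cov = pd.DataFrame(
            {
                "pa_code": [0, 1, 2, 3] * 3,
                "age": np.linspace(25, 80, 12),
                "bmi": np.linspace(20, 30, 12),
                "race": ["white"] * 12,
                "tmt_set": ["s1"] * 6 + ["s2"] * 6,
            },
            index=[f"D{i}" for i in range(12)],
        )
        cov["fiber_ratio"] = cov["pa_code"] * 2.0  # exactly collinear
        with pytest.raises(ValueError, match="fiber_ratio|pa_code"):
            build_design(cov, ModelSpec(drop_zero_variance=False))

    def test_zero_variance_column_dropped(self):
        cov = pd.DataFrame(
            {
                "pa_code": [0, 1, 2, 3] * 3,
                "age": np.linspace(25, 80, 12),
                "bmi": [24, 31, 22, 28, 26, 35, 21, 29, 27, 23, 30, 25],
                "race": ["white", "black"] * 6,
                "tmt_set": ["s1"] * 6 + ["s2"] * 6,
                "fiber_ratio": [0.5] * 12,
            },
            index=[f"D{i}" for i in range(12)],
        )
        X, _, meta = build_design(cov, ModelSpec())
        assert "fiber_ratio" in meta["dropped_columns"]
        assert "fiber_ratio" not in X.columns

    def test_fixed_set_effect_matches_dummy_ols(self):
        rng = np.random.default_rng(12)
        X, groups = random_design(rng)
        y = X @ [0.2, 0.05, 0.0, 0.0] + rng.normal(0, 0.2, len(X))
        cov = pd.DataFrame(
            {
                "pa_code": X[:, 1],
                "age": X[:, 2],
                "bmi": X[:, 3],
                "race": ["white"] * len(X),
                "tmt_set": [f"s{g}" for g in groups],
            },
            index=[f"D{i}" for i in range(len(X))],
        )
        fit = fit_protein_mixed_model(y, cov, ModelSpec(set_effect="fixed"))
        Xd = np.column_stack([X] + [(groups == g).astype(float) for g in range(1, 6)])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert fit.beta == pytest.approx(beta[1], abs=1e-8)
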