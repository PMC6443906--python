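"""Per-protein linear mixed models of abundance on physical activity.

Each protein's log2 relative abundance is regressed on the ordinal
activity code (a single numeric slope over codes 0-3) adjusting for age,
race, BMI and the myosin fiber-type ratio, with a random intercept per
TMT set absorbing batch differences between labeling experiments.

Estimation is REML with the single variance ratio ``lambda = tau^2 /
sigma^2`` profiled out: with ``Z`` the set-indicator matrix and ``Q D
Q' = Z Z'`` its eigendecomposition, the marginal covariance ``V =
sigma^2 (I + lambda Z Z')`` is diagonal in the eigenbasis, so every
profile-likelihood evaluation and the Satterthwaite degrees-of-freedom
calculation reduce to diagonal weighting.  The activity slope is tested
with a t-statistic on Satterthwaite-approximated df, emulating the
lme4 + lmerTest convention; when the batch variance estimate hits the
zero boundary the fit falls back to (and exactly matches) ordinary
least squares with residual df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_TINY = 1e-300
#: log(lambda) search interval; the upper end is effectively "all batch".
_LOGLAM_BOUNDS = (-30.0, 25.0)


@dataclass
class ModelSpec:
    """Specification of the per-protein regression.

    ``set_effect`` chooses how the TMT labeling experiment enters the
    model: ``"random"`` (random intercept, the default) or ``"fixed"``
    (dummy-coded fixed effect).  ``df_method`` selects Satterthwaite or
    plain residual degrees of freedom for the activity-slope t-test.
    Covariate columns with zero variance (e.g. a fiber ratio that is
    constant by construction) are dropped with a note rather than
    producing a singular design.
    """

    set_effect: str = "random"
    reml: bool = True
    df_method: str = "satterthwaite"
    use_fiber_ratio: bool = True
    drop_zero_variance: bool = True

    def __post_init__(self) -> None:
        if self.set_effect not in ("random", "fixed"):
            raise ValueError("set_effect must be 'random' or 'fixed'")
        if self.df_method not in ("satterthwaite", "residual"):
            raise ValueError("df_method must be 'satterthwaite' or 'residual'")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelSpec":
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown ModelSpec keys: {', '.join(unknown)}")
        return cls(**dict(data))


@dataclass
class FitResult:
    """Activity-slope estimate for one protein."""

    beta: float
    se: float
    df: float
    p_value: float
    sigma2: float
    tau2: float
    converged: bool
    method: str


def build_design(
    covariates: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, np.ndarray, dict[str, Any]]:
    """Fixed-effect design matrix and grouping from the covariate table.

    Race is dummy-coded against its most frequent level; the activity
    code enters as a single numeric regressor.  Returns the design, the
    TMT-set labels per row, and metadata (race reference, dropped
    zero-variance columns, fixed-effect names).
    """
    X = pd.DataFrame(index=covariates.index)
    X["Intercept"] = 1.0
    X["pa_code"] = covariates["pa_code"].astype(float)
    X["age"] = covariates["age"].astype(float)
    X["bmi"] = covariates["bmi"].astype(float)
    if spec.use_fiber_ratio and "fiber_ratio" in covariates.columns:
        X["fiber_ratio"] = covariates["fiber_ratio"].astype(float)
    race = covariates["race"].astype(str)
    reference = race.value_counts().idxmax()
    for level in sorted(race.unique()):
        if level != reference:
            X[f"race[{level}]"] = (race == level).astype(float)
    meta: dict[str, Any] = {"race_reference": reference, "dropped_columns": []}

    if spec.drop_zero_variance:
        for col in list(X.columns):
            scale = max(1.0, float(X[col].abs().max()))
            if col != "Intercept" and float(X[col].std()) < 1e-10 * scale:
                meta["dropped_columns"].append(col)
                X = X.drop(columns=col)
                logger.warning("dropping zero-variance covariate column %r", col)

    groups = covariates["tmt_set"].astype(str).to_numpy()
    if spec.set_effect == "fixed":
        levels = pd.unique(groups)
        for level in levels[1:]:
            X[f"tmt_set[{level}]"] = (groups == level).astype(float)

    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        from scipy.linalg import qr

        _, r, piv = qr(arr, pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        raise ValueError(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(map(str, bad))
        )
    meta["columns"] = list(X.columns)
    if spec.set_effect == "random" and len(np.unique(groups)) < 2:
        raise ValueError("random-intercept model needs at least 2 TMT sets")
    return X, groups, meta


class MixedDesign:
    """Precomputed eigenbasis machinery shared across the protein sweep."""

    def __init__(self, X: np.ndarray, groups: np.ndarray, contrast: int):
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.contrast = contrast
        _, inv = np.unique(groups, return_inverse=True)
        Z = np.zeros((self.n, inv.max() + 1))
        Z[np.arange(self.n), inv] = 1.0
        d, Q = np.linalg.eigh(Z @ Z.T)
        self.d = np.clip(d, 0.0, None)
        self.Q = Q
        self.Xt = Q.T @ self.X

    def _neg2reml(self, lam: float, yt: np.ndarray) -> float:
        w = 1.0 + lam * self.d
        Xw = self.Xt / w[:, None]
        M = self.Xt.T @ Xw
        try:
            beta = np.linalg.solve(M, Xw.T @ yt)
        except np.linalg.LinAlgError:
            return np.inf
        r = yt - self.Xt @ beta
        rss = float(np.sum(r * r / w))
        sig2 = max(rss / (self.n - self.p), _TINY)
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return np.inf
        return (self.n - self.p) * np.log(sig2) + float(np.sum(np.log(w))) + logdet

    def fit(self, y: np.ndarray, df_method: str = "satterthwaite") -> FitResult:
        yt = self.Q.T @ np.asarray(y, dtype=float)
        crit0 = self._neg2reml(0.0, yt)
        res = optimize.minimize_scalar(
            lambda t: self._neg2reml(np.exp(t), yt),
            bounds=_LOGLAM_BOUNDS,
            method="bounded",
            options={"xatol": 1e-9},
        )
        converged = bool(res.success)
        lam = float(np.exp(res.x)) if converged else 0.0
        if not converged or crit0 <= res.fun + 1e-10:
            return self._ols(yt, converged=converged, method="ols_boundary")

        w = 1.0 + lam * self.d
        Xw = self.Xt / w[:, None]
        M = self.Xt.T @ Xw
        beta = np.linalg.solve(M, Xw.T @ yt)
        r = yt - self.Xt @ beta
        sig2 = float(np.sum(r * r / w)) / (self.n - self.p)
        tau2 = lam * sig2
        C = np.linalg.inv(M) * sig2
        ci = self.contrast
        se = float(np.sqrt(max(C[ci, ci], 0.0)))
        if df_method == "satterthwaite":
            df = self._satterthwaite(sig2, tau2, ci)
        else:
            df = float(self.n - self.p)
        if not np.isfinite(df) or df <= 0:
            df = float(self.n - self.p)
        b = float(beta[ci])
        if se == 0.0:
            t, p = 0.0, 1.0
        else:
            t = b / se
            p = 2.0 * stats.t.sf(abs(t), df)
        return FitResult(b, se, df, float(p), sig2, tau2, converged, "reml")

    def _satterthwaite(self, sig2: float, tau2: float, ci: int) -> float:
        """Delta-method df for the contrast variance in (sigma^2, tau^2)."""
        v = sig2 + tau2 * self.d
        Xv = self.Xt / v[:, None]
        M = self.Xt.T @ Xv
        C = np.linalg.inv(M)
        ccol = C[:, ci]
        f = float(C[ci, ci])
        b = Xv @ ccol
        g = np.array([float(np.sum(b * b)), float(np.sum(self.d * b * b))])
        P = np.diag(1.0 / v) - Xv @ C @ Xv.T
        P2 = P * P
        rs = P2 @ self.d
        info = 0.5 * np.array(
            [
                [float(P2.sum()), float(rs.sum())],
                [float(rs.sum()), float(self.d @ rs)],
            ]
        )
        try:
            A = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return float("nan")
        var_f = float(g @ A @ g)
        if var_f <= 0:
            return float("nan")
        return 2.0 * f * f / var_f

    def _ols(self, yt: np.ndarray, converged: bool, method: str) -> FitResult:
        M = self.Xt.T @ self.Xt
        beta = np.linalg.solve(M, self.Xt.T @ yt)
        r = yt - self.Xt @ beta
        dof = self.n - self.p
        sig2 = float(r @ r) / dof
        C = np.linalg.inv(M) * sig2
        ci = self.contrast
        se = float(np.sqrt(max(C[ci, ci], 0.0)))
        b = float(beta[ci])
        if se == 0.0:
            t, p = 0.0, 1.0
        else:
            t = b / se
            p = 2.0 * stats.t.sf(abs(t), dof)
        return FitResult(b, se, float(dof), float(p), sig2, 0.0, converged, method)


def fit_protein_mixed_model(
    y: pd.Series | np.ndarray,
    covariates: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> FitResult:
    """Fit one protein's activity model and test the activity slope.

    ``y`` must align with the rows of ``covariates`` (reference channels
    never appear in either).  With ``set_effect="fixed"`` the TMT set is
    dummy-coded and the fit is OLS with residual df.
    """
    spec = spec or ModelSpec()
    X, groups, _ = build_design(covariates, spec)
    ci = list(X.columns).index("pa_code")
    yv = np.asarray(y, dtype=float)
    if yv.shape[0] != len(X):
        raise ValueError("response length does not match covariate rows")
    design = MixedDesign(X.to_numpy(dtype=float), groups, ci)
    if spec.set_effect == "fixed":
        return design._ols(design.Q.T @ yv, converged=True, method="ols_fixed_set")
    return design.fit(yv, df_method=spec.df_method)


def fit_all(
    matrix,
    covariates: pd.DataFrame,
    spec: ModelSpec | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Fit the activity model for every protein in the matrix.

    Returns one row per protein (beta, se, df, p, BH q, direction,
    convergence flag, note) and a metadata dict describing the design
    (columns, race reference, dropped covariates).  Per-protein failures
    are captured in their row; the sweep never aborts.
    """
    spec = spec or ModelSpec()
    values = getattr(matrix, "values_df", matrix)
    cov = covariates.reindex(values.columns)
    if cov.isna().all(axis=1).any():
        missing = cov.index[cov.isna().all(axis=1)]
        raise ValueError(
            "covariates missing for sample(s): " + ", ".join(map(str, missing[:5]))
        )
    X, groups, meta = build_design(cov, spec)
    ci = list(X.columns).index("pa_code")
    design = MixedDesign(X.to_numpy(dtype=float), groups, ci)

    rows = []
    for k, (acc, y) in enumerate(values.iterrows()):
        if k and k % 500 == 0:
            logger.info("fitted %d/%d proteins", k, len(values))
        try:
            yv = y.to_numpy(dtype=float)
            if spec.set_effect == "fixed":
                fit = design._ols(design.Q.T @ yv, True, "ols_fixed_set")
            else:
                fit = design.fit(yv, df_method=spec.df_method)
            rows.append(
                {
                    "accession": acc,
                    "beta": fit.beta,
                    "se": fit.se,
                    "df": fit.df,
                    "p_value": fit.p_value,
                    "sigma2": fit.sigma2,
                    "tau2": fit.tau2,
                    "converged": int(fit.converged),
                    "method": fit.method,
                    "note": "",
                }
            )
        except Exception as exc:  # failures stay per-row
            rows.append(
                {
                    "accession": acc,
                    "beta": np.nan,
                    "se": np.nan,
                    "df": np.nan,
                    "p_value": np.nan,
                    "sigma2": np.nan,
                    "tau2": np.nan,
                    "converged": 0,
                    "method": "failed",
                    "note": str(exc),
                }
            )
    results = pd.DataFrame(rows)
    ok = results["p_value"].notna()
    q = np.full(len(results), np.nan)
    if ok.any():
        q[ok.to_numpy()] = adjust_bh(results.loc[ok, "p_value"].to_numpy())
    results["q_value"] = q
    results["direction"] = [
        classify_direction(b, p, alpha) if np.isfinite(p) else "ns"
        for b, p in zip(results["beta"], results["p_value"])
    ]
    meta["alpha"] = alpha
    meta["n_proteins"] = len(results)
    meta["set_effect"] = spec.set_effect
    meta["df_method"] = spec.df_method
    return results, meta


def adjust_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, ties preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def classify_direction(beta: float, p_value: float, alpha: float = 0.05) -> str:
    """'up' / 'down' / 'ns' call for one protein.

    Positive beta with p below alpha is 'up' (higher abundance with
    higher activity), negative is 'down'; a beta of exactly 0 is 'ns'
    regardless of p.
    """
    if p_value < alpha and beta > 0:
        return "up"
    if p_value < alpha and beta < 0:
        return "down"
    return "ns"
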