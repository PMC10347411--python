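"""Parametric empirical-Bayes site harmonization (ComBat).

Removes additive and multiplicative site effects from tabular features while
preserving specified biological covariates. The model per feature f, site i,
subject j is

    y_ijf = alpha_f + x_ij' beta_f + gamma_if + delta_if * eps_ijf

Per-site location gamma and scale delta are estimated on standardized data
and shrunk toward parametric priors (normal for locations, inverse-gamma for
scales) by iterating their conditional posterior means to convergence.
Protected covariates (age, and optionally sex) are fit alongside the site
terms and restored after adjustment, so the harmonized features keep their
age association.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, edge_table, unflatten

__all__ = ["CombatModel", "fit_combat", "apply_combat", "harmonize_matrices", "site_f_statistics"]


@dataclass
class CombatModel:
    feature_names: list[str]
    site_levels: list[str]
    covariate_names: list[str]
    covariate_centers: np.ndarray  # centering constants used at fit time
    grand_mean: np.ndarray  # alpha_f, (F,)
    beta: np.ndarray  # (n_cov, F)
    pooled_sd: np.ndarray  # sigma_f, (F,)
    gamma_star: np.ndarray  # (n_sites, F) EB-shrunken locations
    delta_star: np.ndarray  # (n_sites, F) EB-shrunken scales (delta^2*)
    gamma_hat: np.ndarray  # (n_sites, F) pre-shrinkage locations
    delta_hat: np.ndarray  # (n_sites, F) pre-shrinkage scales
    constant_features: np.ndarray  # boolean (F,), passed through unadjusted
    n_per_site: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "site_levels": self.site_levels,
            "covariate_names": self.covariate_names,
        }
        for name in (
            "covariate_centers",
            "grand_mean",
            "beta",
            "pooled_sd",
            "gamma_star",
            "delta_star",
            "gamma_hat",
            "delta_hat",
            "constant_features",
            "n_per_site",
        ):
            payload[name] = getattr(self, name).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CombatModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            feature_names=payload["feature_names"],
            site_levels=payload["site_levels"],
            covariate_names=payload["covariate_names"],
            covariate_centers=np.asarray(payload["covariate_centers"], dtype=float),
            grand_mean=np.asarray(payload["grand_mean"], dtype=float),
            beta=np.asarray(payload["beta"], dtype=float),
            pooled_sd=np.asarray(payload["pooled_sd"], dtype=float),
            gamma_star=np.asarray(payload["gamma_star"], dtype=float),
            delta_star=np.asarray(payload["delta_star"], dtype=float),
            gamma_hat=np.asarray(payload["gamma_hat"], dtype=float),
            delta_hat=np.asarray(payload["delta_hat"], dtype=float),
            constant_features=np.asarray(payload["constant_features"], dtype=bool),
            n_per_site=np.asarray(payload["n_per_site"], dtype=int),
        )


def _design(sites, site_levels, covariates, centers) -> tuple[np.ndarray, np.ndarray]:
    """Site indicator block and centered covariate block."""
    site_idx = np.array([site_levels.index(s) for s in sites])
    D = np.zeros((len(sites), len(site_levels)))
    D[np.arange(len(sites)), site_idx] = 1.0
    C = covariates - centers if covariates.size else covariates
    return D, C


def _covariate_matrix(covariates: pd.DataFrame | None, names: list[str]) -> np.ndarray:
    if covariates is None or not names:
        return np.zeros((0, 0))
    cols = []
    for name in names:
        col = covariates[name]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {name}: only binary categorical supported")
            cols.append((col.astype(str) == levels[-1]).to_numpy(float))
        else:
            cols.append(col.to_numpy(float))
    return np.column_stack(cols)


def fit_combat(
    features: np.ndarray | pd.DataFrame,
    sites,
    covariates: pd.DataFrame | None = None,
    covariate_names: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> CombatModel:
    """Fit the empirical-Bayes site-effect model on (subjects x F) features."""
    if isinstance(features, pd.DataFrame):
        feature_names = [str(c) for c in features.columns]
        Y = features.to_numpy(dtype=float)
    else:
        Y = np.asarray(features, dtype=float)
        feature_names = [f"f{i}" for i in range(Y.shape[1])]
    sites = [str(s) for s in sites]
    if Y.ndim != 2:
        raise ValueError("features must be subjects x F")
    if len(sites) != Y.shape[0]:
        raise ValueError("sites length must match number of subjects")
    if not np.all(np.isfinite(Y)):
        raise ValueError("features contain missing or non-finite values")

    site_levels = sorted(set(sites))
    if len(site_levels) < 2:
        raise ValueError("ComBat needs at least 2 sites")
    counts = {lev: sites.count(lev) for lev in site_levels}
    singletons = [lev for lev, c in counts.items() if c < 2]
    if singletons:
        raise ValueError(f"singleton site(s): {', '.join(singletons)}")

    if covariate_names is None:
        covariate_names = []
        if covariates is not None:
            covariate_names = [c for c in ("age", "sex") if c in covariates.columns]
    C_raw = _covariate_matrix(covariates, covariate_names)
    centers = C_raw.mean(axis=0) if C_raw.size else np.zeros(0)

    n, F = Y.shape
    D, C = _design(sites, site_levels, C_raw, centers)
    X = np.hstack([D, C]) if C.size else D
    n_sites = len(site_levels)
    n_per_site = np.array([counts[lev] for lev in site_levels])

    # least squares over site indicators + covariates (no global intercept;
    # the grand mean is the sample-size-weighted average of site intercepts)
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    site_coefs = B[:n_sites]
    beta = B[n_sites:]
    grand_mean = (n_per_site / n) @ site_coefs

    fitted = X @ B
    resid = Y - fitted
    pooled_var = (resid**2).mean(axis=0)
    constant = pooled_var <= 1e-12
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) passed through unadjusted",
            stacklevel=2,
        )
        pooled_var = np.where(constant, 1.0, pooled_var)
    pooled_sd = np.sqrt(pooled_var)

    stand_mean = grand_mean[None, :] + (C @ beta if C.size else 0.0)
    s_data = (Y - stand_mean) / pooled_sd[None, :]

    gamma_hat = np.zeros((n_sites, F))
    delta_hat = np.zeros((n_sites, F))
    site_idx = np.array([site_levels.index(s) for s in sites])
    for i in range(n_sites):
        block = s_data[site_idx == i]
        gamma_hat[i] = block.mean(axis=0)
        delta_hat[i] = block.var(axis=0, ddof=1)
    delta_hat = np.clip(delta_hat, 1e-12, None)

    # parametric priors from moment matching across features
    gamma_bar = gamma_hat.mean(axis=1)  # per site
    tau2 = gamma_hat.var(axis=1, ddof=1) if F > 1 else np.zeros(n_sites)
    d_bar = delta_hat.mean(axis=1)
    d_var = delta_hat.var(axis=1, ddof=1) if F > 1 else np.zeros(n_sites)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (d_bar**2 + 2 * d_var) / d_var  # inverse-gamma shape
        theta = (d_bar**3 + d_bar * d_var) / d_var  # inverse-gamma rate

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for i in range(n_sites):
        if tau2[i] <= 0 or d_var[i] <= 0:
            # degenerate prior (e.g. a single feature): no shrinkage possible
            continue
        block = s_data[site_idx == i]
        n_i = block.shape[0]
        g, d2 = gamma_hat[i].copy(), delta_hat[i].copy()
        for _ in range(max_iter):
            g_new = (n_i * tau2[i] * gamma_hat[i] + d2 * gamma_bar[i]) / (
                n_i * tau2[i] + d2
            )
            sse = ((block - g_new[None, :]) ** 2).sum(axis=0)
            d2_new = (theta[i] + 0.5 * sse) / (n_i / 2.0 + lam[i] - 1.0)
            change = max(
                np.abs(g_new - g).max(),
                np.abs(d2_new - d2).max(),
            )
            g, d2 = g_new, d2_new
            if change < tol:
                break
        gamma_star[i], delta_star[i] = g, np.clip(d2, 1e-12, None)

    return CombatModel(
        feature_names=feature_names,
        site_levels=site_levels,
        covariate_names=list(covariate_names),
        covariate_centers=centers,
        grand_mean=grand_mean,
        beta=beta,
        pooled_sd=pooled_sd,
        gamma_star=gamma_star,
        delta_star=delta_star,
        gamma_hat=gamma_hat,
        delta_hat=delta_hat,
        constant_features=constant,
        n_per_site=n_per_site,
    )


def apply_combat(
    model: CombatModel,
    features: np.ndarray | pd.DataFrame,
    sites,
    covariates: pd.DataFrame | None = None,
) -> np.ndarray:
    """Remove site effects; covariate structure is restored."""
    Y = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(
        features, dtype=float
    )
    sites = [str(s) for s in sites]
    unseen = sorted(set(sites) - set(model.site_levels))
    if unseen:
        raise ValueError(f"site(s) not seen during fit: {', '.join(unseen)}")
    C_raw = _covariate_matrix(covariates, model.covariate_names)
    if model.covariate_names and C_raw.shape[0] != Y.shape[0]:
        raise ValueError("covariate rows must match feature rows")

    site_idx = np.array([model.site_levels.index(s) for s in sites])
    C = C_raw - model.covariate_centers if C_raw.size else C_raw
    stand_mean = model.grand_mean[None, :] + (C @ model.beta if C.size else 0.0)
    s_data = (Y - stand_mean) / model.pooled_sd[None, :]

    adj = (s_data - model.gamma_star[site_idx]) / np.sqrt(model.delta_star[site_idx])
    out = adj * model.pooled_sd[None, :] + stand_mean
    if model.constant_features.any():
        out[:, model.constant_features] = Y[:, model.constant_features]
    return out


def harmonize_matrices(
    fcs: list[ConnectivityMatrix],
    phenotypes: pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> tuple[list[ConnectivityMatrix], CombatModel]:
    """Vectorize -> ComBat -> rebuild matrices (clipped into (-1, 1))."""
    if not fcs:
        raise ValueError("no matrices to harmonize")
    R = fcs[0].n_regions
    for fc in fcs:
        if fc.n_regions != R:
            raise ValueError("all matrices must share the same region count")
    pheno = phenotypes.set_index("subject_id").loc[[fc.subject_id for fc in fcs]]
    table = edge_table(fcs)
    feats = table.drop(columns="subject_id")
    model = fit_combat(feats, pheno["site"].tolist(), pheno.reset_index(), covariate_names)
    adjusted = apply_combat(model, feats, pheno["site"].tolist(), pheno.reset_index())
    adjusted = np.clip(adjusted, -0.999999, 0.999999)
    out = [
        unflatten(adjusted[k], R, fc.subject_id, list(fc.region_labels))
        for k, fc in enumerate(fcs)
    ]
    return out, model


def site_f_statistics(features: np.ndarray, sites) -> np.ndarray:
    """One-way ANOVA F statistic per feature column for site differences."""
    Y = np.asarray(features, dtype=float)
    sites = np.asarray([str(s) for s in sites])
    levels = np.unique(sites)
    n, _ = Y.shape
    grand = Y.mean(axis=0)
    ss_between = np.zeros(Y.shape[1])
    ss_within = np.zeros(Y.shape[1])
    for lev in levels:
        block = Y[sites == lev]
        m = block.mean(axis=0)
        ss_between += block.shape[0] * (m - grand) ** 2
        ss_within += ((block - m) ** 2).sum(axis=0)
    df_b = len(levels) - 1
    df_w = n - len(levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ss_between / df_b) / (ss_within / df_w)
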