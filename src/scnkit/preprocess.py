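"""Data preparation: outlier screening, site harmonization, residualization.

Regional volume tables pooled over many scanners need three adjustments
before any covariance is computed:

1. **Outlier screening** — subjects with any region volume further than
   ``z_threshold`` (default 2.698) sample SDs from that region's pooled
   sample mean are removed in a single pass, guarding against
   missegmentation. Screening is per-network: a subject can be excluded
   from one analysis's region set and kept in another.
2. **Site harmonization** — region-wise ComBat: empirical-Bayes shrinkage of
   per-site location and scale effects, preserving variation explained by
   the biological covariates (age entered through a polynomial basis,
   degree 2 by default, plus sex and ICV).
3. **Covariate residualization** — per region, ordinary least squares on
   [intercept, age, age^2, sex, ICV] over all subjects pooled (optionally
   per group for sensitivity analyses); the residuals are the input to all
   covariance network construction.

Severity instrument scores are min-max normalized onto [0, 1] so different
instruments are comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "OutlierTrimmer",
    "ComBatHarmonizer",
    "CovariateResidualizer",
    "remove_outliers",
    "harmonize_sites",
    "residualize",
    "normalize_severity",
]

DEFAULT_Z_THRESHOLD = 2.698
DEFAULT_COVARIATES = ("age", "sex", "icv")


# ---------------------------------------------------------------------------
# outlier screening


class OutlierTrimmer(BaseEstimator):
    """Single-pass region-volume outlier removal.

    ``fit`` computes each region's mean and SD once on the full sample;
    ``transform`` drops every subject whose volume deviates from the fitted
    mean by more than ``z_threshold`` SDs in any region. Because the
    reference statistics are frozen at fit time, re-applying the rule is
    idempotent.
    """

    def __init__(self, regions: list[str] | None = None, z_threshold: float = DEFAULT_Z_THRESHOLD):
        self.regions = regions
        self.z_threshold = z_threshold

    def fit(self, table: pd.DataFrame, y=None):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        if len(table) < 3:
            raise ValueError("outlier screening needs at least 3 subjects")
        regions = list(self.regions) if self.regions is not None else _infer_regions(table)
        vols = table[regions].to_numpy(dtype=float)
        self.regions_ = regions
        self.means_ = vols.mean(axis=0)
        self.sds_ = vols.std(axis=0, ddof=1)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        vols = table[self.regions_].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(vols - self.means_) / self.sds_
        z = np.where(self.sds_ > 0, z, 0.0)
        keep = ~(z > self.z_threshold).any(axis=1)
        self.removed_ids_ = list(table.loc[~keep, "subject_id"]) if "subject_id" in table else \
            list(table.index[~keep])
        if not keep.any():
            raise ValueError("outlier rule removed every subject; degenerate cohort")
        return table.loc[keep].copy()

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(table).transform(table)


def remove_outliers(
    table: pd.DataFrame,
    regions: list[str] | None = None,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> tuple[pd.DataFrame, list]:
    """Functional form of :class:`OutlierTrimmer`: (kept table, removed ids)."""
    trimmer = OutlierTrimmer(regions=regions, z_threshold=z_threshold)
    kept = trimmer.fit_transform(table)
    return kept, trimmer.removed_ids_


def _infer_regions(table: pd.DataFrame) -> list[str]:
    from .io import METADATA_COLUMNS

    return [c for c in table.columns if c not in METADATA_COLUMNS]


# ---------------------------------------------------------------------------
# ComBat harmonization


def _combat(Y: np.ndarray, batch: np.ndarray, X: np.ndarray | None, max_iter: int = 100,
            tol: float = 1e-6) -> np.ndarray:
    """Parametric empirical-Bayes ComBat location/scale batch adjustment.

    Y is subjects x features; batch an integer label per subject; X the
    covariate design (no intercept — batch indicators span it). Returns the
    adjusted data. Follows the standard formulation: standardize with the
    full (batch + covariate) regression, shrink per-batch means toward a
    normal prior and per-batch variances toward an inverse-gamma prior, then
    reconstruct with batch terms removed and covariate terms kept.
    """
    n, g = Y.shape
    batches = np.unique(batch)
    if len(batches) < 2:
        return Y.copy()
    counts = np.array([(batch == b).sum() for b in batches])
    if counts.min() < 2:
        bad = batches[counts.argmin()]
        raise ValueError(f"site {bad!r} has fewer than 2 subjects; cannot harmonize")
    B = np.zeros((n, len(batches)))
    for k, b in enumerate(batches):
        B[batch == b, k] = 1.0
    D = B if X is None else np.hstack([B, X])
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    batch_coef = coef[: len(batches)]
    grand_mean = (counts / n) @ batch_coef
    resid = Y - D @ coef
    var_pooled = (resid**2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise ValueError("zero pooled variance; cannot standardize for harmonization")
    stand_mean = np.tile(grand_mean, (n, 1))
    if X is not None:
        stand_mean = stand_mean + X @ coef[len(batches):]
    s = np.sqrt(var_pooled)
    Z = (Y - stand_mean) / s

    gamma_hat = np.vstack([Z[batch == b].mean(axis=0) for b in batches])
    delta_hat = np.vstack([Z[batch == b].var(axis=0, ddof=1) for b in batches])
    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    # inverse-gamma prior moments for the variances
    v_bar = delta_hat.mean(axis=1)
    s2 = delta_hat.var(axis=1, ddof=1)
    a_prior = (2 * s2 + v_bar**2) / np.maximum(s2, 1e-12)
    b_prior = (v_bar * s2 + v_bar**3) / np.maximum(s2, 1e-12)

    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for k, b in enumerate(batches):
        nk = counts[k]
        g_new, d_new = gamma_hat[k], delta_hat[k]
        Zk = Z[batch == b]
        for _ in range(max_iter):
            g_prev, d_prev = g_new, d_new
            g_new = (nk * tau2[k] * gamma_hat[k] + d_new * gamma_bar[k]) / (nk * tau2[k] + d_new)
            sse = ((Zk - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sse + b_prior[k]) / (nk / 2.0 + a_prior[k] - 1.0)
            if max(np.abs(g_new - g_prev).max(), np.abs(d_new - d_prev).max()) < tol:
                break
        gamma_star[k] = g_new
        delta_star[k] = d_new

    out = Z.copy()
    for k, b in enumerate(batches):
        rows = batch == b
        out[rows] = (Z[rows] - gamma_star[k]) / np.sqrt(delta_star[k])
    return out * s + stand_mean


class ComBatHarmonizer(BaseEstimator, TransformerMixin):
    """Remove site/scanner batch effects from region volumes.

    Uses empirical-Bayes ComBat with a covariate design that preserves
    biological variation: polynomial age basis of configurable degree
    (default 2, standing in for the spline basis of GAM-flavored ComBat),
    plus any other covariate columns entered linearly. Harmonization
    estimates batch effects from the data it adjusts, so the entry point is
    ``fit_transform``; a single site is returned unchanged.
    """

    def __init__(
        self,
        regions: list[str] | None = None,
        site_col: str = "site",
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        age_basis_degree: int = 2,
    ):
        self.regions = regions
        self.site_col = site_col
        self.covariates = covariates
        self.age_basis_degree = age_basis_degree

    def _design(self, table: pd.DataFrame) -> np.ndarray | None:
        cols = []
        for c in self.covariates:
            missing = c not in table.columns
            if missing:
                raise ValueError(f"covariate column {c!r} not in table")
            x = table[c].to_numpy(dtype=float)
            if c == "age":
                xc = x - x.mean()
                for d in range(1, self.age_basis_degree + 1):
                    cols.append(xc**d)
            else:
                cols.append(x - x.mean())
        return np.column_stack(cols) if cols else None

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        regions = list(self.regions) if self.regions is not None else _infer_regions(table)
        sites, batch = np.unique(table[self.site_col].to_numpy(), return_inverse=True)
        counts = np.bincount(batch)
        if len(sites) > 1 and counts.min() < 2:
            bad = sites[counts.argmin()]
            raise ValueError(f"site {bad!r} has fewer than 2 subjects; cannot harmonize")
        Y = table[regions].to_numpy(dtype=float)
        adjusted = _combat(Y, batch, self._design(table) if len(sites) > 1 else None)
        out = table.copy()
        out[regions] = adjusted
        self.regions_ = regions
        self.sites_ = list(sites)
        return out

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:  # pragma: no cover
        raise NotImplementedError("ComBat estimates batch effects in fit_transform; "
                                  "use fit_transform on the full table")


def harmonize_sites(
    table: pd.DataFrame,
    regions: list[str] | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    site_col: str = "site",
    age_basis_degree: int = 2,
) -> pd.DataFrame:
    """Functional form of :class:`ComBatHarmonizer`."""
    return ComBatHarmonizer(
        regions=regions, site_col=site_col, covariates=covariates,
        age_basis_degree=age_basis_degree,
    ).fit_transform(table)


# ---------------------------------------------------------------------------
# covariate residualization


class CovariateResidualizer(BaseEstimator, TransformerMixin):
    """OLS removal of age, age^2, sex and ICV effects per region.

    The model is fit over all subjects pooled (default) so between-group
    covariance differences are untouched; ``scope='per_group'`` fits
    separate models per diagnostic group for sensitivity analyses.
    Residual columns replace the volume columns; metadata is carried over.
    """

    def __init__(
        self,
        regions: list[str] | None = None,
        covariates: tuple[str, ...] = DEFAULT_COVARIATES,
        scope: str = "pooled",
        group_col: str = "group",
        max_condition: float = 1e10,
    ):
        self.regions = regions
        self.covariates = covariates
        self.scope = scope
        self.group_col = group_col
        self.max_condition = max_condition

    def _design(self, table: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(table))]
        for c in self.covariates:
            if c not in table.columns:
                raise ValueError(f"covariate column {c!r} not in table")
            x = table[c].to_numpy(dtype=float)
            if c == "age":
                cols.append(x)
                cols.append(x**2)
            else:
                cols.append(x)
        X = np.column_stack(cols)
        # scale columns before the condition check so units don't dominate
        scale = np.linalg.norm(X, axis=0)
        cond = np.linalg.cond(X / np.where(scale > 0, scale, 1.0))
        if cond > self.max_condition:
            raise ValueError(f"collinear covariate design (condition number {cond:.3g})")
        return X

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        regions = list(self.regions) if self.regions is not None else _infer_regions(table)
        if self.scope not in ("pooled", "per_group"):
            raise ValueError("scope must be 'pooled' or 'per_group'")
        out = table.copy()
        if self.scope == "pooled":
            groups = [np.ones(len(table), dtype=bool)]
        else:
            groups = [
                (table[self.group_col] == g).to_numpy()
                for g in table[self.group_col].unique()
            ]
        Y = table[regions].to_numpy(dtype=float)
        resid = np.empty_like(Y)
        for rows in groups:
            X = self._design(table.loc[rows])
            beta, *_ = np.linalg.lstsq(X, Y[rows], rcond=None)
            resid[rows] = Y[rows] - X @ beta
        out[regions] = resid
        self.regions_ = regions
        return out

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit_transform(table)


def residualize(
    table: pd.DataFrame,
    regions: list[str] | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    scope: str = "pooled",
) -> pd.DataFrame:
    """Residual table after removing [intercept, age, age^2, sex, ICV] per region."""
    return CovariateResidualizer(regions=regions, covariates=covariates, scope=scope).fit_transform(table)


# ---------------------------------------------------------------------------
# severity normalization


def normalize_severity(raw, instrument_min: float, instrument_max: float):
    """Min-max map of instrument scores onto [0, 1].

    Raises if the instrument range is empty or a score falls outside it.
    Accepts scalars or arrays; NaN passes through (missing severity).
    """
    if instrument_max <= instrument_min:
        raise ValueError("instrument_max must exceed instrument_min")
    arr = np.asarray(raw, dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < instrument_min) | (arr[finite] > instrument_max)):
        raise ValueError("raw severity outside the instrument range")
    out = (arr - instrument_min) / (instrument_max - instrument_min)
    return float(out) if np.isscalar(raw) or arr.ndim == 0 else out
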