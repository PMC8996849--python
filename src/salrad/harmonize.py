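"""Parametric empirical-Bayes ComBat harmonization of radiomics features.

Batch effects (per-batch additive location shifts and multiplicative scale
changes) are estimated feature-wise after standardizing out the grand mean
and protected biological covariates, shrunk across features toward a common
prior (normal for location, inverse-gamma for scale) by iterative EB
updates, and removed. Three batch divisions are supported, mirroring
multi-center PET/CT acquisition variability: per center, per scanner
manufacturer, and per voxel-size group (PET in-plane resolution bins or CT
slice-thickness bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BatchDesign",
    "CombatModel",
    "assign_batches",
    "combat_fit_transform",
    "PET_INPLANE_BINS",
    "CT_SLICE_BINS",
]

# voxel-size batch bins, in mm
PET_INPLANE_BINS = ((1.9, 3.0), (3.1, 3.5), (3.6, 4.5), (4.6, 5.5))
CT_SLICE_BINS = ((1.5, 1.5), (2.0, 2.0), (2.1, 2.6), (2.7, 3.0), (3.1, 3.3), (3.4, 5.0))

STRATEGIES = ("none", "center", "manufacturer", "voxel_size")


@dataclass(frozen=True)
class BatchDesign:
    """Assignment of patients to batches plus protected covariates."""

    strategy: str
    batch_of: pd.Series  # patient -> batch label
    covariates: pd.DataFrame | None = None  # numeric design, same index

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        counts = self.batch_of.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"batch(es) with fewer than 2 patients: "
                             f"{small.index.tolist()}")
        if self.covariates is not None and not self.covariates.index.equals(self.batch_of.index):
            raise ValueError("covariates index must match batch assignment")

    @property
    def n_batches(self) -> int:
        return self.batch_of.nunique()


@dataclass(frozen=True)
class CombatModel:
    """Fitted per-feature ComBat parameters (diagnostic output)."""

    alpha: np.ndarray
    beta: np.ndarray | None
    gamma_star: np.ndarray  # batches x features
    delta_star: np.ndarray  # batches x features, > 0
    pooled_var: np.ndarray
    batches: list
    n_iter: int


def _bin_label(value: float, bins) -> str:
    for lo, hi in bins:
        if lo <= value <= hi + 1e-9:
            return f"{lo:g}" if lo == hi else f"{lo:g}-{hi:g}"
    # clamp out-of-range acquisitions onto the nearest bin
    lo0, hi_last = bins[0][0], bins[-1][1]
    if value < lo0:
        lo, hi = bins[0]
    else:
        lo, hi = bins[-1]
    return f"{lo:g}" if lo == hi else f"{lo:g}-{hi:g}"


def pet_inplane_batch(inplane_mm: float) -> str:
    """PET in-plane-resolution batch label (4 bins)."""
    return _bin_label(float(inplane_mm), PET_INPLANE_BINS)


def ct_slice_batch(slice_mm: float) -> str:
    """CT slice-thickness batch label (6 bins)."""
    return _bin_label(float(slice_mm), CT_SLICE_BINS)


def assign_batches(metadata: pd.DataFrame, strategy: str,
                   modality: str = "PET",
                   covariate_cols: list[str] | None = None) -> BatchDesign:
    """Build a BatchDesign from patient metadata.

    Expected metadata columns: ``center``, ``manufacturer``, ``inplane_mm``,
    ``slice_mm`` and any covariate columns (e.g. age, sex, T/N/TNM stage,
    site). Categorical covariates are one-hot encoded with the first level
    dropped.
    """
    if strategy == "none":
        batch = pd.Series("all", index=metadata.index, name="batch")
    elif strategy == "center":
        batch = metadata["center"].astype(str)
    elif strategy == "manufacturer":
        batch = metadata["manufacturer"].astype(str)
    elif strategy == "voxel_size":
        if modality.upper() == "PET":
            batch = metadata["inplane_mm"].map(pet_inplane_batch)
        else:
            batch = metadata["slice_mm"].map(ct_slice_batch)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    cov = None
    if covariate_cols:
        missing = [c for c in covariate_cols if c not in metadata.columns]
        if missing:
            raise ValueError(f"covariate columns missing from metadata: {missing}")
        cov = pd.get_dummies(metadata[covariate_cols], drop_first=True, dtype=float)
    return BatchDesign(strategy, batch.rename("batch"), cov)


def _eb_iterate(gamma_hat, delta_hat_sq, n_b, tol=1e-4, max_iter=500):
    """Iterative EB shrinkage of one batch's location/scale estimates.

    gamma_hat, delta_hat_sq: per-feature estimates within the batch.
    Priors: gamma ~ N(gamma_bar, tau_sq); delta^2 ~ InvGamma(lam, theta),
    hyperparameters estimated from the across-feature moments.
    """
    gamma_bar = gamma_hat.mean()
    tau_sq = gamma_hat.var(ddof=1)
    v = delta_hat_sq.mean()
    s2 = delta_hat_sq.var(ddof=1)
    # method-of-moments inverse-gamma hyperparameters
    lam = (2 * s2 + v ** 2) / s2 if s2 > 0 else 100.0
    theta = (v * s2 + v ** 3) / s2 if s2 > 0 else v * 99.0

    g_new = gamma_hat.copy()
    d_new = delta_hat_sq.copy()
    for it in range(max_iter):
        if tau_sq > 0:
            g_next = (n_b * tau_sq * gamma_hat + d_new * gamma_bar) / (n_b * tau_sq + d_new)
        else:
            g_next = np.full_like(gamma_hat, gamma_bar)
        ssq = (n_b - 1) * delta_hat_sq + n_b * (gamma_hat - g_next) ** 2
        d_next = (theta + 0.5 * ssq) / (n_b / 2 + lam - 1)
        change = max(np.max(np.abs(g_next - g_new)), np.max(np.abs(d_next - d_new)))
        g_new, d_new = g_next, d_next
        if change < tol:
            return g_new, d_new, it + 1
    raise RuntimeError(f"EB shrinkage did not converge in {max_iter} iterations "
                       f"(last change {change:.3g})")


def combat_fit_transform(features: pd.DataFrame, design: BatchDesign,
                         tol: float = 1e-4,
                         return_model: bool = False):
    """Fit ComBat on a feature table and return the harmonized table.

    ``features``: patients x features, numeric, finite. With a single batch
    the input is returned unchanged (identity pass-through). Covariate
    columns that are constant overall or perfectly confounded with batch
    are dropped with a warning.
    """
    X = features.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if not design.batch_of.index.equals(features.index):
        raise ValueError("batch design index must match feature table index")

    batches = sorted(design.batch_of.unique(), key=str)
    if len(batches) < 2:
        out = features.copy()
        return (out, None) if return_model else out

    n, p = X.shape
    onehot = np.column_stack([(design.batch_of == b).to_numpy(float) for b in batches])
    n_per = onehot.sum(axis=0)

    cov = None
    if design.covariates is not None and design.covariates.shape[1]:
        cov = design.covariates.to_numpy(dtype=np.float64)
        keep = []
        for j in range(cov.shape[1]):
            col = cov[:, j]
            if np.ptp(col) == 0:
                warnings.warn(f"dropping constant covariate "
                              f"{design.covariates.columns[j]!r}")
                continue
            # confounded with batch: predictable from batch indicators
            resid = col - onehot @ np.linalg.lstsq(onehot, col, rcond=None)[0]
            if np.max(np.abs(resid)) < 1e-10:
                warnings.warn(f"dropping batch-confounded covariate "
                              f"{design.covariates.columns[j]!r}")
                continue
            keep.append(j)
        cov = cov[:, keep] if keep else None

    design_mat = onehot if cov is None else np.hstack([onehot, cov])
    if np.linalg.matrix_rank(design_mat) < design_mat.shape[1]:
        raise ValueError("design matrix rank-deficient after covariate filtering")

    # feature-wise OLS for batch means + covariate effects
    B = np.linalg.lstsq(design_mat, X, rcond=None)[0]  # (n_batch + q) x p
    batch_means = B[: len(batches)]
    alpha = (n_per / n) @ batch_means  # size-weighted grand intercept
    cov_effect = cov @ B[len(batches):] if cov is not None else 0.0

    stand_mean = alpha[None, :] + cov_effect
    resid = X - onehot @ batch_means - cov_effect
    pooled_var = (resid ** 2).mean(axis=0)
    pooled_var = np.maximum(pooled_var, 1e-12)
    pooled_sd = np.sqrt(pooled_var)
    Z = (X - stand_mean) / pooled_sd

    gamma_star = np.empty((len(batches), p))
    delta_star = np.empty((len(batches), p))
    n_iter_max = 0
    for bi, b in enumerate(batches):
        sel = onehot[:, bi] > 0
        zb = Z[sel]
        gamma_hat = zb.mean(axis=0)
        delta_hat_sq = zb.var(axis=0, ddof=1)
        if p >= 2:
            g_st, d_st, it = _eb_iterate(gamma_hat, delta_hat_sq, sel.sum(), tol=tol)
        else:
            # a single feature gives no across-feature prior; use raw estimates
            g_st, d_st, it = gamma_hat, np.maximum(delta_hat_sq, 1e-12), 0
        gamma_star[bi] = g_st
        delta_star[bi] = np.maximum(d_st, 1e-12)
        n_iter_max = max(n_iter_max, it)

    adj = np.empty_like(Z)
    for bi in range(len(batches)):
        sel = onehot[:, bi] > 0
        adj[sel] = (Z[sel] - gamma_star[bi]) / np.sqrt(delta_star[bi])
    out_arr = adj * pooled_sd + stand_mean
    out = pd.DataFrame(out_arr, index=features.index, columns=features.columns)
    if return_model:
        beta = B[len(batches):] if cov is not None else None
        model = CombatModel(alpha, beta, gamma_star, delta_star, pooled_var,
                            list(batches), n_iter_max)
        return out, model
    return out


def harmonize(features: pd.DataFrame, metadata: pd.DataFrame, strategy: str,
              modality: str = "PET",
              covariate_cols: list[str] | None = None) -> pd.DataFrame:
    """Convenience wrapper: assign batches by strategy, then ComBat."""
    design = assign_batches(metadata.loc[features.index], strategy,
                            modality=modality, covariate_cols=covariate_cols)
    return combat_fit_transform(features, design)
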