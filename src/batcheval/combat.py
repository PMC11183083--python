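"""Parametric empirical-Bayes location/scale batch harmonization (ComBat).

The model assumes each feature value decomposes as

    y = alpha + X_cov beta + gamma_batch + delta_batch * eps,

where ``gamma`` and ``delta`` are per-(batch, feature) location and scale
effects.  Fitting standardizes each feature (removing covariate effects and
the batch-size-weighted grand mean, dividing by the pooled residual SD),
estimates per-batch location/scale on the standardized scale, and shrinks
those estimates across features with parametric empirical Bayes: a normal
prior on locations and an inverse-gamma prior on squared scales, with the
conditional posterior-mean equations iterated to convergence.  Adjusted
data subtract the shrunken location, divide by the shrunken scale, and
restore the grand mean and the protected covariate effects.

This follows the standard parametric formulation (the moment-based
hyperparameter estimators match the reference Bioconductor implementation);
covariate columns are "protected" in the sense that their fitted effects
are added back untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import BatchLabels, CovariateTable, FeatureMatrix, ValidationError

_EB_TOL = 1e-6
_EB_MAX_ITER = 100


@dataclass(frozen=True, eq=False)
class CombatModel:
    """Fitted harmonization parameters.

    gamma_star / delta2_star are (g, m) arrays of EB-shrunken per-batch
    location and squared-scale effects on the standardized scale.
    """

    levels: tuple[str, ...]
    grand_mean: np.ndarray          # (m,)
    cov_coef: np.ndarray            # (q, m) covariate coefficients
    pooled_var: np.ndarray          # (m,)
    gamma_star: np.ndarray          # (g, m)
    delta2_star: np.ndarray         # (g, m)
    constant_features: np.ndarray   # (m,) bool
    single_batch: bool = False


def _coerce_labels(labels) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(labels, BatchLabels):
        # preserve the sorted-level order rather than reference coding
        levels = labels.levels
        lut = {lev: k for k, lev in enumerate(levels)}
        codes = np.array([lut[x] for x in labels.labels], dtype=np.intp)
        return codes, levels
    arr = np.asarray([str(x) for x in labels])
    levels = tuple(sorted(set(arr)))
    lut = {lev: k for k, lev in enumerate(levels)}
    return np.array([lut[x] for x in arr], dtype=np.intp), levels


def _cov_design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    if isinstance(covariates, CovariateTable):
        design = covariates.design()
    else:
        design = np.atleast_2d(np.asarray(covariates, dtype=float))
        if design.shape[0] != n:
            design = design.T
    if design.shape[0] != n:
        raise ValidationError("covariates not aligned to samples")
    return design


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2.0 * s2 + m * m) / s2


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m**3) / s2


def combat_fit(
    x: FeatureMatrix,
    labels,
    covariates: CovariateTable | None = None,
) -> CombatModel:
    """Estimate ComBat harmonization parameters from training data."""
    Y = x.values  # (n, m)
    n, m = Y.shape
    codes, levels = _coerce_labels(labels)
    if len(codes) != n:
        raise ValidationError("labels not aligned to feature matrix")
    g = len(levels)
    counts = np.bincount(codes, minlength=g).astype(float)
    if np.any(counts < 2):
        raise ValidationError("every batch level needs >= 2 samples")
    C = _cov_design(covariates, n)
    q = C.shape[1]

    if g == 1:
        # EB priors are undefined with a single batch; harmonization is the
        # identity by construction
        warnings.warn("single batch level: ComBat is the identity transform")
        return CombatModel(
            levels=levels,
            grand_mean=Y.mean(axis=0),
            cov_coef=np.zeros((q, m)),
            pooled_var=np.ones(m),
            gamma_star=np.zeros((1, m)),
            delta2_star=np.ones((1, m)),
            constant_features=np.zeros(m, dtype=bool),
            single_batch=True,
        )

    B = np.zeros((n, g))
    B[np.arange(n), codes] = 1.0
    X = np.hstack([B, C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(
            "design is rank deficient: a covariate is confounded with batch"
        )
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    batch_coef = coef[:g]                      # (g, m) batch means net of covariates
    cov_coef = coef[g:]                        # (q, m)
    grand_mean = (counts / n) @ batch_coef     # (m,)

    resid = Y - X @ coef
    pooled_var = (resid**2).mean(axis=0)       # divisor n, as in the reference EB fit
    constant = (pooled_var <= 0) | (np.ptp(Y, axis=0) == 0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature(s) bypass harmonization"
        )
    sd = np.where(constant, 1.0, np.sqrt(pooled_var))

    stand = grand_mean[None, :] + C @ cov_coef
    Z = (Y - stand) / sd[None, :]

    gamma_hat = np.stack([Z[codes == k].mean(axis=0) for k in range(g)])
    delta2_hat = np.stack([Z[codes == k].var(axis=0, ddof=1) for k in range(g)])

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for k in range(g):
        if m < 2 or gamma_hat[k].var(ddof=1) <= 0 or delta2_hat[k].var(ddof=1) <= 0:
            # no information to pool across features; keep raw estimates
            gamma_star[k], delta2_star[k] = gamma_hat[k], delta2_hat[k]
            continue
        g_bar = gamma_hat[k].mean()
        t2 = gamma_hat[k].var(ddof=1)
        a, b = _aprior(delta2_hat[k]), _bprior(delta2_hat[k])
        nk = counts[k]
        zk = Z[codes == k]
        g_new, d_new = gamma_hat[k].copy(), delta2_hat[k].copy()
        for _ in range(_EB_MAX_ITER):
            g_old, d_old = g_new, d_new
            g_new = (nk * t2 * gamma_hat[k] + d_old * g_bar) / (nk * t2 + d_old)
            ss = ((zk - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (b + 0.5 * ss) / (nk / 2.0 + a - 1.0)
            change = max(
                np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
                np.abs(d_new - d_old).max() / np.abs(d_old).max(),
            )
            if change < _EB_TOL:
                break
        gamma_star[k], delta2_star[k] = g_new, d_new

    return CombatModel(
        levels=levels,
        grand_mean=grand_mean,
        cov_coef=cov_coef,
        pooled_var=np.where(constant, 1.0, pooled_var),
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        constant_features=constant,
    )


def combat_apply(
    model: CombatModel,
    x: FeatureMatrix,
    labels,
    covariates: CovariateTable | None = None,
) -> FeatureMatrix:
    """Harmonize a feature matrix with a fitted model.

    Every batch level present must have been seen at fit time.  Constant
    features (at fit time) pass through unchanged.
    """
    Y = x.values
    n, m = Y.shape
    codes_raw, levels = _coerce_labels(labels)
    unseen = set(levels) - set(model.levels)
    if unseen:
        raise ValidationError(f"batch level(s) unseen at fit time: {sorted(unseen)}")
    lut = {lev: k for k, lev in enumerate(model.levels)}
    codes = np.array([lut[levels[c]] for c in codes_raw], dtype=np.intp)
    C = _cov_design(covariates, n)
    if C.shape[1] != model.cov_coef.shape[0]:
        raise ValidationError("covariate design does not match the fitted model")

    if model.single_batch:
        return x

    sd = np.sqrt(model.pooled_var)
    stand = model.grand_mean[None, :] + C @ model.cov_coef
    Z = (Y - stand) / sd[None, :]
    Zadj = (Z - model.gamma_star[codes]) / np.sqrt(model.delta2_star[codes])
    out = Zadj * sd[None, :] + stand
    if model.constant_features.any():
        out[:, model.constant_features] = Y[:, model.constant_features]
    return FeatureMatrix(out, x.sample_ids, x.feature_names)


def combat_fit_apply(
    x: FeatureMatrix,
    labels,
    covariates: CovariateTable | None = None,
) -> tuple[FeatureMatrix, CombatModel]:
    """Convenience one-shot fit-and-transform on the same data."""
    model = combat_fit(x, labels, covariates)
    return combat_apply(model, x, labels, covariates), model
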