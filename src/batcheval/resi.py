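"""Robust Effect Size Index (RESI) for the effect of batch on a feature.

For each feature a linear model ``feature ~ batch`` is fit with the batch
variable reference-coded (intercept = reference-batch mean, one coefficient
per non-reference batch).  Effect sizes are derived from robust Wald
statistics built on a heteroskedasticity-consistent sandwich covariance
(HC3 by default):

* per non-reference coefficient, the signed single-parameter conversion
  ``S_j = z_j / sqrt(n)`` with ``z_j = beta_j / sqrt(Var_robust(beta_j))`` --
  for a balanced two-group mean difference this converges to Cohen's d / 2;
* for the joint batch effect, the chi-squared conversion
  ``S = sqrt(max(0, (chi2 - df) / n))`` of the robust Wald statistic over the
  g - 1 non-reference coefficients (the truncation at 0 is part of the
  estimator).

The two conversions coincide asymptotically; at g = 2 they are related by
``overall^2 = max(0, per_coef^2 - 1/n)``.  Confidence intervals are
nonparametric case-resampling bootstrap percentile intervals of the signed
per-coefficient values (and of the overall index), 500 replicates by
default.

Model fitting uses closed-form group statistics (the OLS solution for a
single categorical predictor), which makes the 500-replicate bootstrap a
vectorised per-group aggregation instead of 500 regression fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import BatchLabels, FeatureMatrix, ValidationError

_HC_FLAVORS = ("HC0", "HC1", "HC2", "HC3")
_BOOT_REDRAW_ROUNDS = 50


class DegenerateFitError(ValueError):
    """Zero residual variance in every group: robust variances vanish."""


@dataclass(frozen=True, eq=False)
class ModelFit:
    """Reference-coded OLS fit of one feature on the batch factor.

    ``beta[0]`` is the reference-batch mean; ``beta[1:]`` are non-reference
    batch means minus the reference mean.  ``robust_cov`` is the sandwich
    covariance of ``beta``.
    """

    beta: np.ndarray
    robust_cov: np.ndarray
    n: int
    reference_level: str
    levels: tuple[str, ...]

    @property
    def coef_names(self) -> tuple[str, ...]:
        return tuple(self.levels[1:])


def _group_stats(y: np.ndarray, codes: np.ndarray, g: int):
    counts = np.bincount(codes, minlength=g).astype(float)
    sums = np.bincount(codes, weights=y, minlength=g)
    means = sums / counts
    ss_res = np.bincount(codes, weights=y * y, minlength=g) - counts * means**2
    return counts, means, np.maximum(ss_res, 0.0)


def _mean_variances(counts, ss_res, n, g, cov_type: str) -> np.ndarray:
    """Robust variance of each group mean under the chosen HC flavor.

    For the cell-means design the leverage of every observation in group k is
    1/n_k, so the sandwich reduces to a weighted residual sum per group.
    """
    if cov_type == "HC0":
        scale = np.ones_like(counts)
    elif cov_type == "HC1":
        scale = np.full_like(counts, n / (n - g))
    elif cov_type == "HC2":
        scale = 1.0 / (1.0 - 1.0 / counts)
    elif cov_type == "HC3":
        scale = 1.0 / (1.0 - 1.0 / counts) ** 2
    else:
        raise ValueError(f"cov_type must be one of {_HC_FLAVORS}")
    return scale * ss_res / counts**2


def fit_batch_model(y, labels: BatchLabels, cov_type: str = "HC3") -> ModelFit:
    """OLS of a feature on reference-coded batch with sandwich covariance."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(labels):
        raise ValidationError("y must be a length-n vector aligned to labels")
    if not np.isfinite(y).all():
        raise ValidationError("non-finite values in y")
    codes = labels.codes
    g = labels.n_levels
    n = len(y)
    counts, means, ss_res = _group_stats(y, codes, g)
    if np.all(ss_res <= 0):
        raise DegenerateFitError(
            "feature is constant within every batch level; zero residual variance"
        )
    v = _mean_variances(counts, ss_res, n, g, cov_type)
    beta = np.concatenate([[means[0]], means[1:] - means[0]])
    # cov of (mean_ref, mean_k - mean_ref): groups are independent
    cov = np.full((g, g), v[0])
    cov[0, 1:] *= -1.0
    cov[1:, 0] *= -1.0
    cov[np.arange(1, g), np.arange(1, g)] += v[1:]
    return ModelFit(
        beta=beta,
        robust_cov=cov,
        n=n,
        reference_level=labels.reference_level,
        levels=labels.ordered_levels,
    )


def z_to_resi(z, n):
    """Signed RESI from a single-parameter Wald z statistic: S = z / sqrt(n)."""
    return np.asarray(z, dtype=float) / np.sqrt(n)


def chisq_to_resi(chisq, df, n):
    """RESI from a Wald chi-squared statistic: sqrt(max(0, (chi2 - df)/n))."""
    return np.sqrt(np.maximum(0.0, (np.asarray(chisq, dtype=float) - df) / n))


def _truncated_z_to_resi(z, n):
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.sqrt(np.maximum(0.0, (z * z - 1.0) / n))


def resi_point(fit: ModelFit, df_adjust: bool = False):
    """Per-coefficient (signed) and overall RESI point estimates.

    ``df_adjust=True`` switches the per-coefficient conversion to the
    truncated chi-squared form sign(z) * sqrt(max(0, (z^2 - 1)/n)).
    """
    g = len(fit.beta)
    var = np.diag(fit.robust_cov)[1:]
    if np.any(var <= 0):
        raise DegenerateFitError("zero robust variance for a batch coefficient")
    z = fit.beta[1:] / np.sqrt(var)
    per_coef = _truncated_z_to_resi(z, fit.n) if df_adjust else z_to_resi(z, fit.n)
    cov_b = fit.robust_cov[1:, 1:]
    chi2 = float(fit.beta[1:] @ np.linalg.solve(cov_b, fit.beta[1:]))
    overall = float(chisq_to_resi(chi2, g - 1, fit.n))
    return per_coef, overall


@dataclass(frozen=True, eq=False)
class ResiResult:
    """Point estimates and bootstrap CI bounds for one feature."""

    per_coefficient: np.ndarray
    overall: float
    ci_low: np.ndarray
    ci_high: np.ndarray
    overall_ci: tuple[float, float]
    n_boot: int
    coef_names: tuple[str, ...]


def _boot_resi(
    y: np.ndarray,
    codes: np.ndarray,
    g: int,
    n_boot: int,
    rng: np.random.Generator,
    cov_type: str,
    df_adjust: bool,
):
    """Vectorised case-resampling bootstrap of (per-coef S, overall S).

    Replicates in which any batch level ends up with < 2 observations are
    redrawn (bounded rounds), mirroring the validity requirement on the
    original fit.
    """
    n = len(y)
    zs = np.empty((n_boot, g - 1))
    overall = np.empty(n_boot)
    need = np.arange(n_boot)
    for _ in range(_BOOT_REDRAW_ROUNDS):
        if len(need) == 0:
            break
        idx = rng.integers(0, n, size=(len(need), n))
        yb = y[idx]
        cb = codes[idx]
        cnts = np.stack([(cb == k).sum(axis=1) for k in range(g)], axis=1).astype(float)
        ok = (cnts >= 2).all(axis=1)
        rows = need[ok]
        if len(rows):
            yb, cb, cnts_ok = yb[ok], cb[ok], cnts[ok]
            sums = np.stack([np.where(cb == k, yb, 0.0).sum(axis=1) for k in range(g)], 1)
            sqs = np.stack([np.where(cb == k, yb * yb, 0.0).sum(axis=1) for k in range(g)], 1)
            means = sums / cnts_ok
            ss = np.maximum(sqs - cnts_ok * means**2, 0.0)
            if cov_type == "HC0":
                scale = np.ones_like(cnts_ok)
            elif cov_type == "HC1":
                scale = np.full_like(cnts_ok, n / (n - g))
            elif cov_type == "HC2":
                scale = 1.0 / (1.0 - 1.0 / cnts_ok)
            else:
                scale = 1.0 / (1.0 - 1.0 / cnts_ok) ** 2
            v = scale * ss / cnts_ok**2
            diff = means[:, 1:] - means[:, :1]
            denom = v[:, 1:] + v[:, :1]
            with np.errstate(divide="ignore", invalid="ignore"):
                zb = np.where(denom > 0, diff / np.sqrt(denom), 0.0)
            zs[rows] = zb
            # overall Wald chi2 with compound-symmetric covariance:
            # Sigma = diag(v_k) + v_ref * 11'; use Sherman-Morrison
            inv_diag = np.where(v[:, 1:] > 0, 1.0 / v[:, 1:], 0.0)
            u = (diff * inv_diag).sum(axis=1)
            quad = (diff**2 * inv_diag).sum(axis=1) - v[:, 0] * u**2 / (
                1.0 + v[:, 0] * inv_diag.sum(axis=1)
            )
            overall[rows] = quad
            need = need[~ok]
    if len(need):
        raise ValidationError(
            "bootstrap could not produce replicates with every batch level present"
        )
    s_coef = _truncated_z_to_resi(zs, n) if df_adjust else z_to_resi(zs, n)
    s_overall = chisq_to_resi(overall, g - 1, n)
    return s_coef, s_overall


def resi_bootstrap_ci(
    y,
    labels: BatchLabels,
    n_boot: int = 500,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
    cov_type: str = "HC3",
    df_adjust: bool = False,
):
    """Percentile bootstrap CI for the per-coefficient and overall RESI.

    Returns ``(ci_low, ci_high, overall_ci)`` where the first two are arrays
    over the g - 1 non-reference coefficients.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(y, dtype=float)
    codes = labels.codes
    g = labels.n_levels
    s_coef, s_overall = _boot_resi(y, codes, g, n_boot, rng, cov_type, df_adjust)
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(s_coef, [alpha, 100.0 - alpha], axis=0)
    olo, ohi = np.percentile(s_overall, [alpha, 100.0 - alpha])
    return lo, hi, (float(olo), float(ohi))


def resi_feature(
    y,
    labels: BatchLabels,
    n_boot: int = 500,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
    cov_type: str = "HC3",
    df_adjust: bool = False,
) -> ResiResult:
    """Point estimate plus bootstrap CI for one feature."""
    fit = fit_batch_model(y, labels, cov_type=cov_type)
    per_coef, overall = resi_point(fit, df_adjust=df_adjust)
    lo, hi, overall_ci = resi_bootstrap_ci(
        y, labels, n_boot=n_boot, level=level, rng=rng, cov_type=cov_type, df_adjust=df_adjust
    )
    return ResiResult(
        per_coefficient=np.atleast_1d(per_coef),
        overall=overall,
        ci_low=lo,
        ci_high=hi,
        overall_ci=overall_ci,
        n_boot=n_boot,
        coef_names=fit.coef_names,
    )


def resi_table(
    x: FeatureMatrix,
    labels: BatchLabels,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
    cov_type: str = "HC3",
    df_adjust: bool = False,
) -> pd.DataFrame:
    """Per-feature RESI table: one row per (feature, non-reference level).

    Features whose fit is degenerate are recorded with NaN estimates and a
    reason code rather than aborting the table.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for j, name in enumerate(x.feature_names):
        y = x.values[:, j]
        try:
            res = resi_feature(
                y, labels, n_boot=n_boot, level=level, rng=rng,
                cov_type=cov_type, df_adjust=df_adjust,
            )
        except DegenerateFitError as exc:
            for lev in labels.ordered_levels[1:]:
                rows.append(
                    dict(feature=name, batch_level=lev, resi=np.nan,
                         ci_low=np.nan, ci_high=np.nan, overall=np.nan,
                         overall_ci_low=np.nan, overall_ci_high=np.nan,
                         n_boot=n_boot, status=f"degenerate: {exc}")
                )
            continue
        for k, lev in enumerate(res.coef_names):
            rows.append(
                dict(feature=name, batch_level=lev,
                     resi=float(res.per_coefficient[k]),
                     ci_low=float(res.ci_low[k]), ci_high=float(res.ci_high[k]),
                     overall=res.overall,
                     overall_ci_low=res.overall_ci[0],
                     overall_ci_high=res.overall_ci[1],
                     n_boot=n_boot, status="ok")
            )
    return pd.DataFrame(rows)
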