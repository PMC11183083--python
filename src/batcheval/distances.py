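"""Pairwise sample-distance computation for the six PERMANOVA metrics.

Metrics follow the conventions of the vegan ``vegdist`` implementation:

* ``euclidean``   sqrt(sum_k (x_k - y_k)^2)
* ``chord``       Euclidean distance between the L2-normalised sample vectors
* ``clark``       sqrt((1/M') * sum_k ((x_k - y_k)/(x_k + y_k))^2), M' the
                  number of columns with x_k + y_k > 0 (= m on positive data)
* ``gower``       (1/M'') * sum_k |x_k - y_k| / R_k, with R_k the column range
                  over all n samples and M'' the number of columns with R_k > 0
* ``jaccard``     2B / (1 + B) with B the Bray-Curtis dissimilarity
                  sum_k |x_k - y_k| / sum_k (x_k + y_k)
* ``mahalanobis`` sqrt((x - y)^T S^-1 (x - y)), S the sample covariance of the
                  features over all n samples

Clark and Jaccard require strictly positive data; ``exp_transform`` maps an
arbitrary real matrix into that domain (and, by magnifying differences
between large values, tends to amplify location batch effects for those two
metrics).  ``compute_distance`` applies the transform per the chosen policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datamodel import FeatureMatrix, ValidationError


class DomainError(ValueError):
    """Input outside a metric's domain (e.g. nonpositive values for Clark)."""


class SingularCovarianceError(ValueError):
    """Feature covariance is singular; Mahalanobis distance is undefined."""


#: exp() of anything above this overflows a double
_EXP_OVERFLOW = 709.0

#: row-chunk size bounding memory of the vectorized pairwise loops
_CHUNK = 256


def exp_transform(x: FeatureMatrix) -> FeatureMatrix:
    """Elementwise exponential of the feature matrix (output strictly positive)."""
    v = x.values
    if np.abs(v).max() > _EXP_OVERFLOW:
        j = int(np.unravel_index(np.argmax(np.abs(v)), v.shape)[1])
        raise DomainError(
            f"exp_transform would overflow on feature {x.feature_names[j]!r} "
            f"(|value| > {_EXP_OVERFLOW:g})"
        )
    return FeatureMatrix(np.exp(v), x.sample_ids, x.feature_names)


def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)


def _require_positive(v: np.ndarray, metric: str):
    if v.min() <= 0:
        raise DomainError(
            f"{metric} distance requires strictly positive values; "
            "apply exp_transform first"
        )


def _euclidean(v: np.ndarray) -> np.ndarray:
    sq = (v * v).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (v @ v.T)
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2)


def _chord(v: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise DomainError("chord distance undefined for all-zero sample vectors")
    return _euclidean(v / norms[:, None])


def _clark(v: np.ndarray, normalized: bool = True) -> np.ndarray:
    _require_positive(v, "clark")
    n, m = v.shape
    out = np.zeros((n, n))
    for s in range(0, n, _CHUNK):
        blk = slice(s, min(s + _CHUNK, n))
        r = (v[blk, None, :] - v[None, :, :]) / (v[blk, None, :] + v[None, :, :])
        ssq = (r * r).sum(axis=2)
        out[blk] = np.sqrt(ssq / m) if normalized else np.sqrt(ssq)
    return out


def _gower(v: np.ndarray) -> np.ndarray:
    ranges = v.max(axis=0) - v.min(axis=0)
    keep = ranges > 0
    if not keep.any():
        raise DomainError("gower distance undefined: every column is constant")
    vk = v[:, keep] / ranges[keep]
    n = vk.shape[0]
    out = np.zeros((n, n))
    for s in range(0, n, _CHUNK):
        blk = slice(s, min(s + _CHUNK, n))
        out[blk] = np.abs(vk[blk, None, :] - vk[None, :, :]).mean(axis=2)
    return out


def _jaccard(v: np.ndarray) -> np.ndarray:
    _require_positive(v, "jaccard")
    rs = v.sum(axis=1)
    n = v.shape[0]
    out = np.zeros((n, n))
    for s in range(0, n, _CHUNK):
        blk = slice(s, min(s + _CHUNK, n))
        num = np.abs(v[blk, None, :] - v[None, :, :]).sum(axis=2)
        bray = num / (rs[blk][:, None] + rs[None, :])
        out[blk] = 2.0 * bray / (1.0 + bray)
    return out


def _mahalanobis(v: np.ndarray, cov: np.ndarray | None = None) -> np.ndarray:
    n, m = v.shape
    if cov is None:
        if n <= m:
            raise SingularCovarianceError(
                f"sample covariance of {m} features from {n} samples is singular"
            )
        cov = np.cov(v, rowvar=False)
    cov = np.atleast_2d(cov)
    # exactly collinear features leave near-zero eigenvalues that a Cholesky
    # factorization can slip past numerically; reject on conditioning instead
    eigvals = scipy.linalg.eigvalsh(cov)
    if eigvals[0] <= 0 or eigvals[0] < 1e-10 * eigvals[-1]:
        raise SingularCovarianceError(
            "singular covariance matrix: near-zero eigenvalue "
            f"(min {eigvals[0]:.3g}, max {eigvals[-1]:.3g})"
        )
    chol = scipy.linalg.cholesky(cov, lower=True)
    # whiten, then Euclidean distance is Mahalanobis distance
    white = scipy.linalg.solve_triangular(chol, v.T, lower=True).T
    return _euclidean(white)


METRICS = ("euclidean", "chord", "clark", "gower", "jaccard", "mahalanobis")
#: metrics whose formulas require strictly positive data
POSITIVE_METRICS = frozenset({"clark", "jaccard"})

_DISPATCH = {
    "euclidean": _euclidean,
    "chord": _chord,
    "clark": _clark,
    "gower": _gower,
    "jaccard": _jaccard,
    "mahalanobis": _mahalanobis,
}


@dataclass(frozen=True, eq=False)
class DistanceMatrix:
    """Symmetric non-negative n x n matrix tagged with its metric."""

    values: np.ndarray
    metric: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"distance matrix must be square, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValidationError("non-finite distances")
        if v.min() < 0:
            raise ValidationError("negative distances")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise ValidationError("nonzero diagonal")
        if np.abs(v - v.T).max() > 1e-10:
            raise ValidationError("asymmetric distance matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_distance(x, metric: str, **kwargs) -> DistanceMatrix:
    """Full pairwise distance matrix for one metric.

    ``x`` is a :class:`FeatureMatrix` or array; Clark/Jaccard expect the
    caller to have applied :func:`exp_transform` (or otherwise positive
    data).  ``_clark`` accepts ``normalized=False`` to drop the 1/M'
    constant; ``_mahalanobis`` accepts an explicit ``cov``.
    """
    if metric not in _DISPATCH:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    v = _as_values(x)
    if not np.isfinite(v).all():
        raise ValidationError("non-finite feature values")
    d = _DISPATCH[metric](v, **kwargs)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # kill floating-point asymmetry from chunked loops
    return DistanceMatrix(d, metric)


def compute_distance(
    x: FeatureMatrix, metric: str, transform: str = "required", **kwargs
) -> DistanceMatrix:
    """Distance with the exponential-transform policy applied.

    transform='required' exponentiates only for the positive-domain metrics
    (Clark, Jaccard); 'all' exponentiates for every metric; 'none' never does
    (and Clark/Jaccard then fail on nonpositive data).
    """
    if transform not in ("required", "all", "none"):
        raise ValueError("transform must be one of 'required', 'all', 'none'")
    if transform == "all" or (transform == "required" and metric in POSITIVE_METRICS):
        x = exp_transform(x)
    return pairwise_distance(x, metric, **kwargs)
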