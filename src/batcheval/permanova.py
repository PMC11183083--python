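"""Distance-based multivariate permutation test (PERMANOVA).

Given an n x n distance matrix D and a g-level grouping, the pseudo-F
statistic is

    F = [tr(H G H) / (g - 1)] / [tr((I - H) G (I - H)) / (n - g)]

where G is Gower's double-centered matrix of A = -1/2 D.^2 and H the hat
matrix of the one-hot group design.  The same quantity is computed here via
the equivalent sum-of-squared-distance identity

    SS_T = (1/n) sum_{i<j} d_ij^2,
    SS_W = sum_k (1/n_k) sum_{i<j in k} d_ij^2,   SS_B = SS_T - SS_W,

which costs O(n^2) per permutation and carries no matrix products, making
2000-permutation tests practical at n = 2500.  The trace form is retained as
an independent cross-check.  The permutation null relabels samples uniformly
at random and the p-value uses the add-one convention
p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations), so p is never exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .datamodel import BatchLabels, ValidationError
from .distances import DistanceMatrix

#: permutation batch size bounding the B x n indicator workspace
_PERM_CHUNK = 250


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    SS_B: float
    SS_R: float
    n_permutations: int
    metric: str
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PermanovaResult":
        return cls(**d)


def gower_center(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower's centered matrix G = C A C with A = -1/2 D.^2, C = I - 11'/n."""
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    a = -0.5 * d * d
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def hat_matrix(labels: BatchLabels) -> np.ndarray:
    """Projection onto the one-hot group design: H_ij = 1/n_k iff i, j share
    group k, else 0 (idempotent, symmetric, trace g)."""
    codes = labels.codes
    counts = np.bincount(codes).astype(float)
    same = codes[:, None] == codes[None, :]
    return np.where(same, 1.0 / counts[codes][None, :], 0.0)


def pseudo_f(G: np.ndarray, H: np.ndarray, n: int, g: int) -> tuple[float, float, float]:
    """Trace-form pseudo-F: returns (F, SS_B, SS_R)."""
    if not n > g >= 2:
        raise ValidationError(f"need n > g >= 2, got n={n}, g={g}")
    I = np.eye(n)
    ss_b = float(np.trace(H @ G @ H))
    R = I - H
    ss_r = float(np.trace(R @ G @ R))
    if ss_r <= 0:
        warnings.warn("zero within-group sum of squares; pseudo-F is infinite")
        return float("inf"), ss_b, ss_r
    f = (ss_b / (g - 1)) / (ss_r / (n - g))
    return f, ss_b, ss_r


def _group_sum_ss(d2: np.ndarray, codes: np.ndarray, g: int) -> tuple[float, float]:
    """(SS_T, SS_W) via the squared-distance group-sum identity."""
    n = d2.shape[0]
    ss_t = d2.sum() / (2.0 * n)
    ss_w = 0.0
    for k in range(g):
        idx = np.flatnonzero(codes == k)
        ss_w += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return float(ss_t), float(ss_w)


def _f_from_ssw(ss_t: float, ss_w, n: int, g: int):
    ss_b = ss_t - np.asarray(ss_w)
    with np.errstate(divide="ignore"):
        return np.where(
            np.asarray(ss_w) > 0,
            (ss_b / (g - 1)) / (np.asarray(ss_w) / (n - g)),
            np.inf,
        )


def permanova_test(
    D: DistanceMatrix,
    labels: BatchLabels,
    n_permutations: int = 2000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutation test of association between group membership and distances.

    Relabelings are uniform random permutations of the sample labels
    (equivalently simultaneous row/column permutations of D); group sizes are
    preserved by construction.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if D.n != len(labels):
        raise ValidationError("distance matrix and labels are not aligned")
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = labels.codes
    g = labels.n_levels
    n = D.n
    if not n > g:
        raise ValidationError(f"need n > g, got n={n}, g={g}")
    d2 = D.values * D.values
    ss_t, ss_w = _group_sum_ss(d2, codes, g)
    ss_b = ss_t - ss_w
    if ss_w <= 0:
        warnings.warn("zero within-group sum of squares; pseudo-F is infinite")
        f_obs = float("inf")
    else:
        f_obs = float(_f_from_ssw(ss_t, ss_w, n, g))

    counts = np.bincount(codes).astype(float)
    n_ge = 0
    done = 0
    while done < n_permutations:
        b = min(_PERM_CHUNK, n_permutations - done)
        perms = np.empty((b, n), dtype=np.intp)
        for i in range(b):
            perms[i] = rng.permutation(codes)
        ss_w_perm = np.zeros(b)
        for k in range(g):
            mask = (perms == k).astype(float)
            # sum of within-group squared distances: (m' D2 m)/2 per row
            ss_w_perm += np.einsum("bi,bi->b", mask @ d2, mask) / (2.0 * counts[k])
        f_perm = _f_from_ssw(ss_t, ss_w_perm, n, g)
        n_ge += int(np.sum(f_perm >= f_obs))
        done += b
    p = (1.0 + n_ge) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_F=f_obs,
        p_value=p,
        SS_B=ss_b,
        SS_R=ss_w,
        n_permutations=n_permutations,
        metric=D.metric,
        seed=seed,
    )
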