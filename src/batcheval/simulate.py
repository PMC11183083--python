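"""Synthetic radiomic-feature generator with location/scale batch effects.

Each simulated dataset consists of i.i.d. standard-normal residuals
``eps ~ N(0, 1)`` per (sample, feature).  When batch effects are requested,
samples are first assigned uniformly at random to one of ``n_groups``
batches, the residuals are multiplied by a per-batch scale effect
``delta ~ Uniform(0.8, 1.2)`` and then shifted by a per-batch location
effect ``gamma ~ Uniform(-2, 2)``:

    y = gamma[batch] + delta[batch] * eps

By default a single (gamma, delta) pair is drawn per batch and applied to
every feature of the dataset, so that an unlucky near-tie between the batch
locations attenuates all features of that dataset at once; independent
per-(batch, feature) draws are available via ``params_per_feature``.  The
no-batch arm simply returns the residuals (algebraically identical to
gamma = 0, delta = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .datamodel import BatchLabels, FeatureMatrix, ValidationError

_ASSIGNMENT_RETRIES = 100


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    Defaults are the two-batch design used throughout the power study:
    20 features, gamma ~ U(-2, 2), delta ~ U(0.8, 1.2), shared across
    features within a dataset.
    """

    n_samples: int
    add_batch: bool
    n_features: int = 20
    n_groups: int = 2
    gamma_range: tuple[float, float] = (-2.0, 2.0)
    delta_range: tuple[float, float] = (0.8, 1.2)
    params_per_feature: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 1 or self.n_groups < 2:
            raise ValidationError("need n_features >= 1 and n_groups >= 2")
        if self.n_samples < 2 * self.n_groups:
            raise ValidationError("need n_samples >= 2 * n_groups")
        lo, hi = self.delta_range
        if lo <= 0 or hi < lo:
            raise ValidationError("delta_range must be a positive interval")
        if self.gamma_range[1] < self.gamma_range[0]:
            raise ValidationError("gamma_range must be a valid interval")


@dataclass(frozen=True, eq=False)
class SimulatedDataset:
    """A simulated feature matrix, its batch labels, and ground truth."""

    features: FeatureMatrix
    labels: BatchLabels
    truth: bool
    params: dict = field(default_factory=dict)


def _assign_groups(n: int, g: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform i.i.d. assignment; redraw (bounded) if any group gets < 2 samples."""
    for _ in range(_ASSIGNMENT_RETRIES):
        codes = rng.integers(0, g, size=n)
        if np.all(np.bincount(codes, minlength=g) >= 2):
            return codes
    raise ValidationError(
        f"could not assign {n} samples to {g} groups with >=2 samples each"
    )


def simulate_dataset(config: SimConfig, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Draw one dataset under ``config``.

    Draw order is fixed (group assignment, residuals, then delta before
    gamma) so that a given seed always yields the same dataset.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, m, g = config.n_samples, config.n_features, config.n_groups
    codes = _assign_groups(n, g, rng)
    eps = rng.normal(size=(n, m))
    params: dict = {}
    if config.add_batch:
        shape = (g, m) if config.params_per_feature else (g,)
        delta = rng.uniform(*config.delta_range, size=shape)
        gamma = rng.uniform(*config.gamma_range, size=shape)
        if config.params_per_feature:
            values = gamma[codes, :] + delta[codes, :] * eps
        else:
            values = gamma[codes, None] + delta[codes, None] * eps
        params = {"gamma": gamma, "delta": delta}
    else:
        values = eps
    width = len(str(g - 1))
    labels = BatchLabels(tuple(f"batch{c:0{width}d}" for c in codes))
    features = FeatureMatrix(
        values,
        tuple(f"s{i:04d}" for i in range(n)),
        tuple(f"feature{j:02d}" for j in range(m)),
    )
    return SimulatedDataset(features, labels, truth=config.add_batch, params=params)


def iteration_rng(base_seed: int, k: int) -> np.random.Generator:
    """Independent, reproducible substream for iteration ``k``.

    Built from ``SeedSequence(base_seed, spawn_key=(k,))`` so that iteration
    k is reproducible from ``(base_seed, k)`` alone and iterations can run
    in any order or in parallel.
    """
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(k,)))


def simulate_study(
    config: SimConfig, n_iterations: int, base_seed: int | None = None
) -> Iterator[SimulatedDataset]:
    """Yield ``n_iterations`` independent datasets with per-iteration substreams."""
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    seed = config.seed if base_seed is None else base_seed
    for k in range(n_iterations):
        yield simulate_dataset(config, iteration_rng(seed, k))
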