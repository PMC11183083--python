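"""Orchestration: the power/Type-I simulation harness, dataset screening,
feature-level quantification, and pre/post-harmonization comparison.

The power study follows the simulation design exactly: for each sample size
and each arm (with/without batch effects) it simulates ``n_iterations``
datasets of 20 features, runs one PERMANOVA decision per (iteration,
metric) at the dataset level, one univariate-test decision per (iteration,
feature, test) at the feature level, and RESI point estimates (with
optional bootstrap CIs) per (iteration, feature).  All randomness derives
from per-iteration substreams of a single base seed, so results are
reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .combat import combat_fit_apply
from .comparators import test_suite
from .datamodel import BatchLabels, CovariateTable, FeatureMatrix, ValidationError
from .distances import METRICS, SingularCovarianceError, compute_distance
from .permanova import PermanovaResult, permanova_test
from .resi import DegenerateFitError, fit_batch_model, resi_point, resi_table
from .simulate import SimConfig, iteration_rng, simulate_dataset


@dataclass(frozen=True)
class PowerStudyConfig:
    """Settings for the power / Type-I-error experiment."""

    sample_sizes: tuple[int, ...] = (100, 1000, 2500)
    n_iterations: int = 250
    n_features: int = 20
    n_permutations: int = 2000
    n_boot: int = 500
    alpha: float = 0.05
    metrics: tuple[str, ...] = METRICS
    tests: tuple[str, ...] = ("wrs", "ks", "ad")
    arms: tuple[bool, ...] = (False, True)
    transform: str = "required"
    compute_resi: bool = True
    resi_ci: bool = True
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        for v in (self.n_iterations, self.n_features, self.n_permutations, self.n_boot):
            if v < 1:
                raise ValidationError("all counts must be positive")
        if self.scale <= 0:
            raise ValidationError("scale must be positive")

    def scaled(self) -> "PowerStudyConfig":
        """Apply the desk-scale factor to iteration/permutation/bootstrap counts."""
        if self.scale == 1.0:
            return self
        s = self.scale
        return replace(
            self,
            n_iterations=max(1, round(self.n_iterations / s)),
            n_permutations=max(1, round(self.n_permutations / s)),
            n_boot=max(2, round(self.n_boot / s)),
            scale=1.0,
        )


@dataclass(frozen=True, eq=False)
class PowerSummary:
    """Aggregated study results.

    ``dataset_level``: per (metric, n, arm) PERMANOVA rejection rate with
    Monte-Carlo SE.  ``feature_level``: per (test, n, arm) univariate
    rejection rate (pooled over features, SE on the iteration scale since
    features within an iteration share batch parameters).  ``resi_summary``:
    per (arm, n) mean |RESI| point estimate and mean CI width.
    """

    dataset_level: pd.DataFrame
    feature_level: pd.DataFrame
    resi_summary: pd.DataFrame
    config: PowerStudyConfig
    failures: dict = field(default_factory=dict)


def _binom_se(rate: float, reps: int) -> float:
    return float(np.sqrt(rate * (1.0 - rate) / reps)) if reps else float("nan")


def run_power_study(config: PowerStudyConfig) -> PowerSummary:
    """Run the full simulation experiment described by ``config``."""
    cfg = config.scaled()
    ds_rows, ft_rows, resi_rows = [], [], []
    failures: dict[str, int] = {}
    for add_batch in cfg.arms:
        arm = "+Batch" if add_batch else "-Batch"
        for n in cfg.sample_sizes:
            sim = SimConfig(n_samples=n, add_batch=add_batch, n_features=cfg.n_features)
            ds_rej = {m: [] for m in cfg.metrics}
            ft_rej = {t: [] for t in cfg.tests}
            abs_points, ci_widths = [], []
            # distinct substream per (arm, n, iteration)
            base = (cfg.seed, int(add_batch), n)
            for k in range(cfg.n_iterations):
                rng = np.random.default_rng(np.random.SeedSequence(base + (k,)))
                data = simulate_dataset(sim, rng)
                for metric in cfg.metrics:
                    try:
                        D = compute_distance(data.features, metric, transform=cfg.transform)
                        res = permanova_test(D, data.labels, cfg.n_permutations, rng=rng)
                        ds_rej[metric].append(res.p_value < cfg.alpha)
                    except SingularCovarianceError:
                        failures[f"{metric}:singular"] = failures.get(f"{metric}:singular", 0) + 1
                if cfg.tests:
                    table = test_suite(data.features, data.labels, cfg.tests, cfg.alpha)
                    ok = table[table.status == "ok"]
                    for t in cfg.tests:
                        sub = ok[ok.test == t]
                        if len(sub):
                            ft_rej[t].append(sub.reject.to_numpy())
                if cfg.compute_resi:
                    pts, widths = _resi_iteration(
                        data.features, data.labels, cfg.n_boot if cfg.resi_ci else 0, rng
                    )
                    abs_points.append(pts)
                    if widths is not None:
                        ci_widths.append(widths)
            for metric in cfg.metrics:
                rej = ds_rej[metric]
                if not rej:
                    continue
                rate = float(np.mean(rej))
                ds_rows.append(
                    dict(method=f"permanova_{metric}", n=n, arm=arm,
                         rate=rate, se=_binom_se(rate, len(rej)), reps=len(rej))
                )
            for t in cfg.tests:
                if not ft_rej[t]:
                    continue
                per_iter = [r.mean() for r in ft_rej[t]]
                pooled = float(np.concatenate(ft_rej[t]).mean())
                ft_rows.append(
                    dict(test=t, n=n, arm=arm, rate=pooled,
                         rate_iteration_mean=float(np.mean(per_iter)),
                         se=float(np.std(per_iter, ddof=1) / np.sqrt(len(per_iter)))
                         if len(per_iter) > 1 else float("nan"),
                         reps=len(per_iter)))
            if cfg.compute_resi and abs_points:
                allpts = np.concatenate(abs_points)
                row = dict(arm=arm, n=n,
                           mean_abs_point=float(np.mean(allpts)),
                           sd_point=float(np.std(allpts, ddof=1)),
                           reps=len(abs_points))
                if ci_widths:
                    row["mean_ci_width"] = float(np.mean(np.concatenate(ci_widths)))
                resi_rows.append(row)
    return PowerSummary(
        dataset_level=pd.DataFrame(ds_rows),
        feature_level=pd.DataFrame(ft_rows),
        resi_summary=pd.DataFrame(resi_rows),
        config=config,
        failures=failures,
    )


def _resi_iteration(features: FeatureMatrix, labels: BatchLabels, n_boot: int, rng):
    """|RESI| point estimates (and CI widths when n_boot > 0) for one dataset."""
    from .resi import resi_bootstrap_ci

    pts = np.empty(features.n_features)
    widths = np.empty(features.n_features) if n_boot else None
    for j in range(features.n_features):
        y = features.values[:, j]
        fit = fit_batch_model(y, labels)
        per_coef, _ = resi_point(fit)
        pts[j] = np.abs(per_coef).mean()
        if n_boot:
            lo, hi, _ = resi_bootstrap_ci(y, labels, n_boot=n_boot, rng=rng)
            widths[j] = float(np.mean(hi - lo))
    return pts, widths


def screen_dataset(
    x: FeatureMatrix,
    labels: BatchLabels,
    metrics: tuple[str, ...] = METRICS,
    n_permutations: int = 2000,
    rng: np.random.Generator | None = None,
    transform: str = "required",
    alpha: float = 0.05,
) -> dict[str, PermanovaResult | str]:
    """Dataset-level PERMANOVA screen across metrics.

    A metric whose distance fails (e.g. singular covariance for Mahalanobis)
    is reported as an error string, not raised; only all metrics failing is
    an error.
    """
    if rng is None:
        rng = np.random.default_rng()
    out: dict[str, PermanovaResult | str] = {}
    n_ok = 0
    for metric in metrics:
        try:
            D = compute_distance(x, metric, transform=transform)
            out[metric] = permanova_test(D, labels, n_permutations, rng=rng)
            n_ok += 1
        except (SingularCovarianceError, ValidationError) as exc:
            out[metric] = f"failed: {exc}"
    if n_ok == 0:
        raise ValidationError("every requested metric failed")
    return out


def quantify_dataset(
    x: FeatureMatrix,
    labels: BatchLabels,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Feature-level RESI table plus a summary.

    The summary reports the mean |RESI|, per-batch-level mean signed RESI,
    and the features ranked by |RESI| (largest first).
    """
    table = resi_table(x, labels, n_boot=n_boot, rng=rng)
    ok = table[table.status == "ok"]
    per_level = ok.groupby("batch_level")["resi"].mean().to_dict()
    by_feature = ok.groupby("feature")["resi"].apply(lambda s: s.abs().mean())
    summary = dict(
        mean_abs_resi=float(ok.resi.abs().mean()) if len(ok) else float("nan"),
        per_level_mean=per_level,
        ranked_features=list(by_feature.sort_values(ascending=False).index),
        n_degenerate=int((table.status != "ok").sum() // max(1, labels.n_levels - 1)),
    )
    return table, summary


def compare_harmonization(
    x: FeatureMatrix,
    labels: BatchLabels,
    covariates: CovariateTable | None = None,
    metrics: tuple[str, ...] = METRICS,
    n_permutations: int = 2000,
    n_boot: int = 500,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> dict:
    """Run screen + quantify + AD testing before and after ComBat.

    Returns a report with both arms' full tables, per-feature RESI deltas,
    and the AD rejection fractions pre/post.
    """
    if rng is None:
        rng = np.random.default_rng()
    harmonized, model = combat_fit_apply(x, labels, covariates)
    report: dict = {"model": model}
    for arm_name, data in (("pre", x), ("post", harmonized)):
        perm = screen_dataset(data, labels, metrics, n_permutations, rng=rng)
        resi_tab, resi_sum = quantify_dataset(data, labels, n_boot=n_boot, rng=rng)
        ad = test_suite(data, labels, tests=("ad",), alpha=alpha)
        report[arm_name] = dict(
            permanova=perm,
            resi_table=resi_tab,
            resi_summary=resi_sum,
            ad_table=ad,
            ad_rejection_rate=float(ad[ad.status == "ok"].reject.mean()),
        )
    pre_t, post_t = report["pre"]["resi_table"], report["post"]["resi_table"]
    merged = pre_t.merge(
        post_t, on=["feature", "batch_level"], suffixes=("_pre", "_post")
    )
    merged["delta_abs_resi"] = merged.resi_post.abs() - merged.resi_pre.abs()
    report["delta"] = merged[["feature", "batch_level", "resi_pre", "resi_post", "delta_abs_resi"]]
    report["mean_abs_resi_pre"] = report["pre"]["resi_summary"]["mean_abs_resi"]
    report["mean_abs_resi_post"] = report["post"]["resi_summary"]["mean_abs_resi"]
    return report
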