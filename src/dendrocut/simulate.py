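"""Synthetic Gaussian cluster generator and Monte-Carlo evaluation harness.

The generator draws up to four bivariate normal clusters of equal size
whose centers sit at the corners (±m/2, ±m/2) of a square of side m
(default separation 6, i.e. centers (±3, ±3)), with per-cluster covariance
scale_r * I.  When fewer than four clusters are requested the centers are
taken in the fixed order (-3,-3), (3,3), (-3,3), (3,-3).

The harness repeatedly generates data, applies a set of estimators
(optionally wrapped in mixing or leave-one-out consensus) and summarises
each method by its mean estimate, success rate S (fraction of runs with
k_hat equal to the true k) and error size E (mean |k - k_hat| over the
wrong runs only; 0 when no run is wrong).  All methods see identical data
within a run, so comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DendrocutError, InputError
from .estimators import (
    METHODS,
    GapParams,
    ModeParams,
    estimate_k,
)
from .hca import DataMatrix, compute_linkage, pairwise_distances
from .resampling import (
    MixingParams,
    aggregate_replicates,
    draw_subsets,
    loocv_subsets,
    replicate_estimates,
)

# corner pattern scaled by separation/2; order matters when k_true < 4
_CENTER_PATTERN = np.array([(-1.0, -1.0), (1.0, 1.0), (-1.0, 1.0), (1.0, -1.0)])


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth configuration of one synthetic clustering problem."""

    k_true: int = 4
    points_per_cluster: int = 100
    dim: int = 2
    separation: float = 6.0
    covariance_scales: tuple[float, ...] | None = None
    centers: np.ndarray | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise InputError("k_true must be >= 1")
        if self.points_per_cluster < 1:
            raise InputError("points_per_cluster must be >= 1")
        if self.separation <= 0:
            raise InputError("separation must be positive")
        scales = self.covariance_scales
        if scales is not None:
            scales = tuple(float(s) for s in scales)
            if len(scales) != self.k_true:
                raise InputError("need one covariance scale per cluster")
            if any(s <= 0 for s in scales):
                raise InputError("covariance scales must be positive")
            object.__setattr__(self, "covariance_scales", scales)
        if self.centers is not None:
            centers = np.asarray(self.centers, dtype=float)
            if centers.shape != (self.k_true, self.dim):
                raise InputError("centers must have shape (k_true, dim)")
            object.__setattr__(self, "centers", centers)
        elif self.k_true > 4:
            raise InputError("default corner centers support at most 4 clusters")
        elif self.dim != 2 and self.k_true > 2:
            raise InputError("default centers for k_true > 2 require dim=2")

    def resolve_centers(self) -> np.ndarray:
        if self.centers is not None:
            return self.centers
        half = self.separation / 2.0
        if self.dim == 2:
            return _CENTER_PATTERN[: self.k_true] * half
        # 1-D or higher-dim fallback: all-minus then all-plus corners
        signs = np.array([[-1.0], [1.0]])[: self.k_true]
        return np.tile(signs, (1, self.dim)) * half

    def resolve_scales(self) -> tuple[float, ...]:
        if self.covariance_scales is None:
            return (1.0,) * self.k_true
        return self.covariance_scales

    @property
    def n_points(self) -> int:
        return self.k_true * self.points_per_cluster


def generate_clusters(scenario: SimulationScenario,
                      rng: np.random.Generator | None = None) -> DataMatrix:
    """Draw one synthetic dataset; deterministic given the seed or rng."""
    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed)
    centers = scenario.resolve_centers()
    scales = scenario.resolve_scales()
    blocks = []
    for center, scale in zip(centers, scales):
        cov = scale * np.identity(scenario.dim)
        blocks.append(
            rng.multivariate_normal(center, cov,
                                    size=scenario.points_per_cluster)
        )
    return DataMatrix(np.concatenate(blocks, axis=0))


def success_rate(estimates: Sequence[int], k_true: int) -> float:
    """Fraction of estimates equal to the true cluster count."""
    est = np.asarray(estimates)
    if est.size == 0:
        raise InputError("no estimates supplied")
    return float(np.mean(est == k_true))


def error_size(estimates: Sequence[int], k_true: int) -> float:
    """Mean |k - k_hat| over the incorrect estimates only (0 if none wrong)."""
    est = np.asarray(estimates)
    if est.size == 0:
        raise InputError("no estimates supplied")
    wrong = np.abs(est[est != k_true] - k_true)
    return float(wrong.mean()) if wrong.size else 0.0


@dataclass(frozen=True)
class ExperimentConfig:
    """A Monte-Carlo experiment: scenario × methods × number of runs."""

    scenario: SimulationScenario = field(default_factory=SimulationScenario)
    n_runs: int = 200
    methods: tuple[str, ...] = METHODS
    mixing: MixingParams | None = None
    loocv: bool = False
    mode_params: ModeParams = field(default_factory=ModeParams)
    gap_params: GapParams = field(default_factory=GapParams)
    master_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise InputError("n_runs must be >= 1")
        for m in self.methods:
            if m not in METHODS:
                raise InputError(f"unknown method {m!r}")
        if self.mixing is not None and self.loocv:
            raise InputError("choose either mixing or leave-one-out, not both")


@dataclass(frozen=True)
class EvaluationSummary:
    """Per-method Monte-Carlo summary."""

    method: str
    mean_k_hat: float
    success: float
    error_size: float
    n_wrong: int
    n_runs: int
    n_failed: int = 0


def _run_once(X: DataMatrix, config: ExperimentConfig,
              rng: np.random.Generator) -> dict[str, int | None]:
    """Estimates of every configured method on one dataset."""
    out: dict[str, int | None] = {}
    resampled = config.mixing is not None or config.loocv
    if not resampled:
        merges = compute_linkage(X)
        for method in config.methods:
            try:
                out[method] = estimate_k(
                    X, method, merges=merges,
                    mode_params=config.mode_params,
                    gap_params=config.gap_params, rng=rng,
                ).k_hat
            except DendrocutError:
                out[method] = None
        return out
    distances = pairwise_distances(X)
    if config.loocv:
        subsets = loocv_subsets(X.n_points)
    else:
        m = config.mixing.resolve_m(X.n_points)
        subsets = draw_subsets(X.n_points, m, config.mixing.L, rng)
    counts = replicate_estimates(
        X, subsets, config.methods, mode_params=config.mode_params,
        gap_params=config.gap_params, rng=rng, distances=distances,
    )
    for method in config.methods:
        try:
            out[method] = aggregate_replicates(method, counts[method]).k_hat
        except DendrocutError:
            out[method] = None
    return out


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Monte-Carlo evaluation of the configured methods.

    Returns a tidy table with one row per method: mean k_hat, success rate,
    error size, number of wrong runs, runs evaluated and runs on which the
    method failed outright.  Reproducible given ``master_seed``: one master
    seed spawns an independent substream per run, and every method sees the
    same data within a run.
    """
    seed_seq = np.random.SeedSequence(config.master_seed)
    per_method: dict[str, list[int]] = {m: [] for m in config.methods}
    failures = {m: 0 for m in config.methods}
    for child in seed_seq.spawn(config.n_runs):
        rng = np.random.default_rng(child)
        X = generate_clusters(config.scenario, rng=rng)
        result = _run_once(X, config, rng)
        for method, k_hat in result.items():
            if k_hat is None:
                failures[method] += 1
            else:
                per_method[method].append(k_hat)
    rows = []
    for method in config.methods:
        est = per_method[method]
        if not est:
            raise DendrocutError(f"{method} failed on every run")
        k = config.scenario.k_true
        rows.append(EvaluationSummary(
            method=method,
            mean_k_hat=float(np.mean(est)),
            success=success_rate(est, k),
            error_size=error_size(est, k),
            n_wrong=int(np.sum(np.asarray(est) != k)),
            n_runs=len(est),
            n_failed=failures[method],
        ))
    frame = pd.DataFrame([vars(r) for r in rows])
    frame.insert(0, "k_true", config.scenario.k_true)
    frame.insert(1, "separation", config.scenario.separation)
    return frame


def separation_sweep(m_values: Sequence[float],
                     config: ExperimentConfig) -> pd.DataFrame:
    """Run the experiment at each cluster separation; long-format table."""
    if len(m_values) == 0:
        raise InputError("no separation values supplied")
    if any(m <= 0 for m in m_values):
        raise InputError("separations must be positive")
    tables = []
    for m in m_values:
        scenario = replace(config.scenario, separation=float(m))
        tables.append(run_experiment(replace(config, scenario=scenario)))
    return pd.concat(tables, ignore_index=True)
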