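"""Subsampling consensus for cluster-number estimation.

Two schemes are provided on top of any base estimator:

* **mixing** — draw L random subsamples of M rows without replacement
  (defaults M = floor(N/2), L = 100), estimate the cluster count on each,
  and report the mode of the L estimates;
* **leave-one-out** — the same idea with each observation removed once
  (L = N replicates of size N - 1).

A replicate on which the base estimator fails (e.g. too few merges) is
skipped and counted; if more than half of the replicates fail the whole
procedure errors out.  Ties in the mode are broken toward the smallest
cluster count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import squareform

from .errors import InputError, InsufficientMergesError, ResamplingError
from .estimators import (
    METHODS,
    ClusterCountEstimate,
    GapParams,
    ModeParams,
    elbow_estimate,
    gap_estimate,
    gap_profile,
    maxdiff_estimate,
    mode_estimate,
)
from .hca import DataMatrix, linkage_from_distances, pairwise_distances


@dataclass(frozen=True)
class MixingParams:
    """Subsample size M, replicate count L and seed of the mixing scheme."""

    M: int | None = None  # None -> floor(N/2)
    L: int = 100
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.M is not None and self.M < 2:
            raise InputError("subsample size M must be >= 2")
        if self.L < 1:
            raise InputError("replicate count L must be >= 1")

    def resolve_m(self, n_points: int) -> int:
        m = n_points // 2 if self.M is None else self.M
        if m > n_points:
            raise InputError(f"M={m} exceeds the number of observations {n_points}")
        return m


def mode_of_counts(counts: Sequence[int]) -> int:
    """Most frequent value; ties broken toward the smallest value."""
    if len(counts) == 0:
        raise InputError("cannot take the mode of an empty sequence")
    tally = Counter(int(c) for c in counts)
    best = max(tally.values())
    return min(k for k, v in tally.items() if v == best)


def _apply_merge_estimator(method: str, merges, mode_params: ModeParams) -> int:
    if method == "elbow":
        return elbow_estimate(merges).k_hat
    if method == "maxdiff":
        return maxdiff_estimate(merges).k_hat
    return mode_estimate(merges, mode_params).k_hat


def replicate_estimates(data: DataMatrix,
                        subsets: Iterable[np.ndarray],
                        methods: Sequence[str],
                        mode_params: ModeParams = ModeParams(),
                        gap_params: GapParams = GapParams(),
                        rng: np.random.Generator | None = None,
                        distances: np.ndarray | None = None,
                        ) -> dict[str, list[int | None]]:
    """Run estimators on row subsets, sharing one linkage per replicate.

    Returns, per method, the replicate cluster counts (None where the
    estimator failed on that replicate).  The full pairwise distance matrix
    is computed once and sliced per subset.
    """
    for method in methods:
        if method not in METHODS:
            raise InputError(f"unknown method {method!r}")
    if distances is None:
        distances = pairwise_distances(data)
    needs_gap = "gap" in methods
    if needs_gap and rng is None:
        rng = np.random.default_rng()
    results: dict[str, list[int | None]] = {m: [] for m in methods}
    for idx in subsets:
        idx = np.asarray(idx)
        sub = distances[np.ix_(idx, idx)]
        condensed = squareform(sub, checks=False)
        try:
            merges = linkage_from_distances(condensed, n_points=idx.size)
        except InputError:
            merges = None
        for method in methods:
            if method == "gap":
                try:
                    sub_data = DataMatrix(data.values[idx])
                    profile = gap_profile(sub_data, gap_params, rng=rng)
                    results[method].append(gap_estimate(profile).k_hat)
                except InputError:
                    results[method].append(None)
                continue
            if merges is None:
                results[method].append(None)
                continue
            try:
                results[method].append(
                    _apply_merge_estimator(method, merges, mode_params)
                )
            except InsufficientMergesError:
                results[method].append(None)
    return results


def aggregate_replicates(method: str,
                         counts: Sequence[int | None],
                         extra_diag: dict | None = None) -> ClusterCountEstimate:
    """Mode-aggregate replicate counts into a consensus estimate."""
    ok = [c for c in counts if c is not None]
    n_failed = len(counts) - len(ok)
    if len(ok) < len(counts) / 2 or not ok:
        raise ResamplingError(
            f"{method}: {n_failed}/{len(counts)} replicates failed"
        )
    diagnostics = {
        "replicate_counts": [int(c) if c is not None else None for c in counts],
        "replicate_histogram": dict(sorted(Counter(ok).items())),
        "n_replicates": len(counts),
        "n_failed": n_failed,
    }
    if extra_diag:
        diagnostics.update(extra_diag)
    return ClusterCountEstimate(
        k_hat=mode_of_counts(ok), method=method, diagnostics=diagnostics
    )


def draw_subsets(n_points: int, m: int, L: int,
                 rng: np.random.Generator) -> list[np.ndarray]:
    """L sorted index subsets of size m, each drawn without replacement."""
    return [np.sort(rng.choice(n_points, size=m, replace=False))
            for _ in range(L)]


def mixed_estimate(data: DataMatrix,
                   method: str,
                   mix: MixingParams = MixingParams(),
                   mode_params: ModeParams = ModeParams(),
                   gap_params: GapParams = GapParams(),
                   rng: np.random.Generator | None = None,
                   distances: np.ndarray | None = None) -> ClusterCountEstimate:
    """Consensus estimate over L random half-samples (the mixing scheme)."""
    if rng is None:
        rng = np.random.default_rng(mix.rng_seed)
    m = mix.resolve_m(data.n_points)
    subsets = draw_subsets(data.n_points, m, mix.L, rng)
    counts = replicate_estimates(
        data, subsets, [method], mode_params=mode_params,
        gap_params=gap_params, rng=rng, distances=distances,
    )[method]
    return aggregate_replicates(method, counts, {"M": m, "L": mix.L})


def loocv_subsets(n_points: int) -> list[np.ndarray]:
    """The N leave-one-out index subsets, in order of the removed point."""
    all_idx = np.arange(n_points)
    return [np.delete(all_idx, i) for i in range(n_points)]


def loocv_estimate(data: DataMatrix,
                   method: str,
                   mode_params: ModeParams = ModeParams(),
                   gap_params: GapParams = GapParams(),
                   rng: np.random.Generator | None = None,
                   distances: np.ndarray | None = None) -> ClusterCountEstimate:
    """Consensus estimate with each observation left out once."""
    if data.n_points < 3:
        raise InputError("leave-one-out needs at least 3 observations")
    counts = replicate_estimates(
        data, loocv_subsets(data.n_points), [method],
        mode_params=mode_params, gap_params=gap_params, rng=rng,
        distances=distances,
    )[method]
    return aggregate_replicates(method, counts, {"M": data.n_points - 1,
                                                 "L": data.n_points})
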