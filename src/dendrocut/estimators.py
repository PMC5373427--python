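"""Automated cluster-number estimators for a dendrogram.

Four rules are implemented, all operating on an average-linkage Euclidean
hierarchy of N points with merge heights d_1 <= ... <= d_m (m = N - 1):

``elbow``
    The acceleration (second difference) of merge-height growth,
    a_i = d_i - 2 d_{i-1} + d_{i-2}; the estimate is the number of clusters
    present just before the merge with the largest acceleration,
    k = m + 2 - argmax_i a_i.  Never returns 1 or N.
``maxdiff``
    The first difference (jump) d_i - d_{i-1}; k = m + 2 - argmax.  Never
    returns 1, but handles singleton clusters.
``mode``
    A height threshold D_hat + alpha * sigma_D, where D_hat is the modal
    merge height (histogram mode) and sigma_D the sample standard deviation
    of the heights; the estimate is the cluster count at that cut.  Can
    return 1.
``gap``
    The gap statistic: Gap(k) = E*[log W_k] - log W_k, comparing the
    within-cluster dispersion W_k of the data against its expectation under
    B uniform reference datasets drawn over the observed per-feature
    ranges; the estimate is the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1}.  Can return 1.

Argmax and modal-bin ties are broken toward the smallest index, making every
estimator deterministic; on continuous data ties are measure-zero events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.cluster.hierarchy import cut_tree
from scipy.spatial.distance import pdist, squareform

from .errors import InputError, InsufficientMergesError
from .hca import (
    ClusterAssignment,
    DataMatrix,
    MergeSequence,
    compute_linkage,
    cut_at_height,
)

METHODS = ("elbow", "maxdiff", "mode", "gap")

#: Methods that need only the merge heights (no raw coordinates).
MERGE_BASED_METHODS = ("elbow", "maxdiff", "mode")


@dataclass(frozen=True)
class ClusterCountEstimate:
    """An estimated number of clusters with method-specific diagnostics."""

    k_hat: int
    method: str
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_hat < 1:
            raise InputError("k_hat must be >= 1")


@dataclass(frozen=True)
class ModeParams:
    """Parameters of the mode (modal merge height) rule.

    alpha scales how far above the modal jump size the cut threshold sits;
    the default of 3 treats jumps more than three height-standard-deviations
    above the typical jump as cluster boundaries.
    """

    alpha: float = 3.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha) or self.alpha < 0:
            raise InputError("alpha must be finite and >= 0")


@dataclass(frozen=True)
class GapParams:
    """Parameters of the gap statistic.

    k_max is the largest candidate cluster count examined; n_reference is
    the number B of uniform reference datasets used to estimate
    E*[log W_k] and its standard error.
    """

    k_max: int = 10
    n_reference: int = 50
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise InputError("k_max must be >= 1")
        if self.n_reference < 2:
            raise InputError("need at least 2 reference datasets")


@dataclass(frozen=True)
class GapProfile:
    """Per-k gap-statistic curves for k = 1..k_max."""

    log_wk: np.ndarray
    expected_log_wk: np.ndarray
    gap: np.ndarray
    s_k: np.ndarray

    def __post_init__(self) -> None:
        arrays = (self.log_wk, self.expected_log_wk, self.gap, self.s_k)
        lengths = {np.asarray(a).shape for a in arrays}
        if len(lengths) != 1:
            raise InputError("profile arrays must have equal length")
        if np.any(np.asarray(self.s_k) < 0):
            raise InputError("s_k must be non-negative")

    @property
    def k_max(self) -> int:
        return len(np.asarray(self.gap))


def _require_merges(merges: MergeSequence, minimum: int, method: str) -> np.ndarray:
    heights = merges.heights
    if len(heights) < minimum:
        raise InsufficientMergesError(
            f"{method} needs at least {minimum} merges, got {len(heights)}"
        )
    return heights


def elbow_estimate(merges: MergeSequence) -> ClusterCountEstimate:
    """Cluster count from the largest acceleration of merge-height growth."""
    d = _require_merges(merges, 3, "elbow")
    m = len(d)
    accel = d[2:] - 2.0 * d[1:-1] + d[:-2]  # a_i for i = 3..m (1-based)
    i_star = int(np.argmax(accel)) + 3
    k_hat = m + 2 - i_star
    return ClusterCountEstimate(
        k_hat=k_hat,
        method="elbow",
        diagnostics={"argmax_index": i_star, "max_acceleration": float(accel[i_star - 3])},
    )


def maxdiff_estimate(merges: MergeSequence) -> ClusterCountEstimate:
    """Cluster count from the largest jump between consecutive merge heights."""
    d = _require_merges(merges, 2, "maxdiff")
    m = len(d)
    diffs = np.diff(d)  # jump at i = 2..m (1-based)
    i_star = int(np.argmax(diffs)) + 2
    k_hat = m + 2 - i_star
    return ClusterCountEstimate(
        k_hat=k_hat,
        method="maxdiff",
        diagnostics={"argmax_index": i_star, "max_difference": float(diffs[i_star - 2])},
    )


def _histogram_mode(values: np.ndarray) -> float:
    """Modal value of a continuous sample: midpoint of the fullest of
    ceil(sqrt(m)) equal-width bins, ties going to the lowest bin."""
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    n_bins = math.ceil(math.sqrt(len(values)))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    b = int(np.argmax(counts))
    return float((edges[b] + edges[b + 1]) / 2.0)


def mode_estimate(merges: MergeSequence,
                  params: ModeParams = ModeParams()) -> ClusterCountEstimate:
    """Cluster count at the height threshold D_hat + alpha * sigma_D."""
    d = _require_merges(merges, 2, "mode")
    d_hat = _histogram_mode(d)
    sigma = float(np.std(d, ddof=1))
    threshold = d_hat + params.alpha * sigma
    assignment = cut_at_height(merges, threshold)
    return ClusterCountEstimate(
        k_hat=assignment.k,
        method="mode",
        diagnostics={
            "mode_height": d_hat,
            "sigma": sigma,
            "threshold": threshold,
            "alpha": params.alpha,
        },
    )


def within_cluster_dispersion(data: DataMatrix,
                              assignment: ClusterAssignment) -> float:
    """Size-normalised within-cluster dispersion W_k.

    W_k = sum_r (1 / (2 n_r)) * sum_{i, i' in C_r} d_{ii'}, with the inner
    sum over ordered pairs (each unordered pair counted twice) and d the
    Euclidean distance.
    """
    if assignment.n_points != data.n_points:
        raise InputError("assignment does not match data")
    dmat = squareform(pdist(data.values))
    return _dispersion_from_distances(dmat, assignment.labels, assignment.k)


def _dispersion_from_distances(dmat: np.ndarray, labels: np.ndarray,
                               k: int) -> float:
    total = 0.0
    for r in range(1, k + 1):
        idx = np.flatnonzero(labels == r)
        if idx.size == 0:
            raise InputError(f"cluster {r} is empty")
        total += dmat[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return total


def _log_dispersion_profile(values: np.ndarray, k_max: int) -> np.ndarray:
    """log W_k for k = 1..k_max of an average-linkage hierarchy of `values`."""
    n = values.shape[0]
    merges = compute_linkage(DataMatrix(values))
    cuts = cut_tree(merges.linkage_matrix, n_clusters=list(range(1, k_max + 1)))
    dmat = squareform(pdist(values))
    out = np.empty(k_max)
    for j in range(k_max):
        labels = cuts[:, j]
        total = 0.0
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            total += dmat[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
        # W_k > 0 almost surely for continuous data; guard the degenerate case
        out[j] = math.log(total) if total > 0 else -math.inf
    return out


def gap_profile(data: DataMatrix,
                params: GapParams = GapParams(),
                rng: np.random.Generator | None = None) -> GapProfile:
    """Gap-statistic curves of a data matrix.

    For each candidate k the data are clustered (average linkage, cut to k)
    to give log W_k; B reference datasets, uniform over the observed range
    of each feature, are clustered identically to give E*[log W_k] and the
    standard error s_k = sd * sqrt(1 + 1/B).  Deterministic given the seed.
    """
    if params.k_max >= data.n_points:
        raise InputError("k_max must be smaller than the number of observations")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    log_wk = _log_dispersion_profile(data.values, params.k_max)
    lo = data.values.min(axis=0)
    hi = data.values.max(axis=0)
    B = params.n_reference
    ref = np.empty((B, params.k_max))
    for b in range(B):
        sample = rng.uniform(lo, hi, size=data.values.shape)
        ref[b] = _log_dispersion_profile(sample, params.k_max)
    expected = ref.mean(axis=0)
    s_k = ref.std(axis=0, ddof=1) * math.sqrt(1.0 + 1.0 / B)
    return GapProfile(
        log_wk=log_wk,
        expected_log_wk=expected,
        gap=expected - log_wk,
        s_k=s_k,
    )


def gap_estimate(profile: GapProfile) -> ClusterCountEstimate:
    """Smallest k with Gap(k) >= Gap(k+1) - s_{k+1}.

    If no k below k_max satisfies the rule, k_max is returned with a
    ``no_elbow`` diagnostic flag set.
    """
    gap = np.asarray(profile.gap)
    s = np.asarray(profile.s_k)
    if len(gap) < 2:
        raise InputError("gap profile must cover at least 2 values of k")
    no_elbow = True
    k_hat = len(gap)
    for k in range(1, len(gap)):
        if gap[k - 1] >= gap[k] - s[k]:
            k_hat = k
            no_elbow = False
            break
    return ClusterCountEstimate(
        k_hat=k_hat,
        method="gap",
        diagnostics={
            "no_elbow": no_elbow,
            "gap": gap.tolist(),
            "s_k": s.tolist(),
        },
    )


def estimate_k(data: DataMatrix,
               method: str,
               merges: MergeSequence | None = None,
               mode_params: ModeParams = ModeParams(),
               gap_params: GapParams = GapParams(),
               rng: np.random.Generator | None = None) -> ClusterCountEstimate:
    """Apply one named estimator to a data matrix.

    A precomputed :class:`MergeSequence` may be passed to avoid repeating
    the linkage computation; the gap statistic additionally needs the raw
    coordinates to build its reference distribution.
    """
    if method not in METHODS:
        raise InputError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "gap":
        profile = gap_profile(data, gap_params, rng=rng)
        return gap_estimate(profile)
    if merges is None:
        merges = compute_linkage(data)
    if method == "elbow":
        return elbow_estimate(merges)
    if method == "maxdiff":
        return maxdiff_estimate(merges)
    return mode_estimate(merges, mode_params)
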