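"""Core data model for agglomerative hierarchical clustering.

Observations live in a :class:`DataMatrix` (rows = observations, columns =
features).  Clustering a matrix produces a :class:`MergeSequence` — the
ordered merge heights plus the merge tree — from which flat partitions are
recovered either by undoing the last merges (:func:`cut_to_k`) or by
thresholding merge heights (:func:`cut_at_height`).

All clustering in this package uses the agglomerative hierarchy with average
linkage and the Euclidean distance, for which merge heights are
non-decreasing in merge order; a violation beyond numerical noise is treated
as an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import InputError, ParseError

# merge-height inversions smaller than this are clamped, larger ones raised
_MONOTONE_TOL = 1e-9


@dataclass(frozen=True)
class DataMatrix:
    """A numeric observations × features matrix.

    Parameters
    ----------
    values
        Real matrix with N >= 2 rows (observations) and p >= 1 columns
        (features).  All entries must be finite.
    row_labels
        Optional per-observation labels (e.g. sample names).
    """

    values: np.ndarray
    row_labels: list[str] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values.reshape(-1, 1)
        if values.ndim != 2:
            raise InputError("data matrix must be 2-dimensional")
        if values.shape[0] < 2:
            raise InputError("need at least 2 observations")
        if values.shape[1] < 1:
            raise InputError("need at least 1 feature")
        if not np.all(np.isfinite(values)):
            raise InputError("data matrix contains non-finite entries")
        if self.row_labels is not None and len(self.row_labels) != values.shape[0]:
            raise InputError("row_labels length does not match number of rows")
        object.__setattr__(self, "values", values)

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MergeSequence:
    """The merge history of an agglomerative clustering of N points.

    Wraps the standard (N-1) × 4 linkage matrix: each row holds the two
    child node ids (a node id < N is a leaf, an id >= N refers to the
    cluster formed by merge ``id - N``), the merge height, and the size of
    the newly formed cluster.  Heights must be non-decreasing.
    """

    n_points: int
    linkage_matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        Z = np.asarray(self.linkage_matrix, dtype=float)
        if Z.ndim != 2 or Z.shape[1] != 4 or Z.shape[0] != self.n_points - 1:
            raise InputError(
                f"linkage matrix must have shape ({self.n_points - 1}, 4)"
            )
        heights = Z[:, 2]
        if np.any(heights < -_MONOTONE_TOL):
            raise InputError("merge heights must be non-negative")
        drops = np.diff(heights)
        worst = drops.min(initial=0.0)
        if worst < -_MONOTONE_TOL:
            raise InputError(
                f"merge heights are not non-decreasing (violation {-worst:.3g}); "
                "this should not happen with average linkage on a metric"
            )
        if worst < 0 or heights[0] < 0:  # clamp numerical noise
            Z = Z.copy()
            Z[:, 2] = np.maximum.accumulate(np.maximum(heights, 0.0))
        object.__setattr__(self, "linkage_matrix", Z)

    @property
    def heights(self) -> np.ndarray:
        """Merge heights d_1 <= ... <= d_m with m = N - 1."""
        return self.linkage_matrix[:, 2]

    @property
    def n_merges(self) -> int:
        return self.n_points - 1

    def to_frame(self) -> pd.DataFrame:
        """Merge history as a four-column table (child_a, child_b, height, size)."""
        return pd.DataFrame(
            {
                "child_a": self.linkage_matrix[:, 0].astype(int),
                "child_b": self.linkage_matrix[:, 1].astype(int),
                "height": self.linkage_matrix[:, 2],
                "size": self.linkage_matrix[:, 3].astype(int),
            }
        )


@dataclass(frozen=True)
class ClusterAssignment:
    """A flat partition of N observations into k clusters, labels in 1..k."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1:
            raise InputError("labels must be a 1-d integer array")
        present = np.unique(labels)
        if present.min(initial=1) < 1 or present.max(initial=1) > self.k:
            raise InputError("labels must lie in 1..k")
        if len(present) != self.k:
            raise InputError("every cluster 1..k must be non-empty")
        object.__setattr__(self, "labels", labels)

    @property
    def n_points(self) -> int:
        return self.labels.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def compute_linkage(data: DataMatrix, method: str = "average") -> MergeSequence:
    """Build the agglomerative hierarchy of a data matrix.

    Average linkage with Euclidean distances by default; other linkage
    methods are accepted for exploratory use but everything in this package
    is calibrated for average linkage.
    """
    if not isinstance(data, DataMatrix):
        data = DataMatrix(np.asarray(data))
    Z = linkage(data.values, method=method, metric="euclidean")
    return MergeSequence(n_points=data.n_points, linkage_matrix=Z)


def linkage_from_distances(condensed: np.ndarray, n_points: int,
                           method: str = "average") -> MergeSequence:
    """Build the hierarchy from a condensed pairwise-distance vector.

    Used internally when distances are precomputed once and reused across
    resampling replicates.
    """
    Z = linkage(condensed, method=method)
    return MergeSequence(n_points=n_points, linkage_matrix=Z)


def pairwise_distances(data: DataMatrix) -> np.ndarray:
    """Full symmetric Euclidean distance matrix of the observations."""
    return squareform(pdist(data.values))


def cut_to_k(merges: MergeSequence, k: int) -> ClusterAssignment:
    """Recover exactly k clusters by undoing the last k - 1 merges."""
    n = merges.n_points
    if not 1 <= k <= n:
        raise InputError(f"k must be in 1..{n}, got {k}")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        raw = cut_tree(merges.linkage_matrix, n_clusters=k).ravel()
        # relabel in order of first appearance so labels are 1..k
        _, first = np.unique(raw, return_index=True)
        order = {raw[i]: rank + 1 for rank, i in enumerate(np.sort(first))}
        labels = np.array([order[v] for v in raw])
    return ClusterAssignment(labels=labels, k=k)


def cut_at_height(merges: MergeSequence, h: float) -> ClusterAssignment:
    """Apply exactly the merges with height <= h.

    The resulting number of clusters is N minus the number of merge heights
    not exceeding h; monotone non-increasing in h.
    """
    if h < 0:
        raise InputError("cut height must be non-negative")
    k = merges.n_points - int(np.count_nonzero(merges.heights <= h))
    return cut_to_k(merges, k)


def read_matrix(path, delimiter: str = ",", has_header: bool = False,
                label_col: int | None = None) -> DataMatrix:
    """Read a rectangular numeric matrix from a delimited text file.

    Parameters
    ----------
    path
        CSV/TSV file, UTF-8, rows = observations.
    delimiter
        Field separator (``","`` or ``"\\t"`` typically).
    has_header
        Whether the first row is a header to skip.
    label_col
        0-based index of a column holding row labels, or None.
    """
    try:
        frame = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if has_header else None,
            index_col=label_col,
            encoding="utf-8",
        )
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: file is empty") from exc
    except (pd.errors.ParserError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ParseError(f"{path}: no data rows")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {frame.iat[r, c]!r} at row {r}, "
            f"column {frame.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(f"{path}: missing value at row {r}, column {frame.columns[c]!r}")
    labels = None
    if label_col is not None:
        labels = [str(x) for x in numeric.index]
    return DataMatrix(values=numeric.to_numpy(dtype=float), row_labels=labels)
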