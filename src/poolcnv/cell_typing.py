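"""Reference-cell typing: clustering, informative-bin selection and the
type-bin consensus matrix TB.

The deconvolution pipeline presumes the subclonal types are characterised in
advance by conventional per-cell sequencing of a reference subset.  This
module turns a reference copy-number matrix (cells x bins, integers) into the
T x B' matrix TB: cells are clustered into T types, bins whose most common
copy number is shared by fewer than a fraction theta of cells are discarded
as unreliable, the per-type modal copy number is taken as the type's value,
and bins where every type is diploid (copy number 2) are dropped as
uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "TypeBinMatrix",
    "cluster_cells",
    "select_informative_bins",
    "build_type_bin_matrix",
]


@dataclass(frozen=True)
class TypeBinMatrix:
    """Types x informative-bins consensus copy numbers (matrix TB)."""

    TB: np.ndarray  # T x B' int
    kept_bin_indices: np.ndarray  # strictly increasing indices into the original bins
    theta: float
    type_labels: list[str]

    def __post_init__(self):
        idx = np.asarray(self.kept_bin_indices)
        if self.TB.shape[1] != len(idx):
            raise ValueError("TB columns must match kept_bin_indices")
        if len(idx) > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("kept_bin_indices must be strictly increasing")

    @property
    def T(self) -> int:
        return self.TB.shape[0]

    @property
    def n_bins(self) -> int:
        return self.TB.shape[1]


def cluster_cells(
    cn_matrix: np.ndarray,
    T: int,
    method: str = "ward",
    metric: str = "euclidean",
) -> np.ndarray:
    """Agglomerative clustering of cells by their copy-number vectors.

    Ward linkage on Euclidean distance by default; the tree is cut at exactly
    ``T`` clusters.  Returned labels are integers in [0, T) renumbered by
    order of first appearance, so the labelling is deterministic for a given
    input.
    """
    cn_matrix = np.asarray(cn_matrix, dtype=np.float64)
    if T < 2:
        raise ValueError("need at least 2 clusters")
    if cn_matrix.shape[0] < T:
        raise ValueError(f"cannot form {T} clusters from {cn_matrix.shape[0]} cells")
    n_distinct = len(np.unique(cn_matrix, axis=0))
    if n_distinct < T:
        raise ValueError(
            f"cannot form {T} non-empty clusters from {n_distinct} distinct profiles"
        )
    Z = linkage(cn_matrix, method=method, metric=metric)
    raw = fcluster(Z, t=T, criterion="maxclust")
    # renumber by first occurrence for deterministic identities
    remap: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=np.int64)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    if len(remap) != T:
        raise ValueError(f"tree cut produced {len(remap)} clusters instead of {T}")
    return labels


def _mode_with_tiebreak(values: np.ndarray) -> tuple[int, int]:
    """Return (modal copy number, its count).

    Ties between equally common values are broken toward the value nearest
    the diploid 2, then toward the smaller value — a conservative bias
    toward calling bins normal.
    """
    vals, counts = np.unique(values, return_counts=True)
    max_count = counts.max()
    candidates = vals[counts == max_count]
    best = min(candidates, key=lambda v: (abs(int(v) - 2), int(v)))
    return int(best), int(max_count)


def select_informative_bins(
    cn_matrix: np.ndarray, theta: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Keep bins whose modal copy number is shared by >= theta of the cells.

    Mode frequencies are computed over all reference cells jointly.  Returns
    ``(kept_indices, mode_values)`` with one mode per kept bin.
    """
    if not (0.5 < theta <= 1.0):
        raise ValueError("theta must lie in (0.5, 1]")
    cn_matrix = np.asarray(cn_matrix)
    c = cn_matrix.shape[0]
    kept, modes = [], []
    for b in range(cn_matrix.shape[1]):
        mode, count = _mode_with_tiebreak(cn_matrix[:, b])
        if count / c >= theta:
            kept.append(b)
            modes.append(mode)
    return np.asarray(kept, dtype=np.int64), np.asarray(modes, dtype=np.int64)


def build_type_bin_matrix(
    cn_matrix: np.ndarray,
    labels: np.ndarray,
    kept_bins: np.ndarray,
    theta: float = 0.8,
    type_labels: list[str] | None = None,
) -> TypeBinMatrix:
    """Consensus TB over the kept bins, with all-diploid columns removed.

    ``TB[t, b]`` is the modal copy number of the cells labelled ``t`` at bin
    ``b`` (same tie rule as bin selection).  Columns where every type is 2
    carry no signal for distinguishing types and are dropped; if none remain
    the method is inapplicable to this population.
    """
    cn_matrix = np.asarray(cn_matrix)
    labels = np.asarray(labels)
    kept_bins = np.asarray(kept_bins, dtype=np.int64)
    if len(labels) != cn_matrix.shape[0]:
        raise ValueError("labels must cover every cell")
    if len(kept_bins) == 0:
        raise ValueError("kept_bins must be non-empty")
    uniq = np.unique(labels)
    T = len(uniq)
    sub = cn_matrix[:, kept_bins]
    TB = np.empty((T, len(kept_bins)), dtype=np.int64)
    for ti, t in enumerate(uniq):
        rows = sub[labels == t]
        for b in range(sub.shape[1]):
            TB[ti, b], _ = _mode_with_tiebreak(rows[:, b])
    informative = ~np.all(TB == 2, axis=0)
    if not informative.any():
        raise ValueError(
            "every consensus bin is diploid in all types; no CNV signal to "
            "distinguish types"
        )
    if type_labels is None:
        type_labels = [f"type{int(t) + 1}" for t in uniq]
    return TypeBinMatrix(
        TB=TB[:, informative],
        kept_bin_indices=kept_bins[informative],
        theta=theta,
        type_labels=type_labels,
    )
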