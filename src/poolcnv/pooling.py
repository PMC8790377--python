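"""Overlapping pool design (matrix PC) and pool profile synthesis (matrix PB).

Cells are distributed into p < c pools so that one sequencing library per
pool suffices; each pool holds round(k*c) cells drawn uniformly at random,
and a cell may sit in several pools ("overlapping").  Pool copy-number
profiles are then either averaged directly from member-cell profiles
(profile space) or recomputed from summed read counts (count space, which is
what merging equal-depth libraries produces).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_typing import TypeBinMatrix
from .simulate import CellPopulation, counts_to_continuous_profile

__all__ = [
    "PoolingDesign",
    "PoolBinMatrix",
    "design_pooling_matrix",
    "synthesize_pools_profile_space",
    "synthesize_pools_count_space",
]


@dataclass(frozen=True)
class PoolingDesign:
    """Binary pools x cells membership matrix PC.

    ``PC[i, j] = 1`` iff cell j is contained in pool i.  Every pool is
    non-empty and every cell belongs to at least one pool.
    """

    PC: np.ndarray  # p x c, 0/1
    k: float
    seed: int | None = None

    def __post_init__(self):
        PC = np.asarray(self.PC)
        if not np.isin(PC, (0, 1)).all():
            raise ValueError("PC must be binary")
        if np.any(PC.sum(axis=1) == 0):
            raise ValueError("PC has an empty pool (all-zero row)")
        if np.any(PC.sum(axis=0) == 0):
            raise ValueError("PC has an unpooled cell (all-zero column)")

    @property
    def p(self) -> int:
        return self.PC.shape[0]

    @property
    def c(self) -> int:
        return self.PC.shape[1]

    @property
    def pool_sizes(self) -> np.ndarray:
        return self.PC.sum(axis=1)

    @property
    def cells_in_single_pool(self) -> np.ndarray:
        """Indices of cells appearing in only one pool (weakly constrained)."""
        return np.flatnonzero(self.PC.sum(axis=0) < 2)


@dataclass(frozen=True)
class PoolBinMatrix:
    """Pools x informative-bins continuous copy-number profiles (matrix PB)."""

    PB: np.ndarray  # p x B' float
    kept_bin_indices: np.ndarray
    provenance: str  # "profile" or "count"

    def __post_init__(self):
        if self.PB.shape[1] != len(self.kept_bin_indices):
            raise ValueError("PB columns must match kept_bin_indices")
        if np.any(self.PB < 0):
            raise ValueError("pool profiles cannot be negative")


def design_pooling_matrix(
    c: int,
    p: int,
    k: float,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 1000,
) -> PoolingDesign:
    """Draw a random overlapping design with fixed pool size round(k*c).

    Each pool independently receives a uniform random subset of exactly
    ``round(k*c)`` cells; designs leaving any cell unpooled are rejected and
    redrawn.  Repeated rejection signals an infeasible (c, p, k) combination.
    """
    if p < 2:
        raise ValueError("need at least 2 pools")
    m = round(k * c)
    if not (1 <= m <= c):
        raise ValueError(f"pool size round(k*c)={m} must lie in [1, {c}]")
    if p * m < c:
        raise ValueError(
            f"p*round(k*c)={p * m} < c={c}: every-cell coverage is impossible"
        )
    rng = np.random.default_rng(rng)
    for _ in range(max_retries):
        PC = np.zeros((p, c), dtype=np.int64)
        for i in range(p):
            PC[i, rng.choice(c, size=m, replace=False)] = 1
        if np.all(PC.sum(axis=0) > 0):
            return PoolingDesign(PC=PC, k=k)
    raise RuntimeError(
        f"no design without unpooled cells found in {max_retries} draws for "
        f"(c={c}, p={p}, k={k})"
    )


def synthesize_pools_profile_space(
    design: PoolingDesign,
    cn_matrix: np.ndarray,
    kept_bins: np.ndarray,
) -> PoolBinMatrix:
    """Pool profiles as the equal-weight mean of member-cell CN profiles.

    The mean is kept continuous: rounding a mixture average would destroy
    the type-proportion information the deconvolution step relies on.
    """
    cn_matrix = np.asarray(cn_matrix, dtype=np.float64)
    if design.c != cn_matrix.shape[0]:
        raise ValueError("design and copy-number matrix disagree on cell count")
    kept_bins = np.asarray(kept_bins, dtype=np.int64)
    PB = (design.PC @ cn_matrix) / design.pool_sizes[:, None]
    return PoolBinMatrix(
        PB=PB[:, kept_bins], kept_bin_indices=kept_bins, provenance="profile"
    )


def synthesize_pools_count_space(
    design: PoolingDesign,
    read_counts: np.ndarray,
    kept_bins: np.ndarray,
    pool_ploidies: np.ndarray | None = None,
    cell_ploidies: np.ndarray | None = None,
    total_tolerance: float = 1e-3,
) -> PoolBinMatrix:
    """Pool profiles recomputed from summed member read counts.

    Mirrors merging equal-depth libraries: member counts are summed per bin,
    then scaled to a continuous copy-number profile with the pool's ploidy
    (mean of member-cell ploidies).  Equal per-cell totals are required so
    that every member carries the same weight in the pool.
    """
    read_counts = np.asarray(read_counts, dtype=np.float64)
    if design.c != read_counts.shape[0]:
        raise ValueError("design and read-count matrix disagree on cell count")
    totals = read_counts.sum(axis=1)
    if (totals.max() - totals.min()) > total_tolerance * totals.mean():
        raise ValueError(
            "per-cell read totals differ by more than 0.1%; equal pooling "
            "weight is violated"
        )
    if pool_ploidies is None:
        if cell_ploidies is None:
            raise ValueError("provide pool_ploidies or cell_ploidies")
        cell_ploidies = np.asarray(cell_ploidies, dtype=np.float64)
        pool_ploidies = (design.PC @ cell_ploidies) / design.pool_sizes
    pool_counts = design.PC @ read_counts
    kept_bins = np.asarray(kept_bins, dtype=np.int64)
    PB = np.vstack(
        [
            counts_to_continuous_profile(pool_counts[i], pool_ploidies[i])
            for i in range(design.p)
        ]
    )
    return PoolBinMatrix(
        PB=PB[:, kept_bins], kept_bin_indices=kept_bins, provenance="count"
    )


def pools_from_population(
    design: PoolingDesign,
    pop: CellPopulation,
    tb: TypeBinMatrix,
    space: str = "count",
    use_true_cn: bool = False,
) -> PoolBinMatrix:
    """Convenience: build PB for a synthetic population aligned to TB's bins."""
    if space == "profile":
        cn = pop.cn_true if use_true_cn else pop.cn_observed
        if cn is None:
            raise ValueError("population has no observed copy numbers yet")
        return synthesize_pools_profile_space(design, cn, tb.kept_bin_indices)
    if space == "count":
        if pop.read_counts is None:
            raise ValueError("population has no read counts yet")
        return synthesize_pools_count_space(
            design,
            pop.read_counts,
            tb.kept_bin_indices,
            cell_ploidies=pop.ploidy,
        )
    raise ValueError(f"unknown pool space {space!r}")
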