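"""Deconvolution of pooled CNV profiles into per-cell type assignments.

Two linked linear systems are solved.  First, with TB the types x bins
consensus matrix and PB the pools x bins observed pool profiles,

    PT . TB = PB

is solved for the pools x types mixture matrix PT through the Moore-Penrose
pseudoinverse of TB (PT = PB . TB^+), the minimum-norm least-squares
solution; row i of PT estimates the proportion of each type in pool i.
Second, with PC the binary pools x cells design, the cells x types one-hot
assignment CT is recovered by minimising

    sum_t sum_i ( sum_j PC[i,j] CT[j,t] - PT[i,t] )^2
    subject to each CT row having exactly one 1,

i.e. the squared Frobenius norm || PC . CT - PT ||^2 with PT on the
cell-count scale.  The minimisation is exact branch and bound: each node
relaxes the unfixed assignment rows onto the probability simplex, solves the
resulting convex quadratic with Frank-Wolfe iterations whose duality gap
certifies a lower bound, and incumbents come from rounding the relaxation
followed by coordinate-descent improvement.  The relaxation/heuristic effort
is 100 iterations at the root node and 2 at every subsequent node by
default.
"""

from __future__ import annotations

import heapq
import time
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .cell_typing import TypeBinMatrix
from .pooling import PoolBinMatrix, PoolingDesign

__all__ = [
    "PoolTypeMatrix",
    "AssignmentMatrix",
    "solve_pool_type",
    "scale_mixture_to_counts",
    "objective_value",
    "coordinate_descent_heuristic",
    "solve_assignment_bb",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PoolTypeMatrix:
    """Pools x types least-squares mixture estimate (matrix PT).

    On the proportion scale each row approximately sums to 1; scaling by the
    pool sizes (once) converts it to expected member-cell counts per type.
    Entries may be negative: the least-squares solution is not clamped.
    """

    PT: np.ndarray  # p x T float
    scaled: bool = False
    pool_sizes: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.PT.shape[0]

    @property
    def T(self) -> int:
        return self.PT.shape[1]


@dataclass(frozen=True)
class AssignmentMatrix:
    """Binary cells x types one-hot assignment (matrix CT) with solver state.

    ``objective`` is the residual ||PC.CT - PT||^2 of the returned
    assignment; ``gap`` the certified optimality gap (0 when the tree was
    exhausted); ``status`` one of optimal / gap_limit / budget_exhausted /
    heuristic.
    """

    CT: np.ndarray  # c x T, 0/1
    objective: float
    gap: float
    node_count: int
    status: str

    def __post_init__(self):
        CT = np.asarray(self.CT)
        if not np.isin(CT, (0, 1)).all() or np.any(CT.sum(axis=1) != 1):
            raise ValueError("every CT row must contain exactly one 1")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        """Assigned type index per cell."""
        return np.argmax(self.CT, axis=1)


def solve_pool_type(
    PB: PoolBinMatrix | np.ndarray,
    TB: TypeBinMatrix | np.ndarray,
    sv_rtol: float = 1e-10,
) -> PoolTypeMatrix:
    """Solve PT . TB = PB for PT via the pseudoinverse of TB.

    Singular values below ``sv_rtol`` times the largest are treated as zero.
    A rank-deficient TB (types not linearly separable by their profiles)
    makes PT non-unique; the minimum-norm solution is still returned with a
    warning.
    """
    PB_arr = PB.PB if isinstance(PB, PoolBinMatrix) else np.asarray(PB, dtype=float)
    TB_arr = TB.TB if isinstance(TB, TypeBinMatrix) else np.asarray(TB, dtype=float)
    if (
        isinstance(PB, PoolBinMatrix)
        and isinstance(TB, TypeBinMatrix)
        and not np.array_equal(PB.kept_bin_indices, TB.kept_bin_indices)
    ):
        raise ValueError("PB and TB are built over different bin sets")
    if PB_arr.shape[1] != TB_arr.shape[1]:
        raise ValueError("PB and TB must share bin columns")
    if not np.any(TB_arr):
        raise ValueError("TB is all zeros; the system is degenerate")
    U, s, Vt = np.linalg.svd(TB_arr.astype(np.float64), full_matrices=False)
    keep = s > sv_rtol * s[0]
    rank = int(keep.sum())
    if rank < TB_arr.shape[0]:
        warnings.warn(
            f"TB has row rank {rank} < {TB_arr.shape[0]} types; mixture "
            "estimates are non-unique",
            RuntimeWarning,
            stacklevel=2,
        )
    # TB^+ = V . diag(1/s) . U^T restricted to the kept singular values
    TB_pinv = (Vt[keep].T / s[keep]) @ U[:, keep].T
    return PoolTypeMatrix(PT=PB_arr @ TB_pinv, scaled=False)


def scale_mixture_to_counts(
    PT: PoolTypeMatrix, design: PoolingDesign
) -> PoolTypeMatrix:
    """Convert PT from type proportions to expected member-cell counts.

    Row i is multiplied by the pool size n_i, so that PC . CT (which counts
    cells per type in each pool) is directly comparable to PT.
    """
    if PT.scaled:
        raise ValueError("PT is already on the count scale")
    if PT.p != design.p:
        raise ValueError("PT and design disagree on the number of pools")
    n = design.pool_sizes.astype(np.float64)
    return replace(PT, PT=PT.PT * n[:, None], scaled=True, pool_sizes=n)


def _as_counts_array(PT) -> np.ndarray:
    if isinstance(PT, PoolTypeMatrix):
        if not PT.scaled:
            raise ValueError("PT must be on the count scale; apply "
                             "scale_mixture_to_counts first")
        return PT.PT
    return np.asarray(PT, dtype=np.float64)


def _check_feasible(CT: np.ndarray) -> np.ndarray:
    CT = np.asarray(CT)
    if CT.ndim != 2 or not np.isin(CT, (0, 1)).all() or np.any(CT.sum(axis=1) != 1):
        raise ValueError("CT must be one-hot per row")
    return CT.astype(np.float64)


def objective_value(PC: np.ndarray, CT: np.ndarray, PT_counts) -> float:
    """Squared Frobenius residual || PC . CT - PT ||^2 for a feasible CT."""
    PC = np.asarray(PC, dtype=np.float64)
    PT_arr = _as_counts_array(PT_counts)
    CT = _check_feasible(CT)
    if PC.shape[1] != CT.shape[0] or PC.shape[0] != PT_arr.shape[0] \
            or CT.shape[1] != PT_arr.shape[1]:
        raise ValueError("inconsistent dimensions among PC, CT and PT")
    R = PC @ CT - PT_arr
    return float(np.sum(R * R))


def _labels_to_onehot(z: np.ndarray, T: int) -> np.ndarray:
    CT = np.zeros((len(z), T), dtype=np.int64)
    CT[np.arange(len(z)), z] = 1
    return CT


def _cd_sweeps(
    PC: np.ndarray,
    PT: np.ndarray,
    z: np.ndarray,
    pool_rows: list[np.ndarray],
    max_sweeps: int,
    frozen: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """In-place coordinate descent over cells; returns (labels, objective).

    Per cell, the objective change of every reassignment is evaluated from
    the running residual in O(pools containing the cell); the best strictly
    improving move is applied.  Stops after a full sweep without change.
    """
    c = len(z)
    T = PT.shape[1]
    R = PC @ _labels_to_onehot(z, T).astype(np.float64) - PT
    for _ in range(max_sweeps):
        changed = False
        for j in range(c):
            if frozen is not None and frozen[j]:
                continue
            rows = pool_rows[j]
            if len(rows) == 0:
                continue
            a = z[j]
            d = R[rows].sum(axis=0)
            # moving j from a to b changes the objective by
            # 2*(d[b] - d[a]) + 2*|rows|
            delta = 2.0 * (d - d[a]) + 2.0 * len(rows)
            delta[a] = 0.0
            b = int(np.argmin(delta))  # ties -> lowest type index
            if delta[b] < -_EPS:
                R[rows, a] -= 1.0
                R[rows, b] += 1.0
                z[j] = b
                changed = True
        if not changed:
            break
    return z, float(np.sum(R * R))


def coordinate_descent_heuristic(
    PC: np.ndarray,
    PT_counts,
    CT_init: np.ndarray,
    max_sweeps: int = 100,
) -> AssignmentMatrix:
    """Greedy local search over single-cell reassignments.

    The objective never increases across sweeps; the result is a local
    optimum under single-cell moves (and the global optimum's own fixed
    point).  Used as the incumbent generator inside branch and bound and as
    a fallback at scales where certification is out of reach.
    """
    PC = np.asarray(PC, dtype=np.float64)
    PT_arr = _as_counts_array(PT_counts)
    CT = _check_feasible(CT_init)
    z = np.argmax(CT, axis=1).astype(np.int64)
    pool_rows = [np.flatnonzero(PC[:, j] != 0) for j in range(PC.shape[1])]
    z, obj = _cd_sweeps(PC, PT_arr, z, pool_rows, max_sweeps)
    return AssignmentMatrix(
        CT=_labels_to_onehot(z, PT_arr.shape[1]),
        objective=obj,
        gap=np.inf,
        node_count=0,
        status="heuristic",
    )


def _frank_wolfe(
    PC: np.ndarray,
    PT: np.ndarray,
    X: np.ndarray,
    free: np.ndarray,
    n_iters: int,
) -> tuple[np.ndarray, float, float]:
    """Frank-Wolfe on the row-wise simplex relaxation, fixed rows locked.

    Minimises f(X) = ||PC.X - PT||^2 over X whose free rows lie in the
    probability simplex.  Returns (X, best certified lower bound, f(X)).
    The Frank-Wolfe duality gap g = <grad f, X - S> with S the best vertex
    satisfies f(X) - g <= f*, so f - g is a valid lower bound at every
    iterate; the largest such bound over the run is reported.
    """
    best_bound = -np.inf
    f = 0.0
    for _ in range(max(1, n_iters)):
        R = PC @ X - PT
        f = float(np.sum(R * R))
        G = 2.0 * (PC.T @ R)
        S = X.copy()
        if free.any():
            idx = np.flatnonzero(free)
            S[idx] = 0.0
            S[idx, np.argmin(G[idx], axis=1)] = 1.0
        gap = float(np.sum(G * (X - S)))
        best_bound = max(best_bound, f - max(gap, 0.0))
        if gap <= _EPS:
            break
        D = S - X
        PD = PC @ D
        denom = 2.0 * float(np.sum(PD * PD))
        gamma = 1.0 if denom <= _EPS else min(1.0, gap / denom)
        X = X + gamma * D
    return X, best_bound, f


class _Node:
    __slots__ = ("bound", "X", "fixed", "order")

    def __init__(self, bound, X, fixed, order):
        self.bound = bound
        self.X = X
        self.fixed = fixed  # int array, -1 = free
        self.order = order

    def __lt__(self, other):  # heap ties broken by insertion order
        return (self.bound, self.order) < (other.bound, other.order)


def solve_assignment_bb(
    PC: np.ndarray,
    PT_counts,
    T: int | None = None,
    max_nodes: int = 100_000,
    time_limit: float = 60.0,
    gap_tol: float = 0.0,
    root_passes: int = 100,
    node_passes: int = 2,
    cd_sweeps: int = 50,
    rng_seed: int | None = None,
) -> AssignmentMatrix:
    """Exact best-first branch and bound for the one-hot assignment CT.

    Nodes fix a subset of cells to types; the remaining rows are relaxed to
    the simplex and bounded by Frank-Wolfe (``root_passes`` iterations at the
    root, ``node_passes`` elsewhere).  Branching picks the most fractional
    free cell (smallest maximum relaxed weight); its children, one per type,
    are ordered by relaxed weight descending.  A node is pruned when its
    certified bound cannot improve the incumbent by more than ``gap_tol``.
    Exhausting the tree proves optimality; hitting ``max_nodes`` or
    ``time_limit`` returns the incumbent with its certified gap
    (status ``budget_exhausted``).  The algorithm is deterministic;
    ``rng_seed`` is accepted for interface uniformity and unused.
    """
    del rng_seed
    PC = np.asarray(PC, dtype=np.float64)
    PT_arr = _as_counts_array(PT_counts)
    if PC.shape[0] != PT_arr.shape[0]:
        raise ValueError("PC and PT disagree on the number of pools")
    c = PC.shape[1]
    if T is None:
        T = PT_arr.shape[1]
    elif T != PT_arr.shape[1]:
        raise ValueError("T does not match PT's column count")
    if gap_tol < 0:
        raise ValueError("gap_tol must be non-negative")

    start = time.monotonic()
    pool_rows = [np.flatnonzero(PC[:, j] != 0) for j in range(c)]

    inc_z: np.ndarray | None = None
    inc_obj = np.inf

    def try_incumbent(X: np.ndarray, fixed: np.ndarray) -> None:
        nonlocal inc_z, inc_obj
        z = np.argmax(X, axis=1).astype(np.int64)
        z[fixed >= 0] = fixed[fixed >= 0]
        # incumbents may move fixed cells: any feasible CT counts
        z, obj = _cd_sweeps(PC, PT_arr, z, pool_rows, cd_sweeps)
        if obj < inc_obj - _EPS:
            inc_obj = obj
            inc_z = z.copy()

    # root node
    X0 = np.full((c, T), 1.0 / T)
    fixed0 = np.full(c, -1, dtype=np.int64)
    X0, bound0, _ = _frank_wolfe(PC, PT_arr, X0, fixed0 < 0, root_passes)
    try_incumbent(X0, fixed0)

    counter = 0
    heap: list[_Node] = [_Node(bound0, X0, fixed0, counter)]
    node_count = 1
    status = "optimal"
    final_gap = 0.0

    def safety() -> float:
        return 1e-9 * (1.0 + abs(inc_obj))

    while heap:
        if node_count >= max_nodes or time.monotonic() - start > time_limit:
            status = "budget_exhausted"
            final_gap = max(0.0, inc_obj - heap[0].bound)
            break
        node = heapq.heappop(heap)
        if node.bound >= inc_obj - safety():
            # best-first: nothing left can beat the incumbent
            status = "optimal"
            final_gap = 0.0
            break
        if gap_tol > 0 and node.bound >= inc_obj - gap_tol:
            status = "gap_limit"
            final_gap = max(0.0, inc_obj - node.bound)
            break
        free_idx = np.flatnonzero(node.fixed < 0)
        if len(free_idx) == 0:
            continue  # leaf; its objective was already tried as incumbent
        # branch on the most fractional free cell
        frac = node.X[free_idx].max(axis=1)
        j = int(free_idx[np.argmin(frac)])
        child_order = np.argsort(-node.X[j], kind="stable")
        for t in child_order:
            child_fixed = node.fixed.copy()
            child_fixed[j] = t
            Xc = node.X.copy()
            Xc[j] = 0.0
            Xc[j, t] = 1.0
            free = child_fixed < 0
            Xc, b, _ = _frank_wolfe(PC, PT_arr, Xc, free, node_passes)
            b = max(b, node.bound)  # parent bound remains valid for the child
            node_count += 1
            try_incumbent(Xc, child_fixed)
            if b < inc_obj - max(safety(), gap_tol):
                counter += 1
                heapq.heappush(heap, _Node(b, Xc, child_fixed, counter))
    else:
        status = "optimal"
        final_gap = 0.0

    assert inc_z is not None
    CT = _labels_to_onehot(inc_z, T)
    # report the objective recomputed from scratch for the returned CT
    obj = objective_value(PC, CT, PT_arr)
    return AssignmentMatrix(
        CT=CT,
        objective=obj,
        gap=final_gap if status != "optimal" else 0.0,
        node_count=node_count,
        status=status,
    )
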