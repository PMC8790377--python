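"""Synthetic single-cell CNV data generation.

Produces populations of single cells whose integer copy-number profiles fall
into a small number of distinct subclonal types, with within-type cell-to-cell
noise and binned read-count sampling — the statistical structure that
overlapping-pool deconvolution assumes.  The defaults emulate a medium-scale
tumour study: 7 subclonal types, 80 cells, bins of ~100 kb, 1 million reads
per cell.

The generator deliberately excludes amplification and GC bias: those arise
upstream of pooled deconvolution (in alignment and copy-number calling) and
the method consumes integer copy-number matrices produced after such
corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinSet",
    "SegmentConfig",
    "TypeProfileSet",
    "CellPopulation",
    "uniform_bins",
    "generate_type_profiles",
    "generate_cells",
    "simulate_read_counts",
    "counts_to_copy_number",
    "counts_to_continuous_profile",
]

#: quality-control floor on median reads per bin, below which single-cell
#: copy-number calls are considered unreliable
MEDIAN_READS_QC_FLOOR = 50

DEFAULT_MAX_CN = 8


@dataclass(frozen=True)
class BinSet:
    """An ordered set of non-overlapping genomic intervals (0-based, half-open)."""

    chroms: np.ndarray  # dtype object/str, length B
    starts: np.ndarray  # int, length B
    ends: np.ndarray  # int, length B

    def __post_init__(self):
        if len(self.chroms) != len(self.starts) or len(self.starts) != len(self.ends):
            raise ValueError("chroms, starts and ends must have equal length")
        if len(self.starts) < 1:
            raise ValueError("a BinSet needs at least one bin")
        if np.any(self.ends <= self.starts):
            raise ValueError("every bin must satisfy end > start")
        # bins must be sorted and non-overlapping within each chromosome
        for chrom in np.unique(self.chroms):
            mask = self.chroms == chrom
            s, e = self.starts[mask], self.ends[mask]
            if np.any(np.diff(s) <= 0) or np.any(s[1:] < e[:-1]):
                raise ValueError(f"bins on {chrom} overlap or are unsorted")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def ids(self) -> list[str]:
        return [
            f"{c}:{s}-{e}"
            for c, s, e in zip(self.chroms, self.starts, self.ends)
        ]


def uniform_bins(B: int, bin_size: int = 100_000, chrom: str = "chr1") -> BinSet:
    """A single synthetic chromosome tiled with ``B`` equal bins."""
    starts = np.arange(B, dtype=np.int64) * bin_size
    return BinSet(
        chroms=np.array([chrom] * B, dtype=object),
        starts=starts,
        ends=starts + bin_size,
    )


@dataclass(frozen=True)
class SegmentConfig:
    """Distributions of CNV segments laid onto a diploid background.

    Each type receives ``n_segments`` (drawn uniformly from
    ``segments_range``) contiguous segments; each segment's length in bins is
    uniform over ``length_range``, its state is an amplification with
    probability ``p_amplification`` (level drawn from ``amp_levels``) and a
    deletion otherwise (level from ``del_levels``).
    """

    segments_range: tuple[int, int] = (6, 12)
    length_range: tuple[int, int] = (50, 400)
    amp_levels: tuple[int, ...] = (3, 4, 5, 6)
    del_levels: tuple[int, ...] = (0, 1)
    p_amplification: float = 0.6
    min_hamming_frac: float = 0.05
    max_cn: int = DEFAULT_MAX_CN


@dataclass(frozen=True)
class TypeProfileSet:
    """Consensus integer copy-number profile of each subclonal type."""

    profiles: np.ndarray  # T x B int
    labels: list[str] = field(default_factory=list)
    max_cn: int = DEFAULT_MAX_CN

    def __post_init__(self):
        prof = np.asarray(self.profiles)
        if prof.ndim != 2:
            raise ValueError("profiles must be a T x B matrix")
        if prof.min() < 0 or prof.max() > self.max_cn:
            raise ValueError(f"copy numbers must lie in [0, {self.max_cn}]")
        T = prof.shape[0]
        for a in range(T):
            for b in range(a + 1, T):
                if np.array_equal(prof[a], prof[b]):
                    raise ValueError(f"type profiles {a} and {b} are identical")
        if not self.labels:
            object.__setattr__(self, "labels", [f"type{t + 1}" for t in range(T)])

    @property
    def T(self) -> int:
        return self.profiles.shape[0]

    @property
    def B(self) -> int:
        return self.profiles.shape[1]


@dataclass
class CellPopulation:
    """A population of single cells drawn from a :class:`TypeProfileSet`.

    ``cn_true`` is the per-cell ground-truth integer profile, ``read_counts``
    the sampled binned read counts (filled by :func:`simulate_read_counts`)
    and ``cn_observed`` the integer profile recovered from the counts.
    """

    types: TypeProfileSet
    true_labels: np.ndarray  # int, length c, values in [0, T)
    cn_true: np.ndarray  # c x B int
    read_counts: np.ndarray | None = None  # c x B int
    cn_observed: np.ndarray | None = None  # c x B int
    qc_low_depth: np.ndarray | None = None  # bool, length c

    def __post_init__(self):
        if self.true_labels.min() < 0 or self.true_labels.max() >= self.types.T:
            raise ValueError("true_labels reference non-existent types")
        if np.any(self.cn_true < 0):
            raise ValueError("copy numbers must be non-negative")

    @property
    def c(self) -> int:
        return self.cn_true.shape[0]

    @property
    def B(self) -> int:
        return self.cn_true.shape[1]

    @property
    def ploidy(self) -> np.ndarray:
        """Per-cell mean ground-truth copy number."""
        return self.cn_true.mean(axis=1)


def generate_type_profiles(
    T: int,
    B: int,
    seg_config: SegmentConfig | None = None,
    rng: np.random.Generator | int | None = None,
    max_retries: int = 50,
) -> TypeProfileSet:
    """Draw ``T`` distinct type profiles of ``B`` bins on a diploid background.

    Profiles are redrawn until every pair differs in at least
    ``min_hamming_frac * B`` bins; failing that within ``max_retries``
    signals an inconsistent segment configuration.
    """
    if T < 2:
        raise ValueError("at least 2 types are required")
    if B < T:
        raise ValueError("need at least as many bins as types")
    cfg = seg_config or SegmentConfig()
    rng = np.random.default_rng(rng)
    min_dist = max(1, round(cfg.min_hamming_frac * B))

    for _ in range(max_retries):
        prof = np.full((T, B), 2, dtype=np.int64)
        for t in range(T):
            n_seg = rng.integers(cfg.segments_range[0], cfg.segments_range[1] + 1)
            for _ in range(n_seg):
                length = int(
                    rng.integers(cfg.length_range[0], min(cfg.length_range[1], B) + 1)
                )
                start = int(rng.integers(0, B - length + 1))
                if rng.random() < cfg.p_amplification:
                    level = int(rng.choice(cfg.amp_levels))
                else:
                    level = int(rng.choice(cfg.del_levels))
                prof[t, start : start + length] = level
        dists = [
            np.count_nonzero(prof[a] != prof[b])
            for a in range(T)
            for b in range(a + 1, T)
        ]
        if min(dists) >= min_dist:
            return TypeProfileSet(profiles=prof, max_cn=cfg.max_cn)
    raise RuntimeError(
        f"could not draw {T} profiles with pairwise Hamming distance >= "
        f"{min_dist} in {max_retries} attempts; seg_config is too sparse"
    )


def generate_cells(
    tps: TypeProfileSet,
    cells_per_type: list[int] | np.ndarray,
    flip_rate: float = 0.02,
    rng: np.random.Generator | int | None = None,
) -> CellPopulation:
    """Instantiate cells from type profiles with per-bin +/-1 copy flips.

    Each cell copies its type profile and, independently per bin with
    probability ``flip_rate``, shifts the copy number by +1 or -1 (equal
    odds), clamped to [0, max_cn] — a minimal model of within-type
    heterogeneity.
    """
    if not (0.0 <= flip_rate <= 0.2):
        raise ValueError("flip_rate must lie in [0, 0.2]")
    cells_per_type = np.asarray(cells_per_type, dtype=np.int64)
    if len(cells_per_type) != tps.T:
        raise ValueError("cells_per_type must have one entry per type")
    if np.any(cells_per_type < 1):
        raise ValueError("every type needs at least one cell")
    rng = np.random.default_rng(rng)

    labels = np.repeat(np.arange(tps.T), cells_per_type)
    cn = tps.profiles[labels].copy()
    if flip_rate > 0:
        flips = rng.random(cn.shape) < flip_rate
        signs = rng.choice([-1, 1], size=cn.shape)
        cn = np.clip(cn + flips * signs, 0, tps.max_cn)
    return CellPopulation(types=tps, true_labels=labels, cn_true=cn)


def simulate_read_counts(
    pop: CellPopulation,
    reads_per_cell: int = 1_000_000,
    rng: np.random.Generator | int | None = None,
) -> CellPopulation:
    """Sample binned read counts for every cell in place, and return ``pop``.

    Per cell, counts are multinomial over bins with probabilities
    proportional to the true copy number, so every cell carries exactly
    ``reads_per_cell`` reads (equal weighting when pools are later merged).
    Cells whose median reads/bin falls below the QC floor of
    ``MEDIAN_READS_QC_FLOOR`` are flagged, not dropped.
    """
    if reads_per_cell < 1:
        raise ValueError("reads_per_cell must be >= 1")
    rng = np.random.default_rng(rng)

    counts = np.empty_like(pop.cn_true, dtype=np.int64)
    for j in range(pop.c):
        cn = pop.cn_true[j].astype(np.float64)
        total = cn.sum()
        if total == 0:
            raise ValueError(f"cell {j} has an all-zero copy-number profile")
        counts[j] = rng.multinomial(reads_per_cell, cn / total)
    pop.read_counts = counts
    pop.qc_low_depth = np.median(counts, axis=1) < MEDIAN_READS_QC_FLOOR
    pop.cn_observed = np.vstack(
        [
            counts_to_copy_number(counts[j], pop.ploidy[j])
            for j in range(pop.c)
        ]
    )
    return pop


def counts_to_continuous_profile(counts: np.ndarray, ploidy: float) -> np.ndarray:
    """Scale bin counts to a continuous copy-number profile.

    ``profile[b] = counts[b] / mean(counts) * ploidy``; the per-bin ratio to
    the mean removes depth, the ploidy restores absolute copy number.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.min() < 0:
        raise ValueError("counts must be non-negative")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("cannot scale an all-zero count vector")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    return counts / mean * ploidy


def counts_to_copy_number(counts: np.ndarray, ploidy: float) -> np.ndarray:
    """Integer copy number from bin counts: scaled ratios rounded per bin."""
    return np.rint(counts_to_continuous_profile(counts, ploidy)).astype(np.int64)
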