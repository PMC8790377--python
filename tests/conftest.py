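import numpy as np
import pytest

import poolcnv


@pytest.fixture(scope="session")
def small_generator_config():
    """An 80-cell, 7-type population at reduced bin count for fast tests."""
    return poolcnv.GeneratorConfig(
        B=2000,
        reads_per_cell=200_000,
        seg_config=poolcnv.SegmentConfig(length_range=(20, 120)),
    )


@pytest.fixture(scope="session")
def small_population(small_generator_config):
    cfg = small_generator_config
    ss = np.random.SeedSequence(42)
    s1, s2, s3 = ss.spawn(3)
    tps = poolcnv.generate_type_profiles(
        cfg.T, cfg.B, cfg.seg_config, rng=np.random.default_rng(s1)
    )
    pop = poolcnv.generate_cells(
        tps, cfg.cells_per_type, cfg.flip_rate, rng=np.random.default_rng(s2)
    )
    poolcnv.simulate_read_counts(
        pop, cfg.reads_per_cell, rng=np.random.default_rng(s3)
    )
    return pop


def exhaustive_minimum(PC, PT):
    """Brute-force oracle: enumerate every one-hot CT and return the minimum.

    Vectorised over all T^c assignments; usable up to T^c ~ 1e5.
    """
    p, c = PC.shape
    T = PT.shape[1]
    n = T**c
    assert n <= 200_000, "instance too large for enumeration"
    z = np.empty((n, c), dtype=np.int64)
    idx = np.arange(n)
    for j in range(c):
        z[:, j] = (idx // T**j) % T
    onehot = np.zeros((n, c, T))
    onehot[np.arange(n)[:, None], np.arange(c)[None, :], z] = 1.0
    fits = np.einsum("ij,njt->nit", PC.astype(float), onehot)
    objs = ((fits - PT[None]) ** 2).sum(axis=(1, 2))
    best = int(np.argmin(objs))
    return float(objs[best]), z[best]
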