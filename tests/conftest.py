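import numpy as np
import pytest

import dexil

# Default-condition simulation: 4 donors x 4 conditions, the standard gene-class
# mixture, planted |log2FC| ~ 2.  Session-scoped because several suites and the
# acceptance checks interrogate the same run from different angles.


@pytest.fixture(scope="session")
def sim_default():
    cfg = dexil.SimConfig(n_genes=2000, seed=11)
    matrix, truth = dexil.generate_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def de_default(sim_default):
    _cfg, matrix, _truth = sim_default
    return dexil.run_de(matrix)


@pytest.fixture(scope="session")
def sim_null():
    """Global-null simulation: no planted effects, no phenotype coupling."""
    cfg = dexil.SimConfig(
        n_genes=2000, seed=7, class_fractions={"null": 1.0}, cilia_coupling=0.0
    )
    matrix, truth = dexil.generate_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def de_null(sim_null):
    _cfg, matrix, _truth = sim_null
    return dexil.run_de(matrix)


@pytest.fixture(scope="session")
def small_sim():
    cfg = dexil.SimConfig(n_genes=300, seed=1)
    matrix, truth = dexil.generate_counts(cfg)
    return cfg, matrix, truth


def brute_force_es(scores: np.ndarray, hits: np.ndarray, weight: float = 1.0) -> float:
    """Independent O(N) running-sum enrichment score used as a test oracle.

    Walks the full ranked list accumulating hit/miss increments; the signed
    extremum is returned with |max| = |min| ties resolved toward the
    positive side (1e-12 guard against summation-order noise).
    """
    scores = np.asarray(scores, float)
    hits = np.asarray(hits, bool)
    n, k = len(scores), int(hits.sum())
    w = np.abs(scores) ** weight
    denom = w[hits].sum()
    if denom > 0:
        hit_inc = w / denom
    else:
        hit_inc = np.full(n, 1.0 / k)
    miss_dec = 1.0 / (n - k) if n > k else 0.0
    run = np.cumsum(np.where(hits, hit_inc, -miss_dec))
    mx, mn = run.max(), min(run.min(), 0.0)
    return float(mx if mx >= -mn - 1e-12 else mn)
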