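import math

import numpy as np
import pandas as pd
import pytest

from costress import SimulationConfig, simulate_experiment


def scalar_oracle_label(l2h: float, l2s: float, l2hs: float, tol: float = 0.5) -> str:
    """Independent per-gene reimplementation of the interaction statistic,
    written with plain math only, used to cross-check the vectorized path."""

    def pex(x):
        fc = 2.0 ** x if x >= 0 else -(2.0 ** abs(x))
        return fc - 1.0 if fc > 0 else fc + 1.0

    dev = pex(l2hs) - (pex(l2h) + pex(l2s))
    if dev > tol:
        return "enhanced"
    if dev < -tol:
        return "divergent"
    return "additive"


def brute_force_bh(p):
    """Step-up definition applied literally: q_i = min_{k>=i} p_(k)*m/k, capped."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic small experiment shared across tests."""
    cfg = SimulationConfig(n_genes=400, tissues=("shoot",), seed=7)
    truth, matrices = simulate_experiment(cfg)
    return cfg, truth, matrices["shoot"]


def contrast_from_truth(truth: pd.DataFrame, column: str) -> pd.DataFrame:
    """Noise-free contrast table built directly from planted log2FCs."""
    return pd.DataFrame({"gene_id": truth["gene_id"], "log2fc": truth[column]})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
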