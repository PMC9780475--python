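import numpy as np
import pandas as pd
import pytest

from tp53tme import SimulationConfig, load_signature


@pytest.fixture(scope="session")
def signature():
    return load_signature()


@pytest.fixture
def small_expr():
    """5 genes x 4 samples, strictly ordered expression per sample."""
    rng = np.random.default_rng(7)
    values = rng.lognormal(mean=2.0, sigma=1.0, size=(5, 4))
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(4)],
    )


@pytest.fixture
def sim_cfg():
    return SimulationConfig(n_samples=60, seed=11)


def es_bruteforce(ranks: dict, gene_set, alpha: float = 0.0) -> float:
    """Independent ECDF-difference summation: O(N^2), no cumulative sums.

    At each rank position i, recount from scratch the weighted member mass
    and the non-member count among the top-i genes.
    """
    genes = sorted(ranks, key=lambda g: (ranks[g], g))
    n = len(genes)
    members = [g for g in genes if g in gene_set]
    total_w = sum((n - ranks[g] + 1) ** alpha for g in members)
    n_out = n - len(members)
    es = 0.0
    for i in range(1, n + 1):
        top = genes[:i]
        w_in = sum((n - ranks[g] + 1) ** alpha for g in top if g in gene_set)
        c_out = sum(1 for g in top if g not in gene_set)
        es += w_in / total_w - c_out / n_out
    return es


def random_rank_instance(rng, max_genes=50, max_set=10):
    """Random strict ranking plus a random proper subset of the universe."""
    n = int(rng.integers(3, max_genes + 1))
    genes = [f"g{i}" for i in range(n)]
    perm = rng.permutation(n) + 1
    ranks = {g: int(r) for g, r in zip(genes, perm)}
    k = int(rng.integers(1, min(max_set, n - 1) + 1))
    gene_set = set(rng.choice(genes, size=k, replace=False))
    return ranks, gene_set
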