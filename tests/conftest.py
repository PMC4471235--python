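"""Shared fixtures: synthetic studies, their networks and module catalogs.

The heavy end-to-end objects (module discovery with 100 permutations,
connectivity-dynamics scoring) are session-scoped so the unit and
acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mdmodules as md
from mdmodules.dynamics import mcds, mcds_significance
from mdmodules.network import build_dcn
from mdmodules.pipeline import RunConfig, build_networks

SIM_SEED = 1
SEARCH_SEED = 2
MCDS_SEED = 3


@pytest.fixture(scope="session")
def small_sim():
    truth = md.default_fixture("small")
    panel, de, pheno, truth = md.simulate_panel(truth, np.random.default_rng(SIM_SEED))
    return panel, de, pheno, truth


@pytest.fixture(scope="session")
def small_dcns(small_sim):
    panel, de, _, _ = small_sim
    return build_networks(panel, de, RunConfig(expression="-", de_pvalues="-", delta=0.8))


@pytest.fixture(scope="session")
def small_mdms(small_dcns):
    return md.discover_mdms(small_dcns, n_rand=100, rng=np.random.default_rng(SEARCH_SEED))


@pytest.fixture(scope="session")
def rewiring_sim():
    truth = md.rewiring_fixture()
    panel, de, pheno, truth = md.simulate_panel(truth, np.random.default_rng(SIM_SEED))
    return panel, de, pheno, truth


@pytest.fixture(scope="session")
def rewiring_dcns(rewiring_sim):
    panel, de, _, _ = rewiring_sim
    return build_networks(panel, de, RunConfig(expression="-", de_pvalues="-", delta=0.8))


@pytest.fixture(scope="session")
def rewiring_mdms(rewiring_dcns):
    return md.discover_mdms(rewiring_dcns, n_rand=100, rng=np.random.default_rng(SEARCH_SEED))


@pytest.fixture(scope="session")
def rewiring_mcds(rewiring_dcns, rewiring_mdms):
    by_condition = {d.condition: d for d in rewiring_dcns}
    shared = [m for m in rewiring_mdms if m.level >= 2]
    results = [mcds(m, [by_condition[c] for c in m.subset]) for m in shared]
    return mcds_significance(
        results, by_condition, n_rand=100, rng=np.random.default_rng(MCDS_SEED)
    )


@pytest.fixture(scope="session")
def tiny_sim():
    truth = md.default_fixture("tiny")
    panel, de, pheno, truth = md.simulate_panel(truth, np.random.default_rng(SIM_SEED))
    return panel, de, pheno, truth


@pytest.fixture()
def toy_panel():
    """A hand-sized panel: 4 genes, baseline + one condition, 2 time
    points x 2 replicates each."""
    rng = np.random.default_rng(0)
    cols = pd.MultiIndex.from_tuples(
        [
            (c, t, r)
            for c in ("ctrl", "dis")
            for t in ("t1", "t2")
            for r in ("r1", "r2")
        ],
        names=["condition", "time", "replicate"],
    )
    vals = pd.DataFrame(
        rng.uniform(1, 10, (4, 8)),
        index=pd.Index([f"g{i}" for i in range(4)], name="gene"),
        columns=cols,
    )
    return md.ExpressionPanel(values=vals, baseline="ctrl")


def make_dcn(adj, condition="c1", genes=None, delta=0.8):
    adj = np.asarray(adj, dtype=float)
    if genes is None:
        genes = [f"g{i:02d}" for i in range(adj.shape[0])]
    return md.DCN(condition=condition, genes=list(genes), adjacency=adj, delta=delta)


@pytest.fixture()
def dcn_factory():
    return make_dcn


def clique_adjacency(n, size, weight=0.8, offset=0):
    """n x n adjacency with one `size`-clique at `offset`."""
    A = np.zeros((n, n))
    for i in range(offset, offset + size):
        for j in range(i + 1, offset + size):
            A[i, j] = A[j, i] = weight
    return A


@pytest.fixture()
def clique_factory():
    return clique_adjacency
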