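import numpy as np
import pytest

import pathorm as pm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_graph():
    """4 sites, 3 diseases, a couple of similarity and association edges."""
    sites = [f"s{i}" for i in range(4)]
    diseases = [f"d{j}" for j in range(3)]
    assoc = pm.AssociationTable(
        positives={("s0", "d0"), ("s1", "d2"), ("s3", "d1")},
        negatives={("s2", "d0"), ("s0", "d1")},
        site_index=sites,
        disease_index=diseases,
    )
    C_ss = np.zeros((4, 4))
    C_ss[0, 1] = C_ss[1, 0] = 1.0
    C_dd = np.zeros((3, 3))
    rng = np.random.default_rng(7)
    site_feats = pm.NamedMatrix(sites, rng.standard_normal((4, 5)))
    disease_feats = pm.NamedMatrix(diseases, rng.standard_normal((3, 5)))
    graph = pm.assemble_hetero_graph(
        C_ss, C_dd, assoc, site_feats, disease_feats, pm.GraphConfig(tau=0.5)
    )
    return graph, assoc


@pytest.fixture(scope="session")
def small_bundle():
    """Small synthetic dataset reused by pipeline-level tests."""
    return pm.simulate_dataset(
        pm.SynthParams(m=30, n=12, clusters=3, pos_count=60, window=11, seed=5)
    )
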