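import numpy as np
import pytest
import scipy.sparse as sp

import drugwalk as dw


@pytest.fixture(scope="session")
def toy_hierarchy():
    """Five-descriptor tree: R -> {A, B}, A -> {A1, A2}."""
    return dw.MeshHierarchy({
        "R": {"R"},
        "A": {"R.A"},
        "B": {"R.B"},
        "A1": {"R.A.1"},
        "A2": {"R.A.2"},
    })


@pytest.fixture(scope="session")
def default_bundle():
    return dw.generate(dw.SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def default_network(default_bundle):
    return dw.network_from_bundle(default_bundle, include_prior=True)


def random_network(rng, n_diseases=4, n_proteins=6, n_drugs=3, density=0.4,
                   with_prior=True):
    """A small random HeteroNetwork built directly from random matrices."""
    nd, np_, ng = n_diseases, n_proteins, n_drugs

    def bern(shape):
        return sp.csr_matrix((rng.random(shape) < density).astype(float))

    def sym01(n):
        m = np.where(rng.random((n, n)) < density, rng.random((n, n)), 0.0)
        m = np.triu(m, 1)
        m = m + m.T
        np.fill_diagonal(m, 1.0)
        return m

    s3 = np.triu(np.where(rng.random((np_, np_)) < density,
                          rng.random((np_, np_)), 0.0), 1)
    net = dw.HeteroNetwork(
        diseases=tuple(f"D{i}" for i in range(nd)),
        proteins=tuple(f"P{i}" for i in range(np_)),
        drugs=tuple(f"G{i}" for i in range(ng)),
        S1=bern((nd, np_)),
        S2=bern((np_, ng)),
        S3=sp.csr_matrix(s3 + s3.T),
        S4=sym01(ng),
        S5=sym01(nd),
        S6=bern((ng, nd)) if with_prior else sp.csr_matrix((ng, nd)),
    )
    return net
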