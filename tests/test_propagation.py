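"""Seed construction and the restart iteration against a linear-solve oracle."""

import numpy as np
import pytest
import scipy.sparse as sp

import drugwalk as dw
from drugwalk.propagation import ConvergenceError
from drugwalk.transition import build_blocks, weight_and_assemble

from conftest import random_network


def linear_solve_oracle(tm, p0, r):
    """Closed form of the restart fixed point: p = r (I - (1-r) M^T)^-1 p0."""
    m = tm.matrix.toarray()
    n = m.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1 - r) * m.T, p0)


class TestBuildSeed:
    def test_no_prior_mass_split_over_protein_and_drug_blocks(self, default_network):
        net = default_network
        w = dw.LayerWeights(0.5, 0.4, 0.1)
        drug = next(g for g in net.drugs if net.drug_targets(g))
        seed = dw.build_seed(net, drug, w, "no_prior")
        u0, v0, h0 = seed.blocks()
        assert u0.sum() == pytest.approx(0.0)
        # renormalized over b + c = 0.5: protein block 0.8, drug block 0.2
        assert v0.sum() == pytest.approx(0.8)
        assert h0.sum() == pytest.approx(0.2)
        assert h0[net.drug_pos(drug)] == pytest.approx(0.2)

    def test_targets_seeded_uniformly(self, default_network):
        net = default_network
        drug = next(g for g in net.drugs if len(net.drug_targets(g)) >= 2)
        seed = dw.build_seed(net, drug, dw.LayerWeights(), "no_prior")
        _, v0, _ = seed.blocks()
        vals = v0[v0 > 0]
        assert np.allclose(vals, vals[0])
        assert len(vals) == len(net.drug_targets(drug))

    def test_drug_without_targets_gets_all_mass(self):
        net = random_network(np.random.default_rng(0), density=0.0,
                             with_prior=False)
        seed = dw.build_seed(net, "G0", dw.LayerWeights(), "no_prior")
        _, v0, h0 = seed.blocks()
        assert v0.sum() == 0.0
        assert h0[0] == pytest.approx(1.0)

    def test_full_strategy_seeds_prior_diseases_with_weight_a(self, default_network):
        net = default_network
        w = dw.LayerWeights(0.5, 0.4, 0.1)
        drug = next(
            g for g in net.drugs
            if net.drug_prior_diseases(g) and net.drug_targets(g)
        )
        seed = dw.build_seed(net, drug, w, "full")
        u0, v0, h0 = seed.blocks()
        assert u0.sum() == pytest.approx(0.5)
        assert v0.sum() == pytest.approx(0.4)
        assert h0.sum() == pytest.approx(0.1)

    def test_unknown_drug_rejected(self, default_network):
        with pytest.raises(KeyError):
            dw.build_seed(default_network, "NOSUCH", dw.LayerWeights())

    def test_seed_sums_to_one(self, default_network):
        for drug in default_network.drugs[:5]:
            seed = dw.build_seed(default_network, drug, dw.LayerWeights(), "full")
            assert seed.p0.sum() == pytest.approx(1.0)


class TestPropagate:
    def test_restart_one_returns_seed_in_one_step(self, default_network):
        tm = dw.build_transition(default_network, "no_prior")
        seed = dw.build_seed(default_network, default_network.drugs[0])
        res = dw.propagate(tm, seed, r=1.0)
        assert res.iterations == 1
        assert np.array_equal(res.p_inf, seed.p0)

    def test_zero_matrix_fixed_point_is_r_p0(self):
        net = random_network(np.random.default_rng(1), density=0.0,
                             with_prior=False)
        s4 = np.eye(len(net.drugs))
        s5 = np.eye(len(net.diseases))
        net = dw.HeteroNetwork(net.diseases, net.proteins, net.drugs,
                               net.S1, net.S2, net.S3, s4, s5, net.S6)
        tm = dw.build_transition(net, "no_prior")
        seed = dw.build_seed(net, "G0")
        res = dw.propagate(tm, seed, r=0.7)
        assert np.allclose(res.p_inf, 0.7 * seed.p0, atol=1e-10)

    @pytest.mark.parametrize("seed_idx", range(10))
    def test_matches_dense_linear_solve(self, seed_idx):
        rng = np.random.default_rng(seed_idx)
        net = random_network(rng, n_diseases=6, n_proteins=10, n_drugs=4)
        tm = dw.build_transition(net, "full")
        seed = dw.build_seed(net, net.drugs[seed_idx % len(net.drugs)],
                             strategy="full")
        sigma = np.abs(np.linalg.eigvals(tm.matrix.toarray())).max()
        r = next(r for r in (0.3, 0.5, 0.7, 0.9) if (1 - r) * sigma < 0.9)
        res = dw.propagate(tm, seed, r=r, tol=1e-12)
        expected = linear_solve_oracle(tm, seed.p0, r)
        assert np.abs(res.p_inf - expected).sum() < 1e-8

    def test_fixed_point_residual_small(self, default_network):
        tm = dw.build_transition(default_network, "full")
        seed = dw.build_seed(default_network, default_network.drugs[0],
                             strategy="full")
        res = dw.propagate(tm, seed, r=0.7, tol=1e-10)
        mt = tm.matrix.T
        residual = np.abs(res.p_inf - ((1 - 0.7) * (mt @ res.p_inf) + 0.7 * seed.p0)).sum()
        assert residual < 1e-9

    def test_restart_monotonicity(self, default_network):
        tm = dw.build_transition(default_network, "no_prior")
        seed = dw.build_seed(default_network, default_network.drugs[0])
        dists = []
        for r in (0.3, 0.5, 0.7, 0.9, 0.99):
            res = dw.propagate(tm, seed, r=r)
            dists.append(np.abs(res.p_inf - seed.p0).sum())
        assert all(d1 >= d2 - 1e-12 for d1, d2 in zip(dists, dists[1:]))

    def test_divergence_detected_not_looped(self):
        # an expansive matrix (rescaled up by min-max from a tiny max entry)
        # must raise a convergence error with diagnostics, not spin
        n = 4
        m = sp.csr_matrix(np.full((n, n), 5.0))
        tm = dw.TransitionMatrix(matrix=m, strategy="no_prior",
                                 weights=dw.LayerWeights(), layer_sizes=(1, 2, 1))
        p0 = np.full(n, 0.25)
        seed = dw.SeedProfile(drug="x", p0=p0, layer_sizes=(1, 2, 1))
        with pytest.raises(ConvergenceError) as exc:
            dw.propagate(tm, seed, r=0.1)
        assert exc.value.iterations > 0

    def test_invalid_restart_rejected(self, default_network):
        tm = dw.build_transition(default_network, "no_prior")
        seed = dw.build_seed(default_network, default_network.drugs[0])
        with pytest.raises(ValueError, match="restart"):
            dw.propagate(tm, seed, r=0.0)


class TestPrioritize:
    def test_planted_disease_ranks_first(self):
        # only one disease is reachable from the seed drug
        nd, np_, ng = 3, 2, 1
        s1 = sp.csr_matrix(np.array([[1.0, 0], [0, 0], [0, 0]]))
        s2 = sp.csr_matrix(np.array([[1.0], [0.0]]))
        net = dw.HeteroNetwork(
            ("DA", "DB", "DC"), ("P0", "P1"), ("G0",),
            s1, s2, sp.csr_matrix((np_, np_)), np.eye(ng), np.eye(nd),
            sp.csr_matrix((ng, nd)),
        )
        tm = dw.build_transition(net, "no_prior")
        seed = dw.build_seed(net, "G0")
        res = dw.propagate(tm, seed, r=0.7)
        table = dw.prioritize(res, net)
        assert table.iloc[0]["disease_id"] == "DA"
        assert table.iloc[0]["score"] > table.iloc[1]["score"]

    def test_ties_broken_lexicographically(self, default_network):
        net = default_network
        res = dw.PropagationResult(
            seed=dw.build_seed(net, net.drugs[0]),
            p_inf=np.zeros(net.n_nodes), iterations=1, final_delta=0.0,
            restart=0.7,
        )
        table = dw.prioritize(res, net)
        assert list(table["disease_id"]) == sorted(net.diseases)
        assert np.allclose(table["top_percent"],
                           table["rank"] / len(net.diseases) * 100)

    def test_rank_one_of_hundred_is_top_one_percent(self):
        rng = np.random.default_rng(0)
        net = random_network(rng, n_diseases=100, n_proteins=5, n_drugs=2)
        res = dw.PropagationResult(
            seed=dw.build_seed(net, "G0"),
            p_inf=rng.random(net.n_nodes), iterations=1, final_delta=0.0,
            restart=0.7,
        )
        table = dw.prioritize(res, net)
        assert table.iloc[0]["top_percent"] == pytest.approx(1.0)

    def test_deterministic_rankings(self, default_network):
        tm = dw.build_transition(default_network, "full")
        drug = default_network.drugs[0]
        tables = []
        for _ in range(2):
            seed = dw.build_seed(default_network, drug, strategy="full")
            res = dw.propagate(tm, seed, r=0.7)
            tables.append(dw.prioritize(res, default_network))
        assert tables[0].equals(tables[1])
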