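"""Perturbation-factor propagation, pathway p-values, impact ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathmeta.impact import (
    PathwayGraph,
    compute_pf,
    fisher_combine,
    p_de_hypergeometric,
    p_pert_permutation,
    pathway_total_pf,
    run_impact_analysis,
)


def chain_graph():
    return PathwayGraph("chain", "chain", ["A", "B"], [("A", "B", 1.0)])


def two_cycle_graph():
    return PathwayGraph(
        "cyc", "cycle", ["A", "B"], [("A", "B", 1.0), ("B", "A", -1.0)]
    )


def random_graph(rng, n=12, density=0.15, repression=0.3):
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < density:
                beta = -1.0 if rng.random() < repression else 1.0
                edges.append((nodes[i], nodes[j], beta))
    return PathwayGraph("rnd", "random", nodes, edges)


class TestPathwayGraph:
    def test_out_degree_and_upstream_derived(self):
        g = PathwayGraph(
            "p", "p", ["A", "B", "C"],
            [("A", "B", 1.0), ("A", "C", -1.0), ("B", "C", 1.0)],
        )
        assert g.n_ds == {"A": 2, "B": 1, "C": 0}
        assert sorted(u for u, _ in g.upstream["C"]) == ["A", "B"]

    def test_parallel_edges_collapse_by_summing(self):
        g = PathwayGraph(
            "p", "p", ["A", "B"],
            [("A", "B", 1.0), ("A", "B", -1.0)],
        )
        assert len(g.edges) == 1
        assert g.edges[0][2] == 0.0

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="endpoint"):
            PathwayGraph("p", "p", ["A"], [("A", "Z", 1.0)])


class TestComputePf:
    def test_zero_input_zero_output(self):
        g = two_cycle_graph()
        pf = compute_pf(g, {"A": 0.0, "B": 0.0})
        assert pf == {"A": 0.0, "B": 0.0}
        assert pathway_total_pf(pf) == 0.0

    def test_chain_hand_propagation(self):
        # PF(A)=1; PF(B)=0 + 1*PF(A)/1 = 1; total 2
        pf = compute_pf(chain_graph(), {"A": 1.0, "B": 0.0})
        assert pf["A"] == pytest.approx(1.0)
        assert pf["B"] == pytest.approx(1.0)
        assert pathway_total_pf(pf) == pytest.approx(2.0)

    def test_two_cycle_hand_solution(self):
        # PF(A) = 1 - PF(B), PF(B) = PF(A)  =>  both 0.5
        pf = compute_pf(two_cycle_graph(), {"A": 1.0, "B": 0.0})
        assert pf["A"] == pytest.approx(0.5)
        assert pf["B"] == pytest.approx(0.5)

    def test_linearity_in_delta_e(self):
        rng = np.random.default_rng(3)
        g = random_graph(rng)
        d1 = {n: rng.normal() for n in g.nodes}
        d2 = {n: rng.normal() for n in g.nodes}
        mix = {n: 2.0 * d1[n] - 0.5 * d2[n] for n in g.nodes}
        pf1, pf2, pfm = (compute_pf(g, d) for d in (d1, d2, mix))
        for n in g.nodes:
            assert pfm[n] == pytest.approx(2 * pf1[n] - 0.5 * pf2[n], abs=1e-9)

    def test_matches_damped_fixed_point_iteration(self):
        # independent oracle: iterate PF <- dE + B.PF when rho(B) < 1
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 30:
            g = random_graph(rng, n=rng.integers(5, 15))
            b = g.propagation_matrix()
            if np.max(np.abs(np.linalg.eigvals(b))) >= 0.95:
                continue
            de = rng.normal(size=len(g))
            pf_vec = np.zeros(len(g))
            for _ in range(3000):
                nxt = de + b @ pf_vec
                if np.max(np.abs(nxt - pf_vec)) < 1e-12:
                    break
                pf_vec = nxt
            pf = compute_pf(g, dict(zip(g.nodes, de)))
            assert np.allclose([pf[n] for n in g.nodes], pf_vec, atol=1e-8)
            checked += 1

    def test_missing_delta_e_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compute_pf(chain_graph(), {"A": 1.0})

    def test_singular_system_flagged_untestable(self):
        # A->B and B->A both activation with out-degree 1: I - B singular
        g = PathwayGraph(
            "sing", "singular", ["A", "B"],
            [("A", "B", 1.0), ("B", "A", 1.0)],
        )
        assert not g.is_testable()
        with pytest.raises(ValueError, match="untestable"):
            compute_pf(g, {"A": 1.0, "B": 0.0})

    def test_accumulation_weights_give_same_total(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            g = random_graph(rng)
            if not g.is_testable():
                continue
            de = {n: rng.normal() for n in g.nodes}
            total = pathway_total_pf(compute_pf(g, de))
            w = g.accumulation_weights()
            assert total == pytest.approx(
                float(w @ np.array([de[n] for n in g.nodes])), abs=1e-9
            )


class TestPdeHypergeometric:
    def test_zero_hits_certain(self):
        assert p_de_hypergeometric(0, 10, 5, 100) == 1.0

    def test_matches_enumeration(self):
        import math

        def enum(k, K, n, N):
            num = sum(
                math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(k, min(K, n) + 1)
            )
            return num / math.comb(N, n)

        assert p_de_hypergeometric(3, 5, 10, 50) == pytest.approx(
            enum(3, 5, 10, 50), abs=1e-12
        )
        assert p_de_hypergeometric(4, 4, 4, 12) == pytest.approx(
            enum(4, 4, 4, 12), abs=1e-12
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            p_de_hypergeometric(6, 5, 10, 50)
        with pytest.raises(ValueError):
            p_de_hypergeometric(1, 60, 10, 50)


class TestPpertPermutation:
    def test_deterministic_given_seed(self):
        g = chain_graph()
        sig = {"A": 1.3}
        a = p_pert_permutation(g, sig, {"A", "B"}, n_perm=300, rng=5)
        b = p_pert_permutation(g, sig, {"A", "B"}, n_perm=300, rng=5)
        assert a == b

    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(6)
        g = random_graph(rng, n=20)
        sig = {g.nodes[0]: 5.0}
        p, _, _ = p_pert_permutation(g, sig, set(g.nodes), n_perm=200, rng=1)
        assert p >= 1 / 201 - 1e-12

    def test_no_signature_on_pathway_returns_one(self):
        p, obs, med = p_pert_permutation(
            chain_graph(), {"Z": 1.0}, {"A", "B"}, n_perm=200, rng=0
        )
        assert (p, obs, med) == (1.0, 0.0, 0.0)

    def test_null_signature_p_is_uniform(self):
        # a random, randomly-signed signature should give calibrated p
        rng = np.random.default_rng(90)
        g = random_graph(rng, n=30, density=0.1)
        assert g.is_testable()
        ps = []
        for rep in range(500):
            nodes = rng.choice(g.nodes, size=5, replace=False)
            sig = {n: rng.choice([-1.0, 1.0]) * rng.normal(1, 0.2)
                   for n in nodes}
            p, _, _ = p_pert_permutation(
                g, sig, set(g.nodes), n_perm=199, rng=np.random.default_rng(rep)
            )
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFisherCombine:
    def test_both_one_gives_one(self):
        assert fisher_combine(1.0, 1.0) == pytest.approx(1.0)

    def test_closed_form_with_one_trivial_component(self):
        # Fisher with k=2 and one p=1: combined = p * (1 - ln p)
        for p in (0.001, 0.05, 0.5):
            assert fisher_combine(p, 1.0) == pytest.approx(
                p * (1 - np.log(p)), rel=1e-10
            )

    def test_chi_square_oracle(self):
        x = -4.0 * np.log(0.05)
        assert fisher_combine(0.05, 0.05) == pytest.approx(
            stats.chi2.sf(x, 4), rel=1e-12
        )

    def test_zero_inputs_survive(self):
        assert 0.0 < fisher_combine(0.0, 0.5) < 1.0


class TestRunImpactAnalysis:
    @staticmethod
    def _gene_stats(genes, selected=(), mu=1.0):
        df = pd.DataFrame(
            {"mu": 0.0, "selected": False},
            index=pd.Index(genes, name="gene"),
        )
        df.loc[list(selected), "mu"] = mu
        df.loc[list(selected), "selected"] = True
        return df

    def test_empty_signature_nothing_significant(self):
        rng = np.random.default_rng(2)
        graphs = [random_graph(rng) for _ in range(5)]
        genes = sorted({n for g in graphs for n in g.nodes})
        out = run_impact_analysis(
            graphs, self._gene_stats(genes), n_perm=200, seed=1
        )
        assert not out["significant"].any()
        assert np.allclose(out.loc[out["testable"], "p_pert"], 1.0)

    def test_result_invariants(self, small_workspace):
        _, studies, truth, pathways, planted = small_workspace
        genes = list(truth.index)
        selected = list(truth.index[truth["mu_true"] > 0][:12])
        out = run_impact_analysis(
            pathways, self._gene_stats(genes, selected), n_perm=200, seed=9
        )
        ok = out[out["testable"]]
        assert np.all((ok["p_de"] > 0) & (ok["p_de"] <= 1))
        assert np.all(ok["p_pert"] >= 1 / 201 - 1e-12)
        assert list(out["rank"]) == list(range(1, len(out) + 1))
        fdrs = ok["fdr"].to_numpy()
        assert np.all(np.diff(fdrs) >= -1e-12)

    def test_independent_of_pathway_order(self, small_workspace):
        _, _, truth, pathways, _ = small_workspace
        genes = list(truth.index)
        selected = list(truth.index[truth["is_de"]][:10])
        stats_df = self._gene_stats(genes, selected)
        fwd = run_impact_analysis(pathways, stats_df, n_perm=200, seed=4)
        rev = run_impact_analysis(pathways[::-1], stats_df, n_perm=200, seed=4)
        fwd = fwd.sort_values("pathway_id").reset_index(drop=True)
        rev = rev.sort_values("pathway_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(fwd, rev)
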