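import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnherit.dag import (
    GRNParams,
    er_edge_prob,
    generate_ppm_dag,
    generate_scalefree_dag,
    ppm_edge_probs,
    ppm_rm_from_probs,
    read_edgelist,
    topology_stats,
    write_edgelist,
)
from grnherit.sem import assign_signs

from conftest import make_topology


class TestReparameterization:
    def test_worked_example(self):
        pr = ppm_edge_probs(GRNParams(n=5000, k=10, m=0.5, r=5))
        assert pr.p == pytest.approx(50 / 4999, abs=1e-15)
        assert pr.q == pytest.approx(50 / 44991, abs=1e-15)

    def test_fully_modular_has_no_between_edges(self):
        pr = ppm_edge_probs(GRNParams(n=5000, k=10, m=1.0, r=5))
        assert pr.q == 0.0

    def test_probability_bound_is_a_hard_error(self):
        with pytest.raises(ValueError, match="probability"):
            ppm_edge_probs(GRNParams(n=3, k=2, m=0.9, r=2))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="er_edge_prob"):
            ppm_edge_probs(GRNParams(n=100, k=1, r=2))

    @given(
        n=st.integers(100, 5000),
        k=st.integers(2, 20),
        r=st.floats(0.1, 5),
        mx=st.floats(0.01, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, n, k, r, mx):
        """Forward then inverse reparameterization recovers (r, m) to 1e-12."""
        m = 1.0 / k + mx * (1.0 - 1.0 / k)
        if m <= 1.0 / k:
            return
        params = GRNParams(n=n, k=k, m=m, r=r)
        try:
            pr = ppm_edge_probs(params)
        except ValueError:
            return
        r2, m2 = ppm_rm_from_probs(n, k, pr)
        assert r2 == pytest.approx(r, abs=1e-12)
        assert m2 == pytest.approx(m, abs=1e-12)

    @pytest.mark.parametrize(
        "n,r,expected", [(1001, 5, 0.01), (2, 0.5, 1.0)]
    )
    def test_er_prob(self, n, r, expected):
        assert er_edge_prob(n, r) == pytest.approx(expected)

    def test_er_prob_bound(self):
        with pytest.raises(ValueError):
            er_edge_prob(3, 2)

    def test_dissociative_regime_rejected(self):
        with pytest.raises(ValueError, match="dissociative"):
            GRNParams(n=50, k=2, m=0.4, r=3)


class TestPPMGenerator:
    def test_zero_regulators_gives_empty_graph(self):
        topo = generate_ppm_dag(GRNParams(n=100, k=1, r=0), seed=1)
        assert topo.n_edges == 0

    def test_determinism(self):
        params = GRNParams(n=200, k=4, m=0.7, r=3)
        a = generate_ppm_dag(params, seed=9)
        b = generate_ppm_dag(params, seed=9)
        assert np.array_equal(a.edges, b.edges)
        assert np.array_equal(a.topo_index, b.topo_index)
        assert np.array_equal(a.groups, b.groups)
        c = generate_ppm_dag(params, seed=10)
        assert not np.array_equal(a.edges, c.edges)

    def test_structural_validity(self):
        for seed in range(5):
            topo = generate_ppm_dag(GRNParams(n=120, k=3, m=0.8, r=4), seed=seed)
            topo.validate()  # acyclic by index, no self/duplicate edges

    def test_calibration_over_seeds(self):
        """Realized mean in-degree and within-group fraction within 3
        binomial standard errors of (r, m) over 200 seeds."""
        n, k, r, m = 500, 5, 4.0, 0.8
        params = GRNParams(n=n, k=k, m=m, r=r)
        indeg, within, edges = [], [], 0
        for seed in range(200):
            st_ = topology_stats(generate_ppm_dag(params, seed))
            indeg.append(st_.mean_in_degree)
            within.append(st_.within_group_fraction)
            edges += st_.n_edges
        # each network has ~n*r edges; treat edges as Bernoulli draws
        se_r = np.sqrt(r / (200 * n))  # Poisson-scale error of the mean in-degree
        assert abs(np.mean(indeg) - r) < 3 * se_r
        se_m = np.sqrt(m * (1 - m) / edges)
        assert abs(np.mean(within) - m) < 3 * se_m


class TestScaleFreeGenerator:
    def test_requires_positive_d(self):
        with pytest.raises(ValueError):
            GRNParams(n=100, k=1, r=2, d=0.0)
        with pytest.raises(ValueError, match="uniformity"):
            generate_scalefree_dag(GRNParams(n=100, k=1, r=2), seed=0)

    def test_zero_regulators(self):
        topo = generate_scalefree_dag(GRNParams(n=10, k=1, r=0, d=1.0), seed=0)
        assert topo.n_edges == 0

    def test_determinism_and_validity(self):
        params = GRNParams(n=150, k=3, m=0.7, r=4, d=2.0)
        a = generate_scalefree_dag(params, seed=5)
        b = generate_scalefree_dag(params, seed=5)
        assert np.array_equal(a.edges, b.edges)
        a.validate()

    def test_mean_in_degree_matches_r(self):
        params = GRNParams(n=500, k=5, m=0.8, r=4, d=3.0)
        indeg = [
            topology_stats(generate_scalefree_dag(params, s)).mean_in_degree
            for s in range(100)
        ]
        se = np.sqrt(4.0 / (100 * 500))
        assert abs(np.mean(indeg) - 4.0) < 3 * se

    def test_within_group_fraction_near_m(self):
        # the sequential construction matches m conditionally per pick;
        # without-replacement drift leaves a small residual bias
        params = GRNParams(n=500, k=5, m=0.8, r=4, d=3.0)
        within = [
            topology_stats(generate_scalefree_dag(params, s)).within_group_fraction
            for s in range(50)
        ]
        assert abs(np.mean(within) - 0.8) < 0.02

    def test_large_d_limit_matches_er_outdegree_variance(self):
        """With d large, preferential attachment vanishes and the
        out-degree spread matches the ER case at equal r (ratio within 10%)."""
        sf = GRNParams(n=500, k=1, r=4, d=1e6)
        er = GRNParams(n=500, k=1, r=4)
        v_sf = np.mean(
            [topology_stats(generate_scalefree_dag(sf, s)).out_degree_variance for s in range(100)]
        )
        v_er = np.mean(
            [topology_stats(generate_ppm_dag(er, s)).out_degree_variance for s in range(100)]
        )
        assert abs(v_sf / v_er - 1.0) < 0.10

    def test_outdegree_variance_monotone_in_d(self):
        """Smaller d concentrates regulation in hubs: average out-degree
        variance is non-increasing on d in {1, 3, 10, 30} and d=1 beats
        d=30 in >=95% of paired seeds."""
        means = {}
        per_seed = {}
        for d in (1.0, 3.0, 10.0, 30.0):
            params = GRNParams(n=500, k=1, r=4, d=d)
            vs = [
                topology_stats(generate_scalefree_dag(params, s)).out_degree_variance
                for s in range(100)
            ]
            means[d] = np.mean(vs)
            per_seed[d] = np.asarray(vs)
        assert means[1.0] >= means[3.0] >= means[10.0] >= means[30.0]
        wins = np.mean(per_seed[1.0] > per_seed[30.0])
        assert wins >= 0.95


class TestTopologyStats:
    def test_chain(self, chain3):
        st_ = topology_stats(chain3)
        assert st_.mean_in_degree == pytest.approx(2 / 3)
        assert st_.n_edges == 2

    def test_empty(self):
        topo = make_topology(5, np.empty((0, 2)))
        assert topology_stats(topo).mean_in_degree == 0.0

    def test_complete_dag_on_four(self):
        edges = [[i, j] for i in range(4) for j in range(i + 1, 4)]
        st_ = topology_stats(make_topology(4, edges))
        assert st_.mean_in_degree == pytest.approx(1.5)
        assert st_.n_edges == 6


def test_edgelist_round_trip(tmp_path):
    params = GRNParams(n=60, k=3, m=0.8, r=3)
    topo = generate_ppm_dag(params, seed=2)
    grn = assign_signs(topo, 0.7, 0.3, seed=3)
    write_edgelist(topo, tmp_path / "e.tsv", tmp_path / "n.tsv", signs=grn.signs)
    back, signs = read_edgelist(tmp_path / "e.tsv", tmp_path / "n.tsv")
    assert back.n == topo.n
    assert set(map(tuple, back.edges.tolist())) == set(map(tuple, topo.edges.tolist()))
    assert np.array_equal(back.topo_index, topo.topo_index)
    assert np.array_equal(back.groups, topo.groups)
    assert np.array_equal(signs, grn.signs)
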