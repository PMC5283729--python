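import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metabolokit.core_data import Dataset
from metabolokit.networks import (
    BumFit,
    Fingerprint,
    NetworkError,
    WeightedNetwork,
    bum_tau,
    correlation_network,
    fit_bum,
    max_scoring_subnetwork,
    partial_correlation_network,
    score_nodes,
    tanimoto,
    tanimoto_network,
)
from metabolokit.fixtures import random_fingerprints, simulate_pvalues


def _ds(mat):
    m = pd.DataFrame(
        mat, index=[f"F{i}" for i in range(len(mat))],
        columns=[f"S{j}" for j in range(len(mat[0]))],
    )
    return Dataset(m)


class TestCorrelationNetwork:
    def test_exact_linear_dependence_passes_default_threshold(self):
        x = np.arange(1.0, 9.0)
        net = correlation_network(_ds([x, 2 * x, np.exp(-x)]), "pearson", threshold=0.7)
        assert net.graph.has_edge("F0", "F1")
        assert net.graph["F0"]["F1"]["weight"] == pytest.approx(1.0)

    def test_negative_correlation_kept_by_absolute_threshold(self):
        x = np.arange(1.0, 9.0)
        net = correlation_network(_ds([x, -x]), "pearson", threshold=0.7)
        assert net.graph.has_edge("F0", "F1")
        assert net.graph["F0"]["F1"]["weight"] == pytest.approx(-1.0)

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = x + rng.normal(0, 0.5, size=20)
        a = correlation_network(_ds([x, y]), "spearman", threshold=0.0)
        b = correlation_network(_ds([x, np.exp(y)]), "spearman", threshold=0.0)
        assert a.graph["F0"]["F1"]["weight"] == pytest.approx(
            b.graph["F0"]["F1"]["weight"], abs=1e-12
        )

    def test_constant_feature_excluded_with_warning(self):
        x = np.arange(1.0, 9.0)
        with pytest.warns(UserWarning, match="constant"):
            net = correlation_network(_ds([x, np.full(8, 3.0)]), threshold=0.5)
        assert "F1" not in net.graph.nodes

    def test_edge_count_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        d = _ds(rng.normal(size=(10, 15)).tolist())
        counts = [
            correlation_network(d, threshold=t).n_edges for t in (0.1, 0.4, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestPartialCorrelation:
    def test_two_features_equal_marginal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 0.8 * x + rng.normal(0, 0.5, size=30)
        z = rng.normal(size=30)
        d = _ds([x, y, z])
        # with an independent third variable, pcor(x,y|z) ~ marginal r(x,y)
        net = partial_correlation_network(d, threshold=0.0, shrinkage=0.0)
        r = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        expected = (r - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert net.graph["F0"]["F1"]["weight"] == pytest.approx(expected, abs=1e-10)

    def test_chain_conditional_independence(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        y = x + rng.normal(0, 0.6, size=2000)
        z = y + rng.normal(0, 0.6, size=2000)
        net = partial_correlation_network(_ds([x, y, z]), threshold=0.0)
        assert abs(net.graph["F0"]["F2"]["weight"]) < 0.1
        assert abs(net.graph["F0"]["F1"]["weight"]) > 0.3

    def test_too_few_samples_rejected(self):
        d = _ds(np.random.default_rng(4).normal(size=(3, 3)).tolist())
        with pytest.raises(NetworkError):
            partial_correlation_network(d)


class TestTanimoto:
    def test_hand_counted_values(self):
        a = Fingerprint("a", {1, 2, 3})
        b = Fingerprint("b", {2, 3, 4})
        assert tanimoto(a, b) == pytest.approx(0.5)
        assert tanimoto(a, Fingerprint("c", {1, 2, 3})) == 1.0
        assert tanimoto(a, Fingerprint("d", {7, 8})) == 0.0

    def test_network_thresholding_and_zero_fp_exclusion(self):
        fps = [
            Fingerprint("a", {1, 2, 3}),
            Fingerprint("b", {2, 3, 4}),
            Fingerprint("c", {1, 2, 3}),
        ]
        net = tanimoto_network(fps, threshold=0.7)
        assert net.graph.has_edge("a", "c") and not net.graph.has_edge("a", "b")
        with pytest.warns(UserWarning, match="all-zero"):
            tanimoto_network(fps + [Fingerprint("z", set())], threshold=0.7)

    def test_expected_similarity_of_random_fingerprints(self):
        # independent Bernoulli(q) bits: E[T] ~ q/(2-q)
        q = 0.2
        fps = random_fingerprints(40, length=881, density=q, seed=5)
        sims = [tanimoto(a, b) for a, b in itertools.combinations(fps, 2)]
        assert np.mean(sims) == pytest.approx(q / (2 - q), abs=0.01)

    def test_bit_positions_validated(self):
        with pytest.raises(NetworkError):
            Fingerprint("a", {900}, length=881)


class TestBum:
    @pytest.mark.parametrize("lam", [0.5, 0.7, 0.9])
    @pytest.mark.parametrize("a", [0.2, 0.4, 0.6])
    def test_parameter_recovery(self, lam, a):
        # estimator recovery: average the ML fit over replicate draws to
        # separate bias from single-sample variability
        fits = [
            fit_bum(simulate_pvalues(lam, a, 5000, seed=1000 * rep + int(lam * 100 + a * 10)))
            for rep in range(3)
        ]
        assert np.mean([f.lam for f in fits]) == pytest.approx(lam, abs=0.05)
        assert np.mean([f.a for f in fits]) == pytest.approx(a, abs=0.05)

    def test_uniform_null_has_no_signal_mass(self):
        p = simulate_pvalues(1.0, 0.5, 5000, seed=6)
        fit = fit_bum(p)
        assert (1 - fit.lam) * (1 - fit.a) < 0.05

    def test_fit_likelihood_not_worse_than_truth(self):
        lam, a = 0.7, 0.3
        p = simulate_pvalues(lam, a, 3000, seed=7)
        fit = fit_bum(p)
        truth_ll = np.sum(np.log(lam + (1 - lam) * a * p ** (a - 1)))
        assert fit.log_likelihood >= truth_ll - 1e-6

    def test_score_sign_and_monotonicity(self):
        fit = BumFit(lam=0.7, a=0.3, fdr=0.05, tau=bum_tau(0.7, 0.3, 0.05))
        s = score_nodes(fit, {"x": fit.tau, "lo": fit.tau / 10, "hi": min(1.0, fit.tau * 10)})
        assert s["x"] == pytest.approx(0, abs=1e-12)
        assert s["lo"] > 0 > s["hi"]
        ps = np.linspace(1e-6, 1, 50)
        vals = [score_nodes(fit, {"n": p})["n"] for p in ps]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_zero_pvalues_clipped_with_warning(self):
        p = np.concatenate([[0.0], simulate_pvalues(0.8, 0.5, 500, seed=8)])
        with pytest.warns(UserWarning, match="clipped"):
            fit_bum(p)


def _exhaustive_best(g, scores):
    best = -np.inf
    for r in range(1, g.number_of_nodes() + 1):
        for comb in itertools.combinations(g.nodes, r):
            if nx.is_connected(g.subgraph(comb)):
                best = max(best, sum(scores[n] for n in comb))
    return best


class TestSubnetwork:
    def test_star_with_single_positive_center(self):
        g = nx.star_graph(4)
        scores = {0: 3.0, 1: -1.0, 2: -1.0, 3: -1.0, 4: -1.0}
        sub, total = max_scoring_subnetwork(WeightedNetwork(g), scores)
        assert set(sub.graph.nodes) == {0} and total == 3.0

    def test_positive_ends_bridge_negative_middle(self):
        net = WeightedNetwork.from_edges([("A", "B", 1.0), ("B", "C", 1.0)])
        sub, total = max_scoring_subnetwork(net, {"A": 2.0, "B": -1.0, "C": 2.0})
        assert set(sub.graph.nodes) == {"A", "B", "C"} and total == pytest.approx(3.0)

    def test_all_negative_returns_best_single_node(self):
        net = WeightedNetwork.from_edges([("A", "B", 1.0)])
        with pytest.warns(UserWarning, match="negative"):
            sub, total = max_scoring_subnetwork(net, {"A": -2.0, "B": -0.5})
        assert set(sub.graph.nodes) == {"B"} and total == -0.5

    def test_heuristic_within_90pct_of_exhaustive_optimum(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 11))
            g = nx.gnp_random_graph(n, 0.35, seed=seed)
            if g.number_of_edges() == 0:
                g.add_edge(0, 1)
            scores = {i: float(rng.normal(0, 1.5)) for i in g.nodes}
            if all(v < 0 for v in scores.values()):
                continue
            _sub, total = max_scoring_subnetwork(WeightedNetwork(g), scores)
            opt = _exhaustive_best(g, scores)
            assert total >= 0.9 * opt - 1e-9, f"seed {seed}: {total} < 0.9*{opt}"

    def test_result_is_connected_subgraph_with_score_at_least_best_node(self):
        rng = np.random.default_rng(42)
        g = nx.gnp_random_graph(12, 0.3, seed=1)
        scores = {i: float(rng.normal()) for i in g.nodes}
        sub, total = max_scoring_subnetwork(WeightedNetwork(g), scores)
        assert nx.is_connected(sub.graph)
        assert set(sub.graph.edges) <= set(g.edges) | {(v, u) for u, v in g.edges}
        assert total >= max(scores.values()) - 1e-12
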