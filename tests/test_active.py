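"""Scoring, background calibration and the annealing sub-network search."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import norm

from stpnet.active import (
    NodeScores,
    SAConfig,
    calibrate_background,
    corrected_score,
    find_active_subnetwork,
    iterated_search,
    module_score_significance,
    p_to_z,
    read_scores,
    score_subnetwork,
    shared_interactors,
)
from stpnet.errors import DegenerateBackgroundError, StpnetError

from conftest import make_network


class TestPToZ:
    def test_median_maps_to_zero(self):
        assert p_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_known_quantile(self):
        # numerical inversion of the standard normal CDF: Phi(2) ~ 0.9772499
        assert p_to_z(0.0227501) == pytest.approx(2.000, abs=1e-3)

    def test_clamping_keeps_extremes_finite(self):
        z0 = p_to_z(0.0, epsilon=1e-16)
        assert math.isfinite(z0)
        assert z0 == pytest.approx(norm.isf(1e-16))
        assert math.isfinite(p_to_z(1.0))

    def test_monotone_decreasing(self):
        ps = np.linspace(0.001, 0.999, 50)
        zs = p_to_z(ps)
        assert (np.diff(zs) < 0).all()

    @pytest.mark.parametrize("bad", [-0.1, 1.1, float("nan")])
    def test_domain_errors(self, bad):
        with pytest.raises(StpnetError):
            p_to_z(bad)


class TestScoreSubnetwork:
    def test_singleton_equals_z(self):
        zs = NodeScores.from_zscores({"A": 2.0})
        assert score_subnetwork(zs, ["A"]) == 2.0

    def test_closed_form(self):
        zs = NodeScores.from_zscores({c: 1.0 for c in "ABCD"})
        assert score_subnetwork(zs, list("ABCD")) == pytest.approx(2.0)

    def test_hand_evaluation(self):
        zs = NodeScores.from_zscores({"A": 0.5, "B": -0.3, "C": 1.2})
        assert score_subnetwork(zs, ["A", "B", "C"]) == pytest.approx(
            1.4 / math.sqrt(3)
        )

    def test_permutation_invariant(self):
        zs = NodeScores.from_zscores({"A": 0.5, "B": -0.3, "C": 1.2})
        assert score_subnetwork(zs, ["C", "A", "B"]) == score_subnetwork(
            zs, ["A", "B", "C"]
        )

    def test_missing_member_errors(self):
        zs = NodeScores.from_zscores({"A": 1.0})
        with pytest.raises(StpnetError):
            score_subnetwork(zs, ["A", "B"])
        with pytest.raises(StpnetError):
            score_subnetwork(zs, [])


class TestBackground:
    def test_degenerate_scores(self):
        zs = {f"G{i}": 1.5 for i in range(30)}
        bg = calibrate_background(zs, max_k=5, n_samples=200, seed=0)
        for k in range(1, 6):
            assert bg.mu_of(k) == pytest.approx(1.5 * math.sqrt(k))
            assert bg.sigma_of(k) == pytest.approx(0.0, abs=1e-12)

    def test_standard_normal_calibration(self):
        rng = np.random.default_rng(42)
        zs = {f"G{i:03d}": float(z) for i, z in enumerate(rng.normal(size=500))}
        bg = calibrate_background(zs, max_k=20, n_samples=2000, seed=1)
        for k in (5, 10, 20):
            assert abs(bg.mu_of(k)) < 0.1
            assert abs(bg.sigma_of(k) - 1.0) < 0.1

    def test_deterministic_under_seed(self):
        zs = {f"G{i}": float(i) / 7 for i in range(40)}
        a = calibrate_background(zs, max_k=10, n_samples=300, seed=9)
        b = calibrate_background(zs, max_k=10, n_samples=300, seed=9)
        assert (a.mu == b.mu).all() and (a.sigma == b.sigma).all()

    def test_sample_floor(self):
        with pytest.raises(StpnetError):
            calibrate_background({"A": 1.0, "B": 2.0}, max_k=2, n_samples=1, seed=0)


class TestCorrectedScore:
    def test_reference_points(self):
        zs = {f"G{i}": 1.5 for i in range(10)}
        bg = calibrate_background(zs, max_k=4, n_samples=100, seed=0)
        # degenerate sigma: exercise the documented error below; use a
        # synthetic model for arithmetic
        bg.sigma[:] = 1.1
        bg.mu[:] = 0.2
        assert corrected_score(0.2, 2, bg) == pytest.approx(0.0)
        assert corrected_score(0.2 + 1.1, 2, bg) == pytest.approx(1.0)
        assert corrected_score(2.5, 3, bg) == pytest.approx(2.0909, abs=1e-4)

    def test_zero_sigma_raises(self):
        zs = {f"G{i}": 1.0 for i in range(10)}
        bg = calibrate_background(zs, max_k=3, n_samples=100, seed=0)
        with pytest.raises(DegenerateBackgroundError):
            corrected_score(5.0, 2, bg)


def _line_network(n, prefix="G"):
    return make_network(
        [(f"{prefix}{i:02d}", f"{prefix}{i + 1:02d}") for i in range(n - 1)]
    )


class TestAnnealingSearch:
    def test_single_strong_node_wins(self):
        net = _line_network(9)
        zmap = {n: -3.0 for n in net.node_ids}
        zmap["G04"] = 3.0
        zs = NodeScores.from_zscores(zmap)
        bg = calibrate_background(zs, max_k=9, n_samples=500, seed=0)
        res = find_active_subnetwork(net, zs, bg, SAConfig(seed=3))
        assert set(res.members) == {"G04"}

    def test_equal_scores_give_null_result(self):
        net = _line_network(8)
        zs = NodeScores.from_zscores({n: 0.7 for n in net.node_ids})
        bg = calibrate_background(zs, max_k=8, n_samples=300, seed=0)
        res = find_active_subnetwork(net, zs, bg, SAConfig(seed=1))
        assert res.corrected_score == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        net = _line_network(30)
        zs = NodeScores.from_zscores(
            {n: float(z) for n, z in zip(net.node_ids, rng.normal(size=30))}
        )
        bg = calibrate_background(zs, max_k=30, n_samples=300, seed=5)
        r1 = find_active_subnetwork(net, zs, bg, SAConfig(seed=11))
        r2 = find_active_subnetwork(net, zs, bg, SAConfig(seed=11))
        assert r1.members == r2.members
        assert r1.corrected_score == r2.corrected_score

    def test_trace_is_nondecreasing(self):
        rng = np.random.default_rng(2)
        net = _line_network(25)
        zs = NodeScores.from_zscores(
            {n: float(z) for n, z in zip(net.node_ids, rng.normal(size=25))}
        )
        bg = calibrate_background(zs, max_k=25, n_samples=300, seed=2)
        res = find_active_subnetwork(net, zs, bg, SAConfig(seed=7))
        scores = [s for _, s in res.best_trace]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_result_recomputable_from_members(self):
        rng = np.random.default_rng(4)
        net = _line_network(20)
        zs = NodeScores.from_zscores(
            {n: float(z) for n, z in zip(net.node_ids, rng.normal(size=20))}
        )
        bg = calibrate_background(zs, max_k=20, n_samples=300, seed=4)
        res = find_active_subnetwork(net, zs, bg, SAConfig(seed=5))
        assert res.raw_score == pytest.approx(
            score_subnetwork(zs, res.members), abs=1e-9
        )
        assert res.corrected_score == pytest.approx(
            corrected_score(res.raw_score, res.k, bg), abs=1e-9
        )

    def test_members_induce_connected_subgraph(self):
        rng = np.random.default_rng(6)
        from conftest import random_gnp

        net = random_gnp(rng, 30, 0.12)
        zs = NodeScores.from_zscores(
            {n: float(z) for n, z in zip(net.node_ids, rng.normal(size=30))}
        )
        bg = calibrate_background(zs, max_k=30, n_samples=300, seed=6)
        res = find_active_subnetwork(net, zs, bg, SAConfig(seed=8))
        import networkx as nx

        sub = net.graph.subgraph(res.members)
        assert nx.is_connected(sub)

    def test_invariant_to_order_preserving_relabeling(self):
        rng = np.random.default_rng(12)
        zvals = rng.normal(size=15)
        net1 = _line_network(15, prefix="A")
        net2 = _line_network(15, prefix="B")
        zs1 = NodeScores.from_zscores(
            {n: float(z) for n, z in zip(net1.node_ids, zvals)}
        )
        zs2 = NodeScores.from_zscores(
            {n: float(z) for n, z in zip(net2.node_ids, zvals)}
        )
        bg1 = calibrate_background(zs1, max_k=15, n_samples=200, seed=3)
        bg2 = calibrate_background(zs2, max_k=15, n_samples=200, seed=3)
        r1 = find_active_subnetwork(net1, zs1, bg1, SAConfig(seed=9))
        r2 = find_active_subnetwork(net2, zs2, bg2, SAConfig(seed=9))
        assert {m[1:] for m in r1.members} == {m[1:] for m in r2.members}

    def test_empty_universe_rejected(self):
        net = _line_network(5)
        zs = NodeScores.from_zscores({n: 0.0 for n in net.node_ids})
        bg = calibrate_background(zs, max_k=5, n_samples=100, seed=0)
        with pytest.raises(StpnetError):
            find_active_subnetwork(net, zs, bg, SAConfig(seed=0), restrict_to=[])


class TestIteratedSearch:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        net = _line_network(30)
        zs = NodeScores.from_zscores(
            {n: float(z) for n, z in zip(net.node_ids, rng.normal(size=30))}
        )
        bg = calibrate_background(zs, max_k=30, n_samples=300, seed=seed)
        return net, zs, bg

    def test_single_pass_matches_direct_search(self):
        net, zs, bg = self._setup()
        cfg = SAConfig(seed=13)
        direct = find_active_subnetwork(net, zs, bg, cfg)
        via_iter = iterated_search(net, zs, bg, cfg, passes=1)
        assert len(via_iter) == 1
        assert via_iter[0].members == direct.members

    def test_nested_containment(self):
        net, zs, bg = self._setup(seed=1)
        results = iterated_search(net, zs, bg, SAConfig(seed=2), passes=3)
        for earlier, later in zip(results, results[1:]):
            assert set(later.members) <= set(earlier.members)


class TestSharedInteractors:
    def test_wired_construction(self):
        net = make_network(
            [("H1", "X"), ("H2", "X"), ("H1", "Y"), ("X", "Y")], hubs=["H1", "H2"]
        )
        zs = NodeScores.from_zscores({n: 1.0 for n in net.node_ids})
        bg = calibrate_background(zs, max_k=4, n_samples=100, seed=0)
        res = find_active_subnetwork(net, zs, bg, SAConfig(seed=0))
        shared = shared_interactors(res, net, ["H1", "H2"])
        key = frozenset(("H1", "H2"))
        assert shared[key] <= {"X"}
        if "X" in res.members:
            assert shared[key] == {"X"}

    def test_no_multi_hub_members(self):
        net = make_network([("H1", "A"), ("H2", "B")], hubs=["H1", "H2"])
        zs = NodeScores.from_zscores({n: 1.0 for n in net.node_ids})
        bg = calibrate_background(zs, max_k=4, n_samples=100, seed=0)
        res = find_active_subnetwork(net, zs, bg, SAConfig(seed=0))
        shared = shared_interactors(res, net, ["H1", "H2"])
        assert shared[frozenset(("H1", "H2"))] == set()


class TestScoresIO:
    def test_read_pvalue_table(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("gene\tp_value\ngat1\t0.01\nHOM2\t0.5\n")
        zs = read_scores(p)
        assert set(zs.p_values) == {"GAT1", "HOM2"}
        assert zs.z_scores["HOM2"] == pytest.approx(0.0, abs=1e-12)

    def test_z_column_bypasses_conversion(self, tmp_path):
        p = tmp_path / "scores.tsv"
        p.write_text("gene\tp_value\tz\nA\t0.9\t1.25\n")
        zs = read_scores(p)
        assert zs.z_scores["A"] == 1.25

    def test_align_drops_unknown_and_imputes_zero(self):
        net = make_network([("A", "B"), ("B", "C")])
        zs = NodeScores.from_zscores({"A": 1.0, "ZZZ": 2.0})
        zmap, dropped = zs.align(net)
        assert dropped == ["ZZZ"]
        assert zmap == {"A": 1.0, "B": 0.0, "C": 0.0}
        with pytest.raises(StpnetError):
            zs.align(net, missing="error")


def test_significance_utility_flags_strong_module():
    rng = np.random.default_rng(0)
    net = _line_network(40)
    zmap = {n: float(z) for n, z in zip(net.node_ids, rng.normal(size=40))}
    for n in list(zmap)[10:16]:
        zmap[n] = 3.0
    zs = NodeScores.from_zscores(zmap)
    bg = calibrate_background(zs, max_k=40, n_samples=500, seed=0)
    res = find_active_subnetwork(net, zs, bg, SAConfig(seed=1))
    p = module_score_significance(res, zs, bg, n_permutations=200, seed=2)
    assert p < 0.05
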