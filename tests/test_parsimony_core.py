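import itertools
import math

import numpy as np
import pytest

from ddinfer import (
    DomainComposition,
    PPINetwork,
    WeightMap,
    build_candidate_pairs,
    build_lp,
    compute_weights,
    count_witnesses,
    empirical_p_values,
    lp_score,
    pw_score,
    round_predictions,
    solve_lp,
)


def brute_force_integer_optimum(candidates, sd, weights=None):
    """Exhaustive oracle: enumerate every pair subset and check coverage
    with at most floor((1-sd)|E|) dropped edges."""
    pairs = candidates.sorted_pairs()
    edges = candidates.sorted_edges()
    budget = math.floor((1 - sd) * len(edges) + 1e-9)
    best = float("inf")
    for mask in range(1 << len(pairs)):
        chosen = {pairs[i] for i in range(len(pairs)) if mask >> i & 1}
        cost = sum((weights[p] if weights else 1.0) for p in chosen)
        if cost >= best:
            continue
        uncovered = sum(
            1 for e in edges if not (candidates.edge_candidates[e] & chosen)
        )
        if uncovered <= budget:
            best = cost
    return best


def random_ppi_instance(seed):
    """Small instance resembling PPI data: mostly single-domain proteins."""
    rng = np.random.default_rng(seed)
    n_prot = int(rng.integers(5, 9))
    n_dom = int(rng.integers(6, 12))
    doms = [f"D{i}" for i in range(n_dom)]
    comp = {}
    for k in range(n_prot):
        size = 1 if rng.random() < 0.75 else 2
        comp[f"P{k}"] = set(rng.choice(doms, size=size, replace=False))
    all_pairs = list(itertools.combinations(sorted(comp), 2))
    rng.shuffle(all_pairs)
    n_e = int(rng.integers(2, 13))
    net = PPINetwork.from_edges(all_pairs[:n_e])
    return net, DomainComposition.from_dict({p: comp[p] for p in net.proteins})


class TestBuildCandidatePairs:
    def test_chain_support_counts(self, toy_chain):
        net, comp = toy_chain
        c = build_candidate_pairs(net, comp)
        assert c.pairs == frozenset({("A", "B"), ("A", "C")})
        assert len(c.support[("A", "B")]) == 2
        assert len(c.support[("A", "C")]) == 1

    def test_homodomain_pair(self):
        net = PPINetwork.from_edges([("P5", "P6")])
        comp = DomainComposition.from_dict({"P5": {"A"}, "P6": {"A"}})
        c = build_candidate_pairs(net, comp)
        assert c.pairs == frozenset({("A", "A")})

    def test_cross_product_of_compositions(self):
        net = PPINetwork.from_edges([("P7", "P8")])
        comp = DomainComposition.from_dict({"P7": {"A", "B"}, "P8": {"C"}})
        c = build_candidate_pairs(net, comp)
        assert c.pairs == frozenset({("A", "C"), ("B", "C")})

    def test_unannotated_endpoint_is_fatal(self):
        net = PPINetwork.from_edges([("P1", "P2")])
        comp = DomainComposition.from_dict({"P1": {"A"}})
        with pytest.raises(KeyError):
            build_candidate_pairs(net, comp)

    def test_edge_candidates_cover_both_orientations(self, default_dataset):
        ds = default_dataset
        c = build_candidate_pairs(ds.network, ds.composition)
        for edge in list(c.edge_candidates)[:50]:
            pm, pn = edge
            expected = {
                tuple(sorted((i, j)))
                for i in ds.composition[pm]
                for j in ds.composition[pn]
            }
            assert c.edge_candidates[edge] == expected
            assert expected  # non-empty for annotated edges


class TestComputeWeights:
    def test_triangle_hub_weights(self, toy_triangle_hub):
        net, comp = toy_triangle_hub
        c = build_candidate_pairs(net, comp)
        w = compute_weights(net, comp, c, K=2)
        assert w[("D1", "D2")] == pytest.approx(0.5)
        assert w[("D2", "D3")] == pytest.approx(0.5)
        assert w[("D1", "D3")] == 1.0
        assert w[("D2", "D4")] == 1.0
        assert w.priority_set_size == 2

    def test_equal_bins_give_no_discount(self):
        # triangle of equal-degree nodes: s == t == 1 -> weight 1, but in S
        k3 = PPINetwork.from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        comp = DomainComposition.from_dict({"a": {"X"}, "b": {"Y"}, "c": {"Z"}})
        c = build_candidate_pairs(k3, comp)
        w = compute_weights(k3, comp, c, K=3)
        assert all(w[p] == 1.0 for p in c.pairs)
        assert w.priority_set_size == 3

    def test_pair_takes_smallest_weight_across_triangles(self):
        # one domain pair (U,V) supported by two triangle edges through
        # degree-2 (bin 1) wedge centers, with bin gaps 2 and 4:
        # w = min(1/(1+2), 1/(1+4)) = 1/5
        ring = [(f"r{i}", f"r{(i + 1) % 10}") for i in range(10)]
        edges = ring + [
            ("p", "m1"), ("p", "n1"), ("m1", "n1"),
            ("q", "m2"), ("q", "n2"), ("m2", "n2"),
            ("m1", "r0"),                                      # deg(m1) = 3
            ("n1", "r1"), ("n1", "r2"), ("n1", "r3"),          # deg(n1) = 5
            ("m2", "r4"),                                      # deg(m2) = 3
            ("n2", "r5"), ("n2", "r6"), ("n2", "r7"),
            ("n2", "r8"), ("n2", "r9"),                        # deg(n2) = 7
        ]
        net = PPINetwork.from_edges(edges)
        comp = {v: {"W"} for v in net.proteins}
        comp["m1"] = comp["m2"] = {"U"}
        comp["n1"] = comp["n2"] = {"V"}
        comp = DomainComposition.from_dict(comp)
        c = build_candidate_pairs(net, comp)
        deg = net.degrees()
        assert deg["p"] == deg["q"] == 2 == min(deg.values())
        assert deg["m1"] == deg["m2"] == 3
        assert deg["n1"] == 5 and deg["n2"] == 7 == max(deg.values())
        # K=6 over [2, 7]: bins m=2, n1=4, n2=6; p, q in bin 1
        w = compute_weights(net, comp, c, K=6)
        assert w[("U", "V")] == pytest.approx(1 / 5)

    def test_k1_gives_unit_weights_everywhere(self, default_dataset):
        ds = default_dataset
        c = build_candidate_pairs(ds.network, ds.composition)
        w = compute_weights(ds.network, ds.composition, c, K=1)
        assert all(v == 1.0 for v in w.weights.values())


class TestBuildAndSolveLP:
    def test_toy_chain_structure(self, toy_chain):
        net, comp = toy_chain
        c = build_candidate_pairs(net, comp)
        p = build_lp(c, net, sd=1.0)
        assert p.n_pairs == 2 and p.n_edges == 3
        assert p.n_variables == 5
        assert p.budget_rhs == 0.0

    def test_sd_zero_allows_dropping_everything(self, toy_chain):
        net, comp = toy_chain
        c = build_candidate_pairs(net, comp)
        sol = solve_lp(build_lp(c, net, sd=0.0))
        assert sol.objective == pytest.approx(0.0)
        assert all(v <= 1e-9 for v in sol.values.values())

    def test_toy_chain_optima(self, toy_chain):
        net, comp = toy_chain
        c = build_candidate_pairs(net, comp)
        full = solve_lp(build_lp(c, net, sd=1.0))
        assert full.objective == pytest.approx(2.0)
        assert full.values[("A", "B")] == pytest.approx(1.0)
        assert full.values[("A", "C")] == pytest.approx(1.0)
        relaxed = solve_lp(build_lp(c, net, sd=2 / 3))
        assert relaxed.objective == pytest.approx(1.0)

    def test_triangle_hub_weighted_optimum(self, toy_triangle_hub):
        net, comp = toy_triangle_hub
        c = build_candidate_pairs(net, comp)
        w = compute_weights(net, comp, c, K=2)
        sol = solve_lp(build_lp(c, net, sd=1.0, weights=w))
        assert sol.objective == pytest.approx(3.0)

    def test_invalid_sd_is_fatal(self, toy_chain):
        net, comp = toy_chain
        c = build_candidate_pairs(net, comp)
        with pytest.raises(ValueError):
            build_lp(c, net, sd=1.2)

    @pytest.mark.parametrize("seed", range(40))
    def test_pure_cover_matches_exhaustive_oracle(self, seed):
        """LP relaxation of the pure cover equals the integer optimum."""
        net, comp = random_ppi_instance(seed)
        c = build_candidate_pairs(net, comp)
        if len(c) > 15:
            pytest.skip("instance exceeds oracle size cap")
        w = compute_weights(net, comp, c, K=3)
        for weights in (None, w):
            sol = solve_lp(build_lp(c, net, sd=1.0, weights=weights))
            expected = brute_force_integer_optimum(
                c, 1.0, weights.weights if weights else None
            )
            assert sol.objective == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("seed", range(20))
    def test_relaxation_lower_bounds_integer_optimum(self, seed):
        """At sd < 1 the LP is a valid relaxation: optimum <= integer optimum."""
        net, comp = random_ppi_instance(seed)
        c = build_candidate_pairs(net, comp)
        if len(c) > 15:
            pytest.skip("instance exceeds oracle size cap")
        rng = np.random.default_rng(seed)
        sd = float(rng.choice([0.75, 0.5]))
        sol = solve_lp(build_lp(c, net, sd=sd))
        assert sol.objective <= brute_force_integer_optimum(c, sd) + 1e-6

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_monotone_in_sd(self, seed):
        net, comp = random_ppi_instance(seed)
        c = build_candidate_pairs(net, comp)
        objectives = [
            solve_lp(build_lp(c, net, sd=sd)).objective
            for sd in (0.2, 0.5, 0.8, 1.0)
        ]
        assert objectives == sorted(objectives)

    @pytest.mark.parametrize("seed", range(10))
    def test_unit_weight_wilp_equals_ilp(self, seed):
        net, comp = random_ppi_instance(seed)
        c = build_candidate_pairs(net, comp)
        unit = WeightMap.unit(c)
        for sd in (1.0, 0.6):
            a = solve_lp(build_lp(c, net, sd=sd))
            b = solve_lp(build_lp(c, net, sd=sd, weights=unit))
            assert a.objective == pytest.approx(b.objective)

    def test_cover_feasibility_after_rounding(self, default_dataset):
        ds = default_dataset
        c = build_candidate_pairs(ds.network, ds.composition)
        sd = 0.8
        sol = solve_lp(build_lp(c, ds.network, sd=sd))
        chosen = round_predictions(sol).pairs
        dropped = sum(
            1 for e in c.sorted_edges() if not (c.edge_candidates[e] & chosen)
        )
        # integral variables respect the budget exactly; each fractional one
        # can add at most one uncovered edge after thresholding
        assert dropped <= (1 - sd) * len(c.sorted_edges()) + sol.n_fractional + 1


class TestRoundPredictions:
    def test_threshold_inclusive(self):
        from ddinfer.parsimony_core import ParsimonySolution

        s = ParsimonySolution(
            values={("A", "B"): 0.0, ("A", "C"): 1.0, ("B", "C"): 0.5},
            slack_values={},
            objective=1.5,
            solver_status="optimal",
            n_fractional=1,
        )
        assert round_predictions(s).pairs == frozenset({("A", "C"), ("B", "C")})

    def test_non_optimal_is_fatal(self):
        from ddinfer.parsimony_core import ParsimonySolution

        s = ParsimonySolution({}, {}, float("nan"), "infeasible", 0)
        with pytest.raises(ValueError):
            round_predictions(s)


class TestWitnesses:
    def test_chain_witness_counts(self, toy_chain):
        net, comp = toy_chain
        w = count_witnesses(net, comp)
        assert w[("A", "B")] == 2
        assert w[("A", "C")] == 1

    def test_multidomain_endpoint_is_no_witness(self):
        net = PPINetwork.from_edges([("P", "Q")])
        comp = DomainComposition.from_dict({"P": {"A", "B"}, "Q": {"C"}})
        assert count_witnesses(net, comp) == {}


class TestLPScore:
    def test_full_reliability_equals_pe_solution(self, toy_chain):
        net, comp = toy_chain
        c = build_candidate_pairs(net, comp)
        scores = lp_score(c, net, r=1.0, n_runs=5, seed=0)
        assert scores[("A", "B")] == pytest.approx(1.0)
        assert scores[("A", "C")] == pytest.approx(1.0)

    def test_private_edge_score_matches_keep_probability(self, toy_chain):
        """(A,C)'s only edge is kept with probability r, and it is selected
        exactly when kept: closed-form expectation r."""
        net, comp = toy_chain
        c = build_candidate_pairs(net, comp)
        r, n_runs = 0.5, 2000
        scores = lp_score(c, net, r=r, n_runs=n_runs, seed=4)
        se = math.sqrt(r * (1 - r) / n_runs)
        assert abs(scores[("A", "C")] - r) < 3 * se

    def test_scores_bounded(self, toy_chain):
        net, comp = toy_chain
        c = build_candidate_pairs(net, comp)
        scores = lp_score(c, net, r=0.7, n_runs=50, seed=1)
        assert all(0.0 <= v <= 1.0 for v in scores.values())

    def test_zero_reliability_is_fatal(self, toy_chain):
        net, comp = toy_chain
        c = build_candidate_pairs(net, comp)
        with pytest.raises(ValueError):
            lp_score(c, net, r=0.0, n_runs=5, seed=0)


class TestEmpiricalPValues:
    def test_bounds_and_trivial_ties(self, default_dataset):
        ds = default_dataset
        c = build_candidate_pairs(ds.network, ds.composition)
        p = empirical_p_values(
            c, ds.network, ds.composition, r=1.0, n_networks=3, seed=0, n_runs=1
        )
        assert all(0.0 <= v <= 1.0 for v in p.values())
        # a pair with observed LP-score 0 is tied or beaten by every reference
        scores = lp_score(c, ds.network, r=1.0, n_runs=1, seed=0)
        zero_pairs = [q for q, v in scores.items() if v == 0.0]
        for q in zero_pairs:
            assert p[q] == 1.0


class TestComputePEScores:
    def test_pipeline_respects_pw_invariant(self, toy_chain):
        from ddinfer import compute_pe_scores

        net, comp = toy_chain
        scores = compute_pe_scores(net, comp, r=0.8, n_runs=20, n_networks=3, seed=0)
        for pair in scores.lp_score:
            w = scores.witnesses.get(pair, 0)
            expected = min(scores.p_value[pair], (1 - scores.r) ** w)
            assert scores.pw_score[pair] == pytest.approx(expected)
            assert 0.0 <= scores.lp_score[pair] <= 1.0


class TestPWScore:
    def test_formula_cases(self):
        lp = {("A", "B"): 0.9, ("A", "C"): 0.3, ("B", "C"): 0.8}
        pv = {("A", "B"): 0.2, ("A", "C"): 0.7, ("B", "C"): 0.05}
        wit = {("A", "B"): 2}
        out = pw_score(lp, pv, wit, r=0.9)
        assert out[("A", "B")] == pytest.approx(min(0.2, 0.1**2))
        assert out[("A", "C")] == pytest.approx(0.7)  # w = 0 -> (1-r)^0 = 1

    def test_full_reliability_with_witness_gives_zero(self):
        out = pw_score({("A", "B"): 1.0}, {("A", "B"): 0.5}, {("A", "B"): 3}, r=1.0)
        assert out[("A", "B")] == 0.0

    def test_mismatched_keys_are_fatal(self):
        with pytest.raises(ValueError):
            pw_score({("A", "B"): 1.0}, {}, {}, r=0.5)
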