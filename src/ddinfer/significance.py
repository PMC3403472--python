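"""Randomization tests for the parsimony principle and the triangle weights.

Two shuffles destroy the co-organization of PPIs and domain compositions
while conserving marginal structure: (1) permute domain assignments across
proteins keeping each protein's domain count, or (2) rewire edges keeping
the degree sequence.  If PPIs really are mediated by a small DDI
repertoire, the minimal cover size T on shuffled data should exceed the
observed T0 — a lower-tail Gaussian test on T0 against the shuffled
distribution.

A third test checks that the triangle-derived weights carry signal: the
weighted model's true-positive count against a gold standard is compared
with a null in which the same number of candidate pairs get i.i.d.
Uniform(0, 0.5) weights — an upper-tail test on the true TP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_formats import DDIPairSet, DomainComposition, PPINetwork, harmonize
from .netstats import NullDistribution, gaussian_tail_p, rewire_preserving_degrees
from .parsimony_core import (
    WeightMap,
    build_candidate_pairs,
    build_lp,
    compute_weights,
    round_predictions,
    solve_lp,
)

__all__ = [
    "RandomizationTestResult",
    "shuffle_domain_composition",
    "shuffle_edges",
    "parsimony_randomization_test",
    "random_weight_test",
    "gaussian_p_value",
]


@dataclass(frozen=True)
class RandomizationTestResult:
    statistic_name: Literal["T", "TP"]
    observed: float
    null: NullDistribution
    mode: Literal["shuffle_compositions", "shuffle_edges", "random_weights"]
    n_shuffles: int
    seed: int

    @property
    def p_value(self) -> float | None:
        return self.null.p_value


def gaussian_p_value(observed, samples, direction):
    """One-sided Gaussian p-value (moment fit; None when samples are constant)."""
    return gaussian_tail_p(observed, samples, direction)


def shuffle_domain_composition(
    composition: DomainComposition, seed: int = 0
) -> DomainComposition:
    """Permute the global multiset of domain tokens across protein slots.

    Every protein keeps its original domain count and the global domain
    multiset is conserved.  A plain permutation can land two copies of one
    domain on the same protein (sets would silently shrink), so a repair
    pass swaps colliding tokens with randomly chosen slots elsewhere until
    every protein's tokens are distinct.
    """
    if len(composition) == 0:
        raise ValueError("cannot shuffle an empty composition")
    rng = np.random.default_rng(seed)
    proteins = sorted(composition.assignments)
    sizes = [len(composition[p]) for p in proteins]
    tokens = [d for p in proteins for d in sorted(composition[p])]
    rng.shuffle(tokens)
    # slot boundaries per protein
    starts = np.concatenate([[0], np.cumsum(sizes)])
    max_tries = 100 * len(tokens) + 1000
    for _ in range(max_tries):
        bad = None
        for k, p in enumerate(proteins):
            slot = tokens[starts[k] : starts[k + 1]]
            if len(set(slot)) != len(slot):
                seen = set()
                for off, tok in enumerate(slot):
                    if tok in seen:
                        bad = starts[k] + off
                        break
                    seen.add(tok)
                break
        if bad is None:
            break
        j = int(rng.integers(0, len(tokens)))
        tokens[bad], tokens[j] = tokens[j], tokens[bad]
    else:
        raise RuntimeError("composition shuffle failed to resolve collisions")
    assignments = {
        p: frozenset(tokens[starts[k] : starts[k + 1]])
        for k, p in enumerate(proteins)
    }
    return DomainComposition(assignments)


def shuffle_edges(network: PPINetwork, seed: int = 0) -> PPINetwork:
    """Rewire edges keeping the exact degree sequence (double-edge swaps)."""
    return rewire_preserving_degrees(network, swap_multiplier=10.0, seed=seed)


def _pe_optimum(network: PPINetwork, composition: DomainComposition) -> float:
    """Minimal (fractional) number of DDIs covering every edge: the T statistic."""
    net, _ = harmonize(network, composition)
    if net.n_edges == 0:
        return 0.0
    candidates = build_candidate_pairs(net, composition)
    sol = solve_lp(build_lp(candidates, net, sd=1.0, include_slack=False))
    if sol.solver_status != "optimal":
        raise RuntimeError(f"PE solve failed: {sol.message}")
    return sol.objective


def parsimony_randomization_test(
    network: PPINetwork,
    composition: DomainComposition,
    mode: Literal["shuffle_compositions", "shuffle_edges"] = "shuffle_compositions",
    n_shuffles: int = 200,
    seed: int = 0,
) -> RandomizationTestResult:
    """Test whether the observed minimal DDI cover T0 is smaller than chance.

    T0 is the pure-cover optimum on the original data; each shuffle
    recomputes the optimum T on data randomized under the chosen rule.
    Parsimoniously organized data gives T0 well below the null mean
    (lower-tail Gaussian p-value).
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if mode not in ("shuffle_compositions", "shuffle_edges"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    t0 = _pe_optimum(network, composition)
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_shuffles):
        s = int(rng.integers(2**31 - 1))
        if mode == "shuffle_compositions":
            t = _pe_optimum(network, shuffle_domain_composition(composition, s))
        else:
            t = _pe_optimum(shuffle_edges(network, s), composition)
        samples.append(t)
    null = NullDistribution(tuple(samples), observed=t0, direction="lower")
    return RandomizationTestResult(
        statistic_name="T",
        observed=t0,
        null=null,
        mode=mode,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def random_weight_test(
    network: PPINetwork,
    composition: DomainComposition,
    gold: DDIPairSet,
    sd: float = 0.5,
    K: int = 50,
    n_runs: int = 500,
    seed: int = 0,
) -> RandomizationTestResult:
    """Test whether triangle weights beat random weights at recovering gold DDIs.

    The observed statistic is the true-positive count of the weighted model
    with triangle-derived weights; the null re-solves with Uniform(0, 0.5)
    weights on a uniformly chosen candidate subset of the same size |S|
    (upper-tail Gaussian p-value on the true TP).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not 0 < sd <= 1:
        raise ValueError("sd must be in (0, 1]")
    net, _ = harmonize(network, composition)
    candidates = build_candidate_pairs(net, composition)
    true_weights = compute_weights(net, composition, candidates, K)
    n_s = true_weights.priority_set_size
    if n_s == 0:
        raise ValueError(
            f"no priority pairs exist at K={K}: no triangle through a poor node "
            "touches any candidate pair; the weighted model reduces to the "
            "unweighted one and the weight test is undefined"
        )
    sol = solve_lp(build_lp(candidates, net, sd=sd, weights=true_weights))
    tp_true = len(round_predictions(sol).pairs & gold.pairs)
    pair_order = candidates.sorted_pairs()
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_runs):
        chosen = rng.choice(len(pair_order), size=min(n_s, len(pair_order)),
                            replace=False)
        w = {p: 1.0 for p in pair_order}
        draws = rng.uniform(0.0, 0.5, size=len(chosen))
        for k, idx in enumerate(chosen):
            # weights must stay in (0, 1]; a draw of exactly 0 is measure-zero
            w[pair_order[idx]] = max(draws[k], 1e-12)
        wm = WeightMap(w, priority_set_size=len(chosen))
        rsol = solve_lp(build_lp(candidates, net, sd=sd, weights=wm))
        samples.append(float(len(round_predictions(rsol).pairs & gold.pairs)))
    null = NullDistribution(tuple(samples), observed=float(tp_true),
                            direction="upper")
    return RandomizationTestResult(
        statistic_name="TP",
        observed=float(tp_true),
        null=null,
        mode="random_weights",
        n_shuffles=n_runs,
        seed=seed,
    )
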