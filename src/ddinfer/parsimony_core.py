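"""Parsimony inference of domain-domain interactions.

An observed PPI network I = (P, E) together with per-protein domain
compositions defines a candidate set D of unordered domain pairs: every
pair (i, j) with i in one endpoint's composition and j in the other's, for
some edge (P_m, P_n) in E.  The parsimony principle asks for the cheapest
subset of D such that every edge contains at least one selected pair — a
weighted set cover.  Three linear programs are built on this:

* PE   — pure cover: minimize sum d_ij subject to one >=1 constraint per
         edge (no slack).
* ILP  — cover with a slack budget: each edge constraint gains a slack
         e_mn, and sum e_mn <= (1 - sd)|E| allows a (1 - sd) fraction of
         edges to go unexplained.
* WILP — the same program with per-pair weights w_ij in the objective.
         Weights below 1 prioritize pairs supported by triangles through
         low-degree ("poor") proteins, a signature of true complexes in
         highly clustered PPI networks: for an edge (P_m, P_n) whose
         endpoints share a poor common neighbor, the involved pairs get
         w = 1/(1 + |s - t|) where s, t are the endpoints' degree-bin
         indices; a pair keeps the smallest weight it receives anywhere.

All three are solved as LP relaxations (variables in [0, 1]); in practice
optima are almost always integral and a count of fractional variables is
reported.  The PE-style scores (LP-score under constraint subsampling at
reliability r, randomization p-values against rewired networks, witness
counts and the combined pw-score) are implemented on top of the same LPs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, lil_matrix

from .io_formats import (
    DDIPairSet,
    DomainComposition,
    PPINetwork,
    canonical_pair,
)
from .netstats import degree_binning, rewire_preserving_degrees

__all__ = [
    "CandidateDDISet",
    "WeightMap",
    "LPProblem",
    "ParsimonySolution",
    "PEScores",
    "build_candidate_pairs",
    "compute_weights",
    "build_lp",
    "solve_lp",
    "round_predictions",
    "count_witnesses",
    "lp_score",
    "empirical_p_values",
    "pw_score",
    "compute_pe_scores",
]

FRACTIONAL_TOL = 1e-6


@dataclass(frozen=True)
class CandidateDDISet:
    """The candidate set D with its support structure.

    ``support`` maps each candidate pair to the network edges it could
    explain; ``edge_candidates`` is the inverse map (every annotated edge
    has at least one candidate pair).
    """

    pairs: frozenset[tuple[str, str]]
    support: Mapping[tuple[str, str], frozenset[tuple[str, str]]]
    edge_candidates: Mapping[tuple[str, str], frozenset[tuple[str, str]]]

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edge_candidates)


def build_candidate_pairs(
    network: PPINetwork, composition: DomainComposition
) -> CandidateDDISet:
    """Enumerate D = {(i, j) : i in comp(P_m), j in comp(P_n), (P_m,P_n) in E}.

    The network must be harmonized first: an edge endpoint without a
    composition is an error.  Homodomain pairs (i, i) arise naturally when
    both endpoints carry the same domain.
    """
    support: dict[tuple[str, str], set[tuple[str, str]]] = {}
    edge_candidates: dict[tuple[str, str], frozenset[tuple[str, str]]] = {}
    for edge in network.edges:
        pm, pn = edge
        if pm not in composition or pn not in composition:
            raise KeyError(
                f"edge ({pm},{pn}) has an endpoint without composition; harmonize first"
            )
        cands = {
            canonical_pair(i, j)
            for i in composition[pm]
            for j in composition[pn]
        }
        edge_candidates[edge] = frozenset(cands)
        for pair in cands:
            support.setdefault(pair, set()).add(edge)
    return CandidateDDISet(
        pairs=frozenset(support),
        support={p: frozenset(e) for p, e in support.items()},
        edge_candidates=edge_candidates,
    )


@dataclass(frozen=True)
class WeightMap:
    """Objective weights w_ij per candidate pair, 1 outside the priority set S."""

    weights: Mapping[tuple[str, str], float]
    priority_set_size: int

    def __post_init__(self) -> None:
        for pair, w in self.weights.items():
            if not 0 < w <= 1:
                raise ValueError(f"weight {w} for {pair} outside (0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return self.weights.get(pair, 1.0)

    @classmethod
    def unit(cls, candidates: CandidateDDISet) -> "WeightMap":
        return cls({p: 1.0 for p in candidates.pairs}, priority_set_size=0)


def compute_weights(
    network: PPINetwork,
    composition: DomainComposition,
    candidates: CandidateDDISet,
    K: int,
) -> WeightMap:
    """Derive priority weights from triangles through poor nodes.

    Bins the degree range into K equal subintervals.  For every poor
    protein P (bin 1) and every observed edge (P_m, P_n) between two of
    P's neighbors, each candidate pair of that edge receives the weight
    1/(1 + |s - t|), s and t the bins of P_m and P_n; a pair spanning
    several such edges keeps the smallest weight.  The priority set S is
    every pair that received a triangle weight (with s = t the weight is
    1, indistinguishable in the objective from an unweighted pair, but the
    pair still counts as a member of S).
    """
    bins = degree_binning(network, K)
    weights = {p: 1.0 for p in candidates.pairs}
    in_s: set[tuple[str, str]] = set()
    adjacency: dict[str, set[str]] = {p: set() for p in network.proteins}
    for a, b in network.edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    poor = [p for p in network.proteins if bins.assignment[p] == 1]
    for p in poor:
        neigh = sorted(adjacency[p])
        for idx, pm in enumerate(neigh):
            for pn in neigh[idx + 1 :]:
                edge = canonical_pair(pm, pn)
                if edge not in candidates.edge_candidates:
                    continue  # requires (P_m, P_n) observed in E
                s = bins.assignment[pm]
                t = bins.assignment[pn]
                w = 1.0 / (1 + abs(s - t))
                for pair in candidates.edge_candidates[edge]:
                    in_s.add(pair)
                    if w < weights[pair]:
                        weights[pair] = w
    return WeightMap(weights, priority_set_size=len(in_s))


@dataclass(frozen=True)
class LPProblem:
    """The assembled cover LP: variables d_ij (pairs) then e_mn (edge slacks).

    ``include_slack=False`` gives the pure-cover PE program (no e_mn and
    no budget row).  The budget right-hand side (1 - sd)|E| is kept
    real-valued, matching the LP relaxation.
    """

    pair_order: tuple[tuple[str, str], ...]
    edge_order: tuple[tuple[str, str], ...]
    objective: np.ndarray
    cover_matrix: csr_matrix  # one row per edge over all variables
    sd: float
    include_slack: bool

    @property
    def n_pairs(self) -> int:
        return len(self.pair_order)

    @property
    def n_edges(self) -> int:
        return len(self.edge_order)

    @property
    def n_variables(self) -> int:
        return self.n_pairs + (self.n_edges if self.include_slack else 0)

    @property
    def budget_rhs(self) -> float:
        return (1.0 - self.sd) * self.n_edges


@dataclass(frozen=True)
class ParsimonySolution:
    """LP-relaxation solution with integrality diagnostics."""

    values: Mapping[tuple[str, str], float]
    slack_values: Mapping[tuple[str, str], float]
    objective: float
    solver_status: Literal["optimal", "infeasible", "error"]
    n_fractional: int
    message: str = ""


def build_lp(
    candidates: CandidateDDISet,
    network: PPINetwork,
    sd: float = 1.0,
    weights: WeightMap | None = None,
    include_slack: bool = True,
) -> LPProblem:
    """Assemble the cover LP for the candidate set.

    ``weights=None`` gives unit weights (the unweighted parsimony model);
    ``include_slack=False`` yields the pure PE cover regardless of sd.
    Variable and constraint order is deterministic (sorted pairs, sorted
    edges) so repeated solves are reproducible.
    """
    if not 0.0 <= sd <= 1.0:
        raise ValueError(f"sd={sd} outside [0, 1]")
    pair_order = tuple(candidates.sorted_pairs())
    edge_order = tuple(candidates.sorted_edges())
    pair_index = {p: k for k, p in enumerate(pair_order)}
    n_pairs, n_edges = len(pair_order), len(edge_order)
    n_vars = n_pairs + (n_edges if include_slack else 0)
    cover = lil_matrix((n_edges, n_vars))
    for row, edge in enumerate(edge_order):
        for pair in candidates.edge_candidates[edge]:
            cover[row, pair_index[pair]] = 1.0
        if include_slack:
            cover[row, n_pairs + row] = 1.0
    objective = np.zeros(n_vars)
    wm = weights if weights is not None else WeightMap.unit(candidates)
    for k, pair in enumerate(pair_order):
        objective[k] = wm[pair]
    return LPProblem(
        pair_order=pair_order,
        edge_order=edge_order,
        objective=objective,
        cover_matrix=csr_matrix(cover),
        sd=sd,
        include_slack=include_slack,
    )


def solve_lp(problem: LPProblem) -> ParsimonySolution:
    """Solve the LP relaxation with the HiGHS simplex solver.

    All variables are bounded in [0, 1]; cover rows become -A x <= -1 and
    the slack budget (when present) sum e_mn <= (1 - sd)|E|.
    """
    n_pairs, n_edges = problem.n_pairs, problem.n_edges
    n_vars = problem.n_variables
    if n_vars == 0:
        return ParsimonySolution({}, {}, 0.0, "optimal", 0)
    a_ub_rows = [-problem.cover_matrix]
    b_ub = [-np.ones(n_edges)]
    if problem.include_slack:
        budget = np.zeros(n_vars)
        budget[n_pairs:] = 1.0
        a_ub_rows.append(csr_matrix(budget))
        b_ub.append(np.array([problem.budget_rhs]))
    from scipy.sparse import vstack

    a_ub = vstack(a_ub_rows, format="csr")
    b_ub = np.concatenate(b_ub)
    res = linprog(
        problem.objective,
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=(0.0, 1.0),
        method="highs",
    )
    if res.status == 2:
        return ParsimonySolution({}, {}, float("nan"), "infeasible", 0, res.message)
    if not res.success:
        return ParsimonySolution({}, {}, float("nan"), "error", 0, res.message)
    x = np.clip(res.x, 0.0, 1.0)
    values = {pair: float(x[k]) for k, pair in enumerate(problem.pair_order)}
    slack_values = (
        {edge: float(x[n_pairs + r]) for r, edge in enumerate(problem.edge_order)}
        if problem.include_slack
        else {edge: 0.0 for edge in problem.edge_order}
    )
    n_fractional = int(
        np.sum((x > FRACTIONAL_TOL) & (x < 1.0 - FRACTIONAL_TOL))
    )
    return ParsimonySolution(
        values=values,
        slack_values=slack_values,
        objective=float(res.fun),
        solver_status="optimal",
        n_fractional=n_fractional,
        message=res.message,
    )


def round_predictions(
    solution: ParsimonySolution, threshold: float = 0.5
) -> DDIPairSet:
    """Threshold LP values into a predicted pair set (value >= threshold)."""
    if solution.solver_status != "optimal":
        raise ValueError(f"cannot round a {solution.solver_status} solution")
    return DDIPairSet.from_pairs(
        p for p, v in solution.values.items() if v >= threshold
    )


def count_witnesses(
    network: PPINetwork, composition: DomainComposition
) -> dict[tuple[str, str], int]:
    """Count witnesses: interacting single-domain protein pairs per domain pair.

    Only edges whose endpoints each carry exactly one domain contribute;
    such an edge pins its explanation down to a single candidate pair.
    """
    counts: dict[tuple[str, str], int] = {}
    for pm, pn in network.edges:
        if pm not in composition or pn not in composition:
            raise KeyError(f"edge ({pm},{pn}) endpoint lacks composition")
        dm, dn = composition[pm], composition[pn]
        if len(dm) == 1 and len(dn) == 1:
            pair = canonical_pair(next(iter(dm)), next(iter(dn)))
            counts[pair] = counts.get(pair, 0) + 1
    return counts


@dataclass(frozen=True)
class PEScores:
    """Per-pair PE statistics: LP-score, witnesses, p-value and pw-score."""

    lp_score: Mapping[tuple[str, str], float]
    witnesses: Mapping[tuple[str, str], int]
    p_value: Mapping[tuple[str, str], float]
    pw_score: Mapping[tuple[str, str], float]
    r: float
    n_runs: int


def lp_score(
    candidates: CandidateDDISet,
    network: PPINetwork,
    r: float = 1.0,
    n_runs: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], float]:
    """Average LP value per pair over constraint-subsampled PE solves.

    Each run keeps every cover constraint independently with probability r
    (modelling edge reliability) and solves the pure-cover LP on the kept
    edges; a pair's LP-score is its mean LP value across runs.  r = 1
    keeps every constraint, so all runs coincide with the full PE solve.
    """
    if not 0 < r <= 1:
        raise ValueError("reliability r must be in (0, 1]")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    pair_order = candidates.sorted_pairs()
    totals = {p: 0.0 for p in pair_order}
    if r == 1.0:
        problem = build_lp(candidates, network, sd=1.0, include_slack=False)
        sol = solve_lp(problem)
        if sol.solver_status != "optimal":
            raise RuntimeError(f"PE solve failed: {sol.message}")
        return {p: sol.values[p] for p in pair_order}
    rng = np.random.default_rng(seed)
    edges = candidates.sorted_edges()
    for _ in range(n_runs):
        keep = rng.random(len(edges)) < r
        kept_edges = [e for e, k in zip(edges, keep) if k]
        sub = _subset_candidates(candidates, kept_edges)
        if sub.pairs:
            sol = solve_lp(build_lp(sub, network, sd=1.0, include_slack=False))
            if sol.solver_status != "optimal":
                raise RuntimeError(f"PE solve failed: {sol.message}")
            for p, v in sol.values.items():
                totals[p] += v
    return {p: totals[p] / n_runs for p in pair_order}


def _subset_candidates(
    candidates: CandidateDDISet, kept_edges
) -> CandidateDDISet:
    """Restrict a candidate set to a subset of its edges."""
    support: dict[tuple[str, str], set[tuple[str, str]]] = {}
    edge_candidates = {}
    for e in kept_edges:
        cands = candidates.edge_candidates[e]
        edge_candidates[e] = cands
        for p in cands:
            support.setdefault(p, set()).add(e)
    return CandidateDDISet(
        pairs=frozenset(support),
        support={p: frozenset(v) for p, v in support.items()},
        edge_candidates=edge_candidates,
    )


def empirical_p_values(
    candidates: CandidateDDISet,
    network: PPINetwork,
    composition: DomainComposition,
    r: float = 1.0,
    n_networks: int = 1000,
    seed: int = 0,
    n_runs: int = 1000,
    swap_multiplier: float = 10.0,
) -> dict[tuple[str, str], float]:
    """Randomization p-values of LP-scores against rewired reference networks.

    Each reference network is a degree-preserving rewiring of the input
    (compositions fixed); a pair's p-value is the fraction of references
    whose LP-score for that pair is >= the observed score.  A pair absent
    from a reference's candidate set scores 0 there.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    rng = np.random.default_rng(seed)
    observed = lp_score(candidates, network, r=r, n_runs=n_runs,
                        seed=int(rng.integers(2**31 - 1)))
    exceed = {p: 0 for p in observed}
    for _ in range(n_networks):
        ref_net = rewire_preserving_degrees(
            network, swap_multiplier, seed=int(rng.integers(2**31 - 1))
        )
        ref_cands = build_candidate_pairs(ref_net, composition)
        ref_scores = lp_score(
            ref_cands, ref_net, r=r, n_runs=n_runs,
            seed=int(rng.integers(2**31 - 1)),
        )
        for p in observed:
            if ref_scores.get(p, 0.0) >= observed[p]:
                exceed[p] += 1
    return {p: exceed[p] / n_networks for p in observed}


def pw_score(
    lp_scores: Mapping[tuple[str, str], float],
    p_values: Mapping[tuple[str, str], float],
    witnesses: Mapping[tuple[str, str], int],
    r: float,
) -> dict[tuple[str, str], float]:
    """Combine randomization p-value and witness evidence per pair.

    pw(i, j) = min(p-value(i, j), (1 - r)^w(i, j)) — the witness term is
    the probability that every single-domain interaction supporting the
    pair is a false positive; pairs without witnesses fall back on the
    p-value alone ((1 - r)^0 = 1).
    """
    if set(lp_scores) != set(p_values):
        raise ValueError("lp_scores and p_values must share the same pair set")
    out = {}
    for pair, p in p_values.items():
        w = witnesses.get(pair, 0)
        out[pair] = min(p, (1.0 - r) ** w)
    return out


def compute_pe_scores(
    network: PPINetwork,
    composition: DomainComposition,
    r: float = 0.9,
    n_runs: int = 1000,
    n_networks: int = 1000,
    seed: int = 0,
) -> PEScores:
    """Full PE scoring pipeline: LP-score, p-values, witnesses, pw-score."""
    candidates = build_candidate_pairs(network, composition)
    rng = np.random.default_rng(seed)
    scores = lp_score(candidates, network, r=r, n_runs=n_runs,
                      seed=int(rng.integers(2**31 - 1)))
    p_values = empirical_p_values(
        candidates, network, composition, r=r, n_networks=n_networks,
        seed=int(rng.integers(2**31 - 1)), n_runs=n_runs,
    )
    witnesses = count_witnesses(network, composition)
    return PEScores(
        lp_score=scores,
        witnesses=witnesses,
        p_value=p_values,
        pw_score=pw_score(scores, p_values, witnesses, r),
        r=r,
        n_runs=n_runs,
    )
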