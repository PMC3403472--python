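"""Clustering-coefficient statistics, degree binning and null-model graph ensembles.

The clustering coefficient used throughout is the Watts-Strogatz one:
locally, the fraction of realized triangles among the triples centered on
a vertex (vertices of degree < 2 contribute 0); globally, the plain
average of the local values over *all* vertices.  Observed PPI networks
show a much larger value of this statistic than either an Erdos-Renyi
G(n, m) ensemble with matched size or a degree-preserving rewiring
ensemble, which is what motivates triangle-derived edge priorities in the
weighted parsimony model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import networkx as nx
import numpy as np
from scipy.stats import norm

from .io_formats import PPINetwork

__all__ = [
    "DegreeBinning",
    "NullDistribution",
    "local_clustering",
    "global_clustering",
    "degree_binning",
    "sample_er_graph",
    "rewire_preserving_degrees",
    "clustering_null_distribution",
]


@dataclass(frozen=True)
class DegreeBinning:
    """Partition of the degree range [d_min, d_max] into K equal-width bins.

    Bin indices run 1..K; bin 1 holds the poorest (lowest-degree) nodes
    and bin K the hubs.  ``assignment`` maps every protein to its bin.
    """

    K: int
    bin_edges: tuple[float, ...]
    assignment: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if len(self.bin_edges) != self.K + 1:
            raise ValueError("bin_edges must have K+1 entries")
        for b in self.assignment.values():
            if not 1 <= b <= self.K:
                raise ValueError(f"bin index {b} outside 1..{self.K}")


@dataclass(frozen=True)
class NullDistribution:
    """Samples of a statistic under a null model, with a Gaussian-tail p-value.

    ``p_value`` is None (undefined) when the sample standard deviation is
    zero; ``direction`` records which tail the test uses.
    """

    samples: tuple[float, ...]
    observed: float
    direction: Literal["lower", "upper"]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1))

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    @property
    def p_value(self) -> float | None:
        return gaussian_tail_p(self.observed, self.samples, self.direction)


def gaussian_tail_p(
    observed: float, samples, direction: Literal["lower", "upper"]
) -> float | None:
    """One-sided Gaussian p-value of ``observed`` against sample mean/sd.

    Fits a normal by moments (sample sd, n-1 denominator) and returns the
    requested tail probability; None when the samples are constant.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need >= 2 samples to fit a Gaussian null")
    mu = samples.mean()
    sd = samples.std(ddof=1)
    if sd == 0:
        return None
    z = (observed - mu) / sd
    return float(norm.cdf(z)) if direction == "lower" else float(norm.sf(z))


def local_clustering(network: PPINetwork, protein: str) -> float:
    """Fraction of triangles among triples centered on one vertex.

    deg < 2 (no triple exists) returns 0 by convention.
    """
    if protein not in network.proteins:
        raise KeyError(f"unknown protein {protein!r}")
    return float(nx.clustering(network.to_networkx(), protein))


def global_clustering(network: PPINetwork) -> float:
    """Average of local clustering over all vertices (degree-0/1 count as 0)."""
    if network.n_proteins == 0:
        raise ValueError("clustering coefficient of an empty network is undefined")
    return float(nx.average_clustering(network.to_networkx(), count_zeros=True))


def _global_clustering_nx(graph: nx.Graph) -> float:
    return float(nx.average_clustering(graph, count_zeros=True))


def degree_binning(network: PPINetwork, K: int) -> DegreeBinning:
    """Assign every node to one of K equal-width degree bins.

    Node with degree d gets bin min(K, floor((d - d_min)/width) + 1) with
    width = (d_max - d_min)/K; when all degrees are equal every node goes
    to bin 1 (the binning degenerates and no node counts as a hub).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if network.n_proteins == 0:
        raise ValueError("cannot bin an empty network")
    degrees = network.degrees()
    d_min = min(degrees.values())
    d_max = max(degrees.values())
    if d_min == d_max:
        edges = tuple(float(d_min) for _ in range(K + 1))
        return DegreeBinning(K, edges, {p: 1 for p in degrees})
    width = (d_max - d_min) / K
    edges = tuple(d_min + i * width for i in range(K + 1))
    assignment = {
        p: min(K, int((d - d_min) // width) + 1) for p, d in degrees.items()
    }
    return DegreeBinning(K, edges, assignment)


def sample_er_graph(n: int, m: int, seed: int) -> PPINetwork:
    """Draw one Erdos-Renyi G(n, m) graph: m distinct edges uniform over pairs."""
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m={m} outside [0, {max_m}] for n={n}")
    g = nx.gnm_random_graph(n, m, seed=seed)
    return PPINetwork.from_networkx(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()}))


def rewire_preserving_degrees(
    network: PPINetwork, swap_multiplier: float = 10.0, seed: int = 0
) -> PPINetwork:
    """Randomize edges by attempted double-edge swaps, conserving every degree.

    Performs ``swap_multiplier * |E|`` swap attempts; an attempt picks two
    distinct edges and rewires them crosswise, and is rejected if the new
    edges would be self-loops or duplicates.  Graphs that admit no valid
    swap (triangles, stars) are returned unchanged.
    """
    if network.n_edges < 2:
        raise ValueError("rewiring needs >= 2 edges")
    rng = np.random.default_rng(seed)
    edges = list(network.edges)
    edge_set = set(edges)
    n_attempts = int(round(swap_multiplier * len(edges)))
    for _ in range(n_attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # random orientation of the second edge picks which crosswise pairing
        if rng.integers(0, 2):
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        new1 = (a, d) if a <= d else (d, a)
        new2 = (c, b) if c <= b else (b, c)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.remove(edges[i])
        edge_set.remove(edges[j])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = new1
        edges[j] = new2
    return PPINetwork(network.proteins, frozenset(edge_set))


def clustering_null_distribution(
    model: Literal["er", "degree_preserving"],
    reference: PPINetwork,
    n_samples: int = 500,
    seed: int = 0,
    swap_multiplier: float = 10.0,
) -> NullDistribution:
    """Ensemble distribution of the global clustering coefficient.

    ``er`` draws G(n, m) graphs with the reference's node and edge counts;
    ``degree_preserving`` rewires the reference.  The observed value is the
    reference's own clustering coefficient; the test is upper-tailed
    (real PPI networks are expected to exceed both nulls).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_samples)
    samples = []
    if model == "er":
        n, m = reference.n_proteins, reference.n_edges
        for s in sub_seeds:
            g = nx.gnm_random_graph(n, m, seed=int(s))
            samples.append(_global_clustering_nx(g))
    elif model == "degree_preserving":
        for s in sub_seeds:
            g = rewire_preserving_degrees(reference, swap_multiplier, seed=int(s))
            samples.append(global_clustering(g))
    else:
        raise ValueError(f"unknown null model {model!r}")
    return NullDistribution(
        samples=tuple(samples),
        observed=global_clustering(reference),
        direction="upper",
    )
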