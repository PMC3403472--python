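"""Synthetic PPI datasets with planted domain-domain interactions.

The generator follows the mechanism the inference assumes: a hidden DDI
set drives which proteins can interact.  Each protein gets a small set of
domains (counts geometric-like, popularity skewed so a few domains are
promiscuous — that skew alone produces hubs and poor nodes); a fraction of
domain pairs is planted as truly interacting; protein pairs sharing a
planted pair become potential edges, subsampled to a target mean degree.
Noise enters as false-negative edge deletions and false-positive edges
between proteins sharing *no* planted pair.  ``triangle_boost`` closes
wedges centered on low-degree proteins with explainable edges, enriching
triangles through poor nodes the way real complexes do.

Nothing here imitates a specific interactome snapshot: degree and domain
frequency spectra are qualitatively skewed, not fitted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    DDIPairSet,
    DomainComposition,
    PPINetwork,
    canonical_pair,
    write_ddi_pairs,
    write_domain_composition,
    write_ppi_edgelist,
)

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "write_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Knobs of the generative model (defaults are desk-scale: ~500 edges)."""

    n_proteins: int = 200
    n_domains: int = 60
    domains_per_protein: float = 1.5  # mean of the (shifted-geometric) count, >= 1
    planted_ddi_density: float = 0.02  # fraction of domain pairs that truly interact
    fp_rate: float = 0.1  # spurious edges added, as a fraction of true edges
    fn_rate: float = 0.1  # fraction of true edges removed
    triangle_boost: float = 0.0  # fraction of poor-node wedges closed
    mean_degree: float = 5.0  # sparsity target for the subsampled base edges
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_domains < 1:
            raise ValueError("n_proteins and n_domains must be >= 1")
        if self.domains_per_protein < 1:
            raise ValueError("domains_per_protein must be >= 1")
        for name in ("planted_ddi_density", "fp_rate", "fn_rate", "triangle_boost"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SyntheticDataset:
    network: PPINetwork
    composition: DomainComposition
    planted: DDIPairSet
    true_edges: frozenset[tuple[str, str]]
    spec: SyntheticSpec


def _protein_ids(n: int) -> list[str]:
    return [f"P{k:04d}" for k in range(n)]


def _domain_ids(n: int) -> list[str]:
    return [f"D{k:03d}" for k in range(n)]


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one dataset from the generative model; reproducible by spec.seed."""
    rng = np.random.default_rng(spec.seed)
    proteins = _protein_ids(spec.n_proteins)
    domains = _domain_ids(spec.n_domains)

    # mildly skewed domain popularity (Zipf-like, exponent 0.5) creates a
    # promiscuous-domain tail and hence hubs, without letting a few domain
    # pairs dominate the candidate-support structure
    popularity = np.arange(1, spec.n_domains + 1, dtype=float) ** -0.5
    popularity /= popularity.sum()

    # per-protein domain count: 1 + geometric, mean = domains_per_protein
    extra_mean = spec.domains_per_protein - 1.0
    assignments: dict[str, frozenset[str]] = {}
    for p in proteins:
        if extra_mean > 0:
            count = 1 + rng.geometric(1.0 / (1.0 + extra_mean)) - 1
        else:
            count = 1
        count = min(count, spec.n_domains)
        idx = rng.choice(spec.n_domains, size=count, replace=False, p=popularity)
        assignments[p] = frozenset(domains[i] for i in idx)
    composition = DomainComposition(assignments)

    # plant truly interacting domain pairs (homodomain pairs included)
    all_pairs = [
        canonical_pair(domains[i], domains[j])
        for i in range(spec.n_domains)
        for j in range(i, spec.n_domains)
    ]
    n_planted = int(round(spec.planted_ddi_density * len(all_pairs)))
    if n_planted == 0:
        if spec.planted_ddi_density > 0:
            raise ValueError(
                "planted_ddi_density too small: rounds to zero planted pairs; "
                "raise the density or the domain count"
            )
        planted_list: list[tuple[str, str]] = []
    else:
        chosen = rng.choice(len(all_pairs), size=n_planted, replace=False)
        planted_list = [all_pairs[i] for i in sorted(chosen)]
    planted = DDIPairSet(frozenset(planted_list))

    # base edges: protein pairs sharing >= 1 planted DDI, subsampled to sparsity
    explainable = []
    for a_idx in range(spec.n_proteins):
        for b_idx in range(a_idx + 1, spec.n_proteins):
            pa, pb = proteins[a_idx], proteins[b_idx]
            if _shares_planted(assignments[pa], assignments[pb], planted):
                explainable.append((pa, pb))
    target = int(round(spec.mean_degree * spec.n_proteins / 2))
    if len(explainable) > target:
        keep = rng.choice(len(explainable), size=target, replace=False)
        base = [explainable[i] for i in sorted(keep)]
    else:
        base = list(explainable)

    # false negatives: remove a fraction of true edges
    n_fn = int(round(spec.fn_rate * len(base)))
    if n_fn:
        drop = set(rng.choice(len(base), size=n_fn, replace=False).tolist())
        base = [e for k, e in enumerate(base) if k not in drop]
    edges = set(base)

    # false positives: spurious edges with no planted explanation, budgeted
    # against the nominal edge count so a pure-noise network (density 0,
    # fp_rate > 0) is expressible
    n_fp = int(round(spec.fp_rate * max(len(base), 1) if base else spec.fp_rate * target))
    tries = 0
    while n_fp > 0 and tries < 100 * max(n_fp, 1):
        tries += 1
        a_idx, b_idx = rng.integers(0, spec.n_proteins, size=2)
        if a_idx == b_idx:
            continue
        pa, pb = proteins[min(a_idx, b_idx)], proteins[max(a_idx, b_idx)]
        if (pa, pb) in edges:
            continue
        if _shares_planted(assignments[pa], assignments[pb], planted):
            continue
        edges.add((pa, pb))
        n_fp -= 1

    # triangle boost: close explainable wedges centered on poor nodes
    planted_pairs = set(planted.pairs)
    if spec.triangle_boost > 0 and edges:
        degree: dict[str, int] = {p: 0 for p in proteins}
        adj: dict[str, set[str]] = {p: set() for p in proteins}
        for a, b in edges:
            degree[a] += 1
            degree[b] += 1
            adj[a].add(b)
            adj[b].add(a)
        positive = sorted(d for d in degree.values() if d > 0)
        poor_cut = positive[len(positive) // 3] if positive else 0
        for p in proteins:
            if not 0 < degree[p] <= poor_cut:
                continue
            neigh = sorted(adj[p])
            for i in range(len(neigh)):
                for j in range(i + 1, len(neigh)):
                    e = canonical_pair(neigh[i], neigh[j])
                    if e in edges or rng.random() >= spec.triangle_boost:
                        continue
                    if not _shares_planted(
                        assignments[e[0]], assignments[e[1]], planted
                    ):
                        # make the closure a true edge by planting its DDI
                        da = sorted(assignments[e[0]])[
                            int(rng.integers(len(assignments[e[0]])))
                        ]
                        db = sorted(assignments[e[1]])[
                            int(rng.integers(len(assignments[e[1]])))
                        ]
                        planted_pairs.add(canonical_pair(da, db))
                    edges.add(e)
    planted = DDIPairSet(frozenset(planted_pairs))

    network = PPINetwork(frozenset(proteins), frozenset(edges))
    true_edges = frozenset(
        e
        for e in edges
        if _shares_planted(assignments[e[0]], assignments[e[1]], planted)
    )
    return SyntheticDataset(network, composition, planted, true_edges, spec)


def _shares_planted(doms_a, doms_b, planted: DDIPairSet) -> bool:
    for i in doms_a:
        for j in doms_b:
            if canonical_pair(i, j) in planted.pairs:
                return True
    return False


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> None:
    """Emit ppi.tsv, domains.tsv, gold.tsv and a JSON manifest of the spec."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ppi_edgelist(dataset.network, directory / "ppi.tsv")
    write_domain_composition(dataset.composition, directory / "domains.tsv")
    write_ddi_pairs(dataset.planted, directory / "gold.tsv")
    manifest = {
        "generator": "ddinfer.synthetic_data",
        "spec": asdict(dataset.spec),
        "n_edges": dataset.network.n_edges,
        "n_planted": len(dataset.planted),
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
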