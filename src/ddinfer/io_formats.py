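"""Delimited-text I/O for PPI networks, domain compositions and DDI pair sets.

All formats are plain whitespace- or character-delimited text: a PPI edge
list is two protein identifiers per row, a domain composition table is
either long format (``protein domain``, one row per assignment) or wide
format (``protein dom1,dom2,...``), and a DDI pair list is two domain
identifiers per row.  Lines starting with ``#`` are comments.  Identifiers
are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger("ddinfer")

__all__ = [
    "PPINetwork",
    "DomainComposition",
    "DDIPairSet",
    "LoadReport",
    "ParseError",
    "read_ppi_edgelist",
    "read_domain_composition",
    "read_ddi_pairs",
    "write_ddi_pairs",
    "write_ppi_edgelist",
    "write_domain_composition",
    "harmonize",
    "write_predictions",
    "canonical_pair",
]


class ParseError(ValueError):
    """A malformed row in a delimited input file."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return an unordered pair as a sorted tuple (lexicographically)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPINetwork:
    """An undirected simple graph of proteins: the observed PPI network.

    Edges are stored canonically (smaller identifier first); self-pairs are
    never present.  Isolated proteins are allowed.
    """

    proteins: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-pair ({a},{b}) in network edges")
            if a > b:
                raise ValueError(f"edge ({a},{b}) is not canonically ordered")
            if a not in self.proteins or b not in self.proteins:
                raise ValueError(f"edge ({a},{b}) has endpoint outside protein set")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str]], proteins: Iterable[str] = ()
    ) -> "PPINetwork":
        """Build a network from an edge iterable, canonicalizing and dropping self-pairs."""
        prot = set(proteins)
        canon = set()
        for a, b in edges:
            if a == b:
                continue
            canon.add(canonical_pair(a, b))
            prot.add(a)
            prot.add(b)
        return cls(frozenset(prot), frozenset(canon))

    @classmethod
    def from_networkx(cls, graph: nx.Graph) -> "PPINetwork":
        return cls.from_edges(
            ((str(a), str(b)) for a, b in graph.edges()),
            (str(p) for p in graph.nodes()),
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from(self.edges)
        return g

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, protein: str) -> int:
        if protein not in self.proteins:
            raise KeyError(f"unknown protein {protein!r}")
        return sum(1 for a, b in self.edges if a == protein or b == protein)

    def degrees(self) -> dict[str, int]:
        d = {p: 0 for p in self.proteins}
        for a, b in self.edges:
            d[a] += 1
            d[b] += 1
        return d

    def neighbors(self, protein: str) -> set[str]:
        if protein not in self.proteins:
            raise KeyError(f"unknown protein {protein!r}")
        out = set()
        for a, b in self.edges:
            if a == protein:
                out.add(b)
            elif b == protein:
                out.add(a)
        return out


@dataclass(frozen=True)
class DomainComposition:
    """Map protein identifier -> set of constituent domain identifiers.

    Domain sets are deduplicated; copy number within one protein is
    irrelevant for which domain pairs an interaction can expose.
    """

    assignments: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for p, doms in self.assignments.items():
            if not p:
                raise ValueError("empty protein identifier in composition")
            if not doms:
                raise ValueError(f"protein {p!r} has an empty domain set")

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "DomainComposition":
        return cls({p: frozenset(doms) for p, doms in d.items()})

    def __contains__(self, protein: str) -> bool:
        return protein in self.assignments

    def __getitem__(self, protein: str) -> frozenset[str]:
        return self.assignments[protein]

    def __len__(self) -> int:
        return len(self.assignments)

    @property
    def proteins(self) -> set[str]:
        return set(self.assignments)

    def domain_universe(self) -> set[str]:
        out: set[str] = set()
        for doms in self.assignments.values():
            out |= doms
        return out


@dataclass(frozen=True)
class DDIPairSet:
    """A set of unordered domain pairs (homodomain pairs (A, A) are legal)."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a > b:
                raise ValueError(f"pair ({a},{b}) is not canonically ordered")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DDIPairSet":
        return cls(frozenset(canonical_pair(a, b) for a, b in pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.pairs


@dataclass
class LoadReport:
    """Counts of rows touched/cleaned while loading or harmonizing."""

    rows_read: int = 0
    self_loops_dropped: int = 0
    duplicate_edges_merged: int = 0
    proteins_without_composition: int = 0
    comment_or_blank: int = 0

    def __post_init__(self) -> None:
        for f in (
            self.rows_read,
            self.self_loops_dropped,
            self.duplicate_edges_merged,
            self.proteins_without_composition,
        ):
            if f < 0:
                raise ValueError("LoadReport counts must be non-negative")


def _data_rows(path: Path, report: LoadReport | None = None):
    """Yield (line_number, stripped_line) for non-comment, non-blank rows."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                if report is not None:
                    report.comment_or_blank += 1
                continue
            yield lineno, stripped


def _split(line: str, delimiter: str | None) -> list[str]:
    # delimiter=None means "any whitespace run", the default dialect
    return line.split(delimiter) if delimiter else line.split()


def read_ppi_edgelist(
    path: str | Path, delimiter: str | None = None
) -> tuple[PPINetwork, LoadReport]:
    """Read a two-column PPI edge list.

    Duplicate rows (in either orientation) are merged and counted;
    self-pairs are dropped and counted.  Extra columns are ignored.
    """
    path = Path(path)
    report = LoadReport()
    proteins: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for lineno, line in _data_rows(path, report):
        fields = _split(line, delimiter)
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected >= 2 fields, got {len(fields)}")
        report.rows_read += 1
        a, b = fields[0], fields[1]
        proteins.add(a)
        proteins.add(b)
        if a == b:
            report.self_loops_dropped += 1
            continue
        pair = canonical_pair(a, b)
        if pair in edges:
            report.duplicate_edges_merged += 1
        else:
            edges.add(pair)
    return PPINetwork(frozenset(proteins), frozenset(edges)), report


def read_domain_composition(
    path: str | Path, delimiter: str | None = None
) -> DomainComposition:
    """Read a protein -> domains table.

    Accepts long format (``protein domain``, repeated rows unioned) and wide
    format (``protein dom1,dom2,...``), auto-detected per row by the
    presence of commas in the second field.
    """
    path = Path(path)
    assignments: dict[str, set[str]] = {}
    for lineno, line in _data_rows(path):
        fields = _split(line, delimiter)
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected >= 2 fields, got {len(fields)}")
        protein = fields[0]
        domains = [d for chunk in fields[1:] for d in chunk.split(",") if d]
        if not domains:
            raise ParseError(f"{path}:{lineno}: no domain identifiers")
        assignments.setdefault(protein, set()).update(domains)
    return DomainComposition.from_dict(assignments)


def read_ddi_pairs(path: str | Path, delimiter: str | None = None) -> DDIPairSet:
    """Read a two-column list of domain pairs (homodomain pairs retained)."""
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    for lineno, line in _data_rows(path):
        fields = _split(line, delimiter)
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected >= 2 fields, got {len(fields)}")
        pairs.add(canonical_pair(fields[0], fields[1]))
    return DDIPairSet(frozenset(pairs))


def write_ppi_edgelist(network: PPINetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")


def write_domain_composition(composition: DomainComposition, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for protein in sorted(composition.assignments):
            doms = ",".join(sorted(composition.assignments[protein]))
            fh.write(f"{protein}\t{doms}\n")


def write_ddi_pairs(pairs: DDIPairSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(pairs.pairs):
            fh.write(f"{a}\t{b}\n")


def harmonize(
    network: PPINetwork, composition: DomainComposition
) -> tuple[PPINetwork, LoadReport]:
    """Restrict a network to its composition-annotated proteins.

    Returns the induced subnetwork on proteins with a domain annotation,
    dropping edges with one or more unannotated endpoints.  This mirrors
    the usual restriction of a PPI dataset to proteins with known domain
    architecture before candidate domain pairs are enumerated.
    """
    annotated = network.proteins & composition.proteins
    missing = network.proteins - composition.proteins
    kept = frozenset(e for e in network.edges if e[0] in annotated and e[1] in annotated)
    report = LoadReport(proteins_without_composition=len(missing))
    if not annotated:
        logger.warning("harmonize: no network protein has a domain composition")
    return PPINetwork(frozenset(annotated), kept), report


def write_predictions(
    predictions: Iterable[tuple[tuple[str, str], float, float, int, bool]],
    path: str | Path,
) -> None:
    """Write candidate-pair predictions as 6-column TSV.

    Rows are ordered by descending LP value, then lexicographic pair, so
    output is deterministic for a given prediction set.
    """
    rows = sorted(predictions, key=lambda r: (-r[1], r[0]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("domain_i\tdomain_j\tlp_value\tweight\tn_supporting_edges\tpredicted\n")
        for (di, dj), lp_value, weight, n_support, predicted in rows:
            fh.write(
                f"{di}\t{dj}\t{lp_value:.6g}\t{weight:.6g}\t{n_support}\t{int(predicted)}\n"
            )
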