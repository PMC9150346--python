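"""Readers for the four RWRT input data types.

The protein universe is defined by the PPI edge list: every other record
(GO annotation, domain membership, complex catalog) is silently restricted
to proteins that appear in at least one retained interaction.  Identifiers
are matched as exact strings after whitespace trimming; no identifier
mapping is attempted, so the same naming system must be used across files.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger("rwrt")

__all__ = [
    "InputFormatError",
    "ProteinIndex",
    "PPINetwork",
    "FunctionAnnotation",
    "DomainAnnotation",
    "ComplexCatalog",
    "Dataset",
    "read_ppi",
    "write_ppi",
    "read_annotations",
    "read_domains",
    "read_complexes",
    "load_dataset",
]


class InputFormatError(ValueError):
    """A malformed input file; carries the offending path and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


@dataclass(frozen=True)
class ProteinIndex:
    """Bijective map between protein identifiers and dense indices 0..n-1.

    Identifiers are ordered lexicographically so that the index — and hence
    every matrix and tensor built on top of it — is deterministic for a
    given input.
    """

    ids: tuple[str, ...]
    index_of: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "ProteinIndex":
        ordered = tuple(sorted(set(ids)))
        if not ordered:
            raise ValueError("cannot build a ProteinIndex from zero proteins")
        return cls(ids=ordered, index_of={p: i for i, p in enumerate(ordered)})

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, protein: str) -> bool:
        return protein in self.index_of


@dataclass(frozen=True)
class PPINetwork:
    """Undirected PPI network over a ProteinIndex.

    ``edges`` holds each interaction once as an index pair ``(i, j)`` with
    ``i < j``; self-interactions and duplicates are removed on read.
    """

    index: ProteinIndex
    edges: frozenset[tuple[int, int]]

    @property
    def n(self) -> int:
        return self.index.n

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 adjacency matrix."""
        n = self.n
        if not self.edges:
            return sparse.csr_matrix((n, n))
        rows, cols = zip(*self.edges)
        rows, cols = np.array(rows), np.array(cols)
        data = np.ones(len(rows))
        a = sparse.coo_matrix((data, (rows, cols)), shape=(n, n))
        a = a + a.T
        return a.tocsr()

    def closed_neighborhoods(self) -> list[frozenset[int]]:
        """Per protein: the protein itself plus its direct interactors."""
        nbrs: list[set[int]] = [{i} for i in range(self.n)]
        for i, j in self.edges:
            nbrs[i].add(j)
            nbrs[j].add(i)
        return [frozenset(s) for s in nbrs]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


@dataclass(frozen=True)
class FunctionAnnotation:
    """Flat protein -> GO term map (BP namespace) and its transpose."""

    terms_of: Mapping[int, frozenset[str]]
    proteins_of: Mapping[str, frozenset[int]]

    @property
    def term_universe(self) -> frozenset[str]:
        return frozenset(self.proteins_of)

    @property
    def annotated(self) -> tuple[int, ...]:
        """Indices of proteins carrying at least one term, ascending."""
        return tuple(sorted(i for i, ts in self.terms_of.items() if ts))

    def mask(self, proteins: Iterable[int]) -> "FunctionAnnotation":
        """Hide all annotations of the given proteins (for cross-validation).

        The masked proteins keep their network/domain/complex data elsewhere;
        only their GO terms become invisible to the predictor.
        """
        hidden = set(proteins)
        terms_of = {i: ts for i, ts in self.terms_of.items() if i not in hidden}
        proteins_of: dict[str, frozenset[int]] = {}
        for t, ps in self.proteins_of.items():
            kept = frozenset(p for p in ps if p not in hidden)
            if kept:
                proteins_of[t] = kept
        return FunctionAnnotation(terms_of=terms_of, proteins_of=proteins_of)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, str]]) -> "FunctionAnnotation":
        terms: dict[int, set[str]] = defaultdict(set)
        prots: dict[str, set[int]] = defaultdict(set)
        for i, t in pairs:
            terms[i].add(t)
            prots[t].add(i)
        return cls(
            terms_of={i: frozenset(ts) for i, ts in terms.items()},
            proteins_of={t: frozenset(ps) for t, ps in prots.items()},
        )


@dataclass(frozen=True)
class DomainAnnotation:
    """Protein -> structural-domain membership (e.g. PFAM accessions)."""

    domains_of: tuple[frozenset[str], ...]  # position = protein index
    universe: frozenset[str]

    @classmethod
    def from_map(cls, mapping: Mapping[int, Iterable[str]], n: int) -> "DomainAnnotation":
        sets = [frozenset(mapping.get(i, ())) for i in range(n)]
        universe = frozenset().union(*sets) if sets else frozenset()
        return cls(domains_of=tuple(sets), universe=universe)


@dataclass
class ComplexCatalog:
    """Experimentally detected protein complexes, as protein-index sets.

    ``scores`` (per-module PPI edge density in [0, 1]) is filled in by the
    tensor-construction stage.
    """

    modules: list[frozenset[int]]
    scores: list[float] | None = None


@dataclass
class Dataset:
    """The four inputs sharing one ProteinIndex."""

    net: PPINetwork
    domains: DomainAnnotation
    catalog: ComplexCatalog
    annotations: FunctionAnnotation

    @property
    def index(self) -> ProteinIndex:
        return self.net.index


def _data_lines(path, comment: str = "#"):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment):
                continue
            yield lineno, line


def read_ppi(path) -> PPINetwork:
    """Read a two-column TSV edge list into a PPINetwork.

    Self-interactions and repeated interactions are removed; the protein
    index covers exactly the proteins appearing in at least one retained
    edge.  Extra columns (e.g. confidence scores) are ignored.
    """
    pairs: set[tuple[str, str]] = set()
    n_self = n_dup = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise InputFormatError(path, lineno, f"expected >= 2 fields, got {len(fields)}")
        a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in pairs:
            n_dup += 1
        else:
            pairs.add(key)
    if not pairs:
        raise ValueError(f"{path}: no interactions remain after filtering")
    index = ProteinIndex.from_ids(p for pair in pairs for p in pair)
    edges = frozenset(
        tuple(sorted((index.index_of[a], index.index_of[b]))) for a, b in pairs
    )
    if n_self or n_dup:
        logger.info("read_ppi: dropped %d self-interactions, %d duplicates", n_self, n_dup)
    return PPINetwork(index=index, edges=edges)


def write_ppi(net: PPINetwork, path) -> None:
    """Write the edge list back as TSV (round-trips with :func:`read_ppi`)."""
    ids = net.index.ids
    with open(path, "w") as fh:
        for i, j in sorted(net.edges):
            fh.write(f"{ids[i]}\t{ids[j]}\n")


def _looks_like_gaf(path) -> bool:
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("!"):
                return True
            if not line.strip() or line.startswith("#"):
                continue
            return len(line.split("\t")) >= 15
    return False


def _iter_gaf_pairs(path, index: ProteinIndex, namespace: str):
    aspect = {"BP": "P", "MF": "F", "CC": "C"}[namespace]
    for lineno, raw in enumerate(open(path), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) < 15:
            raise InputFormatError(path, lineno, f"GAF line has {len(fields)} columns, expected >= 15")
        if fields[8].strip() != aspect:
            continue
        # match the DB object id first, then the symbol
        for cand in (fields[1].strip(), fields[2].strip()):
            if cand in index:
                yield index.index_of[cand], fields[4].strip()
                break


def _iter_tsv_pairs(path, index: ProteinIndex):
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise InputFormatError(path, lineno, f"expected 2 fields, got {len(fields)}")
        protein, term = fields[0], fields[1]
        if protein in index:
            yield index.index_of[protein], term


def read_annotations(
    path,
    index: ProteinIndex,
    namespace: str = "BP",
    min_count: int = 10,
    max_count: int = 200,
) -> FunctionAnnotation:
    """Read GO annotations (GAF 2.x or 2-column TSV) and filter rare/generic terms.

    Only terms annotating between ``min_count`` and ``max_count`` indexed
    proteins (inclusive on both ends) are retained, which drops terms that
    are too specific or too general to be informative.  Counting happens
    after restriction to the protein index.
    """
    if min_count > max_count:
        raise ValueError(f"min_count {min_count} > max_count {max_count}")
    if _looks_like_gaf(path):
        pairs = _iter_gaf_pairs(path, index, namespace)
    else:
        pairs = _iter_tsv_pairs(path, index)
    full = FunctionAnnotation.from_pairs(pairs)
    kept = {
        t: ps for t, ps in full.proteins_of.items() if min_count <= len(ps) <= max_count
    }
    if not kept:
        raise ValueError(
            f"{path}: no GO terms annotate between {min_count} and {max_count} indexed proteins"
        )
    dropped = len(full.proteins_of) - len(kept)
    if dropped:
        logger.info("read_annotations: removed %d terms outside [%d, %d]", dropped, min_count, max_count)
    return FunctionAnnotation.from_pairs((p, t) for t, ps in kept.items() for p in ps)


def read_domains(path, index: ProteinIndex) -> DomainAnnotation:
    """Read a 2-column protein -> domain TSV; unindexed proteins are ignored."""
    mapping: dict[int, set[str]] = defaultdict(set)
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise InputFormatError(path, lineno, f"expected 2 fields, got {len(fields)}")
        protein, domain = fields[0], fields[1]
        if protein in index:
            mapping[index.index_of[protein]].add(domain)
    return DomainAnnotation.from_map(mapping, index.n)


def read_complexes(path, index: ProteinIndex) -> ComplexCatalog:
    """Read a complex catalog: one complex per line, members whitespace-separated.

    Members absent from the index are dropped; complexes retaining fewer
    than two members are discarded (a one-protein module carries no
    co-membership information).
    """
    modules: list[frozenset[int]] = []
    n_dropped = 0
    for _lineno, line in _data_lines(path):
        members = frozenset(
            index.index_of[p] for p in line.split() if p in index
        )
        if len(members) >= 2:
            modules.append(members)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("read_complexes: dropped %d modules with < 2 indexed members", n_dropped)
    return ComplexCatalog(modules=modules)


def load_dataset(
    ppi_path,
    go_path,
    domains_path,
    complexes_path,
    namespace: str = "BP",
    min_count: int = 10,
    max_count: int = 200,
) -> Dataset:
    """Load all four inputs against the protein index defined by the PPI file."""
    net = read_ppi(ppi_path)
    return Dataset(
        net=net,
        domains=read_domains(domains_path, net.index),
        catalog=read_complexes(complexes_path, net.index),
        annotations=read_annotations(
            go_path, net.index, namespace=namespace, min_count=min_count, max_count=max_count
        ),
    )
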