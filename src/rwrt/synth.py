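"""Synthetic benchmark generator with planted functional structure.

Emulates the statistical structure the method assumes: a planted-partition
PPI graph whose blocks play the role of functional modules, protein
domains shared within a module, GO terms planted per module with
annotation noise, and a complex catalog that subsamples each module.  The
generator writes the four standard input files (edge-list TSV, 2-column
GO TSV, 2-column domain TSV, one-complex-per-line catalog) plus a
``truth.json`` with the planted assignments, and is byte-reproducible
from its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    ComplexCatalog,
    Dataset,
    DomainAnnotation,
    FunctionAnnotation,
    PPINetwork,
    ProteinIndex,
)
from .tensor import LAYER_NAMES, SimilarityTensor, _symmetric_from_upper

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "degenerate_fixtures"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one planted-structure dataset.

    Defaults describe a small but structured benchmark: 200 proteins in
    10 equal modules, dense within-module interaction (0.8) against a
    sparse background (0.02), and 3 domains and 3 GO terms planted per
    module with 10% annotation/domain noise.  The evidence channels are
    deliberately incomplete, mirroring real catalogs: only
    ``domain_coverage`` of proteins carry any domain record (PFAM covers
    roughly 60% of yeast PPI proteins) and each complex record retains
    each module member with probability ``complex_coverage`` (CYC2008
    reaches roughly 30% of network proteins).  Proteins missing both
    channels must be resolved by the walk itself.
    """

    seed: int
    n_proteins: int = 200
    n_modules: int = 10
    p_within: float = 0.8
    p_between: float = 0.02
    domains_per_module: int = 3
    domain_noise: float = 0.1
    domain_coverage: float = 0.6
    terms_per_module: int = 3
    annotation_noise: float = 0.1
    complex_coverage: float = 0.3

    def __post_init__(self):
        for name in (
            "p_within",
            "p_between",
            "domain_noise",
            "domain_coverage",
            "annotation_noise",
            "complex_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_proteins < 2 * self.n_modules:
            raise ValueError("need at least 2 proteins per module")


@dataclass
class SyntheticTruth:
    """The planted ground truth and the emitted dataset."""

    config: SyntheticConfig
    proteins: tuple[str, ...]
    module_of: dict[str, int]
    planted_terms: dict[int, frozenset[str]]
    dataset: Dataset
    files: dict[str, Path] = field(default_factory=dict)


def _protein_names(n: int) -> tuple[str, ...]:
    width = len(str(n - 1))
    return tuple(f"P{str(i).zfill(width)}" for i in range(n))


def generate(cfg: SyntheticConfig, outdir: str | Path | None = None) -> SyntheticTruth:
    """Generate a planted-structure dataset; optionally write its files.

    Stage sub-generators (graph, domains, terms, complexes) are spawned
    deterministically from the single seed, so regenerating one stage
    never shifts another.  A protein left isolated by the edge sampling
    is reconnected to a random same-module partner, since a protein
    absent from the edge list would fall out of the universe.
    """
    n, k = cfg.n_proteins, cfg.n_modules
    names = _protein_names(n)
    module_of_idx = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    graph_rng, domain_rng, term_rng, complex_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(4)
    )

    # --- planted-partition graph -------------------------------------
    iu, ju = np.triu_indices(n, k=1)
    same = module_of_idx[iu] == module_of_idx[ju]
    probs = np.where(same, cfg.p_within, cfg.p_between)
    mask = graph_rng.random(len(iu)) < probs
    edges = {(int(i), int(j)) for i, j in zip(iu[mask], ju[mask])}
    degree = np.zeros(n, dtype=int)
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1
    for i in np.flatnonzero(degree == 0):
        mates = np.flatnonzero(module_of_idx == module_of_idx[i])
        mates = mates[mates != i]
        j = int(graph_rng.choice(mates))
        edges.add((min(i, j), max(i, j)))
        degree[i] += 1
        degree[j] += 1

    index = ProteinIndex.from_ids(names)  # zero-padded names sort in order
    net = PPINetwork(index=index, edges=frozenset(edges))

    # --- domains: a shared pool per module, plus noise ----------------
    pool = {
        m: [f"PF{90000 + m * cfg.domains_per_module + d}" for d in range(cfg.domains_per_module)]
        for m in range(k)
    }
    all_domains = [d for m in range(k) for d in pool[m]]
    domains_of: dict[int, set[str]] = {}
    for i in range(n):
        covered = domain_rng.random() < cfg.domain_coverage
        ds = set(pool[int(module_of_idx[i])]) if covered else set()
        if domain_rng.random() < cfg.domain_noise:
            ds.add(all_domains[int(domain_rng.integers(len(all_domains)))])
        domains_of[i] = ds
    domains = DomainAnnotation.from_map(domains_of, n)

    # --- GO terms: planted per module, dropped/replaced with noise ----
    planted = {
        m: frozenset(
            f"GO:{900000 + m * cfg.terms_per_module + t:07d}"
            for t in range(cfg.terms_per_module)
        )
        for m in range(k)
    }
    all_terms = sorted(t for ts in planted.values() for t in ts)
    pairs: list[tuple[int, str]] = []
    for i in range(n):
        m = int(module_of_idx[i])
        for term in sorted(planted[m]):
            r = term_rng.random()
            if r < cfg.annotation_noise / 2.0:
                continue  # dropped
            if r < cfg.annotation_noise:  # replaced by a random foreign term
                foreign = [t for t in all_terms if t not in planted[m]]
                if foreign:
                    term = foreign[int(term_rng.integers(len(foreign)))]
            pairs.append((i, term))
    annotations = FunctionAnnotation.from_pairs(pairs)

    # --- complexes: one subsample per module, >= 2 members ------------
    complexes: list[frozenset[int]] = []
    for m in range(k):
        members = np.flatnonzero(module_of_idx == m)
        while True:
            kept = members[complex_rng.random(len(members)) < cfg.complex_coverage]
            if len(kept) >= 2:
                break
        complexes.append(frozenset(int(i) for i in kept))
    catalog = ComplexCatalog(modules=complexes)

    dataset = Dataset(net=net, domains=domains, catalog=catalog, annotations=annotations)
    truth = SyntheticTruth(
        config=cfg,
        proteins=names,
        module_of={names[i]: int(module_of_idx[i]) for i in range(n)},
        planted_terms=planted,
        dataset=dataset,
    )
    if outdir is not None:
        truth.files = _write_files(truth, Path(outdir))
    return truth


def _write_files(truth: SyntheticTruth, outdir: Path) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    names = truth.proteins
    ds = truth.dataset
    paths = {
        "ppi": outdir / "ppi.tsv",
        "go": outdir / "annotations.tsv",
        "domains": outdir / "domains.tsv",
        "complexes": outdir / "complexes.txt",
        "truth": outdir / "truth.json",
    }
    with open(paths["ppi"], "w") as fh:
        for i, j in sorted(ds.net.edges):
            fh.write(f"{names[i]}\t{names[j]}\n")
    with open(paths["go"], "w") as fh:
        for i in sorted(ds.annotations.terms_of):
            for term in sorted(ds.annotations.terms_of[i]):
                fh.write(f"{names[i]}\t{term}\n")
    with open(paths["domains"], "w") as fh:
        for i, doms in enumerate(ds.domains.domains_of):
            for d in sorted(doms):
                fh.write(f"{names[i]}\t{d}\n")
    with open(paths["complexes"], "w") as fh:
        for mod in ds.catalog.modules:
            fh.write(" ".join(names[i] for i in sorted(mod)) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "config": asdict(truth.config),
                "module_of": truth.module_of,
                "planted_terms": {m: sorted(ts) for m, ts in truth.planted_terms.items()},
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return paths


def degenerate_fixtures() -> dict[str, object]:
    """Hand-built edge-case inputs used across the test suite.

    Returns a dict with: a single-edge network, a network carrying an
    annotation-free protein, an empty domain annotation, a one-module
    catalog, and a 5-node 3-layer multigraph tensor with hand-set weights
    for contraction oracles.
    """
    idx2 = ProteinIndex.from_ids(["A", "B"])
    single_edge = PPINetwork(index=idx2, edges=frozenset({(0, 1)}))

    idx4 = ProteinIndex.from_ids(["A", "B", "C", "D"])
    path_net = PPINetwork(index=idx4, edges=frozenset({(0, 1), (1, 2), (2, 3)}))
    annotations = FunctionAnnotation.from_pairs(
        [(0, "GO:0900000"), (1, "GO:0900000"), (2, "GO:0900001")]
    )  # protein D (index 3) is annotation-free

    empty_domains = DomainAnnotation.from_map({}, 4)
    one_module = ComplexCatalog(modules=[frozenset({0, 1, 2})])

    layers = (
        _symmetric_from_upper(5, [0, 1, 0], [1, 2, 2], [0.9, 0.8, 0.5]),
        _symmetric_from_upper(5, [1, 3], [3, 4], [0.7, 0.6]),
        _symmetric_from_upper(5, [0, 2, 1], [4, 3, 4], [0.4, 0.3, 0.2]),
    )
    five_node = SimilarityTensor(n=5, layers=layers, layer_names=LAYER_NAMES)

    return {
        "single_edge": single_edge,
        "path_network": path_net,
        "annotations_with_gap": annotations,
        "empty_domains": empty_domains,
        "one_module_catalog": one_module,
        "five_node_multigraph": five_node,
    }
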