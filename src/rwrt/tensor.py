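"""Construction of the n x n x 3 functional-similarity tensor.

The tensor stacks three symmetric association layers over one protein set:

* layer 0 ("physical")     — topological similarity from shared closed
  PPI neighborhoods;
* layer 1 ("co-structure") — similarity of the domain content of the two
  proteins' closed neighborhoods, scored hypergeometrically and min-max
  normalized;
* layer 2 ("co-module")    — co-membership in experimentally detected
  complexes, weighted by complex edge density.

All layers exclude the diagonal and store only strictly positive values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.special import gammaln

from .io import ComplexCatalog, DomainAnnotation, PPINetwork, ProteinIndex

logger = logging.getLogger("rwrt")

__all__ = [
    "LAYER_NAMES",
    "SimilarityTensor",
    "DomainContext",
    "topology_layer",
    "domain_context",
    "domain_similarity",
    "costructure_layer",
    "module_density",
    "comodule_layer",
    "build_tensor",
    "write_tensor",
    "read_tensor",
]

LAYER_NAMES = ("physical", "co-structure", "co-module")


@dataclass(frozen=True)
class SimilarityTensor:
    """Sparse third-order tensor T: one symmetric n x n matrix per layer.

    Invariants: every stored value is positive and finite, each layer is
    exactly symmetric, and the diagonal is never stored (self-similarity
    would dominate the walk and the annotation step never uses it).
    """

    n: int
    layers: tuple[sparse.csr_matrix, ...]
    layer_names: tuple[str, ...] = LAYER_NAMES

    @property
    def m(self) -> int:
        return len(self.layers)

    def nnz(self) -> int:
        return int(sum(layer.nnz for layer in self.layers))


def _symmetric_from_upper(n: int, rows, cols, vals) -> sparse.csr_matrix:
    """Build an exactly symmetric CSR matrix from upper-triangle entries."""
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    vals = np.asarray(vals, dtype=float)
    keep = vals > 0
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    mat = sparse.coo_matrix(
        (np.concatenate([vals, vals]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    mat.sum_duplicates()
    return mat


def topology_layer(net: PPINetwork) -> sparse.csr_matrix:
    """Topological similarity from shared closed neighborhoods.

    For closed neighborhoods N_i (protein plus direct interactors),

        t(i,j) = 4 |N_i ∩ N_j|^2 / ((|N_i| + |N_i ∩ N_j|) (|N_j| + |N_i ∩ N_j|))

    computed for every pair with a non-empty intersection (the formula
    needs no direct edge between i and j); values lie in (0, 1].
    """
    n = net.n
    b = net.adjacency()
    b = (b + sparse.identity(n, format="csr")).astype(float)
    sizes = np.asarray(b.sum(axis=1)).ravel()  # |N_i|
    common = sparse.triu(b @ b.T, k=1).tocoo()  # |N_i ∩ N_j| for i < j
    c = common.data
    si = sizes[common.row]
    sj = sizes[common.col]
    vals = 4.0 * c * c / ((si + c) * (sj + c))
    return _symmetric_from_upper(n, common.row, common.col, vals)


@dataclass(frozen=True)
class DomainContext:
    """Per-protein neighborhood domain content.

    ``context_of[i]`` is the set of distinct domain types carried by
    protein i or any of its direct PPI neighbors; ``universe`` is the
    set of domain types present anywhere in the network (DT).
    """

    context_of: tuple[frozenset[str], ...]
    universe: frozenset[str]


def domain_context(net: PPINetwork, domains: DomainAnnotation) -> DomainContext:
    """Assemble each protein's closed-neighborhood domain set."""
    own = domains.domains_of
    ctx: list[set[str]] = [set(own[i]) for i in range(net.n)]
    for i, j in net.edges:
        ctx[i] |= own[j]
        ctx[j] |= own[i]
    return DomainContext(
        context_of=tuple(frozenset(s) for s in ctx), universe=domains.universe
    )


def _log_binom(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _domain_similarity_sizes(di, dj, dc, dt):
    """Vectorized -log hypergeometric score from set sizes (log-gamma)."""
    log_ratio = (
        _log_binom(dt, dc)
        + _log_binom(dt - dc, di - dc)
        + _log_binom(dt - di, dj - dc)
        - _log_binom(dt, di)
        - _log_binom(dt, dj)
    )
    return -log_ratio


def domain_similarity(d_i: frozenset, d_j: frozenset, dt_size: int) -> float:
    """Domain content similarity DS(i, j) of two neighborhood domain sets.

    DS is the negative log of a hypergeometric ratio: how surprising it
    is that |D_i ∩ D_j| domain types are shared given |DT| types exist.
    Binomials are evaluated in log space (log-gamma), which stays finite
    for |DT| of order 10^3 where naive factorials overflow.
    """
    di, dj = len(d_i), len(d_j)
    dc = len(d_i & d_j)
    dt = int(dt_size)
    if di > dt or dj > dt or dj - dc > dt - di or di - dc > dt - dc:
        raise ValueError(
            f"undefined binomial for |D_i|={di}, |D_j|={dj}, |DC|={dc}, |DT|={dt}"
        )
    return float(_domain_similarity_sizes(di, dj, dc, dt))


def costructure_layer(dc: DomainContext) -> sparse.csr_matrix:
    """Co-structure similarity: min-max-normalized DS over evidence pairs.

    DS is evaluated only for unordered pairs whose neighborhood domain
    sets overlap (pairs without shared domain types carry no co-structure
    evidence and stay implicit zeros); the min-max normalization is taken
    over exactly that evaluated set, mapping it into [0, 1].  If every
    evaluated pair has the same DS, all entries are set to 1.
    """
    n = len(dc.context_of)
    dt = len(dc.universe)
    if dt == 0:
        logger.warning("costructure_layer: no domain data; layer is empty")
        return sparse.csr_matrix((n, n))
    dom_index = {d: k for k, d in enumerate(sorted(dc.universe))}
    rows, cols = [], []
    for i, ds in enumerate(dc.context_of):
        for d in ds:
            rows.append(i)
            cols.append(dom_index[d])
    inc = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, dt)
    ).tocsr()
    shared = sparse.triu(inc @ inc.T, k=1).tocoo()  # |D_i ∩ D_j| for i < j
    if shared.nnz == 0:
        logger.warning("costructure_layer: no pair shares a domain; layer is empty")
        return sparse.csr_matrix((n, n))
    sizes = np.asarray(inc.sum(axis=1)).ravel()
    ds_vals = _domain_similarity_sizes(
        sizes[shared.row], sizes[shared.col], shared.data, float(dt)
    )
    lo, hi = ds_vals.min(), ds_vals.max()
    if hi > lo:
        vals = (ds_vals - lo) / (hi - lo)
    else:
        logger.warning("costructure_layer: degenerate min-max range; all entries set to 1")
        vals = np.ones_like(ds_vals)
    return _symmetric_from_upper(n, shared.row, shared.col, vals)


def module_density(module: frozenset[int], net: PPINetwork) -> float:
    """PPI edge density of a complex: 2|E_k| / (|V_k| (|V_k| - 1)).

    Internal edges are counted from the physical PPI edge set only.
    """
    v = len(module)
    if v < 2:
        raise ValueError(f"module has {v} member(s); density needs >= 2")
    e = sum(1 for i, j in net.edges if i in module and j in module)
    return 2.0 * e / (v * (v - 1))


def comodule_layer(catalog: ComplexCatalog, net: PPINetwork) -> sparse.csr_matrix:
    """Co-module similarity from density-weighted complex co-membership.

    With S_ij the summed density of complexes containing both i and j and
    S_i the summed density of complexes containing i,

        t(i,j) = S_ij^2 / (S_i * S_j),

    which lies in [0, 1] since S_ij <= min(S_i, S_j).  The pair is an
    implicit zero when it shares no positive-density complex.  Computed
    module densities are stored back on ``catalog.scores``.
    """
    n = net.n
    scores = [module_density(mod, net) for mod in catalog.modules]
    catalog.scores = scores
    if not catalog.modules:
        return sparse.csr_matrix((n, n))
    rows, cols = [], []
    for k, mod in enumerate(catalog.modules):
        for i in mod:
            rows.append(i)
            cols.append(k)
    w = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, len(catalog.modules))
    ).tocsr()
    s = np.asarray(scores, dtype=float)
    totals = w @ s  # S_i
    shared = sparse.triu(w @ sparse.diags(s) @ w.T, k=1).tocoo()  # S_ij, i < j
    if shared.nnz == 0:
        return sparse.csr_matrix((n, n))
    denom = totals[shared.row] * totals[shared.col]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, shared.data**2 / np.where(denom > 0, denom, 1.0), 0.0)
    return _symmetric_from_upper(n, shared.row, shared.col, vals)


def build_tensor(
    net: PPINetwork, domains: DomainAnnotation, catalog: ComplexCatalog
) -> SimilarityTensor:
    """Assemble the three association layers into one SimilarityTensor."""
    layers = (
        topology_layer(net),
        costructure_layer(domain_context(net, domains)),
        comodule_layer(catalog, net),
    )
    if all(layer.nnz == 0 for layer in layers):
        raise ValueError("all three tensor layers are empty; nothing to walk on")
    return SimilarityTensor(n=net.n, layers=layers)


def write_tensor(tensor: SimilarityTensor, index: ProteinIndex, path) -> None:
    """Serialize as 4-column TSV (i_id, j_id, layer_name, value), i_id < j_id."""
    ids = index.ids
    with open(path, "w") as fh:
        fh.write("# i\tj\tlayer\tvalue\n")
        for name, layer in zip(tensor.layer_names, tensor.layers):
            upper = sparse.triu(layer, k=1).tocoo()
            order = np.lexsort((upper.col, upper.row))
            for r, c, v in zip(upper.row[order], upper.col[order], upper.data[order]):
                fh.write(f"{ids[r]}\t{ids[c]}\t{name}\t{float(v)!r}\n")


def read_tensor(path, index: ProteinIndex) -> SimilarityTensor:
    """Load a TSV written by :func:`write_tensor`, re-symmetrizing each layer."""
    n = index.n
    per_layer: dict[str, list[tuple[int, int, float]]] = {name: [] for name in LAYER_NAMES}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            a, b, name, val = fields
            if name not in per_layer:
                raise ValueError(f"{path}:{lineno}: unknown layer {name!r}")
            per_layer[name].append((index.index_of[a], index.index_of[b], float(val)))
    layers = []
    for name in LAYER_NAMES:
        entries = per_layer[name]
        if entries:
            rows, cols, vals = zip(*entries)
            layers.append(_symmetric_from_upper(n, rows, cols, vals))
        else:
            layers.append(sparse.csr_matrix((n, n)))
    return SimilarityTensor(n=n, layers=tuple(layers))
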