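"""Bi-random walk with restart on the functional-similarity tensor.

The tensor T is normalized two ways: protein-mode (each (j, k) column is
made to sum to 1 over the first protein index, an all-zero column becoming
uniform 1/n) and layer-mode (each (i, j) fiber sums to 1 over layers, an
all-zero fiber becoming uniform 1/m).  For a target protein i the coupled
iteration

    X^{t+1} = alpha * (T~ contracted with X^t and Y^t) + (1 - alpha) * X^0
    Y^{t+1} = T~' contracted with X^t and X^{t+1}

updates a protein-importance vector X on the n-simplex and a
layer-importance vector Y on the m-simplex until the L1 change in X falls
below tolerance.  Uniform-fallback columns and fibers are never
materialized: their contribution is added analytically during contraction,
which keeps the tensor sparse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse

from .io import ComplexCatalog, DomainAnnotation, PPINetwork
from .tensor import SimilarityTensor

logger = logging.getLogger("rwrt")

__all__ = [
    "WalkConfig",
    "NormalizedTensorPair",
    "FunctionalSimilarityMatrix",
    "normalize_tensor",
    "contract_protein_mode",
    "contract_layer_mode",
    "restart_builder",
    "run_walk",
    "all_walks",
    "network_stats",
]

# X and Y are renormalized onto the simplex only when accumulated
# floating-point drift exceeds this; below it the raw update is kept so
# that exact fixed points (e.g. alpha = 0) are returned bit-identically.
_SIMPLEX_DRIFT = 1e-12


@dataclass(frozen=True)
class WalkConfig:
    """Iteration parameters.

    alpha    — restart mix in [0, 1]; the diffusion term carries weight
               alpha and the restart distribution X^0 weight (1 - alpha).
    tol      — L1 convergence tolerance on successive X iterates.
    max_iter — iteration cap; non-convergence logs a warning.
    """

    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")


@dataclass(frozen=True)
class NormalizedTensorPair:
    """The two stochastic normalizations of one SimilarityTensor.

    ``protein_mode[k]`` holds the explicitly stored part of the
    column-stochastic layer k; columns listed in ``zero_columns[k]`` are
    implicitly uniform 1/n.  ``layer_mode[k]`` holds the fiber-normalized
    entries on the stored support; (i, j) pairs outside ``support`` are
    implicitly uniform 1/m across layers.
    """

    n: int
    m: int
    protein_mode: tuple[sparse.csr_matrix, ...]
    zero_columns: tuple[np.ndarray, ...]  # boolean masks, length n
    layer_mode: tuple[sparse.csr_matrix, ...]
    support: sparse.csr_matrix  # 0/1 indicator of stored (i, j) pairs


def normalize_tensor(tensor: SimilarityTensor) -> NormalizedTensorPair:
    """Compute both stochastic normalizations of the tensor."""
    n, m = tensor.n, tensor.m
    protein_mode, zero_columns = [], []
    for layer in tensor.layers:
        colsum = np.asarray(layer.sum(axis=0)).ravel()
        zero = colsum == 0.0
        inv = np.zeros(n)
        inv[~zero] = 1.0 / colsum[~zero]
        protein_mode.append((layer @ sparse.diags(inv)).tocsr())
        zero_columns.append(zero)

    total = tensor.layers[0].copy()
    for layer in tensor.layers[1:]:
        total = total + layer
    total = total.tocsr()
    recip = total.copy()
    recip.data = 1.0 / recip.data
    layer_mode = tuple((layer.multiply(recip)).tocsr() for layer in tensor.layers)
    support = total.copy()
    support.data = np.ones_like(support.data)
    return NormalizedTensorPair(
        n=n,
        m=m,
        protein_mode=tuple(protein_mode),
        zero_columns=tuple(zero_columns),
        layer_mode=layer_mode,
        support=support,
    )


def contract_protein_mode(ntp: NormalizedTensorPair, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """out_i = sum_{j,k} t~(i,j,k) x_j y_k, implicit-uniform columns included."""
    out = np.zeros(ntp.n)
    for k in range(ntp.m):
        vec = ntp.protein_mode[k] @ x
        zero_mass = float(x[ntp.zero_columns[k]].sum())
        if zero_mass:
            vec = vec + zero_mass / ntp.n
        out += y[k] * vec
    return out


def contract_layer_mode(
    ntp: NormalizedTensorPair, x_old: np.ndarray, x_new: np.ndarray
) -> np.ndarray:
    """y_k = sum_{i,j} t~'(i,j,k) x_old_i x_new_j, implicit-uniform fibers included."""
    y = np.empty(ntp.m)
    for k in range(ntp.m):
        y[k] = float(x_old @ (ntp.layer_mode[k] @ x_new))
    covered = float(x_old @ (ntp.support @ x_new))
    residual_mass = max(0.0, float(x_old.sum()) * float(x_new.sum()) - covered)
    y += residual_mass / ntp.m
    return y


def _renormalize(v: np.ndarray) -> np.ndarray:
    s = float(v.sum())
    if abs(s - 1.0) > _SIMPLEX_DRIFT and s > 0.0:
        return v / s
    return v


def restart_builder(
    net: PPINetwork, domains: DomainAnnotation, catalog: ComplexCatalog
):
    """Return a function mapping a target index to its restart vector X^0.

    The unnormalized affinity of the target i to protein j is the sum of
    two cosine overlaps — of the proteins' own domain sets and of their
    complex-membership sets — each taken as 0 when a set is empty:

        d_ij = |D_i ∩ D_j| / sqrt(|D_i| |D_j|) + |C_i ∩ C_j| / sqrt(|C_i| |C_j|)

    X^0 is d_i. scaled to sum 1.  A target with no domain and no complex
    evidence falls back to the uniform distribution over its closed PPI
    neighborhood.
    """
    n = net.n

    def normalized_incidence(sets_of: list[frozenset]) -> sparse.csr_matrix:
        labels = sorted(set().union(*sets_of)) if sets_of else []
        col = {d: k for k, d in enumerate(labels)}
        rows, cols, vals = [], [], []
        for i, members in enumerate(sets_of):
            if not members:
                continue
            w = 1.0 / np.sqrt(len(members))
            for d in members:
                rows.append(i)
                cols.append(col[d])
                vals.append(w)
        return sparse.coo_matrix((vals, (rows, cols)), shape=(n, max(len(labels), 1))).tocsr()

    dom_inc = normalized_incidence(list(domains.domains_of))
    membership: list[set[int]] = [set() for _ in range(n)]
    for k, mod in enumerate(catalog.modules):
        for i in mod:
            membership[i].add(k)
    mod_inc = normalized_incidence([frozenset(s) for s in membership])
    closed = net.closed_neighborhoods()

    def build(i: int) -> np.ndarray:
        d = np.asarray((dom_inc[i] @ dom_inc.T).todense()).ravel() + np.asarray(
            (mod_inc[i] @ mod_inc.T).todense()
        ).ravel()
        total = float(d.sum())
        if total > 0.0:
            return d / total
        x0 = np.zeros(n)
        nb = sorted(closed[i])
        x0[nb] = 1.0 / len(nb)
        return x0

    return build


def run_walk(
    ntp: NormalizedTensorPair,
    x0: np.ndarray,
    cfg: WalkConfig = WalkConfig(),
    residual_trace: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterate the coupled X/Y update from X^0 (Y^0 uniform) to convergence.

    Returns (X*, Y*, iterations).  Stops when the L1 change in X drops
    below ``cfg.tol``; hitting ``cfg.max_iter`` logs a warning with the
    final residual and returns the last state.  ``residual_trace``, if
    given, collects the per-iteration L1 residuals.
    """
    x = np.asarray(x0, dtype=float)
    y = np.full(ntp.m, 1.0 / ntp.m)
    alpha = cfg.alpha
    iters = 0
    for iters in range(1, cfg.max_iter + 1):
        if alpha > 0.0:
            x_new = alpha * contract_protein_mode(ntp, x, y) + (1.0 - alpha) * x0
        else:
            x_new = x0
        x_new = _renormalize(x_new)
        y = _renormalize(contract_layer_mode(ntp, x, x_new))
        residual = float(np.abs(x_new - x).sum())
        if residual_trace is not None:
            residual_trace.append(residual)
        x = x_new
        if residual < cfg.tol:
            return x, y, iters
    logger.warning(
        "walk did not converge in %d iterations (residual %.3e)", cfg.max_iter, residual
    )
    return x, y, iters


@dataclass(frozen=True)
class FunctionalSimilarityMatrix:
    """n x n matrix M_fs; row i is the converged X for target i.

    The diagonal is zeroed before downstream use; ``diagonal`` keeps the
    removed self-similarity mass so that the pre-zeroing row sums
    (each 1 up to iteration tolerance) remain reconstructable.
    """

    matrix: np.ndarray
    diagonal: np.ndarray = field(repr=False)
    iterations: tuple[int, ...] = field(repr=False, default=())

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def row(self, i: int) -> np.ndarray:
        return self.matrix[i]


def all_walks(
    ntp: NormalizedTensorPair,
    restart,
    cfg: WalkConfig = WalkConfig(),
) -> FunctionalSimilarityMatrix:
    """Run one walk per target protein and stack the converged X vectors.

    Targets are independent, so the result does not depend on execution
    order; ``restart`` maps a target index to its X^0.
    """
    n = ntp.n
    m = np.empty((n, n))
    iters = []
    for i in range(n):
        x_star, _, it = run_walk(ntp, restart(i), cfg)
        m[i] = x_star
        iters.append(it)
    diag = np.diagonal(m).copy()
    np.fill_diagonal(m, 0.0)
    return FunctionalSimilarityMatrix(matrix=m, diagonal=diag, iterations=tuple(iters))


def network_stats(
    obj: PPINetwork | FunctionalSimilarityMatrix | np.ndarray,
    threshold: float | None = None,
) -> dict[str, float]:
    """Descriptive statistics: average degree, clustering, density, heterogeneity.

    For a similarity matrix an undirected graph is built from pairs whose
    symmetrized score (average of the two directed entries) exceeds
    ``threshold`` (default 1/n, the mass a uniform row would spread).
    Heterogeneity is the coefficient of variation of the degree sequence.
    """
    if isinstance(obj, PPINetwork):
        g = obj.to_networkx()
    else:
        m = obj.matrix if isinstance(obj, FunctionalSimilarityMatrix) else np.asarray(obj)
        n = m.shape[0]
        if threshold is None:
            threshold = 1.0 / n
        sym = (m + m.T) / 2.0
        rows, cols = np.nonzero(np.triu(sym > threshold, k=1))
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    n_nodes = g.number_of_nodes()
    if n_nodes == 0 or g.number_of_edges() == 0:
        return {"average_degree": 0.0, "clustering": 0.0, "density": 0.0, "heterogeneity": 0.0}
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    mean_deg = degrees.mean()
    return {
        "average_degree": float(mean_deg),
        "clustering": float(nx.average_clustering(g)),
        "density": float(nx.density(g)),
        "heterogeneity": float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0,
    }
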