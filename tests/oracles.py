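"""Independent brute-force oracles for the formula-level tests.

Everything here is deliberately naive — exact integer arithmetic, explicit
set operations, dense triple loops — and shares no code with the package
implementation it checks.
"""

import math
from fractions import Fraction

import numpy as np


def topology_similarity_oracle(closed_i: set, closed_j: set) -> float:
    """Shared-closed-neighborhood similarity by direct set arithmetic."""
    c = len(closed_i & closed_j)
    if c == 0:
        return 0.0
    return 4.0 * c * c / ((len(closed_i) + c) * (len(closed_j) + c))


def domain_similarity_oracle(d_i: set, d_j: set, dt: int) -> float:
    """-log of the exact hypergeometric ratio via big-integer binomials."""
    di, dj, dc = len(d_i), len(d_j), len(d_i & d_j)
    num = math.comb(dt, dc) * math.comb(dt - dc, di - dc) * math.comb(dt - di, dj - dc)
    den = math.comb(dt, di) * math.comb(dt, dj)
    ratio = Fraction(num, den)
    return -(math.log(ratio.numerator) - math.log(ratio.denominator))


def module_density_oracle(module: set, edges: set) -> float:
    v = len(module)
    e = sum(1 for a, b in edges if a in module and b in module)
    return 2.0 * e / (v * (v - 1))


def comodule_similarity_oracle(i, j, modules, scores) -> float:
    """Density-weighted co-membership score by explicit summation."""
    shared = sum(s for mod, s in zip(modules, scores) if i in mod and j in mod)
    tot_i = sum(s for mod, s in zip(modules, scores) if i in mod)
    tot_j = sum(s for mod, s in zip(modules, scores) if j in mod)
    if shared == 0 or tot_i == 0 or tot_j == 0:
        return 0.0
    return shared**2 / (tot_i * tot_j)


def cohesiveness_oracle(j, module: set, m: np.ndarray) -> float:
    fs_in = sum(m[j, p] for p in module if p != j)
    fs_out = sum(m[j, p] for p in range(m.shape[0]) if p not in module and p != j)
    total = fs_in + fs_out
    return fs_in / total if total > 0 else 0.0


def ranking_score_oracle(term, target, survivors, terms_of, m: np.ndarray) -> float:
    return sum(m[target, j] for j in survivors if term in terms_of.get(j, set()))


def single_network_oracle(layers, a, b) -> np.ndarray:
    """Weighted layer mix as dense arithmetic."""
    l0, l1, l2 = (np.asarray(x) for x in layers)
    return a * l0 + b * l1 + (1.0 - a - b) * l2


def dense_normalized(tensor) -> tuple[np.ndarray, np.ndarray]:
    """Dense protein-mode and layer-mode normalizations with explicit
    uniform fill-in for all-zero columns/fibers."""
    n, m = tensor.n, tensor.m
    t = np.stack([layer.toarray() for layer in tensor.layers], axis=2)
    protein = np.empty_like(t)
    for j in range(n):
        for k in range(m):
            s = t[:, j, k].sum()
            protein[:, j, k] = t[:, j, k] / s if s > 0 else 1.0 / n
    layer = np.empty_like(t)
    for i in range(n):
        for j in range(n):
            s = t[i, j, :].sum()
            layer[i, j, :] = t[i, j, :] / s if s > 0 else 1.0 / m
    return protein, layer


def contraction_oracle(protein_norm: np.ndarray, x, y) -> np.ndarray:
    """out_i = sum_j sum_k t~(i,j,k) x_j y_k by triple loop."""
    n, _, m = protein_norm.shape
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for k in range(m):
                out[i] += protein_norm[i, j, k] * x[j] * y[k]
    return out


def layer_contraction_oracle(layer_norm: np.ndarray, x_old, x_new) -> np.ndarray:
    """y_k = sum_i sum_j t~'(i,j,k) x_old_i x_new_j by triple loop."""
    n, _, m = layer_norm.shape
    y = np.zeros(m)
    for k in range(m):
        for i in range(n):
            for j in range(n):
                y[k] += layer_norm[i, j, k] * x_old[i] * x_new[j]
    return y
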