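# Methods

## Overview

`rwrt` scores protein–protein functional similarity by a random walk
with restart extended to a third-order tensor, then transfers GO
Biological Process terms from high-similarity, high-cohesiveness
partners to the target. The stages run in this order: input parsing and
filtering → tensor construction → two stochastic normalizations →
per-target coupled walk → partner filtering and term ranking →
cross-validated evaluation.

## Inputs and preprocessing

The protein universe is fixed by the PPI edge list: self-interactions
and duplicate edges are dropped, and every other record is restricted to
proteins that appear in at least one retained interaction. GO terms are
used as flat sets (no ontology propagation); terms annotating fewer than
10 or more than 200 indexed proteins are removed, inclusive on both
bounds — too-specific terms are unlearnable, too-general ones
uninformative. Complexes keep only indexed members and are dropped below
two surviving members. Identifiers are matched as exact trimmed strings;
no identifier mapping is attempted.

## The similarity tensor

Three symmetric layers over the same index, diagonal excluded, only
strictly positive entries stored:

1. **Topology.** For closed neighborhoods `N_i` (protein + direct
   interactors), `t = 4c²/((|N_i|+c)(|N_j|+c))` with `c = |N_i∩N_j|`,
   evaluated for every pair with `c > 0` — the formula needs no direct
   edge between the pair, and restricting it to interacting pairs would
   discard exactly the shared-neighbor signal it measures. Values lie in
   (0, 1].
2. **Co-structure.** Each protein's neighborhood domain set `D_i` is the
   union of its own and its neighbors' domain types. Pairs sharing at
   least one such type get
   `DS = −log [ C(|DT|,|DC|) C(|DT|−|DC|, |D_i|−|DC|) C(|DT|−|D_i|, |D_j|−|DC|) / (C(|DT|,|D_i|) C(|DT|,|D_j|)) ]`,
   the negative log-probability of observing exactly `|DC|` shared types
   by chance; pairs with no shared type carry no co-structure evidence
   and stay implicit zeros. DS is min–max normalized **over the
   evaluated pair set only**: evaluating all n² pairs would be wasteful
   and would let zero-evidence pairs define the normalization range. If
   all evaluated pairs tie, every entry is set to 1 (degenerate range,
   logged). Binomials are evaluated with `scipy.special.gammaln`; naive
   factorials overflow near |DT| ≈ 10³. The test suite checks the
   log-gamma path against exact big-integer arithmetic to 1e−9 relative.
3. **Co-module.** Complex `M_k` is weighted by its physical-edge density
   `Score_k`; a pair's similarity is the squared sum of shared-complex
   scores over the product of per-protein score sums, which
   Cauchy–Schwarz bounds by 1.

Diagonal entries are excluded everywhere: self-similarity would dominate
the walk and the annotation stage never consumes it.

## Normalization and the coupled walk

Two normalizations are precomputed:

* protein mode: each (column j, layer k) fiber sums to 1 over the first
  protein index; an all-zero column is implicitly uniform `1/n`;
* layer mode: each (i, j) fiber sums to 1 over layers; an (i, j) pair
  with no stored entry in any layer (including the diagonal) is
  implicitly uniform `1/m`.

Implicit-uniform columns and fibers are never materialized — their
contribution is added analytically inside the contraction (the mass on
zero columns times `1/n`, and the uncovered probability mass times
`1/m`), which keeps memory proportional to the stored entries at
n ≈ 5000.

Per target `i` the iteration is

```
X^{t+1} = α Σ_{j,k} t̃(·,j,k) x_j y_k + (1−α) X⁰,    Y^{t+1}_k = Σ_{i,j} t̃′(i,j,k) x^t_i x^{t+1}_j
```

with `Y⁰` uniform — the only symmetry-respecting start, since nothing
distinguishes the layers before the walk. Contraction semantics (second
protein mode against X, layer mode against Y) are the only
dimensionally consistent reading with `X ∈ R^n`, `Y ∈ R^m`. After each
update X and Y are projected back to the simplex by scaling, but only
when the drift from 1 exceeds 1e−12: uniform-fallback terms can
introduce tiny leakage, while below that threshold the raw update is
kept so exact fixed points (α = 0 returns X⁰ bit-identically) are
preserved. Iteration stops when the L1 change in X falls below `tol`.

Defaults: `α = 0.5` (equal mix of diffusion and restart), `tol = 1e−6`
(L1), `max_iter = 100`. The tolerance and cap are conventional
random-walk-with-restart settings and are exposed in `WalkConfig`; on
the shipped benchmarks walks converge in ≈ 20–30 iterations and the
residual is non-increasing after burn-in.

The restart distribution `X⁰` uses the target's **own** domain set and
complex-membership set (not the neighborhood sets of the co-structure
layer): `d_ij` is the sum of the two cosine overlaps, each defined as 0
on empty sets, normalized to sum 1. A target with neither evidence
channel falls back to the uniform distribution over its closed PPI
neighborhood — the mildest topology-only prior.

Rows of the resulting `M_fs` each sum to 1 (up to iteration tolerance);
the diagonal is then zeroed and retained separately.

## Annotation

Candidates are the `pool_size = 20` annotated proteins with the highest
similarity to the target (ties by protein index; zero scores never
enter). The pre-filter pool rule is an artifact of this implementation:
after the walk all entries are positive, so *some* cutoff is mandatory;
20 comfortably exceeds the module sizes the method models and is
configurable. Cohesiveness of each candidate is computed against the
full initial module (target + all candidates) and removals at
`CC ≤ 1/3` are applied simultaneously in a single pass — iterative
re-evaluation would change the module mid-filter. If everyone is
removed, the single best candidate is retained so a prediction always
exists when any annotated partner has positive similarity. Term scores
sum the target's similarity over the surviving partners annotated with
the term; ties break lexicographically by GO ID; `K` is the term count
of the best survivor, clamped to the number of ranked terms.

## Evaluation

Cross-validation masks the held-out proteins' annotations only — their
network, domain and complex records stay visible, and the similarity
matrix is computed once because the walk never reads GO data. This
matches the train/test semantics of predicting a test protein from
training annotations. Leave-one-out masks one protein at a time;
ten-fold masks a seeded random tenth simultaneously, and repeats pool
records (each repeat covers every protein once, so pooled macro averages
equal the mean of per-repeat averages).

Per protein: `precision = TP/|predicted|` (0 when empty), `recall =
TP/|known|`, F their harmonic mean, and `FPR = FP/(FP+TN)` with
`TN = |universe| − |known ∪ predicted|` over the filtered term universe —
the only consistent finite negative background. Proteins with empty
predictions enter the macro averages as zeros (configurable). The ROC
sweeps the ranking depth from 0 to the deepest ranking, averaging TPR
and FPR over proteins at each depth, and the AUROC integrates the curve
exactly as drawn without extrapolating to (1, 1); the swept curve
usually ends far left of FPR = 1, so AUROC magnitudes well below 0.5 are
the expected scale of this convention. Matching statistics count
proteins with at least one hit (OM), full coverage of the known set
(FM), non-empty predictions without false positives (ZM), and exact
set equality (PM).

The single-network ablation collapses the layers into
`SN = a·t₁ + b·t₂ + (1−a−b)·t₃` (defaults `a = b = 1/3`, an unweighted
mix) and runs the identical walk/annotate pipeline with `m = 1`, where
the layer vector Y stays degenerate at 1. Comparing macro-F against the
tensor run isolates the value of keeping evidence channels separate.

## Synthetic benchmark

The generator plants `n_modules` equal blocks of proteins; edges appear
with `p_within = 0.8` inside and `p_between = 0.02` between blocks.
Each block has a pool of 3 domain types and 3 GO terms; each member
inherits the pool, with 10% noise (a random foreign domain added; a
planted term dropped or replaced by a foreign term with equal shares).
Evidence is deliberately incomplete, mirroring real catalogs: only 60%
of proteins carry any domain record and each complex record keeps each
member with probability 0.3 — roughly the PFAM and CYC2008 coverage of
yeast PPI networks. Stage sub-generators are spawned deterministically
from the single seed; outputs are byte-reproducible, and any protein the
edge sampler leaves isolated is reconnected within its module so the
universe stays intact.

What the generator does **not** emulate: scale-free, hub-dominated
degree distributions (the planted-partition graph is nearly regular,
degree CV ≈ 0.13 versus ≈ 1.4 in real yeast networks), ontology
structure among GO terms, overlapping modules, and false-positive
interactions concentrated on hubs. Consequences for interpreting the
shipped results:

* the direction "similarity network is less degree-heterogeneous than
  the input" cannot be reproduced here — there is no hub heterogeneity
  to remove, and the walk's module-boundary leakage adds slight degree
  variance instead (the clustering-coefficient increase does
  reproduce);
* the benchmark is close to saturation: 20-member blocks at these edge
  probabilities are recoverable by almost any guilt-by-association
  scheme, so the tensor's margin over the single-network ablation is
  consistently positive at the shipped seed but small (order 10⁻³–10⁻²
  macro-F), far smaller than on noisy real data. Passing tests
  demonstrate correctness of the machinery, not effect sizes on real
  networks.

## Numerical choices and degenerate inputs

* Log-gamma binomials; exact-integer oracle in tests.
* Min–max normalization over evaluated pairs; single-pair or tied
  ranges map to 1 (logged); the minimum-DS pair maps to 0 and is
  therefore stored implicitly.
* Simplex re-projection only beyond 1e−12 drift (exactness at α = 0).
* Tie-breaks are deterministic and seedless everywhere: protein-index
  order for partner scores and K selection, GO-ID order for term ranks.
* Empty domain data leaves the co-structure layer empty and the
  pipeline intact; a tensor with all three layers empty is a fatal
  error.
* The similarity-network binarization threshold for descriptive
  statistics defaults to `1/n` (the mass a uniform row would spread)
  and is configurable; no principled universal threshold exists.

## Problem sizes

The shipped benchmark uses 200 proteins in 10 modules; the full test
suite (including two leave-one-out evaluations of 200 proteins each and
one ten-fold run) completes in well under a minute, and
`scripts/acceptance.py` in a few seconds. The implementation is sparse
throughout and has been exercised at the few-thousand-protein scale of
real yeast networks.
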