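# rwrt

Protein function prediction by **bi-random walks with restart on a
multilayer functional-similarity tensor**.

Most proteins carry out their biological roles inside modules of
interacting partners, so an unannotated protein can be characterized by
the Gene Ontology (GO) Biological Process terms of its functionally
similar neighbors — guilt by association. Physical protein–protein
interaction (PPI) networks alone are noisy and incomplete; collapsing
several evidence types into one weighted network recovers more partners
but blurs which evidence supported which link. `rwrt` instead keeps the
evidence separate as layers of a third-order tensor and lets a coupled
random walk decide, per target, how much each layer should be trusted.

The package is aimed at computational biologists working with yeast-style
PPI datasets (edge lists, PFAM domain assignments, CYC2008-style complex
catalogs, GO annotations) and ships a planted-structure synthetic
generator so the entire pipeline is testable without any downloads.

## Model

Given `n` proteins, a sparse nonnegative tensor `T ∈ R^{n×n×3}` stacks
three symmetric association layers:

* **physical** — shared closed PPI neighborhoods `N_i` (the protein plus
  its interactors):
  `t(i,j,1) = 4|N_i∩N_j|² / ((|N_i|+|N_i∩N_j|)(|N_j|+|N_i∩N_j|))`;
* **co-structure** — the domain content of the two closed neighborhoods
  `D_i, D_j` scored as the negative log of a hypergeometric ratio over
  the global domain universe `DT`, then min–max normalized;
* **co-module** — co-membership in cataloged complexes `M_k`, weighted by
  each complex's PPI edge density
  `Score(M_k) = 2|E_k| / (|V_k|(|V_k|−1))`:
  `t(i,j,3) = (Σ_{k:i,j∈M_k} Score_k)² / (Σ_{k:i∈M_k} Score_k · Σ_{k:j∈M_k} Score_k)`.

Two stochastic normalizations of `T` drive, for each target protein `i`,
the coupled iteration

```
X_i^{t+1} = α · T̃ X_i^t Y_i^t + (1 − α) X_i^0
Y_i^{t+1} = T̃′ X_i^t X_i^{t+1}
```

where `X_i` is a distribution over proteins, `Y_i` a distribution over
the three layers, `α = 0.5` the restart mix, and `X_i^0` a restart
distribution built from cosine overlaps of own-domain and
complex-membership sets. The converged rows form a functional-similarity
matrix `M_fs`. For each target, the best-scoring annotated partners form
a candidate module; partners whose cohesiveness coefficient
`CC = fs_in/(fs_in+fs_out)` is ≤ 1/3 are removed as pretenders, the
survivors' GO terms are ranked by similarity-weighted votes, and the top
`K` terms (K = term count of the most similar survivor) are predicted.

## Worked example

Generate a synthetic benchmark and run the pipeline from the shell:

```bash
rwrt simulate --seed 5 -o data/
rwrt validate --ppi data/ppi.tsv --go data/annotations.tsv \
              --domains data/domains.tsv --complexes data/complexes.txt
```

```
proteins            200
interactions        1868
annotated proteins  200
GO terms retained   30
domain types        30
complexes retained  10
```

Ten-fold cross-validation on the same files:

```bash
rwrt evaluate --ppi data/ppi.tsv --go data/annotations.tsv \
              --domains data/domains.tsv --complexes data/complexes.txt \
              --mode tenfold --seed 3 -o report.json
```

```
"macro_precision": 0.8725,
"macro_recall":    0.9083333333333334,
"macro_f":         0.8831666666666667,
"macro_fpr":       0.013614760080277321,
"auroc":           0.11752619009608951,
```

Read: held-out proteins are re-annotated with ~87% precision and ~91%
recall against their planted terms. The AUROC integrates the
ranking-depth ROC sweep exactly as drawn (the curve ends where the
deepest ranking ends, well before FPR = 1), so small absolute values are
expected; they are comparable between methods run the same way. Ranked
per-target predictions come from `rwrt annotate`, and
`rwrt stats` prints average degree, clustering coefficient, density and
degree heterogeneity for the input network and the thresholded
similarity network.

The same steps are available as a library API
(`rwrt.generate`, `rwrt.build_tensor`, `rwrt.functional_similarity`,
`rwrt.predict`, `rwrt.loocv`, `rwrt.tenfold_cv`).

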