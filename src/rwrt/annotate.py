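"""Function assignment from a target's functional-similarity row.

Pipeline per target: collect the best-scoring annotated partners, drop
"pretenders" whose similarity mass mostly leaves the candidate module
(cohesiveness filter), pool the survivors' GO terms weighted by their
similarity to the target, and keep the top K terms, K being the term
count of the most similar surviving partner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import FunctionAnnotation
from .walk import FunctionalSimilarityMatrix

logger = logging.getLogger("rwrt")

__all__ = [
    "AnnotateConfig",
    "PartnerSet",
    "PredictionResult",
    "candidate_partners",
    "cohesiveness",
    "filter_pretenders",
    "rank_functions",
    "choose_k",
    "predict",
]

# A partner whose cohesiveness is <= 1/3 has at least twice as much
# similarity mass outside the candidate module as inside it.
CC_THRESHOLD = 1.0 / 3.0


@dataclass(frozen=True)
class AnnotateConfig:
    """pool_size — annotated partners considered before the cohesiveness
    filter; cc_threshold — partners at or below it are removed."""

    pool_size: int = 20
    cc_threshold: float = CC_THRESHOLD

    def __post_init__(self):
        if self.pool_size < 1:
            raise ValueError(f"pool_size must be >= 1, got {self.pool_size}")


@dataclass(frozen=True)
class PartnerSet:
    """Candidate partners of one target and the subset surviving the filter.

    Both lists hold (protein index, similarity score) pairs with strictly
    positive scores, non-increasing; ``survivors`` is the FSP set.
    """

    target: int
    candidates: tuple[tuple[int, float], ...]
    survivors: tuple[tuple[int, float], ...] = ()


@dataclass(frozen=True)
class PredictionResult:
    """Ranked GO terms for one target and the chosen prediction depth K."""

    target: int
    ranked_terms: tuple[tuple[str, float], ...]
    k: int
    predicted: tuple[str, ...]
    survivors: tuple[tuple[int, float], ...] = ()


def candidate_partners(
    i: int,
    m_fs: FunctionalSimilarityMatrix,
    ann: FunctionAnnotation,
    pool_size: int = 20,
) -> tuple[tuple[int, float], ...]:
    """Top ``pool_size`` annotated proteins by similarity to target i.

    Zero-score proteins are never included; ties are broken by ascending
    protein index for determinism.
    """
    row = m_fs.row(i)
    scored = [(j, float(row[j])) for j in ann.annotated if j != i and row[j] > 0.0]
    scored.sort(key=lambda js: (-js[1], js[0]))
    return tuple(scored[:pool_size])


def cohesiveness(
    j: int, module: frozenset[int], m_fs: FunctionalSimilarityMatrix
) -> float:
    """Fraction of protein j's similarity mass staying inside ``module``.

    CC = fs_in / (fs_in + fs_out) where fs_in sums j's similarity to the
    other module members and fs_out its similarity to everything outside;
    0 when j has no similarity mass at all.
    """
    row = m_fs.row(j)
    inside = [p for p in module if p != j]
    fs_in = float(row[inside].sum()) if inside else 0.0
    outside_mask = np.ones(m_fs.n, dtype=bool)
    outside_mask[list(module)] = False
    outside_mask[j] = False
    fs_out = float(row[outside_mask].sum())
    total = fs_in + fs_out
    return fs_in / total if total > 0.0 else 0.0


def filter_pretenders(
    ps: PartnerSet,
    m_fs: FunctionalSimilarityMatrix,
    cc_threshold: float = CC_THRESHOLD,
) -> PartnerSet:
    """Remove candidates whose cohesiveness is <= ``cc_threshold``.

    All CC values are computed against the full initial module (target
    plus every candidate) and the removals applied simultaneously in one
    pass.  If the filter would empty the set, the single highest-scoring
    candidate is retained so that a prediction can still be made.
    """
    if not ps.candidates:
        return ps
    module = frozenset({ps.target} | {j for j, _ in ps.candidates})
    survivors = tuple(
        (j, s) for j, s in ps.candidates if cohesiveness(j, module, m_fs) > cc_threshold
    )
    if not survivors:
        logger.info(
            "target %d: all %d candidates filtered; keeping the best one",
            ps.target,
            len(ps.candidates),
        )
        survivors = (ps.candidates[0],)
    return PartnerSet(target=ps.target, candidates=ps.candidates, survivors=survivors)


def rank_functions(
    ps: PartnerSet, ann: FunctionAnnotation
) -> tuple[tuple[str, float], ...]:
    """Score each GO term carried by the survivors.

    RS(f) sums the target's similarity to every surviving partner
    annotated with f; terms are sorted by descending RS, ties broken by
    GO ID.
    """
    scores: dict[str, float] = {}
    for j, s in ps.survivors:
        for term in ann.terms_of.get(j, ()):
            scores[term] = scores.get(term, 0.0) + s
    return tuple(sorted(scores.items(), key=lambda ts: (-ts[1], ts[0])))


def choose_k(ps: PartnerSet, ann: FunctionAnnotation) -> int:
    """K = number of GO terms of the most similar surviving partner.

    Score ties are broken by ascending protein index (the survivor list
    order already encodes this).
    """
    if not ps.survivors:
        return 0
    best = ps.survivors[0][0]
    return len(ann.terms_of.get(best, ()))


def predict(
    i: int,
    m_fs: FunctionalSimilarityMatrix,
    ann: FunctionAnnotation,
    cfg: AnnotateConfig = AnnotateConfig(),
) -> PredictionResult:
    """Full annotation of one target: candidates, filter, ranking, top K."""
    candidates = candidate_partners(i, m_fs, ann, pool_size=cfg.pool_size)
    if not candidates:
        logger.info("target %d: no annotated protein with positive similarity", i)
        return PredictionResult(target=i, ranked_terms=(), k=0, predicted=())
    ps = filter_pretenders(
        PartnerSet(target=i, candidates=candidates), m_fs, cc_threshold=cfg.cc_threshold
    )
    ranked = rank_functions(ps, ann)
    k = min(choose_k(ps, ann), len(ranked))
    return PredictionResult(
        target=i,
        ranked_terms=ranked,
        k=k,
        predicted=tuple(t for t, _ in ranked[:k]),
        survivors=ps.survivors,
    )
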