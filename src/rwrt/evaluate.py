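"""Cross-validation harness and prediction metrics.

Leave-one-out and ten-fold cross-validation mask the held-out proteins'
GO annotations (their network, domain and complex records stay visible),
re-predict them from the training annotations, and report per-protein
precision / recall / FPR / F-score, macro averages, a ranking-depth ROC
sweep with its AUROC, the four matching statistics (OM, FM, ZM, PM), and
a per-functional-size stratification.  A single-network ablation collapses
the three tensor layers into one weighted matrix so the value of keeping
the layers separate can be measured on the same data.

The per-protein false-positive rate uses the filtered GO-term universe as
the finite negative background: TN = |universe| - |known ∪ predicted|.
The AUROC integrates the swept ROC curve exactly as drawn; the sweep can
end before FPR reaches 1, so values well below 0.5 are expected and are
not extrapolated away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import AnnotateConfig, predict
from .io import Dataset, FunctionAnnotation
from .tensor import SimilarityTensor, build_tensor
from .walk import (
    FunctionalSimilarityMatrix,
    WalkConfig,
    all_walks,
    normalize_tensor,
    restart_builder,
)

logger = logging.getLogger("rwrt")

__all__ = [
    "ProteinEval",
    "EvalReport",
    "score_prediction",
    "functional_similarity",
    "loocv",
    "tenfold_cv",
    "roc_from_records",
    "matching_stats",
    "stratify_by_size",
    "single_network_baseline",
]


@dataclass(frozen=True)
class ProteinEval:
    """Outcome of one held-out prediction."""

    protein: int
    known: frozenset[str]
    predicted: frozenset[str]
    ranked_terms: tuple[tuple[str, float], ...]
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    fpr: float
    f_score: float


@dataclass(frozen=True)
class EvalReport:
    """Aggregate cross-validation report (macro = unweighted protein mean)."""

    records: tuple[ProteinEval, ...]
    universe_size: int
    macro_precision: float
    macro_recall: float
    macro_fpr: float
    macro_f: float
    roc_points: np.ndarray = field(repr=False)  # columns: depth, FPR, TPR
    auroc: float = 0.0
    matching: dict[str, int] = field(default_factory=dict)

    @property
    def n_evaluated(self) -> int:
        return len(self.records)


def score_prediction(
    predicted: frozenset[str] | set[str],
    known: frozenset[str] | set[str],
    universe_size: int,
    protein: int = -1,
    ranked_terms: tuple[tuple[str, float], ...] = (),
) -> ProteinEval:
    """Confusion counts and metrics for one predicted/known term-set pair.

    precision = TP/|predicted| (0 for an empty prediction), recall =
    TP/|known|, F the harmonic mean, FPR = FP/(FP + TN) against the
    term-universe background.
    """
    predicted = frozenset(predicted)
    known = frozenset(known)
    if not known:
        raise ValueError("score_prediction requires a non-empty known term set")
    tp = len(predicted & known)
    fp = len(predicted - known)
    fn = len(known - predicted)
    tn = universe_size - len(known | predicted)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(known)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    fpr = fp / (fp + tn) if fp + tn > 0 else 0.0
    return ProteinEval(
        protein=protein,
        known=known,
        predicted=predicted,
        ranked_terms=ranked_terms,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        precision=precision,
        recall=recall,
        fpr=fpr,
        f_score=f,
    )


def functional_similarity(
    dataset: Dataset,
    walk_cfg: WalkConfig = WalkConfig(),
    tensor: SimilarityTensor | None = None,
) -> FunctionalSimilarityMatrix:
    """Build (or accept) the tensor and run all per-target walks."""
    if tensor is None:
        tensor = build_tensor(dataset.net, dataset.domains, dataset.catalog)
    ntp = normalize_tensor(tensor)
    restart = restart_builder(dataset.net, dataset.domains, dataset.catalog)
    return all_walks(ntp, restart, walk_cfg)


def roc_from_records(
    records: tuple[ProteinEval, ...], universe_size: int
) -> tuple[np.ndarray, float]:
    """Ranking-depth ROC sweep over the evaluated proteins.

    At depth d each protein's prediction is its top-d ranked terms; the
    point is (mean FPR, mean TPR) over proteins.  Depth 0 pins the curve
    at (0, 0).  The AUROC is the trapezoidal area under the curve as
    drawn, without extrapolation to (1, 1).
    """
    if not records:
        return np.zeros((1, 3)), 0.0
    max_depth = max(len(r.ranked_terms) for r in records)
    points = [(0, 0.0, 0.0)]
    for depth in range(1, max_depth + 1):
        fprs, tprs = [], []
        for r in records:
            pred = frozenset(t for t, _ in r.ranked_terms[:depth])
            tp = len(pred & r.known)
            fp = len(pred - r.known)
            tn = universe_size - len(pred | r.known)
            tprs.append(tp / len(r.known))
            fprs.append(fp / (fp + tn) if fp + tn > 0 else 0.0)
        points.append((depth, float(np.mean(fprs)), float(np.mean(tprs))))
    arr = np.array(points)
    auroc = float(np.trapezoid(arr[:, 2], arr[:, 1]))
    return arr, auroc


def matching_stats(records: tuple[ProteinEval, ...]) -> dict[str, int]:
    """OM / FM / ZM / PM counts over the evaluated proteins.

    OM — at least one predicted term matches; FM — every known term is
    predicted; ZM — a non-empty prediction with no false positives;
    PM — predicted set equals known set.
    """
    om = sum(1 for r in records if r.tp >= 1)
    fm = sum(1 for r in records if r.known <= r.predicted)
    zm = sum(1 for r in records if r.predicted and r.predicted <= r.known)
    pm = sum(1 for r in records if r.predicted == r.known)
    return {"OM": om, "FM": fm, "ZM": zm, "PM": pm}


def _make_report(records: list[ProteinEval], universe_size: int) -> EvalReport:
    if not records:
        raise ValueError("no proteins were evaluated")
    roc, auroc = roc_from_records(tuple(records), universe_size)
    return EvalReport(
        records=tuple(records),
        universe_size=universe_size,
        macro_precision=float(np.mean([r.precision for r in records])),
        macro_recall=float(np.mean([r.recall for r in records])),
        macro_fpr=float(np.mean([r.fpr for r in records])),
        macro_f=float(np.mean([r.f_score for r in records])),
        roc_points=roc,
        auroc=auroc,
        matching=matching_stats(tuple(records)),
    )


def _evaluate_heldout(
    heldout: list[int],
    m_fs: FunctionalSimilarityMatrix,
    ann: FunctionAnnotation,
    ann_cfg: AnnotateConfig,
    universe_size: int,
    include_empty: bool,
) -> list[ProteinEval]:
    masked = ann.mask(heldout)
    records = []
    for i in heldout:
        result = predict(i, m_fs, masked, ann_cfg)
        if not result.predicted and not include_empty:
            continue
        records.append(
            score_prediction(
                frozenset(result.predicted),
                ann.terms_of[i],
                universe_size,
                protein=i,
                ranked_terms=result.ranked_terms,
            )
        )
    return records


def loocv(
    dataset: Dataset,
    walk_cfg: WalkConfig = WalkConfig(),
    ann_cfg: AnnotateConfig = AnnotateConfig(),
    tensor: SimilarityTensor | None = None,
    include_empty: bool = True,
) -> EvalReport:
    """Leave-one-out cross-validation over the annotated proteins.

    The similarity matrix is computed once — the walk never sees GO
    annotations, so masking the held-out protein's terms from the
    annotation maps is the complete train/test split.  Proteins whose
    prediction comes back empty enter the averages with all-zero metrics
    unless ``include_empty`` is False.
    """
    annotated = dataset.annotations.annotated
    if len(annotated) < 2:
        raise ValueError("leave-one-out needs at least 2 annotated proteins")
    m_fs = functional_similarity(dataset, walk_cfg, tensor)
    universe_size = len(dataset.annotations.term_universe)
    records: list[ProteinEval] = []
    for i in annotated:
        records.extend(
            _evaluate_heldout(
                [i], m_fs, dataset.annotations, ann_cfg, universe_size, include_empty
            )
        )
    return _make_report(records, universe_size)


def tenfold_cv(
    dataset: Dataset,
    seed: int,
    repeats: int = 1,
    walk_cfg: WalkConfig = WalkConfig(),
    ann_cfg: AnnotateConfig = AnnotateConfig(),
    tensor: SimilarityTensor | None = None,
    include_empty: bool = True,
    n_folds: int = 10,
) -> EvalReport:
    """Ten-fold cross-validation: each fold's annotations masked together.

    The random partition is reproducible from ``seed``; each repeat draws
    a fresh partition from the same generator, and all repeats' records
    are pooled (every repeat covers each annotated protein exactly once,
    so the pooled macro average equals the mean of per-repeat averages).
    """
    annotated = list(dataset.annotations.annotated)
    if len(annotated) < n_folds:
        raise ValueError(f"{n_folds}-fold CV needs >= {n_folds} annotated proteins")
    m_fs = functional_similarity(dataset, walk_cfg, tensor)
    universe_size = len(dataset.annotations.term_universe)
    rng = np.random.default_rng(seed)
    records: list[ProteinEval] = []
    for _ in range(repeats):
        order = rng.permutation(len(annotated))
        folds = np.array_split(order, n_folds)
        for fold in folds:
            heldout = [annotated[j] for j in fold]
            records.extend(
                _evaluate_heldout(
                    heldout, m_fs, dataset.annotations, ann_cfg, universe_size, include_empty
                )
            )
    return _make_report(records, universe_size)


def single_network_baseline(
    tensor: SimilarityTensor, a: float = 1.0 / 3.0, b: float = 1.0 / 3.0
) -> SimilarityTensor:
    """Collapse the three layers into one network SN (the ablation baseline).

    SN(i,j) = a * t(i,j,topology) + b * t(i,j,co-structure)
              + (1 - a - b) * t(i,j,co-module),

    returned as a one-layer tensor so the identical walk/annotate pipeline
    runs on it (with m = 1 the layer-importance vector Y stays at 1).
    """
    if not (0.0 < a < 1.0 and 0.0 < b < 1.0 and a + b < 1.0):
        raise ValueError(f"need a, b in (0, 1) with a + b < 1; got a={a}, b={b}")
    if tensor.m != 3:
        raise ValueError(f"expected a 3-layer tensor, got m={tensor.m}")
    sn = (
        a * tensor.layers[0] + b * tensor.layers[1] + (1.0 - a - b) * tensor.layers[2]
    ).tocsr()
    sn.eliminate_zeros()
    return SimilarityTensor(n=tensor.n, layers=(sn,), layer_names=("single",))


def stratify_by_size(
    records: tuple[ProteinEval, ...], min_support: int = 5
) -> pd.DataFrame:
    """Mean FPR and F-score bucketed by the protein's known-term count.

    Buckets backed by fewer than ``min_support`` proteins are flagged
    low-support; their means are reported but not statistically firm.
    """
    rows = []
    sizes = sorted({len(r.known) for r in records})
    for size in sizes:
        bucket = [r for r in records if len(r.known) == size]
        rows.append(
            {
                "functional_size": size,
                "n_proteins": len(bucket),
                "mean_fpr": float(np.mean([r.fpr for r in bucket])),
                "mean_f": float(np.mean([r.f_score for r in bucket])),
                "low_support": len(bucket) < min_support,
            }
        )
    return pd.DataFrame(rows)
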