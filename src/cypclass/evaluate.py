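"""Metrics, coverage, applicability domain, and feature-importance reports.

The Matthews correlation coefficient (MCC) is the primary classification
metric; the Jaccard score (substrate class) and ROC AUC support comparisons
with other tools. Abstaining models additionally report per-class coverage.
The applicability domain is defined by the maximum Tanimoto similarity of a
query's Morgan2 fingerprint to the training set: predictions with a nearest
training neighbor at Tanimoto >= 0.7 are flagged reliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .consensus import ConsensusLabel, ConsensusPrediction
from .train import Algorithm, TrainedClassifier

RELIABILITY_THRESHOLD = 0.7
DEFAULT_BIN_EDGES = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with SUBSTRATE as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true: Sequence[int], y_pred: Sequence[int]):
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class EvaluationReport:
    mcc: float
    jaccard: float
    auc: float | None = None
    coverage_substrates: float | None = None
    coverage_non_substrates: float | None = None


def mcc_from_counts(counts: ConfusionCounts) -> float:
    """MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).

    Defined as 0 when any factor of the denominator is 0.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def jaccard_from_counts(counts: ConfusionCounts) -> float:
    """Jaccard score on the substrate class: tp / (tp + fp + fn)."""
    denom = counts.tp + counts.fp + counts.fn
    return counts.tp / denom if denom else 0.0


def classification_metrics(counts: ConfusionCounts) -> EvaluationReport:
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    return EvaluationReport(
        mcc=mcc_from_counts(counts), jaccard=jaccard_from_counts(counts)
    )


def auc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """ROC AUC; equals the Mann-Whitney rank statistic with ties at half."""
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        raise ValueError("AUC requires both classes in the truth labels")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Tanimoto similarity and the applicability domain
# ---------------------------------------------------------------------------

def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|A n B| / |A u B| over set bits; 0 when both fingerprints are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return int(np.sum(a & b)) / union


def nearest_training_similarity(
    query_fp: np.ndarray,
    training_fps: np.ndarray,
    threshold: float = RELIABILITY_THRESHOLD,
) -> tuple[float, bool]:
    """Maximum Tanimoto similarity to the training set and the reliability
    flag (inclusive at the threshold)."""
    training_fps = np.asarray(training_fps).astype(bool)
    if training_fps.size == 0:
        raise ValueError("training fingerprint set is empty")
    q = np.asarray(query_fp).astype(bool)
    if q.shape[0] != training_fps.shape[1]:
        raise ValueError("fingerprints must have equal length")
    inter = (training_fps & q).sum(axis=1)
    union = (training_fps | q).sum(axis=1)
    sims = np.where(union == 0, 0.0, inter / np.maximum(union, 1))
    best = float(sims.max())
    return best, best >= threshold


# ---------------------------------------------------------------------------
# Coverage of abstaining models
# ---------------------------------------------------------------------------

def coverage(
    predictions: Sequence[ConsensusPrediction], y_true: Sequence[int]
) -> tuple[float | None, float | None]:
    """Fraction of queries receiving a prediction, per true class.

    Returns (coverage_substrates, coverage_non_substrates); a class absent
    from the truth yields None for its coverage.
    """
    y_true = np.asarray(y_true)
    answered = np.array(
        [p.label is not ConsensusLabel.ABSTAIN for p in predictions]
    )
    out = []
    for cls in (1, 0):
        mask = y_true == cls
        out.append(float(answered[mask].mean()) if mask.any() else None)
    return out[0], out[1]


def evaluate_consensus(
    predictions: Sequence[ConsensusPrediction], y_true: Sequence[int]
) -> EvaluationReport:
    """Metrics on covered queries plus per-class coverage; AUC only when the
    strategy emits probabilities (never for hard voting)."""
    y_true = np.asarray(y_true)
    labels = np.array(
        [
            1 if p.label is ConsensusLabel.SUBSTRATE else
            0 if p.label is ConsensusLabel.NON_SUBSTRATE else -1
            for p in predictions
        ]
    )
    answered = labels >= 0
    if not answered.any():
        raise ValueError("no covered predictions to evaluate")
    counts = ConfusionCounts.from_labels(y_true[answered], labels[answered])
    report = classification_metrics(counts)
    has_probs = all(p.probability is not None for p in predictions)
    if has_probs and len(np.unique(y_true)) == 2:
        # probability of the substrate class for ranking
        scores = np.array(
            [
                p.probability
                if p.label is ConsensusLabel.SUBSTRATE
                else 1.0 - p.probability
                for p in predictions
            ]
        )
        report.auc = auc(scores, y_true)
    abstaining = any(p.label is ConsensusLabel.ABSTAIN for p in predictions) or not has_probs
    if abstaining:
        report.coverage_substrates, report.coverage_non_substrates = coverage(
            predictions, y_true
        )
    return report


# ---------------------------------------------------------------------------
# Similarity-binned performance
# ---------------------------------------------------------------------------

@dataclass
class SimilarityProfile:
    bin_edges: tuple
    bin_mid: list[float]
    bin_mcc: list[float | None]
    bin_counts: list[int]
    spearman_r: float | None
    similarities: np.ndarray = field(default_factory=lambda: np.array([]))
    reliability_threshold: float = RELIABILITY_THRESHOLD


def similarity_binned_performance(
    predictions: Sequence[int],
    truths: Sequence[int],
    similarities: Sequence[float],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> SimilarityProfile:
    """Per-bin MCC over nearest-training-neighbor similarity, plus the
    Spearman rank correlation between bin midpoint and bin MCC.

    Bins follow [e_i, e_{i+1}) with the last bin closed at 1. Bins whose
    confusion matrix is degenerate (zero MCC denominator) are reported as
    undefined (None) and excluded from the rank correlation; with fewer than
    two defined bins the correlation is absent. Ties use average ranks.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    sims = np.asarray(similarities, dtype=float)
    if not (len(predictions) == len(truths) == len(sims)):
        raise ValueError("predictions, truths, and similarities must align")
    edges = np.asarray(bin_edges, dtype=float)
    mids, mccs, counts = [], [], []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        if i == len(edges) - 2:
            mask = (sims >= lo) & (sims <= hi)
        else:
            mask = (sims >= lo) & (sims < hi)
        mids.append(float((lo + hi) / 2))
        counts.append(int(mask.sum()))
        if not mask.any():
            mccs.append(None)
            continue
        c = ConfusionCounts.from_labels(truths[mask], predictions[mask])
        denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
        mccs.append(mcc_from_counts(c) if denom else None)
    defined = [(m, v) for m, v in zip(mids, mccs) if v is not None]
    if len(defined) < 2:
        r_s = None
    else:
        xs, ys = zip(*defined)
        if len(set(ys)) == 1 or len(set(xs)) == 1:
            r_s = None  # rank correlation undefined for constant input
        else:
            r_s = float(stats.spearmanr(xs, ys).statistic)
    return SimilarityProfile(
        bin_edges=tuple(float(e) for e in edges),
        bin_mid=mids,
        bin_mcc=mccs,
        bin_counts=counts,
        spearman_r=r_s,
        similarities=sims,
    )


# ---------------------------------------------------------------------------
# Gini feature importances (random forest only)
# ---------------------------------------------------------------------------

@dataclass
class FeatureImportanceReport:
    importances: dict[str, float]  # normalized; sums to 1

    def ranking(self) -> list[tuple[str, float]]:
        return sorted(self.importances.items(), key=lambda kv: (-kv[1], kv[0]))

    def top(self, k: int) -> list[tuple[str, float]]:
        return self.ranking()[:k]


def feature_importance_report(model: TrainedClassifier) -> FeatureImportanceReport:
    """Normalized Gini importances over the features surviving preprocessing.

    Computed as the impurity decrease attributed to each feature averaged
    over the forest's trees. Only defined for random-forest classifiers.
    """
    if model.spec.algorithm is not Algorithm.RF:
        raise ValueError("Gini feature importances require a random forest model")
    raw = np.asarray(model.learner.feature_importances_, dtype=float)
    total = raw.sum()
    norm = raw / total if total > 0 else raw
    names = model.feature_names
    if len(names) != len(norm):
        names = [f"f{i}" for i in range(len(norm))]
    return FeatureImportanceReport(
        importances={n: float(v) for n, v in zip(names, norm)}
    )
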