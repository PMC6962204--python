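"""Pscore confidence scoring, target-decoy FDR filtering and model selection.

The Pscore of a classified GSM is -ln(1 - (P1 - P2)), where P1 and P2 are
the highest and second-highest class probabilities: a large gap between the
top two classes gives a large score, a tie gives 0. Decoy GSMs are built by
permuting each feature vector's 14 values within the spectrum, destroying
the diagnostic-ion pairing structure while conserving the intensity
multiset. Targets and (replicate-averaged) decoys are compared by ROC AUC
and by a score threshold controlling the decoy-based false discovery rate;
models are ranked by the Euclidean length sqrt(accuracy^2 + AUC^2), and the
two families are combined by a consensus rule requiring class agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .models import TrainedModel, classify
from .spectra import CLASS_ORDER

#: Clamp on P1 - P2 so the Pscore stays finite: -ln(1e-12) ~ 27.63.
PSCORE_EPS = 1e-12


def pscore(probs: np.ndarray) -> float:
    """Confidence score from the top-two probability gap (clamped, finite)."""
    p = np.sort(np.asarray(probs, dtype=float))[::-1]
    gap = min(p[0] - p[1], 1.0 - PSCORE_EPS)
    return -math.log(1.0 - gap)


def pscores(proba: np.ndarray) -> np.ndarray:
    """Vectorised Pscore over an (n, 4) probability matrix."""
    p = np.sort(np.asarray(proba, dtype=float), axis=1)[:, ::-1]
    gap = np.minimum(p[:, 0] - p[:, 1], 1.0 - PSCORE_EPS)
    return -np.log(1.0 - gap)


@dataclass
class PscoreRecord:
    """Per-GSM classification outcome with its confidence score."""

    gsm: object
    predicted_class: str
    pscore: float
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not (self.pscore >= 0 and math.isfinite(self.pscore)):
            raise ValueError("pscore must be finite and non-negative")


@dataclass
class RocResult:
    auc: float
    curve: list[tuple[float, float]]


@dataclass
class ModelPerformance:
    """Selection metrics for one trained model on one evaluation set."""

    accuracy: float
    auc: float
    pscore_cutoff: float
    n_filtered: int
    euclidean_length: float = field(init=False)

    def __post_init__(self) -> None:
        self.euclidean_length = math.sqrt(self.accuracy ** 2 + self.auc ** 2)


def make_decoys(features: np.ndarray, n_repeats: int = 5,
                seed: int = 0) -> list[np.ndarray]:
    """Decoy feature sets: each repeats the target set with every vector's
    14 values independently permuted (multiset conserved exactly)."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    return [rng.permuted(X, axis=1) for _ in range(n_repeats)]


def decoy_pscores(model: TrainedModel,
                  decoy_sets: Sequence[np.ndarray]) -> np.ndarray:
    """Per-GSM Pscore averaged across decoy replicates."""
    per_rep = np.vstack([pscores(model.predict_proba(d)) for d in decoy_sets])
    return per_rep.mean(axis=0)


def roc_auc(target_scores: Sequence[float],
            decoy_scores: Sequence[float]) -> RocResult:
    """Target-vs-decoy ROC. The AUC equals the Mann-Whitney statistic
    (probability a random target outscores a random decoy, ties 0.5)."""
    t = np.asarray(target_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    if len(t) == 0 or len(d) == 0:
        raise ValueError("target and decoy score lists must both be non-empty")
    y = np.concatenate([np.ones(len(t)), np.zeros(len(d))])
    s = np.concatenate([t, d])
    fpr, tpr, _ = roc_curve(y, s)
    return RocResult(auc=float(roc_auc_score(y, s)),
                     curve=list(zip(fpr.tolist(), tpr.tolist())))


def fdr_cutoff(target_scores: Sequence[float], decoy_scores: Sequence[float],
               q: float = 0.01) -> tuple[float, int]:
    """Smallest observed target score whose decoy-based FDR is below ``q``.

    FDR(t) = |{decoys >= t}| / max(1, |{targets >= t}|). Returns
    (cutoff, number of targets at or above it); (inf, 0) when no threshold
    reaches the requested FDR.
    """
    t = np.sort(np.asarray(target_scores, dtype=float))
    if len(t) == 0:
        raise ValueError("empty target score list")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    d = np.sort(np.asarray(decoy_scores, dtype=float))
    n = len(t)
    for i, thr in enumerate(t):  # ascending: first passing threshold is smallest
        n_target = n - i
        n_decoy = len(d) - np.searchsorted(d, thr, side="left")
        if n_decoy / max(1, n_target) < q:
            return float(thr), int(n_target)
    return math.inf, 0


def select_best_model(performances: Sequence[ModelPerformance]) -> int:
    """Index of the model with maximal Euclidean length (ties: lowest index)."""
    if not performances:
        raise ValueError("empty performance list")
    lengths = [p.euclidean_length for p in performances]
    return int(np.argmax(lengths))


def evaluate_model(
    model: TrainedModel,
    X: np.ndarray,
    labels: Sequence[str],
    q: float = 0.01,
    decoy_repeats: int = 5,
    decoy_seed: int = 0,
) -> ModelPerformance:
    """Accuracy, target-decoy AUC and FDR cutoff for one model on one set."""
    proba = model.predict_proba(X)
    predicted = [classify(p) for p in proba]
    accuracy = float(np.mean([p == l for p, l in zip(predicted, labels)]))
    target = pscores(proba)
    decoys = make_decoys(X, n_repeats=decoy_repeats, seed=decoy_seed)
    decoy = decoy_pscores(model, decoys)
    auc = roc_auc(target, decoy).auc
    cutoff, n_filtered = fdr_cutoff(target, decoy, q=q)
    return ModelPerformance(accuracy=accuracy, auc=auc,
                            pscore_cutoff=cutoff, n_filtered=n_filtered)


def consensus(
    dnn_results: Sequence[PscoreRecord],
    svm_results: Sequence[PscoreRecord],
    dnn_cutoff: float,
    svm_cutoff: float,
    rule: str = "union",
) -> list[tuple[object, str]]:
    """Consensus classifications across the two model families.

    A GSM is consensus-classified when it passes the FDR cutoff in at least
    one family ('union' rule) or in both ('intersection'), AND both families
    predict the same class. Returns (gsm, shared class) pairs in input order.
    """
    if rule not in ("union", "intersection"):
        raise ValueError(f"unknown consensus rule {rule!r}")
    if len(dnn_results) != len(svm_results):
        raise ValueError("result lists must cover the same GSMs")
    for a, b in zip(dnn_results, svm_results):
        if a.gsm != b.gsm:
            raise ValueError("result lists must be aligned on the same GSM order")
    out = []
    for a, b in zip(dnn_results, svm_results):
        pass_a = a.pscore >= dnn_cutoff
        pass_b = b.pscore >= svm_cutoff
        passed = (pass_a or pass_b) if rule == "union" else (pass_a and pass_b)
        if passed and a.predicted_class == b.predicted_class:
            out.append((a.gsm, a.predicted_class))
    return out


def evaluate(predicted: Sequence[str | None],
             manual: Sequence[str]) -> tuple[float, float, np.ndarray]:
    """Accuracy, sensitivity and the 4x4 confusion matrix.

    ``predicted`` entries may be None for GSMs without a consensus class;
    those are excluded from the confusion matrix and sensitivity (correct
    classifications are true positives, incorrect ones false negatives) and
    count as errors in the accuracy.
    """
    if len(predicted) != len(manual):
        raise ValueError("predicted and manual label lists differ in length")
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    confusion = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=int)
    n_correct = 0
    n_classified = 0
    for p, m in zip(predicted, manual):
        if p is None:
            continue
        n_classified += 1
        confusion[idx[m], idx[p]] += 1
        if p == m:
            n_correct += 1
    accuracy = n_correct / len(manual) if manual else 0.0
    sensitivity = n_correct / n_classified if n_classified else 0.0
    return accuracy, sensitivity, confusion
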