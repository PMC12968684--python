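"""Patient-grouped cross-validation, training loops, and the metric suite.

Folds are always patient-disjoint (window-level splits would leak
near-identical signal between train and test) and group-stratified where
counts permit.  Training uses the printed recipe: batch size 16, up to 20
epochs, Adam, a learning-rate sweep over {1e-3, 1e-4, 1e-5} selected by
validation loss on a held-out slice of the training stream, binary
cross-entropy for detection and cross-entropy for classification.

Metrics are AUROC, AUPRC and F1 (decision threshold 0.5 by default, with a
best-over-thresholds secondary value), reported per seizure type and — for
classification — support-weighted over the four seizure classes, with
cross-fold mean and standard deviation.  Every reported number is
recomputable from the per-window / per-clip score dumps the evaluators
return.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score, f1_score,
                             precision_recall_curve, roc_auc_score)

from ._nn import Adam, Tensor, binary_cross_entropy_with_logits, \
    cross_entropy_with_logits
from .features import FeatureTensor, frequency_bands, raw_passthrough
from .models import (CLASS_ORDER, Classifier, Detector, ModelConfig,
                     _as_image, build_classifier, build_detector)
from .windowing import ClassificationClip, DetectionChunk, slide

logger = logging.getLogger("rtseiz")

__all__ = [
    "FoldSpec",
    "TrainConfig",
    "MetricsReport",
    "make_patient_folds",
    "roc_auc",
    "pr_auc",
    "f1_at_threshold",
    "best_f1",
    "detection_examples",
    "classification_examples",
    "train",
    "evaluate_detection",
    "evaluate_classification",
    "aggregate_folds",
]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FoldSpec:
    k: int
    assignments: dict  # patient_id -> fold index

    def fold_of(self, patient_id: str) -> int:
        return self.assignments[patient_id]

    def test_patients(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignments.items() if f == fold)

    def train_patients(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignments.items() if f != fold)


def make_patient_folds(patient_groups: dict[str, str], k: int = 5,
                       seed: int = 0) -> FoldSpec:
    """Patient-disjoint, group-stratified folds.

    Within each group, patients are shuffled (seeded) and dealt round-robin,
    so any group with >= k members appears in every fold.
    """
    if len(patient_groups) < k:
        raise ValueError(f"{len(patient_groups)} patients < {k} folds")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    offset = 0
    for group in sorted(set(patient_groups.values())):
        members = sorted(p for p, g in patient_groups.items() if g == group)
        rng.shuffle(members)
        for i, pid in enumerate(members):
            assignments[pid] = (offset + i) % k
        offset += len(members)  # stagger so small groups spread across folds
    return FoldSpec(k=k, assignments=assignments)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_two_class(labels: np.ndarray, what: str) -> None:
    u = np.unique(labels)
    if u.size < 2:
        raise ValueError(
            f"{what} undefined: labels contain a single class ({u.tolist()})")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUROC: probability a random positive outranks a random negative,
    ties counting one half."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    _check_two_class(labels, "AUROC")
    return float(roc_auc_score(labels, scores))

def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUPRC via step-wise precision-recall integration (average precision)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    _check_two_class(labels, "AUPRC")
    return float(average_precision_score(labels, scores))


def f1_at_threshold(scores: Sequence[float], labels: Sequence[int],
                    threshold: float = 0.5) -> float:
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    return float(f1_score(labels, (scores >= threshold).astype(int),
                          zero_division=0.0))


def best_f1(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Best F1 over all decision thresholds (secondary, clearly labeled)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    _check_two_class(labels, "best F1")
    prec, rec, _ = precision_recall_curve(labels, scores)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = 2 * prec * rec / (prec + rec)
    return float(np.nanmax(f1))


# ---------------------------------------------------------------------------
# Training streams
# ---------------------------------------------------------------------------

def _featurize(samples: np.ndarray, extractor: str) -> FeatureTensor:
    if extractor == "raw":
        return raw_passthrough(samples)
    return frequency_bands(samples)


def detection_examples(chunks: Sequence[DetectionChunk], window_len_s: int,
                       shift_s: int = 1, extractor: str = "raw"
                       ) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """One example per chunk: (stacked window images, per-window labels,
    patient_id), ready for Detector.sequence_logits."""
    out = []
    for c in chunks:
        wins = slide(c, window_len_s, shift_s)
        images = np.stack([_as_image(_featurize(w.samples, extractor))
                           for w in wins])
        labels = np.array([w.label for w in wins], dtype=np.float64)
        out.append((images, labels, c.patient_id))
    return out


def classification_examples(clips: Sequence[ClassificationClip],
                            extractor: str = "raw"
                            ) -> list[tuple[FeatureTensor, int, str]]:
    """(features, class index in CLASS_ORDER, patient_id) per clip."""
    return [(_featurize(c.samples, extractor), CLASS_ORDER.index(c.type_label),
             c.patient_id) for c in clips]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 16
    epochs: int = 20
    learning_rates: tuple[float, ...] = (1e-3, 1e-4, 1e-5)
    val_fraction: float = 0.2
    clip_grad_norm: float = 5.0  # global-norm gradient clipping; 0 disables
    seed: int = 0


def _example_loss(model, example) -> Tensor:
    if isinstance(model, Detector):
        images, labels, _ = example
        logits = model.sequence_logits(images, train=True)
        return binary_cross_entropy_with_logits(logits.reshape(len(labels)),
                                                labels)
    clip_ft, label, _ = example
    return cross_entropy_with_logits(model.logits(clip_ft, train=True),
                                     np.array([label]))


def _example_val_loss(model, example) -> float:
    if isinstance(model, Detector):
        images, labels, _ = example
        logits = model.sequence_logits(images, train=False)
        return float(binary_cross_entropy_with_logits(
            logits.reshape(len(labels)), labels).data)
    clip_ft, label, _ = example
    return float(cross_entropy_with_logits(
        model.logits(clip_ft, train=False), np.array([label])).data)


def _examples_per_batch(model, stream, batch_size: int) -> int:
    """Batch size counts model inputs.  A detector's input is one sliding
    window and each chunk example already holds a whole window sequence, so
    a chunk saturates a 16-input batch; classifier inputs are clips."""
    if isinstance(model, Detector):
        windows_per_chunk = len(stream[0][1])
        return max(1, batch_size // windows_per_chunk)
    return batch_size


def _run_one_rate(model, train_ex, val_ex, lr, config) -> tuple[list, float]:
    opt = Adam(model.parameters(), lr=lr)
    order_rng = np.random.default_rng(config.seed)
    per_batch = _examples_per_batch(model, train_ex, config.batch_size)
    history = []
    for epoch in range(config.epochs):
        idx = order_rng.permutation(len(train_ex))
        epoch_loss, n_batches = 0.0, 0
        for b0 in range(0, len(idx), per_batch):
            batch = idx[b0: b0 + per_batch]
            opt.zero_grad()
            batch_loss = 0.0
            for i in batch:
                loss = _example_loss(model, train_ex[i])
                v = float(loss.data)
                if not np.isfinite(v):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, lr {lr}: {v}")
                loss.backward(np.full_like(loss.data, 1.0 / len(batch)))
                batch_loss += v / len(batch)
            if config.clip_grad_norm > 0:
                norm = np.sqrt(sum(float((p.grad ** 2).sum())
                                   for p in model.parameters()
                                   if p.grad is not None))
                if norm > config.clip_grad_norm:
                    scale = config.clip_grad_norm / norm
                    for p in model.parameters():
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            epoch_loss += batch_loss
            n_batches += 1
        history.append(epoch_loss / max(1, n_batches))
        logger.info("lr %.0e epoch %d loss %.4f", lr, epoch, history[-1])
    val = (np.mean([_example_val_loss(model, e) for e in val_ex])
           if val_ex else history[-1])
    return history, float(val)


def train(model_factory: "Callable[[], Detector | Classifier] | Detector | Classifier",
          stream: Sequence, config: TrainConfig = TrainConfig()
          ) -> tuple["Detector | Classifier", dict]:
    """Train on a stream of examples from :func:`detection_examples` or
    :func:`classification_examples`.

    With more than one learning rate, one candidate is trained per rate from
    identical initial weights and the candidate with the lowest validation
    loss (held-out slice of the training stream) is returned.  The returned
    history maps each rate to its per-epoch training loss and records the
    selected rate.
    """
    if not len(stream):
        raise ValueError("empty training stream")
    model = model_factory() if callable(model_factory) else model_factory
    init = [a.copy() for a in model.state_arrays()]

    split_rng = np.random.default_rng(config.seed + 7)
    idx = split_rng.permutation(len(stream))
    n_val = (int(round(config.val_fraction * len(stream)))
             if len(config.learning_rates) > 1 else 0)
    val_ex = [stream[i] for i in idx[:n_val]]
    train_ex = [stream[i] for i in idx[n_val:]]

    results = {}
    best_rate, best_val, best_arrays = None, np.inf, None
    for lr in config.learning_rates:
        model.load_arrays(init)
        history, val = _run_one_rate(model, train_ex, val_ex, lr, config)
        results[lr] = {"loss": history, "val_loss": val}
        if val < best_val:
            best_rate, best_val = lr, val
            best_arrays = [a.copy() for a in model.state_arrays()]
    model.load_arrays(best_arrays)
    return model, {"selected_lr": best_rate, "rates": results}


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetricsReport:
    """Per-type (and weighted) metric table with cross-fold dispersion.

    ``per_type[row][metric] = (mean, std)`` across folds; ``per_fold`` keeps
    the raw per-fold dictionaries so every aggregate is recomputable.
    """

    per_type: dict
    weighted: dict | None
    per_fold: list
    config: dict

    def __post_init__(self):
        for row in self.per_type.values():
            for mean, std in row.values():
                if not (0.0 <= mean <= 1.0 and std >= 0.0):
                    raise ValueError("metric out of range")


_DET_METRICS = ("auroc", "auprc", "f1", "f1_best")


def evaluate_detection(detector: Detector,
                       patients: Sequence[tuple[str, str, list[DetectionChunk]]],
                       window_len_s: int, shift_s: int = 1,
                       extractor: str = "raw",
                       train_patient_ids: set[str] | None = None,
                       ) -> tuple[pd.DataFrame, dict]:
    """Stream every chunk of every test patient (full stream, no negative
    subsampling) and score per-window.

    ``patients`` holds (patient_id, group, chunks).  Returns the per-window
    score dump and a metric dict with an "Any" row over all windows plus one
    row per seizure type, whose negatives come from that type's patients
    and the normal controls.  Train/test patient overlap is an error.
    """
    if train_patient_ids is not None:
        overlap = train_patient_ids & {p[0] for p in patients}
        if overlap:
            raise ValueError(f"patient(s) in both train and test: {sorted(overlap)}")

    rows = []
    for pid, group, chunks in patients:
        for chunk in chunks:
            wins = slide(chunk, window_len_s, shift_s)
            fts = [_featurize(w.samples, extractor) for w in wins]
            probs = detector.predict_chunk(fts)
            for w, p in zip(wins, probs):
                rows.append((pid, group, chunk.start_s, w.offset_s,
                             int(w.label), float(p)))
    dump = pd.DataFrame(rows, columns=["patient_id", "group", "chunk_start_s",
                                       "offset_s", "label", "prob"])
    return dump, detection_metrics_from_dump(dump)


def detection_metrics_from_dump(dump: pd.DataFrame) -> dict:
    """Per-type metric rows recomputed from a per-window score dump."""
    metrics = {}

    def row(sub):
        return {
            "auroc": roc_auc(sub["prob"], sub["label"]),
            "auprc": pr_auc(sub["prob"], sub["label"]),
            "f1": f1_at_threshold(sub["prob"], sub["label"]),
            "f1_best": best_f1(sub["prob"], sub["label"]),
        }

    metrics["Any"] = row(dump)
    for t in ("CAE", "IESS", "GN", "FC"):
        sub = dump[dump["group"].isin([t, "normal"])]
        if sub.empty or sub["label"].nunique() < 2:
            continue
        metrics[t] = row(sub)
    return metrics


def evaluate_classification(classifier: Classifier,
                            examples: Sequence[tuple[FeatureTensor, int, str]],
                            include_normal_in_weighted: bool = False,
                            ) -> tuple[pd.DataFrame, dict]:
    """Score test clips with the 5-way classifier.

    Per class: one-vs-rest AUROC/AUPRC from the probability vectors and F1
    of the argmax predictions.  "Weighted" is the support-weighted mean over
    the four seizure classes (normal excluded by default).  A class absent
    from the test set is omitted from the weighted average with a warning.
    """
    rows = []
    for ft, label, pid in examples:
        proba = classifier.predict_proba(ft)
        rows.append((pid, CLASS_ORDER[label], label, int(np.argmax(proba)),
                     *proba))
    dump = pd.DataFrame(rows, columns=["patient_id", "type_label", "label",
                                       "pred"] + [f"p_{c}" for c in CLASS_ORDER])
    return dump, classification_metrics_from_dump(
        dump, include_normal_in_weighted)


def classification_metrics_from_dump(dump: pd.DataFrame,
                                     include_normal_in_weighted: bool = False
                                     ) -> dict:
    labels = dump["label"].to_numpy()
    preds = dump["pred"].to_numpy()
    metrics = {}
    weighted_rows = []
    weight_classes = CLASS_ORDER if include_normal_in_weighted else CLASS_ORDER[1:]
    for k, cls in enumerate(CLASS_ORDER):
        support = int((labels == k).sum())
        if support == 0 or support == len(labels):
            if cls in weight_classes:
                warnings.warn(f"class {cls} absent from test set; omitted "
                              "from weighted average")
            continue
        y = (labels == k).astype(int)
        p = dump[f"p_{cls}"].to_numpy()
        row = {
            "auroc": roc_auc(p, y),
            "auprc": pr_auc(p, y),
            "f1": float(f1_score(y, (preds == k).astype(int), zero_division=0.0)),
        }
        metrics[cls] = row
        if cls in weight_classes:
            weighted_rows.append((support, row))
    if weighted_rows:
        total = sum(s for s, _ in weighted_rows)
        metrics["Weighted"] = {
            m: sum(s * r[m] for s, r in weighted_rows) / total
            for m in ("auroc", "auprc", "f1")
        }
    return metrics


def aggregate_folds(per_fold: list[dict], config: dict | None = None
                    ) -> MetricsReport:
    """Cross-fold mean/std per row and metric from per-fold metric dicts."""
    rows = sorted({r for f in per_fold for r in f if r != "Weighted"})
    per_type = {}
    for r in rows:
        vals = [f[r] for f in per_fold if r in f]
        per_type[r] = {
            m: (float(np.mean([v[m] for v in vals])),
                float(np.std([v[m] for v in vals])))
            for m in vals[0]
        }
    weighted = None
    wvals = [f["Weighted"] for f in per_fold if "Weighted" in f]
    if wvals:
        weighted = {m: (float(np.mean([v[m] for v in wvals])),
                        float(np.std([v[m] for v in wvals])))
                    for m in wvals[0]}
    return MetricsReport(per_type=per_type, weighted=weighted,
                         per_fold=per_fold, config=config or {})
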