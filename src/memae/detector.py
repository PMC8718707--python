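"""Reconstruction-error scoring, minimum-error classification, and metrics.

A :class:`ClassEnsemble` holds one trained one-class autoencoder per
heartbeat class. A beat is assigned to the class whose model reconstructs it
with the smallest error; streams of beats can also be scored against a
single model, which is the anomaly-monitoring view (the score jumps when
beats of a foreign class appear).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autoencoder import ECGBeat, MAEModel, reconstruction_error, zscore
from .trainer import stack_beats

__all__ = ["ClassEnsemble", "EvalCounts", "EvaluationReport", "score_stream",
           "classify", "classify_batch", "compute_metrics", "evaluate",
           "plot_score_stream"]


@dataclass
class ClassEnsemble:
    """One trained model per class; ``class_order`` is the sorted label list."""

    models: dict

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble needs at least one model")
        shapes = {(m.in_channels, m.input_length) for m in self.models.values()}
        ps = {m.loss_p for m in self.models.values()}
        if len(shapes) > 1 or len(ps) > 1:
            raise ValueError("all ensemble models must share input shape and loss_p")

    @property
    def class_order(self) -> list:
        return sorted(self.models)

    def save(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for label, model in self.models.items():
            model.save(d / f"model_{label}.npz")

    @classmethod
    def load(cls, directory) -> "ClassEnsemble":
        from pathlib import Path
        models = {}
        for path in sorted(Path(directory).glob("model_*.npz")):
            label = path.stem[len("model_"):]
            models[label] = MAEModel.load(path)
        return cls(models=models)


@dataclass
class EvalCounts:
    """Per-class confusion counts."""

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EvaluationReport:
    """Per-class precision/recall/F1, macro averages and the confusion matrix."""

    class_order: list
    confusion: np.ndarray          # rows = true class, columns = predicted
    per_class: dict                # label -> {precision, recall, f1, support}
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "confusion_matrix": self.confusion.astype(int).tolist(),
            "per_class": {k: dict(v) for k, v in self.per_class.items()},
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n_samples": self.n_samples,
        }


def _beat_array(beat) -> np.ndarray:
    return beat.samples if isinstance(beat, ECGBeat) else np.atleast_2d(np.asarray(beat))


def score_stream(beats, model: MAEModel, normalize: bool = True) -> np.ndarray:
    """Reconstruction error of each beat in order (the streaming score)."""
    beats = list(beats)
    if not beats:
        return np.empty(0)
    x = stack_beats(beats, normalize=normalize)
    xhat = model.reconstruct(x)
    d = np.abs(x - xhat)
    if model.loss_p == 2:
        d = d * d
    return d.mean(axis=(1, 2))


def classify(beat, ensemble: ClassEnsemble, normalize: bool = True) -> str:
    """Assign the class whose model reconstructs the beat with least error.

    Ties go to the first label in sorted class order.
    """
    x = zscore(_beat_array(beat)) if normalize else _beat_array(beat)
    best_label, best_err = None, np.inf
    for label in ensemble.class_order:
        model = ensemble.models[label]
        err = reconstruction_error(x, model.reconstruct(x), p=model.loss_p)
        if err < best_err:
            best_label, best_err = label, err
    return best_label


def classify_batch(beats, ensemble: ClassEnsemble, normalize: bool = True) -> list:
    """Vectorized minimum-error classification of many beats."""
    beats = list(beats)
    if not beats:
        return []
    errors = np.stack([
        score_stream(beats, ensemble.models[label], normalize=normalize)
        for label in ensemble.class_order
    ])  # (n_classes, n_beats)
    order = ensemble.class_order
    return [order[i] for i in errors.argmin(axis=0)]


def compute_metrics(counts: EvalCounts) -> dict:
    """Precision, recall and F1 from confusion counts; 0/0 is defined as 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1}


def evaluate(predictions, truths, class_order=None) -> EvaluationReport:
    """Confusion matrix (rows = true class) and per-class/macro metrics."""
    predictions, truths = list(predictions), list(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    if class_order is None:
        class_order = sorted(set(truths) | set(predictions))
    index = {label: i for i, label in enumerate(class_order)}
    for label in set(truths) | set(predictions):
        if label not in index:
            raise ValueError(f"label {label!r} not in class_order")

    k = len(class_order)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(truths, predictions):
        confusion[index[t], index[p]] += 1

    per_class = {}
    total = confusion.sum()
    for label, i in index.items():
        tp = int(confusion[i, i])
        fp = int(confusion[:, i].sum() - tp)
        fn = int(confusion[i, :].sum() - tp)
        tn = int(total - tp - fp - fn)
        metrics = compute_metrics(EvalCounts(tp=tp, fp=fp, fn=fn, tn=tn))
        metrics["support"] = int(confusion[i, :].sum())
        per_class[label] = metrics

    macro = {m: float(np.mean([per_class[c][m] for c in class_order]))
             for m in ("precision", "recall", "f1")}
    return EvaluationReport(
        class_order=list(class_order), confusion=confusion, per_class=per_class,
        macro_precision=macro["precision"], macro_recall=macro["recall"],
        macro_f1=macro["f1"], n_samples=int(total),
    )


def plot_score_stream(scores, boundaries=None, ax=None, threshold: float | None = None):
    """Plot a streaming reconstruction-error trace.

    ``boundaries`` marks indices where the underlying beat type changes;
    ``threshold`` (user-supplied, never learned here) draws a horizontal line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(np.asarray(scores), lw=1.0, color="tab:blue")
    for b in boundaries or []:
        ax.axvline(b, color="tab:red", ls="--", lw=0.8)
    if threshold is not None:
        ax.axhline(threshold, color="tab:gray", ls=":", lw=1.0)
    ax.set_xlabel("beat index")
    ax.set_ylabel("reconstruction error")
    return ax
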