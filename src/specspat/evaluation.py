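"""Confusion-matrix metrics: overall/average accuracy and Cohen's kappa."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import LabelMap

__all__ = ["ConfusionMatrix", "EvalReport", "confusion", "metrics"]


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are truth, columns are prediction."""

    counts: np.ndarray
    class_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.class_ids = np.asarray(self.class_ids, dtype=np.int32).ravel()
        k = len(self.class_ids)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K")
        if self.counts.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    """OA and AA in percent, kappa unitless in [-1, 1] (None if undefined)."""

    oa: float
    aa: float
    kappa: float | None
    per_class: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "oa_percent": round(self.oa, 6),
            "aa_percent": round(self.aa, 6),
            "kappa": None if self.kappa is None else round(self.kappa, 6),
            "per_class_percent": {str(k): round(v, 6)
                                  for k, v in sorted(self.per_class.items())},
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def confusion(truth: LabelMap | np.ndarray, pred: LabelMap | np.ndarray,
              mask: np.ndarray | None = None) -> ConfusionMatrix:
    """Count (truth, prediction) pairs over ``mask`` (default: truth > 0).

    The mask should already exclude background and training pixels when the
    report is meant to mirror a held-out evaluation.
    """
    t = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
    p = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError("truth and prediction shapes differ")
    if mask is None:
        mask = t > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != t.shape:
            raise ValueError("mask shape mismatch")
    t = t[mask].ravel()
    p = p[mask].ravel()
    class_ids = np.unique(t[t > 0])
    if np.any(~np.isin(p[p > 0], class_ids)) or np.any(p == 0):
        extra = np.setdiff1d(np.unique(p), class_ids)
        raise ValueError(f"prediction labels {extra.tolist()} outside truth vocabulary")
    k = len(class_ids)
    lut = {int(c): i for i, c in enumerate(class_ids)}
    counts = np.zeros((k, k), dtype=np.int64)
    ti = np.vectorize(lut.get)(t) if t.size else np.empty(0, int)
    pi = np.vectorize(lut.get)(p) if p.size else np.empty(0, int)
    np.add.at(counts, (ti, pi), 1)
    return ConfusionMatrix(counts=counts, class_ids=class_ids)


def metrics(cm: ConfusionMatrix) -> EvalReport:
    """OA, AA, kappa and per-class recall from a confusion matrix.

    ``OA = 100 * trace / total``; ``AA`` averages per-class recall over the
    classes with at least one truth pixel; ``kappa = (po - pe) / (1 - pe)``
    with ``pe`` the chance agreement from the marginals.
    """
    total = cm.total
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts.astype(np.float64)
    po = np.trace(counts) / total
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    pe = float((row * col).sum()) / total**2
    nonempty = row > 0
    if not np.all(nonempty):
        empty = cm.class_ids[~nonempty].tolist()
        warnings.warn(f"classes {empty} have no evaluation pixels; "
                      "excluded from AA", stacklevel=2)
    recalls = np.diag(counts)[nonempty] / row[nonempty]
    kappa = None if pe >= 1.0 else float((po - pe) / (1.0 - pe))
    per_class = {int(c): float(100.0 * np.diag(counts)[i] / row[i])
                 for i, c in enumerate(cm.class_ids) if row[i] > 0}
    return EvalReport(oa=float(100.0 * po), aa=float(100.0 * recalls.mean()),
                      kappa=kappa, per_class=per_class)
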