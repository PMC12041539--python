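"""Evaluation metrics.

ROC-AUC is the probability that a random positive outranks a random
negative (ties count one half). Multi-label inputs are macro-averaged over
tasks; tasks whose observed labels contain a single class are skipped.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = ["roc_auc"]


def _binary_auc(y: np.ndarray, s: np.ndarray) -> float:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            "ROC-AUC is undefined: only one class present in the labels"
        )
    return float(roc_auc_score(y, s))


def roc_auc(labels, scores) -> float:
    """Macro ROC-AUC; NaN labels are treated as missing and masked out."""
    y = np.asarray(labels, dtype=np.float64)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError(f"label shape {y.shape} != score shape {s.shape}")
    if y.ndim == 1:
        mask = ~np.isnan(y)
        return _binary_auc(y[mask], s[mask])
    aucs = []
    for task in range(y.shape[1]):
        mask = ~np.isnan(y[:, task])
        if not mask.any():
            continue
        try:
            aucs.append(_binary_auc(y[mask, task], s[mask, task]))
        except ValueError:
            logger.warning("task %d has a single class; skipped in macro AUC", task)
    if not aucs:
        raise ValueError("ROC-AUC is undefined for every task")
    return float(np.mean(aucs))
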