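"""Held-out metrics for a rare binary outcome: ROC AUC and balanced error rate.

With outcome prevalence of a few percent, raw accuracy is uninformative (the
all-negative classifier scores ~99%); AUC and BER are the standard pair for
imbalanced classification.  AUC is the probability that a random positive
outranks a random negative (ties counted 1/2); BER is one minus the average
of sensitivity and specificity at a probability threshold.  Both accept
optional sampling weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["ClassificationMetrics", "roc_auc", "balanced_error_rate",
           "prevalence_threshold"]


@dataclass
class ClassificationMetrics:
    auc: float
    ber: float
    threshold: float
    weighted: bool

    def to_dict(self) -> dict:
        return {"auc": self.auc, "ber": self.ber,
                "threshold": self.threshold, "weighted": self.weighted}


def _check_two_class(y):
    y = np.asarray(y)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("AUC/BER undefined with a single class present")
    return y


def roc_auc(y, p, w=None) -> float:
    """(Weighted) area under the ROC curve via the trapezoidal integral.

    Equals the weighted probability that a random positive's score exceeds a
    random negative's, with ties contributing 1/2.
    """
    y = _check_two_class(y)
    return float(roc_auc_score(y, np.asarray(p, dtype=float), sample_weight=w))


def balanced_error_rate(y, p, threshold: float = 0.5, w=None) -> float:
    """BER = 1 - (sensitivity + specificity)/2 at the given threshold.

    Rates are computed within each class, weighted when ``w`` is given, so
    the rare class counts as much as the common one.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    y = _check_two_class(y)
    p = np.asarray(p, dtype=float)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    yhat = p >= threshold
    pos, neg = y == 1, y == 0
    sens = float(w[pos & yhat].sum() / w[pos].sum())
    spec = float(w[neg & ~yhat].sum() / w[neg].sum())
    return 1.0 - 0.5 * (sens + spec)


def prevalence_threshold(y, w=None) -> float:
    """(Weighted) outcome prevalence — the threshold matching base rates.

    At low prevalence the default 0.5 cut-off degenerates to the
    all-negative classifier (BER 0.5); cutting at the prevalence is the
    standard remedy and both are reported in round logs.
    """
    y = np.asarray(y)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    return float(np.average(y, weights=w))


def evaluate(y, p, w=None, threshold: float = 0.5,
             weighted: bool = False) -> ClassificationMetrics:
    """Bundle AUC and BER; weights are applied only when ``weighted`` is on."""
    wv = w if weighted else None
    return ClassificationMetrics(
        auc=roc_auc(y, p, w=wv),
        ber=balanced_error_rate(y, p, threshold=threshold, w=wv),
        threshold=threshold,
        weighted=weighted,
    )
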