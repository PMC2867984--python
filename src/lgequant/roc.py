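"""Subject-level ROC analysis of the concordance statistic.

Diseased myocardium shifts the measured intensity distribution away from the
ideal noise curve, so disease is called when concordance falls BELOW a
cutoff.  The sweep enumerates every observed concordance as a candidate
cutoff; AUC is the Mann-Whitney pairwise probability (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import GroupingError, ParameterError

__all__ = ["SubjectRecord", "RocResult", "roc_curve", "optimal_cutoff"]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's group label and concordance, the unit of ROC analysis."""

    subject_id: str
    group: str  # "positive" (disease) or "negative" (control)
    concordance: float

    def __post_init__(self) -> None:
        if self.group not in (POSITIVE, NEGATIVE):
            raise ParameterError(f"group must be 'positive' or 'negative', got {self.group!r}")
        if not 0.0 <= self.concordance <= 100.0:
            raise ParameterError(f"concordance must lie in [0, 100], got {self.concordance}")


@dataclass(frozen=True)
class RocResult:
    """Operating points (cutoff, sensitivity, specificity) and the AUC."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc_curve(records) -> RocResult:
    """ROC of concordance for separating positive from negative subjects.

    A subject is called positive when its concordance is strictly below the
    cutoff.  Candidate cutoffs are -inf, every observed concordance, and
    +inf, giving the full staircase from (sens 0, spec 1) to (sens 1,
    spec 0).  AUC is computed as the rank statistic over all
    positive/negative pairs (equivalently the trapezoidal area).
    """
    records = list(records)
    conc = np.array([r.concordance for r in records], dtype=float)
    is_pos = np.array([r.group == POSITIVE for r in records], dtype=bool)
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise GroupingError("ROC needs at least one subject in each group")

    cutoffs = np.concatenate([[-np.inf], np.unique(conc), [np.inf]])
    sens = np.array([(conc[is_pos] < c).mean() for c in cutoffs])
    spec = np.array([(conc[~is_pos] >= c).mean() for c in cutoffs])

    # Mann-Whitney AUC, ties half-credit; low concordance scores as positive.
    auc = float(roc_auc_score(is_pos.astype(int), -conc))
    return RocResult(cutoffs=cutoffs, sensitivity=sens, specificity=spec, auc=auc)


def optimal_cutoff(roc: RocResult) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher specificity (and the lower cutoff among
    equal-specificity ties).  Returns (cutoff, sensitivity, specificity).
    """
    if roc.cutoffs.size == 0:
        raise ParameterError("empty ROC")
    finite = np.isfinite(roc.cutoffs)
    cand = np.where(finite.any(), finite, np.ones_like(finite, bool))
    j = roc.sensitivity + roc.specificity - 1.0
    best = None
    for i in np.flatnonzero(cand):
        key = (j[i], roc.specificity[i], -roc.cutoffs[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return float(roc.cutoffs[i]), float(roc.sensitivity[i]), float(roc.specificity[i])
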