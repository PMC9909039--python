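"""Binary-classifier evaluation: Sn, Sp, ACC, MCC and AUROC.

Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
ACC = (TP+TN)/n and Matthews correlation
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) are computed from
the confusion matrix at a fixed score threshold (default 0.5). AUROC is
threshold-free: the probability that a random positive outscores a random
negative, with ties counted one half. A degenerate MCC denominator (an
empty row or column of the confusion matrix) is reported as 0 with the
``mcc_degenerate`` flag set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["EvaluationReport", "compute_metrics"]


@dataclass
class EvaluationReport:
    """Sn/Sp/ACC/MCC/AUROC plus confusion counts for one prediction set."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auroc: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float = 0.5
    mcc_degenerate: bool = False
    folds: list["EvaluationReport"] | None = None
    fold_means: dict[str, float] | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.folds is not None:
            d["folds"] = [f.to_dict() for f in self.folds]
        return d

    def summary(self) -> str:
        return (
            f"AUROC={self.auroc:.3f} Sn={self.sn:.3f} Sp={self.sp:.3f} "
            f"ACC={self.acc:.3f} MCC={self.mcc:.3f}"
        )


def compute_metrics(
    truth, scores, threshold: float = 0.5
) -> EvaluationReport:
    """Evaluate continuous scores against binary truth.

    Parameters
    ----------
    truth : array-like of {0, 1}
        True labels; both classes must be present (AUROC is undefined
        otherwise).
    scores : array-like of float
        Classifier scores, higher = more positive; binary calls are made
        at ``scores >= threshold``.
    """
    y = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("truth and scores must have equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("truth must be binary (0/1)")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present (AUROC undefined)")
    calls = (s >= threshold).astype(int)
    tp = int(((calls == 1) & (y == 1)).sum())
    fn = int(((calls == 0) & (y == 1)).sum())
    tn = int(((calls == 0) & (y == 0)).sum())
    fp = int(((calls == 1) & (y == 0)).sum())
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / len(y)
    denom_sq = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom_sq == 0.0
    mcc = 0.0 if degenerate else (tp * tn - fn * fp) / np.sqrt(denom_sq)
    auroc = float(roc_auc_score(y, s))
    return EvaluationReport(
        sn=sn, sp=sp, acc=acc, mcc=float(mcc), auroc=auroc,
        tp=tp, fp=fp, tn=tn, fn=fn,
        threshold=threshold, mcc_degenerate=degenerate,
    )
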