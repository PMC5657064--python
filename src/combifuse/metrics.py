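"""Ranking metrics for imbalanced pairwise prediction.

AUC is computed in its Mann–Whitney form — the probability that a random
positive outranks a random negative, ties counted half — via midranks, so
it vectorises over many score columns at once (used heavily by the fusion
weight grid search). AUPR is the non-interpolated step estimator
(average-precision form); the value of AUPR depends on the interpolation
convention, so the estimator is fixed here.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann–Whitney estimator, ties = 1/2)."""
    return float(auc_columns(np.asarray(scores, dtype=float)[:, None], labels)[0])


def auc_columns(score_matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """AUC of each column of ``score_matrix`` against one label vector."""
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined: both classes must be present")
    ranks = rankdata(score_matrix, axis=0, method="average")
    pos_rank_sum = ranks[labels == 1].sum(axis=0)
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step-wise estimator)."""
    labels = np.asarray(labels)
    if (labels == 1).sum() == 0:
        raise ValueError("AUPR is undefined: no positive instances")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))
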