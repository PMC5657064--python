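"""Pair-level featurization and probabilistic scoring.

A drug pair ``c_ij`` is represented by the elementwise sum of its members'
feature vectors, ``F_ij = f_i + f_j`` — symmetric in the two drugs and a
simple proxy for their synergy. Each feature channel trains its own
logistic model on labelled pairs; the fitted posterior probability of
being a combinative pair is the channel's confidence score. The ATC
channel bypasses the classifier: a Tanimoto similarity already lies in
[0, 1] and is used directly as a score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .datamodel import FeatureMatrix, Pair, SimilarityMatrix


def pair_feature(f_i: np.ndarray, f_j: np.ndarray) -> np.ndarray:
    """Symmetric pair feature ``F_ij = f_i + f_j``."""
    f_i = np.asarray(f_i, dtype=float)
    f_j = np.asarray(f_j, dtype=float)
    if f_i.shape != f_j.shape:
        raise ValueError(
            f"feature dimension mismatch: {f_i.shape} vs {f_j.shape}"
        )
    return f_i + f_j


def pair_matrix(features: FeatureMatrix, pairs: Sequence[Pair]) -> np.ndarray:
    """Stack ``F_ij`` rows for an ordered pair list."""
    idx = {d: i for i, d in enumerate(features.drug_ids)}
    ai = np.fromiter((idx[a] for a, _ in pairs), dtype=int, count=len(pairs))
    bj = np.fromiter((idx[b] for _, b in pairs), dtype=int, count=len(pairs))
    return features.values[ai] + features.values[bj]


@dataclass(frozen=True)
class ClassifierModel:
    """Fitted logistic model for one feature channel."""

    channel: str
    weights: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.weights).all() and np.isfinite(self.intercept)):
            raise ValueError("model parameters must be finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "channel": self.channel,
                "weights": list(map(float, self.weights)),
                "intercept": float(self.intercept),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        obj = json.loads(text)
        return cls(
            channel=obj["channel"],
            weights=np.asarray(obj["weights"], dtype=float),
            intercept=float(obj["intercept"]),
        )


def train_logistic(
    x: np.ndarray,
    y: np.ndarray,
    *,
    channel: str = "",
    l2: float = 0.01,
    max_iter: int = 1000,
) -> ClassifierModel:
    """Fit ``log(p/(1-p)) = w'F + b`` by penalised maximum likelihood.

    Parameters
    ----------
    l2
        L2 penalty strength (lambda); the default is weak and serves only
        to stabilise collinear features. ``l2=0`` fits the unpenalised
        maximum-likelihood model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = set(np.unique(y))
    for cls_, name in ((1, "positive"), (0, "negative")):
        if cls_ not in classes:
            raise ValueError(f"training set contains no {name} instances")
    c = 1.0 / l2 if l2 > 0 else np.inf
    clf = LogisticRegression(C=c, max_iter=max_iter, tol=1e-8)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        clf.fit(x, y)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            warnings.warn(
                f"logistic fit did not converge within {max_iter} iterations"
            )
    return ClassifierModel(
        channel=channel,
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
    )


def score_pairs(model: ClassifierModel, x: np.ndarray) -> np.ndarray:
    """Posterior probability ``1 / (1 + exp(-(w'F + b)))`` per pair."""
    x = np.asarray(x, dtype=float)
    if x.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model "
            f"dimension {model.weights.shape[0]}"
        )
    z = x @ model.weights + model.intercept
    # numerically stable sigmoid
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def similarity_as_score(sim: SimilarityMatrix, pairs: Sequence[Pair]) -> np.ndarray:
    """Read pairwise similarities off the matrix as confidence scores."""
    idx = {d: i for i, d in enumerate(sim.drug_ids)}
    return np.array([sim.values[idx[a], idx[b]] for a, b in pairs])
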