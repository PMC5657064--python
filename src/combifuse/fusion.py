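"""Late fusion of per-channel confidence scores.

Each candidate pair carries four scores in [0, 1] — the logistic
posteriors of the DDI, DTI and SE channels plus the ATC similarity — held
in a :class:`ScoreTable`. Fusion combines them into one confidence score
per pair by a (possibly weighted) mean:

* mean rule — plain average of the four channels;
* direct rule — channels weighted by their training AUC;
* greedy rule — weights found by searching the grid {0, 0.1, ..., 1}^4
  for the combination with the best fused AUC on a held-out slice of the
  training scores.

Weighted scores are normalised by the weight sum so every rule keeps the
fused score in [0, 1] and the mean rule is the uniform-weight special
case.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import Pair
from .metrics import auc_columns

CHANNELS = ("ddi", "dti", "se", "atc")


@dataclass(frozen=True)
class WeightVector:
    """Fusion weights per channel, each in [0, 1], not all zero."""

    ddi: float
    dti: float
    se: float
    atc: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("weights must lie in [0, 1]")
        if not np.any(vals > 0):
            raise ValueError("at least one weight must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.ddi, self.dti, self.se, self.atc], dtype=float)

    @classmethod
    def uniform(cls) -> "WeightVector":
        return cls(1.0, 1.0, 1.0, 1.0)


def make_score_table(
    pairs: Sequence[Pair],
    channel_scores: dict[str, np.ndarray],
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble a per-pair score table (one column per channel)."""
    missing = set(CHANNELS) - set(channel_scores)
    if missing:
        raise ValueError(f"missing channel scores: {sorted(missing)}")
    data = {
        "drug_a": [a for a, _ in pairs],
        "drug_b": [b for _, b in pairs],
    }
    for ch in CHANNELS:
        col = np.asarray(channel_scores[ch], dtype=float)
        if np.any(col < 0) or np.any(col > 1):
            raise ValueError(f"channel {ch!r} scores must lie in [0, 1]")
        data[ch] = col
    if labels is not None:
        data["label"] = np.asarray(labels, dtype=int)
    return pd.DataFrame(data)


def _channel_block(table: pd.DataFrame) -> np.ndarray:
    missing = [c for c in CHANNELS if c not in table.columns]
    if missing:
        raise ValueError(f"score table lacks channel column(s): {missing}")
    block = table[list(CHANNELS)].to_numpy(dtype=float)
    if np.isnan(block).any():
        raise ValueError("score table has missing channel values")
    return block


def fuse_weighted(table: pd.DataFrame, weights: WeightVector) -> pd.DataFrame:
    """Normalised weighted mean of the four channel scores."""
    w = weights.as_array()
    fused = _channel_block(table) @ w / w.sum()
    out = table.copy()
    out["fused"] = fused
    return out


def fuse_average(table: pd.DataFrame) -> pd.DataFrame:
    """Mean rule: plain average of the four channel scores."""
    return fuse_weighted(table, WeightVector.uniform())


def direct_weights(per_channel_auc: dict[str, float]) -> WeightVector:
    """Direct rule: use each channel's (training) AUC as its weight."""
    return WeightVector(*(float(per_channel_auc[ch]) for ch in CHANNELS))


def _weight_grid(grid_step: float) -> np.ndarray:
    n = int(round(1.0 / grid_step))
    levels = np.round(np.arange(n + 1) * grid_step, 10)
    grid = np.array(list(itertools.product(levels, repeat=len(CHANNELS))))
    return grid[grid.sum(axis=1) > 0]  # drop the all-zero corner

def greedy_weight_search(
    table: pd.DataFrame,
    labels: np.ndarray | None = None,
    *,
    grid_step: float = 0.1,
    val_fraction: float | None = 0.5,
    seed: int = 0,
    chunk: int = 2048,
) -> WeightVector:
    """Exhaustive grid search over fusion weights.

    Every candidate on the grid {0, grid_step, ..., 1}^4 (excluding the
    all-zero corner) is scored by the AUC of its fused score on a held-out
    fraction of the supplied labelled scores (a stratified random split;
    ``val_fraction=None`` evaluates on all rows). Ties break toward the
    lexicographically smallest weight vector in channel order
    (ddi, dti, se, atc). The grid subsumes any greedy path over the same
    candidates, and contains the uniform point, so the selected AUC is
    never below the mean rule's on the selection split.
    """
    if labels is None:
        if "label" not in table.columns:
            raise ValueError("labels are required for weight search")
        labels = table["label"].to_numpy()
    labels = np.asarray(labels, dtype=int)
    block = _channel_block(table)

    if val_fraction is not None:
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        if len(pos) < 2 or len(neg) < 2:
            raise ValueError(
                "weight search needs at least two instances of each class"
            )
        val_idx = np.concatenate(
            [
                rng.choice(pos, max(1, int(round(len(pos) * val_fraction))), replace=False),
                rng.choice(neg, max(1, int(round(len(neg) * val_fraction))), replace=False),
            ]
        )
        block, labels = block[val_idx], labels[val_idx]
    if len(set(labels.tolist())) < 2:
        raise ValueError("degenerate labels: both classes required")

    # The grid is generated in lexicographic order and only a strictly
    # better AUC replaces the incumbent, so ties resolve toward the
    # lexicographically smallest weight vector.
    grid = _weight_grid(grid_step)
    best_auc, best_w = -np.inf, None
    for start in range(0, len(grid), chunk):
        w_chunk = grid[start : start + chunk]
        fused = block @ w_chunk.T / w_chunk.sum(axis=1)
        aucs = auc_columns(fused, labels)
        j = int(np.argmax(aucs))  # argmax returns the first maximum
        if aucs[j] > best_auc:
            best_auc = float(aucs[j])
            best_w = w_chunk[j]
    assert best_w is not None
    return WeightVector(*best_w)
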