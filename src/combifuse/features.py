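"""Heterogeneous per-drug feature construction.

Four channels feed the pair classifier:

* ``ddi`` — a spectral embedding of the pharmaceutical drug-drug
  interaction graph. The symmetric adjacency ``T`` is factorised by SVD,
  ``T = U S V'``, and each drug is represented by a row of ``U sqrt(S)``
  truncated to the leading components.
* ``atc`` — Tanimoto similarity of first-level (anatomical main group)
  ATC code sets; used directly as a pairwise confidence score.
* ``dti`` / ``se`` — binary target / side-effect profiles, optionally
  compressed by PCA.

The DDI embedding and the ATC similarity depend only on pharmaceutical
interactions and drug classification — never on combination labels — so
computing them once on the full universe introduces no label leakage even
for "new" drugs in cold-start evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .datamodel import DDINetwork, DrugUniverse, FeatureMatrix, SimilarityMatrix


@dataclass(frozen=True)
class SVDEmbeddingConfig:
    """Truncation policy for the DDI spectral embedding.

    sv_threshold
        Singular values below this are discarded entirely (default 1e-6,
        i.e. numerically-zero spectrum is dropped).
    n_keep
        Number of leading components retained after thresholding
        (default 25); ``None`` keeps every retained component.
    """

    sv_threshold: float = 1e-6
    n_keep: int | None = 25

    def __post_init__(self) -> None:
        if self.sv_threshold < 0:
            raise ValueError("sv_threshold must be nonnegative")
        if self.n_keep is not None and self.n_keep < 1:
            raise ValueError("n_keep must be a positive integer")


@dataclass(frozen=True)
class PCAConfig:
    n_components: int = 25
    center: bool = True

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be a positive integer")


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each component's largest-magnitude loading positive.

    Resolves the per-component sign indeterminacy of SVD/PCA so outputs
    are bit-reproducible across runs and BLAS builds.
    """
    components = components.copy()
    scores = scores.copy()
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1.0
            scores[:, k] *= -1.0
    return components, scores


def ddi_embedding(
    network: DDINetwork, config: SVDEmbeddingConfig | None = None
) -> FeatureMatrix:
    """Spectral embedding ``U sqrt(S)`` of the DDI adjacency.

    Components are ordered by descending singular value; singular values
    below ``config.sv_threshold`` are discarded, then the first
    ``config.n_keep`` components are kept. Isolated drugs get all-zero
    embedding rows. An all-zero adjacency yields a zero-column matrix with
    a warning rather than an error.
    """
    config = config or SVDEmbeddingConfig()
    u, s, _ = np.linalg.svd(network.adjacency.astype(float), hermitian=True)
    retained = int(np.sum(s >= config.sv_threshold))
    if retained == 0:
        warnings.warn(
            "all singular values fall below the threshold; returning a "
            "zero-column DDI embedding"
        )
    k = retained if config.n_keep is None else min(config.n_keep, retained)
    u, _ = _fix_signs(u.T[:k], u[:, :k])  # sign rule applied to columns of U
    emb = u.T * np.sqrt(s[:k])
    return FeatureMatrix(channel="ddi", drug_ids=network.drug_ids, values=emb)


def atc_similarity(universe: DrugUniverse) -> SimilarityMatrix:
    """Pairwise Tanimoto similarity of first-level ATC code sets.

    ``s_ij = |A_i ∩ A_j| / |A_i ∪ A_j|``; a pair where both sets are empty
    is defined as 0 (the diagonal is 1 only for drugs with a non-empty set).
    """
    m = universe.m
    sets = [universe.atc_sets[d] for d in universe.drug_ids]
    if any(not s for s in sets):
        warnings.warn(
            "some drugs have empty ATC sets; their similarities (including "
            "the diagonal) are defined as 0"
        )
    vals = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            union = len(sets[i] | sets[j])
            if union:
                vals[i, j] = vals[j, i] = len(sets[i] & sets[j]) / union
    return SimilarityMatrix(drug_ids=universe.drug_ids, values=vals)


def binary_profiles(universe: DrugUniverse, channel: str) -> FeatureMatrix:
    """The raw binary DTI or SE profile matrix as a feature channel."""
    if channel == "dti":
        vals = universe.dti_profiles
    elif channel == "se":
        vals = universe.se_profiles
    else:
        raise ValueError(f"channel must be 'dti' or 'se', got {channel!r}")
    return FeatureMatrix(
        channel=channel, drug_ids=universe.drug_ids, values=vals.astype(float)
    )


class PCAReducer:
    """Fit-on-train / transform-all PCA with a deterministic sign rule.

    Thin wrapper used both by :func:`reduce_pca` and by cross-validation,
    where the reducer must be fitted on training drugs only and then
    applied to every drug.
    """

    def __init__(self, config: PCAConfig | None = None):
        self.config = config or PCAConfig()
        self._mean: np.ndarray | None = None
        self._components: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "PCAReducer":
        cfg = self.config
        x = np.asarray(x, dtype=float)
        rank = int(np.linalg.matrix_rank(x - x.mean(axis=0) if cfg.center else x))
        n_comp = min(cfg.n_components, rank, x.shape[0] - (1 if cfg.center else 0), x.shape[1])
        n_comp = max(n_comp, 1)
        if n_comp < cfg.n_components:
            warnings.warn(
                f"requested {cfg.n_components} components but data support "
                f"only {n_comp}; retaining {n_comp}"
            )
        if cfg.center:
            pca = PCA(n_components=n_comp, svd_solver="full")
            scores = pca.fit_transform(x)
            comps, _ = _fix_signs(pca.components_, scores)
            self._mean = pca.mean_
            self._components = comps
        else:
            _, _, vt = np.linalg.svd(x, full_matrices=False)
            comps, _ = _fix_signs(vt[:n_comp], x @ vt[:n_comp].T)
            self._mean = np.zeros(x.shape[1])
            self._components = comps
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self._components is None:
            raise RuntimeError("PCAReducer is not fitted")
        return (np.asarray(x, dtype=float) - self._mean) @ self._components.T


def reduce_pca(features: FeatureMatrix, config: PCAConfig | None = None) -> FeatureMatrix:
    """Project a feature matrix onto its leading principal components.

    Components are ordered by descending explained variance; the sign of
    each is fixed so its largest-magnitude loading is positive. Requesting
    more components than the data rank retains the rank with a warning.
    """
    reducer = PCAReducer(config).fit(features.values)
    return FeatureMatrix(
        channel=features.channel,
        drug_ids=features.drug_ids,
        values=reducer.transform(features.values),
    )
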