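"""Gaussian-mixture clustering of the conformational landscape with
silhouette-guided model selection over k = 2..10."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from glycokit.conformers.features import ReducedEmbedding

# silhouette is O(F^2); above this size a seeded subsample is scored instead
_SILHOUETTE_SUBSAMPLE = 50_000
_TIE_TOL = 1e-6


@dataclass
class ClusterModel:
    """The selected mixture model plus the full model-selection trace."""

    n_clusters: int
    labels: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    mixture_weights: np.ndarray
    silhouette_by_k: dict[int, float]
    seed: int

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)


def select_cluster_count(
    embedding: ReducedEmbedding,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 42,
) -> ClusterModel:
    """Fit full-covariance Gaussian mixtures for each k and keep the one
    with the highest silhouette score.

    Ties within 1e-6 go to the smaller k (parsimony).  A k whose fit fails
    or collapses to a single occupied component is skipped with a warning.
    """
    X = embedding.T
    if X.shape[0] < k_max + 1:
        raise ValueError(f"need at least {k_max + 1} frames to search k up to {k_max}")
    rng = np.random.default_rng(seed)
    if X.shape[0] > _SILHOUETTE_SUBSAMPLE:
        score_idx = rng.choice(X.shape[0], _SILHOUETTE_SUBSAMPLE, replace=False)
        warnings.warn(
            f"silhouette scored on a seeded subsample of {_SILHOUETTE_SUBSAMPLE} "
            f"of {X.shape[0]} frames",
            stacklevel=2,
        )
    else:
        score_idx = np.arange(X.shape[0])

    fits: dict[int, GaussianMixture] = {}
    silhouette_by_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                gmm = GaussianMixture(
                    n_components=k, covariance_type="full", random_state=seed
                )
                labels = gmm.fit_predict(X)
        except Exception as exc:  # noqa: BLE001 - any failed fit is skipped
            warnings.warn(f"GMM fit for k={k} failed ({exc}); skipped", stacklevel=2)
            continue
        if len(np.unique(labels[score_idx])) < 2:
            warnings.warn(
                f"GMM fit for k={k} collapsed to one occupied component; skipped",
                stacklevel=2,
            )
            continue
        fits[k] = gmm
        silhouette_by_k[k] = float(
            silhouette_score(X[score_idx], labels[score_idx])
        )
    if not fits:
        raise RuntimeError("every mixture fit in the k range failed")
    best_score = max(silhouette_by_k.values())
    best_k = min(k for k, s in silhouette_by_k.items() if s >= best_score - _TIE_TOL)
    gmm = fits[best_k]
    return ClusterModel(
        n_clusters=best_k,
        labels=gmm.predict(X),
        means=gmm.means_,
        covariances=gmm.covariances_,
        mixture_weights=gmm.weights_,
        silhouette_by_k=silhouette_by_k,
        seed=seed,
    )
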