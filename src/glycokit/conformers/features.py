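"""Frame featurization and dimensionality reduction.

Each frame is described by its full vector of heavy-atom pairwise distances
(the flattened lower triangle of the frame's Euclidean distance matrix).
Because internal distances are blind to rigid-body motion, no superposition
of frames is needed or performed.  PCA then projects the F x p distance
matrix to a low-dimensional conformational landscape (3 components by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from glycokit.conformers.ensemble import ConformationEnsemble


@dataclass
class FlatDistanceRepresentation:
    """F x p matrix; row i is the condensed distance vector of frame i.

    The flattening order is the lower triangle read column by column,
    {g21, g31, ..., gn1, g32, ...} — identical to SciPy's condensed form.
    """

    matrix: np.ndarray
    flatten_order: str = "lower-triangle-column-major"

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ReducedEmbedding:
    """PCA projection of the distance representation."""

    T: np.ndarray  # (F, dim)
    components: np.ndarray  # (dim, p) orthonormal rows
    explained_variance_ratio: np.ndarray
    cumulative_variance: np.ndarray

    @property
    def dim(self) -> int:
        return self.T.shape[1]


def flatten_distances(ensemble: ConformationEnsemble) -> FlatDistanceRepresentation:
    """Pairwise-distance featurization of every frame.

    Raises a ``ValueError`` naming the frame and atom on non-finite input.
    """
    frames = ensemble.frames
    if frames.shape[1] < 2:
        raise ValueError("at least two atoms are required for pairwise distances")
    bad = ~np.isfinite(frames)
    if bad.any():
        f, a, _ = np.argwhere(bad)[0]
        raise ValueError(f"non-finite coordinate at frame {f}, atom {a}")
    rows = [pdist(frame) for frame in frames]
    return FlatDistanceRepresentation(matrix=np.asarray(rows))


def reduce_dimensionality(
    flat: FlatDistanceRepresentation, dim: int = 3
) -> ReducedEmbedding:
    """Project the distance matrix onto its top ``dim`` principal components."""
    X = flat.matrix
    if X.shape[0] <= dim:
        raise ValueError(f"need more than {dim} frames for a {dim}-component PCA")
    if np.allclose(X.std(axis=0), 0.0):
        raise ValueError("degenerate input: all frames identical (zero variance)")
    pca = PCA(n_components=dim, svd_solver="full")
    T = pca.fit_transform(X)
    return ReducedEmbedding(
        T=T,
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        cumulative_variance=np.cumsum(pca.explained_variance_ratio_),
    )
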