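"""Linear (geometric-morphometric) shape space: eigenshape analysis.

Procrustes-aligned outline vertices serve as semi-landmarks; PCA of the
flattened coordinate vectors gives an orthonormal shape basis, and
between-shape distances are Euclidean distances between score vectors
truncated at the dimension explaining a chosen fraction of variance.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .outlines import AlignedSet, Outline

__all__ = [
    "EigenshapePCA",
    "fit_eigenshapes",
    "select_dims",
    "eigenshape_distances",
    "linear_mean",
    "DegenerateShapeError",
]

#: variance-fraction grid commonly scanned when tuning the retained dimension
VARIANCE_FRACTION_GRID = (0.75, 0.9, 0.95, 0.99, 0.999)


class DegenerateShapeError(ValueError):
    """A mean or reconstruction collapsed to a zero-size configuration."""


class EigenshapePCA:
    """PCA of aligned semi-landmark coordinates (scikit-learn style).

    ``fit`` takes an ``(n, N, 2)`` array (or an :class:`AlignedSet`) of
    Procrustes-aligned configurations, flattens to 2N-vectors, and keeps
    the full orthonormal basis; ``transform`` returns score vectors.

    Attributes
    ----------
    mean_ : (2N,) array
        Mean coordinate vector.
    components_ : (r, 2N) array
        Orthonormal principal axes, by descending eigenvalue.
    eigenvalues_ : (r,) array
        Variances along each axis (descending).
    scores_ : (n, r) array
        Training-set coordinates in the eigenbasis.
    d_ : int
        Dimensions needed for ``variance_fraction`` of the variance.
    """

    def __init__(self, variance_fraction: float = 0.999):
        if not 0 < variance_fraction <= 1:
            raise ValueError("variance_fraction must be in (0, 1]")
        self.variance_fraction = variance_fraction

    def get_params(self, deep: bool = True) -> dict:
        return {"variance_fraction": self.variance_fraction}

    def set_params(self, **params) -> "EigenshapePCA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if isinstance(X, AlignedSet):
            X = X.coordinates()
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        if X.ndim != 2:
            raise ValueError("expected (n, N, 2) configurations or (n, 2N) vectors")
        return X

    def fit(self, X, y=None) -> "EigenshapePCA":
        M = self._as_matrix(X)
        if M.shape[0] < 3:
            raise ValueError("need at least 3 shapes")
        self._pca = PCA(svd_solver="full")
        self.scores_ = self._pca.fit_transform(M)
        self.mean_ = self._pca.mean_
        self.components_ = self._pca.components_
        self.eigenvalues_ = self._pca.explained_variance_
        if self.eigenvalues_.sum() <= 0:  # all shapes identical
            self.d_ = 1
        else:
            self.d_ = select_dims(self.eigenvalues_, self.variance_fraction)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "_pca"):
            raise RuntimeError("EigenshapePCA is not fitted")
        return self._pca.transform(self._as_matrix(X))

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return self._pca.inverse_transform(scores)


def fit_eigenshapes(aligned: AlignedSet | np.ndarray, variance_fraction: float = 0.999) -> EigenshapePCA:
    """Fit the eigenshape model to a Procrustes-aligned set."""
    return EigenshapePCA(variance_fraction=variance_fraction).fit(aligned)


def select_dims(eigenvalues, variance_fraction: float) -> int:
    """Smallest d whose leading eigenvalues explain ``variance_fraction``."""
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    ev = np.asarray(eigenvalues, dtype=float)
    total = ev.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    cum = np.cumsum(ev) / total
    return int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)


def eigenshape_distances(model: EigenshapePCA, d: int | None = None) -> np.ndarray:
    """Euclidean distance matrix between d-truncated score vectors."""
    if d is None:
        d = model.d_
    if d < 1 or d > model.components_.shape[0]:
        raise ValueError(f"d={d} outside the available {model.components_.shape[0]} components")
    return squareform(pdist(model.scores_[:, :d]))


def linear_mean(aligned: AlignedSet, member_ids=None) -> Outline:
    """Vertex-wise arithmetic mean of aligned outlines.

    Raises :class:`DegenerateShapeError` if the mean collapses (for
    example when averaging a shape with its point-wise negation).
    """
    outlines = aligned.outlines
    if member_ids is not None:
        wanted = set(member_ids)
        outlines = [o for o in outlines if o.object_id in wanted]
    if not outlines:
        raise ValueError("empty member set")
    mean_pts = np.mean([o.points for o in outlines], axis=0)
    spread = np.sqrt(((mean_pts - mean_pts.mean(axis=0)) ** 2).sum())
    if spread < 1e-9:
        raise DegenerateShapeError("linear mean collapsed to a point")
    return Outline(mean_pts, closed=outlines[0].closed, object_id="linear_mean")
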