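"""Shape spaces: PCA of Procrustes coordinates, projection of unknown
specimens into a fixed morphospace, Brownian-motion ancestral states for
phylomorphospace plots, and thin-plate-spline warps between landmark sets.
"""

from __future__ import annotations

import dendropy
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import AlignedDataset, Configuration, LandmarkScheme
from .procrustes import align_to_reference

__all__ = [
    "ShapePCA",
    "pca_fit",
    "project_new",
    "ancestral_states",
    "tps_warp",
    "shape_at_score",
]


class ShapePCA(TransformerMixin, BaseEstimator):
    """Principal component analysis of vectorized Procrustes shape
    coordinates.

    The eigendecomposition is of the covariance (divisor N−1) of the
    vectorized, mean-centred shapes. After Procrustes superimposition a K×3
    configuration has at most min(N−1, 3K−7) dimensions of variation
    (translation, scale and rotation absorb 7 degrees of freedom), so only
    that many components are retained. Eigenvector signs are fixed so each
    component's largest-magnitude loading is positive.

    Attributes
    ----------
    mean_shape_ : (K, 3) ndarray
    components_ : (m, 3K) ndarray, orthonormal rows
    eigenvalues_ : (m,) ndarray, descending
    variance_fractions_ : (m,) ndarray summing to 1 over nonzero components
    scores_ : (N, m) ndarray of training scores
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            self._shape_kd = X.shape[1:]
            X = X.reshape(X.shape[0], -1)
        else:
            self._shape_kd = (X.shape[1] // 3, 3)
        n, p = X.shape
        if n < 3:
            raise ValueError("PCA needs at least 3 specimens")
        mean = X.mean(axis=0)
        centred = X - mean
        # SVD route: numerically stable, gives eigvals of cov with divisor N-1
        u, s, vt = np.linalg.svd(centred, full_matrices=False)
        eigvals = s**2 / (n - 1)
        m_max = min(n - 1, 3 * self._shape_kd[0] - 7)
        m = m_max if self.n_components is None else min(self.n_components, m_max)
        eigvals, vt, u, s = eigvals[:m], vt[:m], u[:, :m], s[:m]
        # sign fix: largest-|loading| positive per component
        for i in range(vt.shape[0]):
            j = np.argmax(np.abs(vt[i]))
            if vt[i, j] < 0:
                vt[i] *= -1
                u[:, i] *= -1
        self.mean_shape_ = mean.reshape(self._shape_kd)
        self.components_ = vt
        self.eigenvalues_ = eigvals
        total = eigvals.sum()
        self.variance_fractions_ = eigvals / total if total > 0 else eigvals
        self.scores_ = u * s
        self.n_samples_ = n
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        single = X.ndim <= 2 and X.shape == self.mean_shape_.shape
        flat = X.reshape(1, -1) if single else X.reshape(X.shape[0], -1)
        scores = (flat - self.mean_shape_.reshape(1, -1)) @ self.components_.T
        return scores[0] if single else scores

    def inverse_transform(self, scores):
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        flat = self.mean_shape_.reshape(1, -1) + scores @ self.components_
        out = flat.reshape(scores.shape[0], *self._shape_kd)
        return out[0] if scores.shape[0] == 1 else out


def pca_fit(dataset: AlignedDataset, n_components: int | None = None) -> ShapePCA:
    """Fit a shape PCA ("morphospace") to an aligned dataset."""
    return ShapePCA(n_components=n_components).fit(dataset.shapes)


def project_new(
    space: ShapePCA,
    unknown: Configuration | np.ndarray,
    scheme: LandmarkScheme | None = None,
    consensus_align: bool = True,
    slide: bool = True,
) -> np.ndarray:
    """Project an unknown specimen into a fitted morphospace.

    The unknown is first aligned to the *training* consensus (mirrored if
    left-sided, scaled to unit centroid size, optimally rotated) and its
    semilandmarks slid against that fixed consensus, then its centred
    vectorized coordinates are multiplied by the eigenvectors. The reference
    morphospace never moves when unknowns are added.
    """
    if isinstance(unknown, Configuration):
        if scheme is None:
            raise ValueError("scheme required to project a Configuration")
        if consensus_align:
            aligned = align_to_reference(unknown, space.mean_shape_, scheme, slide=slide)
        else:
            aligned = unknown.coords
    else:
        aligned = np.asarray(unknown, dtype=float)
    return space.transform(aligned)


def shape_at_score(space: ShapePCA, axis: int, value: float) -> np.ndarray:
    """Model shape at a given score along one morphospace axis:
    mean + value × eigenvector(axis), reshaped to K×3."""
    if not 0 <= axis < space.components_.shape[0]:
        raise IndexError(f"axis {axis} outside fitted space")
    flat = space.mean_shape_.reshape(-1) + value * space.components_[axis]
    return flat.reshape(space.mean_shape_.shape)


# ---------------------------------------------------------------------------
# Ancestral states under Brownian motion
# ---------------------------------------------------------------------------

def ancestral_states(
    tip_values: dict[str, np.ndarray],
    tree: dendropy.Tree,
) -> dict:
    """Maximum-likelihood Brownian-motion ancestral state estimates for all
    internal nodes of a rooted tree.

    Equivalent to branch-length-weighted squared-change parsimony: the
    internal states jointly minimize Σ_edges Δ²/length, a sparse linear
    system solved exactly. The root estimate equals the phylogenetically
    weighted (GLS) mean of the tip data.

    Parameters
    ----------
    tip_values : mapping from tip label to a 1-D score vector (or scalar).
    tree : dendropy.Tree with branch lengths.

    Returns
    -------
    dict mapping dendropy nodes to estimated vectors; tips map to their data.
    """
    tips = [lf for lf in tree.leaf_node_iter()]
    labels = [t.taxon.label for t in tips]
    missing = [lb for lb in labels if lb not in tip_values]
    if missing:
        raise ValueError(f"tips without data: {missing}")
    vals = {lb: np.atleast_1d(np.asarray(tip_values[lb], dtype=float)) for lb in labels}
    p = len(next(iter(vals.values())))

    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    index = {nd: i for i, nd in enumerate(internal)}
    n_int = len(internal)
    A = np.zeros((n_int, n_int))
    B = np.zeros((n_int, p))
    for nd in internal:
        i = index[nd]
        neigh = list(nd.child_nodes())
        if nd.parent_node is not None:
            neigh.append(nd.parent_node)
        for other in neigh:
            if other is nd.parent_node:
                length = nd.edge.length
            else:
                length = other.edge.length
            if length is None or length <= 0:
                length = 1e-12  # zero-length edge: effectively identical states
            w = 1.0 / length
            A[i, i] += w
            if other.is_leaf():
                B[i] += w * vals[other.taxon.label]
            else:
                j = index[other]
                A[i, j] -= w
    est = np.linalg.solve(A, B)
    out: dict = {nd: est[index[nd]] for nd in internal}
    for t in tips:
        out[t] = vals[t.taxon.label]
    return out


# ---------------------------------------------------------------------------
# Thin-plate spline
# ---------------------------------------------------------------------------

def tps_warp(
    source_landmarks: np.ndarray,
    target_landmarks: np.ndarray,
    query_points: np.ndarray,
) -> np.ndarray:
    """3D thin-plate-spline interpolation mapping source landmarks exactly
    onto target landmarks, applied to arbitrary query points.

    Uses the 3D kernel U(r) = r with a full affine part, the standard
    smooth-deformation model for visualizing shape change between landmark
    configurations. Affine maps are reproduced exactly.
    """
    src = np.asarray(source_landmarks, dtype=float)
    tgt = np.asarray(target_landmarks, dtype=float)
    q = np.asarray(query_points, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching K×3 arrays")
    k = src.shape[0]
    if k < 5:
        raise ValueError("3D TPS needs at least 5 landmarks")

    def _kernel(a, b):
        d = a[:, None, :] - b[None, :, :]
        return np.sqrt((d**2).sum(-1))

    K = _kernel(src, src)
    P = np.hstack([np.ones((k, 1)), src])
    L = np.zeros((k + 4, k + 4))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 4, 3))
    rhs[:k] = tgt
    try:
        params = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular thin-plate-spline system (degenerate/coplanar source "
            "landmarks); jitter the configuration slightly"
        ) from e
    w, a = params[:k], params[k:]
    Uq = _kernel(q, src)
    return Uq @ w + np.hstack([np.ones((q.shape[0], 1)), q]) @ a
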