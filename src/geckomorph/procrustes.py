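"""Procrustes superimposition machinery.

Centroid size, ordinary (pairwise) and generalized (iterative, multi-specimen)
least-squares Procrustes alignment, mirroring of left elements, sliding of
semilandmarks under the Procrustes-distance criterion, and bilateral
symmetrization of paired elements.

Shapes are kept in "partial Procrustes" form: centred at the origin and
scaled to unit centroid size, rotated to the consensus by the least-squares
optimal proper rotation.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import AlignedDataset, Configuration, LandmarkScheme, SchemeError

__all__ = [
    "centroid_size",
    "opa_align",
    "procrustes_distance",
    "mirror_configuration",
    "GeneralizedProcrustes",
    "gpa",
    "slide_semilandmarks",
    "symmetrize_pairs",
    "align_to_reference",
]


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide; size and orientation are undefined."""


class ConvergenceError(RuntimeError):
    """Iterative superimposition failed to converge."""


def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the
    centroid — the standard geometric-morphometric size measure. It is
    invariant to translation and rotation and scales linearly with the
    configuration.

    Accepts a Configuration or a bare (K, 3) array.
    """
    x = config.coords if isinstance(config, Configuration) else np.asarray(config, float)
    centred = x - x.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincident")
    return cs


def _centre_scale(x: np.ndarray) -> tuple[np.ndarray, float]:
    centred = x - x.mean(axis=0)
    cs = np.sqrt((centred**2).sum())
    if cs == 0.0:
        raise DegenerateConfigurationError("all landmarks coincident")
    return centred / cs, float(cs)


def _optimal_rotation(moving: np.ndarray, target: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Least-squares rotation R (applied as ``moving @ R``) onto target.

    Kabsch solution via SVD; the smallest singular direction is sign-flipped
    when a proper rotation (det +1) is required.
    """
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def opa_align(
    moving: np.ndarray,
    target: np.ndarray,
    allow_reflection: bool = False,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Ordinary Procrustes alignment of ``moving`` onto ``target``.

    Removes translation, scale and rotation by least squares. Returns
    ``(aligned, rotation, scale, residual)`` where ``aligned`` is the moving
    configuration mapped into the target's frame, ``rotation`` is the 3×3
    (proper, unless ``allow_reflection``) rotation applied to the unit-size
    moving shape, ``scale`` is the ratio of target to moving centroid size
    times the cosine shrink factor, and ``residual`` is the Procrustes
    distance (root summed squared difference) between ``aligned`` and the
    centred target.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.shape != target.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {target.shape}")
    mu, cs_m = _centre_scale(moving)
    tu, cs_t = _centre_scale(target)
    r = _optimal_rotation(mu, tu, allow_reflection)
    # optimal scale for unit shapes is the correlation <mu R, tu>
    beta = float((mu @ r * tu).sum())
    scale = beta * cs_t / cs_m
    aligned = scale * (moving - moving.mean(axis=0)) @ r + target.mean(axis=0)
    residual = float(np.linalg.norm(aligned - target))
    return aligned, r, scale, residual


def procrustes_distance(a: np.ndarray, b: np.ndarray, allow_reflection: bool = False) -> float:
    """Partial Procrustes distance between two configurations: root summed
    squared difference after centring, scaling to unit centroid size and
    optimal rotation."""
    au, _ = _centre_scale(np.asarray(a, float))
    bu, _ = _centre_scale(np.asarray(b, float))
    r = _optimal_rotation(au, bu, allow_reflection)
    return float(np.linalg.norm(au @ r - bu))


def mirror_configuration(config: Configuration) -> Configuration:
    """Reflect a left element into the right-side frame by negating the first
    coordinate axis. The scheme is assumed side-symmetric, so landmark ids do
    not change. Applying this to a non-left element is permitted but warned.
    """
    if config.side != "left":
        warnings.warn(
            f"mirroring {config.specimen_id!r} with side={config.side!r}",
            stacklevel=2,
        )
    coords = config.coords.copy()
    coords[:, 0] *= -1
    out = config.with_coords(coords)
    out.side = "right" if config.side == "left" else ("left" if config.side == "right" else "unknown")
    out.extra = dict(config.extra, MIRRORED="1")
    return out


class GeneralizedProcrustes(TransformerMixin, BaseEstimator):
    """Generalized least-squares Procrustes superimposition of shape arrays.

    ``fit`` iteratively centres each configuration, scales it to unit
    centroid size, rotates it to the running consensus, and updates the
    consensus (normalized mean) until the consensus stops moving.

    Parameters
    ----------
    tol : float
        Convergence threshold on the root-mean-square consensus change.
    max_iter : int
        Iteration cap; exceeding it raises ``ConvergenceError``.
    allow_reflection : bool
        Permit improper rotations during alignment (off by default).

    Attributes
    ----------
    consensus_ : (K, 3) ndarray — Procrustes mean shape, unit centroid size.
    shapes_ : (N, K, 3) ndarray — aligned training shapes.
    centroid_sizes_ : (N,) ndarray — sizes measured before scaling.
    n_iter_ : int — iterations used.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100, allow_reflection: bool = False):
        self.tol = tol
        self.max_iter = max_iter
        self.allow_reflection = allow_reflection

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != 3 or X.shape[0] < 2:
            raise ValueError("X must be (N>=2, K, 3)")
        n = X.shape[0]
        shapes = np.empty_like(X)
        sizes = np.empty(n)
        for i in range(n):
            shapes[i], sizes[i] = _centre_scale(X[i])
        consensus, _ = _centre_scale(shapes[0])
        last_change = np.inf
        for it in range(1, self.max_iter + 1):
            for i in range(n):
                r = _optimal_rotation(shapes[i], consensus, self.allow_reflection)
                shapes[i] = shapes[i] @ r
            new_consensus, _ = _centre_scale(shapes.mean(axis=0))
            last_change = float(
                np.sqrt(((new_consensus - consensus) ** 2).mean())
            )
            consensus = new_consensus
            if last_change < self.tol:
                break
        else:
            raise ConvergenceError(
                f"GPA did not converge in {self.max_iter} iterations "
                f"(last consensus RMS change {last_change:.3e})"
            )
        self.consensus_ = consensus
        self.shapes_ = shapes
        self.centroid_sizes_ = sizes
        self.n_iter_ = it
        return self

    def transform(self, X):
        """Align new configurations to the fitted consensus (centre, unit
        scale, optimal rotation); does not move the consensus."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = np.empty_like(X, dtype=float)
        for i in range(X.shape[0]):
            u, _ = _centre_scale(X[i])
            out[i] = u @ _optimal_rotation(u, self.consensus_, self.allow_reflection)
        return out[0] if single else out


def gpa(
    configs: list[Configuration],
    scheme: LandmarkScheme | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedDataset:
    """Generalized Procrustes superimposition of a list of configurations.

    Left-side configurations should be mirrored beforehand (see
    :func:`mirror_configuration`); this function aligns whatever it is given.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least two configurations")
    if scheme is None:
        scheme = LandmarkScheme(n_fixed=configs[0].n_landmarks)
    ks = {c.n_landmarks for c in configs}
    if len(ks) != 1 or ks.pop() != scheme.total_landmarks:
        raise ValueError("configurations disagree with the scheme's landmark count")
    X = np.stack([c.coords for c in configs])
    est = GeneralizedProcrustes(tol=tol, max_iter=max_iter).fit(X)
    return AlignedDataset(
        shapes=est.shapes_,
        centroid_sizes=est.centroid_sizes_,
        consensus=est.consensus_,
        metadata=list(configs),
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# Semilandmark sliding
# ---------------------------------------------------------------------------

def _slide_one(
    shape: np.ndarray,
    consensus: np.ndarray,
    neighbours: dict[int, tuple[int, int]],
) -> np.ndarray:
    """Slide each semilandmark of one shape along its local curve tangent by
    the step that minimizes distance to the consensus, with the step bounded
    to half the distance to the nearer neighbour to preserve point ordering.
    """
    out = shape.copy()
    for j, (prev, nxt) in neighbours.items():
        t = shape[nxt] - shape[prev]  # central-difference tangent
        norm = np.linalg.norm(t)
        if norm == 0:
            continue
        t = t / norm
        step = float(t @ (consensus[j] - shape[j]))
        bound = 0.5 * min(
            np.linalg.norm(shape[j] - shape[prev]),
            np.linalg.norm(shape[nxt] - shape[j]),
        )
        step = np.clip(step, -bound, bound)
        out[j] = shape[j] + step * t
    return out


def slide_semilandmarks(
    dataset: AlignedDataset,
    scheme: LandmarkScheme | None = None,
    max_cycles: int = 5,
    tol: float = 1e-6,
) -> AlignedDataset:
    """Optimize semilandmark positions under the Procrustes-distance
    criterion.

    Each cycle displaces every semilandmark of every specimen along its local
    tangent direction (estimated from the flanking points on its curve)
    toward the consensus, then re-runs GPA so the consensus tracks the slid
    shapes. Cycles stop when the total Procrustes distance to the consensus
    changes by less than ``tol``, or after ``max_cycles``. Fixed landmarks
    never move.
    """
    scheme = scheme or dataset.scheme
    if not scheme.curves:
        return dataset
    neighbours = scheme.neighbours()
    for j, (p, n) in neighbours.items():
        if p == j or n == j:
            raise SchemeError(f"semilandmark {j} lacks distinct neighbours")

    shapes = dataset.shapes.copy()
    consensus = dataset.consensus.copy()
    n = shapes.shape[0]
    total = sum(float(np.linalg.norm(shapes[i] - consensus)) for i in range(n))
    cycles_used = 0
    for _ in range(max_cycles):
        for i in range(n):
            shapes[i] = _slide_one(shapes[i], consensus, neighbours)
        est = GeneralizedProcrustes().fit(shapes)
        shapes, consensus = est.shapes_, est.consensus_
        cycles_used += 1
        new_total = sum(float(np.linalg.norm(shapes[i] - consensus)) for i in range(n))
        if abs(total - new_total) < tol:
            total = new_total
            break
        total = new_total
    return AlignedDataset(
        shapes=shapes,
        centroid_sizes=dataset.centroid_sizes.copy(),
        consensus=consensus,
        metadata=list(dataset.metadata),
        scheme=scheme,
        sliding_iterations_used=dataset.sliding_iterations_used + cycles_used,
        symmetrized=dataset.symmetrized,
        unpaired=dataset.unpaired,
    )


def slide_to_reference(
    shape: np.ndarray,
    reference: np.ndarray,
    scheme: LandmarkScheme,
    max_cycles: int = 5,
    tol: float = 1e-6,
) -> np.ndarray:
    """Slide one aligned shape against a *fixed* reference (used when
    projecting unknowns into an existing morphospace: the reference consensus
    must not move)."""
    if not scheme.curves:
        return shape
    neighbours = scheme.neighbours()
    current = shape.copy()
    last = float(np.linalg.norm(current - reference))
    for _ in range(max_cycles):
        current = _slide_one(current, reference, neighbours)
        u, _ = _centre_scale(current)
        current = u @ _optimal_rotation(u, reference, False)
        d = float(np.linalg.norm(current - reference))
        if abs(last - d) < tol:
            break
        last = d
    return current


def align_to_reference(
    config: Configuration,
    reference: np.ndarray,
    scheme: LandmarkScheme,
    slide: bool = True,
    max_cycles: int = 5,
) -> np.ndarray:
    """Full treatment of an unknown specimen against a fixed reference frame:
    mirror if left-sided, centre, scale to unit centroid size, optimally
    rotate onto the reference, and (optionally) slide semilandmarks against
    it. Returns the aligned (K, 3) shape."""
    cfg = mirror_configuration(config) if config.side == "left" else config
    if cfg.n_landmarks != scheme.total_landmarks:
        raise ValueError(
            f"{config.specimen_id}: landmark count {cfg.n_landmarks} does not "
            f"match scheme ({scheme.total_landmarks})"
        )
    u, _ = _centre_scale(cfg.coords)
    aligned = u @ _optimal_rotation(u, reference, False)
    if slide and scheme.curves:
        aligned = slide_to_reference(aligned, reference, scheme, max_cycles=max_cycles)
    return aligned


# ---------------------------------------------------------------------------
# Bilateral symmetrization
# ---------------------------------------------------------------------------

def symmetrize_pairs(dataset: AlignedDataset) -> AlignedDataset:
    """Collapse left/right pairs to their symmetric component.

    For each individual (grouped by ``specimen_id``) with two aligned
    elements — the mirrored left and the right — the symmetric component is
    their Procrustes mean; its centroid size is the mean of the two side
    sizes. Individuals represented by a single side pass through unchanged
    and are flagged in ``unpaired``. More than two elements per individual is
    an error. The symmetrized set is re-superimposed so the stored consensus
    is its own Procrustes mean.
    """
    groups: dict[str, list[int]] = {}
    for i, m in enumerate(dataset.metadata):
        groups.setdefault(m.specimen_id, []).append(i)

    shapes_out: list[np.ndarray] = []
    sizes_out: list[float] = []
    meta_out: list[Configuration] = []
    unpaired: list[bool] = []
    for sid, idx in groups.items():
        if len(idx) > 2:
            raise ValueError(f"individual {sid!r} has {len(idx)} elements (max 2)")
        if len(idx) == 2:
            a, b = dataset.shapes[idx[0]], dataset.shapes[idx[1]]
            r = _optimal_rotation(a, b, False)
            mean, _ = _centre_scale((a @ r + b) / 2.0)
            shapes_out.append(mean)
            sizes_out.append(float(dataset.centroid_sizes[idx].mean()))
            unpaired.append(False)
        else:
            shapes_out.append(dataset.shapes[idx[0]].copy())
            sizes_out.append(float(dataset.centroid_sizes[idx[0]]))
            unpaired.append(True)
        m = dataset.metadata[idx[0]]
        meta_out.append(
            Configuration(
                specimen_id=sid,
                coords=shapes_out[-1],
                species=m.species,
                genus=m.genus,
                side="unknown",
                era=m.era,
                extra=dict(m.extra, SYMMETRIZED="1" if len(idx) == 2 else "0"),
            )
        )

    est = GeneralizedProcrustes().fit(np.stack(shapes_out))
    return AlignedDataset(
        shapes=est.shapes_,
        centroid_sizes=np.asarray(sizes_out),
        consensus=est.consensus_,
        metadata=meta_out,
        scheme=dataset.scheme,
        sliding_iterations_used=dataset.sliding_iterations_used,
        symmetrized=True,
        unpaired=np.asarray(unpaired, dtype=bool),
    )
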