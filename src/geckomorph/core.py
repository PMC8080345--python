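"""Core domain types for landmark-based geometric morphometrics.

A *configuration* is one digitized skeletal element: K landmarks in 3D plus
specimen metadata. A *landmark scheme* declares which landmarks are fixed
(anatomically homologous points) and which are sliding semilandmarks lying on
curves, and is the correspondence contract every configuration must satisfy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Curve",
    "LandmarkScheme",
    "Configuration",
    "AlignedDataset",
    "SchemeError",
    "ConfigurationError",
]


class SchemeError(ValueError):
    """A landmark scheme violates its structural invariants."""


class ConfigurationError(ValueError):
    """A landmark configuration violates its contract with the scheme."""


@dataclass(frozen=True)
class Curve:
    """One semilandmark curve: an ordered run of sliding points between two
    fixed anchor landmarks.

    All indices are 0-based internal ids (file carriers use 1-based ids; the
    I/O layer is the only place the shift occurs).
    """

    start: int
    semilandmarks: tuple[int, ...]
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "semilandmarks", tuple(int(i) for i in self.semilandmarks))

    @property
    def path(self) -> tuple[int, ...]:
        """Anchor-to-anchor landmark ids along the curve."""
        return (self.start, *self.semilandmarks, self.end)


@dataclass(frozen=True)
class LandmarkScheme:
    """Declares the landmark correspondence used by every configuration.

    Parameters
    ----------
    n_fixed : int
        Number of fixed (non-sliding) landmarks. Fixed landmarks occupy ids
        ``0 .. n_fixed-1``.
    curves : sequence of Curve
        Semilandmark curves. Curve anchors must be fixed-landmark ids; every
        semilandmark id in ``n_fixed .. total-1`` must belong to exactly one
        curve.
    dimension : int
        Spatial dimension (3 for micro-CT landmark data).
    """

    n_fixed: int
    curves: tuple[Curve, ...] = ()
    dimension: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "curves", tuple(self.curves))
        if self.n_fixed < 1:
            raise SchemeError("scheme needs at least one fixed landmark")
        if self.dimension not in (2, 3):
            raise SchemeError(f"unsupported dimension {self.dimension}")
        seen: set[int] = set()
        for c in self.curves:
            if not (0 <= c.start < self.n_fixed) or not (0 <= c.end < self.n_fixed):
                raise SchemeError(
                    f"curve anchors ({c.start}, {c.end}) must be fixed-landmark ids "
                    f"< {self.n_fixed}"
                )
            if len(c.semilandmarks) == 0:
                raise SchemeError("curve declares no semilandmarks")
            for s in c.semilandmarks:
                if s < self.n_fixed:
                    raise SchemeError(f"semilandmark id {s} collides with fixed ids")
                if s in seen:
                    raise SchemeError(f"semilandmark {s} assigned to two curves")
                seen.add(s)
        expected = set(range(self.n_fixed, self.n_fixed + len(seen)))
        if seen and seen != expected:
            raise SchemeError(
                "semilandmark ids must be contiguous after the fixed block; got "
                f"{sorted(seen)}"
            )

    @property
    def n_semilandmarks(self) -> int:
        return sum(len(c.semilandmarks) for c in self.curves)

    @property
    def total_landmarks(self) -> int:
        return self.n_fixed + self.n_semilandmarks

    @property
    def semilandmark_ids(self) -> np.ndarray:
        return np.array(
            [s for c in self.curves for s in c.semilandmarks], dtype=int
        )

    def neighbours(self) -> dict[int, tuple[int, int]]:
        """Map each semilandmark id to its flanking ids along its curve."""
        out: dict[int, tuple[int, int]] = {}
        for c in self.curves:
            path = c.path
            for k in range(1, len(path) - 1):
                out[path[k]] = (path[k - 1], path[k + 1])
        return out


@dataclass
class Configuration:
    """One element's K×3 landmark coordinates plus specimen metadata.

    ``side`` is ``left``/``right``/``unknown``; ``era`` is ``modern`` or
    ``subfossil``. Coordinates are in whatever units the digitization used.
    """

    specimen_id: str
    coords: np.ndarray
    species: str = ""
    genus: str = ""
    side: str = "unknown"
    era: str = "modern"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ConfigurationError(
                f"{self.specimen_id}: coords must be K×3, got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ConfigurationError(f"{self.specimen_id}: non-finite coordinates")
        if self.side not in ("left", "right", "unknown"):
            raise ConfigurationError(f"{self.specimen_id}: bad side {self.side!r}")
        if self.era not in ("modern", "subfossil"):
            raise ConfigurationError(f"{self.specimen_id}: bad era {self.era!r}")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def validate_against(self, scheme: LandmarkScheme) -> None:
        if self.n_landmarks != scheme.total_landmarks:
            raise ConfigurationError(
                f"{self.specimen_id}: {self.n_landmarks} landmarks, scheme "
                f"declares {scheme.total_landmarks}"
            )
        d = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        if dist.min() == 0.0:
            i, j = np.unravel_index(np.argmin(dist), dist.shape)
            raise ConfigurationError(
                f"{self.specimen_id}: landmarks {i} and {j} exactly coincident"
            )

    def with_coords(self, coords: np.ndarray) -> "Configuration":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass
class AlignedDataset:
    """Procrustes shape coordinates for a set of configurations.

    Attributes
    ----------
    shapes : (N, K, 3) ndarray
        Unit-centroid-size, centred, optimally rotated shape coordinates.
    centroid_sizes : (N,) ndarray
        Centroid sizes measured before scaling.
    consensus : (K, 3) ndarray
        The Procrustes mean shape (itself unit centroid size).
    metadata : list of Configuration
        Per-specimen metadata; ``coords`` in each entry are the *original*
        input coordinates, the aligned coordinates live in ``shapes``.
    scheme : LandmarkScheme
    sliding_iterations_used : int
        Number of slide/re-align cycles actually performed (0 if no sliding).
    symmetrized : bool
        True once left/right pairs have been collapsed to their symmetric
        component.
    unpaired : (N,) bool ndarray or None
        After symmetrization, flags individuals represented by a single side.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    metadata: list[Configuration]
    scheme: LandmarkScheme
    sliding_iterations_used: int = 0
    symmetrized: bool = False
    unpaired: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.centroid_sizes = np.asarray(self.centroid_sizes, dtype=float)
        self.consensus = np.asarray(self.consensus, dtype=float)
        n = self.shapes.shape[0]
        if len(self.metadata) != n or self.centroid_sizes.shape != (n,):
            raise ValueError("shapes, centroid_sizes and metadata lengths disagree")

    @property
    def n_specimens(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1]

    def flat(self) -> np.ndarray:
        """Shapes vectorized to (N, 3K)."""
        return self.shapes.reshape(self.n_specimens, -1)

    def column(self, name: str) -> np.ndarray:
        """Metadata field as an object array (e.g. ``genus``, ``species``)."""
        return np.array([getattr(m, name) for m in self.metadata], dtype=object)

    def subset(self, mask: Sequence[bool] | np.ndarray) -> "AlignedDataset":
        mask = np.asarray(mask, dtype=bool)
        idx = np.nonzero(mask)[0]
        return AlignedDataset(
            shapes=self.shapes[idx],
            centroid_sizes=self.centroid_sizes[idx],
            consensus=self.consensus.copy(),
            metadata=[self.metadata[i] for i in idx],
            scheme=self.scheme,
            sliding_iterations_used=self.sliding_iterations_used,
            symmetrized=self.symmetrized,
            unpaired=None if self.unpaired is None else self.unpaired[idx],
        )
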