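"""Synthetic landmark datasets with the statistical structure the analysis
assumes.

The default configuration emulates the sampling design of the New Zealand
diplodactylid maxilla study: 5 genera / 13 species / 43 modern skeletal
specimens with paired left+right elements (86 configurations), plus 11
unpaired subfossil elements of unknown affinity. Among-genus shape
divergence evolves on a species tree under Brownian motion; individuals add
isotropic within-species variation, a weak allometric shape–size component,
and small left–right asymmetry; every emitted element sits in its own random
rigid frame at its own centroid size, so the generator exercises the entire
superimposition chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core import Configuration, Curve, LandmarkScheme
from .io import read_newick

__all__ = [
    "SimulationConfig",
    "default_scheme",
    "default_base_shape",
    "default_tree",
    "simulate_bm_shapes",
    "simulate_dataset",
]

# Genus centroid-size distributions (CT units), mean and sd, matching the
# modern skeletal sample the generator emulates.
GENUS_SIZES: dict[str, tuple[float, float]] = {
    "Dactylocnemis": (1198.0, 142.9),
    "Hoplodactylus": (1690.0, 228.1),
    "Mokopirirakau": (1241.0, 115.6),
    "Naultinus": (1093.0, 104.0),
    "Woodworthia": (968.0, 100.9),
}

# 13 species in 5 genera with per-species modern sample counts (total 43).
SPECIES_TABLE: list[tuple[str, str, int]] = [
    ("Dactylocnemis", "Dactylocnemis_pacificus", 3),
    ("Dactylocnemis", "Dactylocnemis_ThreeKings", 3),
    ("Dactylocnemis", "Dactylocnemis_Mokohinau", 3),
    ("Hoplodactylus", "Hoplodactylus_duvaucelii", 8),
    ("Mokopirirakau", "Mokopirirakau_granulatus", 3),
    ("Mokopirirakau", "Mokopirirakau_southernNI", 3),
    ("Naultinus", "Naultinus_elegans", 3),
    ("Naultinus", "Naultinus_punctatus", 3),
    ("Naultinus", "Naultinus_grayii", 3),
    ("Woodworthia", "Woodworthia_maculata", 3),
    ("Woodworthia", "Woodworthia_chrysosiretica", 3),
    ("Woodworthia", "Woodworthia_Otago", 3),
    ("Woodworthia", "Woodworthia_Marlborough", 2),
]


def default_scheme() -> LandmarkScheme:
    """15 fixed landmarks plus 40 semilandmarks on 4 curves of 10."""
    curves = []
    anchors = [(0, 1), (1, 4), (4, 9), (9, 14)]
    nxt = 15
    for a, b in anchors:
        curves.append(Curve(start=a, semilandmarks=tuple(range(nxt, nxt + 10)), end=b))
        nxt += 10
    return LandmarkScheme(n_fixed=15, curves=tuple(curves))


def default_base_shape(scheme: LandmarkScheme | None = None) -> np.ndarray:
    """Deterministic maxilla-like 55×3 base shape, unit centroid size.

    Fixed landmarks sit on an elongate, dorsally bowed arc (a caricature of
    the maxillary body with its facial process); each curve's semilandmarks
    are equally spaced points on a quadratic arc between its anchors, bowed
    out of the anchor line so the configuration is genuinely 3D.
    """
    scheme = scheme or default_scheme()
    t = np.linspace(0.0, 1.0, scheme.n_fixed)
    fixed = np.stack(
        [
            2.0 * t - 1.0,                      # anterior–posterior axis
            0.45 * np.sin(np.pi * t),           # dorsal bow (facial process)
            0.25 * np.cos(2.0 * np.pi * t) - 0.1 * t,  # medial flange relief
        ],
        axis=1,
    )
    coords = np.zeros((scheme.total_landmarks, 3))
    coords[: scheme.n_fixed] = fixed
    for ci, c in enumerate(scheme.curves):
        a, b = coords[c.start], coords[c.end]
        # bow each curve perpendicular to its chord, alternating direction
        chord = b - a
        normal = np.cross(chord, [0.0, 0.0, 1.0])
        nn = np.linalg.norm(normal)
        normal = normal / nn if nn > 0 else np.array([0.0, 1.0, 0.0])
        bow = 0.18 * (-1.0) ** ci
        m = len(c.semilandmarks)
        s = np.linspace(0.0, 1.0, m + 2)[1:-1]
        arc = a[None] + np.outer(s, chord) + np.outer(4.0 * bow * s * (1 - s), normal)
        coords[list(c.semilandmarks)] = arc
    centred = coords - coords.mean(axis=0)
    return centred / np.sqrt((centred**2).sum())


_DEFAULT_TOPOLOGY = (
    "((Naultinus_elegans:{a},(Naultinus_punctatus:{b},Naultinus_grayii:{b}):0.15):0.45,"
    "(((Woodworthia_maculata:{c},Woodworthia_chrysosiretica:{c}):0.2,"
    "(Woodworthia_Otago:{d},Woodworthia_Marlborough:{d}):0.15):0.35,"
    "((Mokopirirakau_granulatus:{e},Mokopirirakau_southernNI:{e}):0.3,"
    "(Hoplodactylus_duvaucelii:{f},(Dactylocnemis_pacificus:{g},"
    "(Dactylocnemis_ThreeKings:{h},Dactylocnemis_Mokohinau:{h}):0.2):0.25):0.1):0.15):0.1);"
)


def default_tree() -> dendropy.Tree:
    """Ultrametric 13-tip, 5-genus species tree of unit depth."""
    newick = _DEFAULT_TOPOLOGY.format(
        a=0.55, b=0.40, c=0.35, d=0.40, e=0.45, f=0.65, g=0.40, h=0.20
    )
    return read_newick(newick)


def simulate_bm_shapes(
    tree: dendropy.Tree,
    base_shape: np.ndarray,
    bm_rate: float,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Evolve species mean shapes on a tree under Brownian motion.

    Each coordinate receives independent Gaussian increments with variance
    ``bm_rate × branch length``; a tip's mean shape is the root (base) shape
    plus the summed increments along its root path, so tip variance equals
    ``bm_rate`` × root-to-tip depth and two tips covary by ``bm_rate`` ×
    shared path length.
    """
    rng = np.random.default_rng(seed)
    base = np.asarray(base_shape, dtype=float)
    out: dict[str, np.ndarray] = {}
    state: dict = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            state[nd] = base.copy()
            continue
        length = nd.edge.length or 0.0
        step = (
            rng.normal(0.0, np.sqrt(bm_rate * length), size=base.shape)
            if bm_rate * length > 0
            else 0.0
        )
        state[nd] = state[nd.parent_node] + step
        if nd.is_leaf():
            out[nd.taxon.label] = state[nd]
    return out


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the emulated sampling design: 43 modern individuals
    (13 species, 5 genera) with paired sides and 11 single-sided subfossil
    elements. Magnitudes are in unit-centroid-size shape space.

    * ``bm_rate`` — Brownian shape variance per coordinate per unit branch
      length, the source of among-species/among-genus divergence.
    * ``within_sd`` — isotropic per-coordinate sd of individual variation
      about the species mean.
    * ``asymmetry_sd`` — per-coordinate sd of the left–right asymmetry
      vector (added to the right side, subtracted from the left before
      mirroring, so the symmetric component is exactly the individual mean).
    * ``allometry_coefficient`` — shape displacement along a fixed unit
      direction per unit deviation of log centroid size from the genus mean
      log size; the default is calibrated so allometry contributes ≈7% of
      total shape variance.
    * ``tangent_jitter_sd`` — optional extra semilandmark jitter directed
      along curve tangents (gives sliding realistic work); off by default.
    """

    scheme: LandmarkScheme = field(default_factory=default_scheme)
    tree: dendropy.Tree = field(default_factory=default_tree)
    species_table: list[tuple[str, str, int]] = field(
        default_factory=lambda: list(SPECIES_TABLE)
    )
    bm_rate: float = 8.1e-5
    within_sd: float = 0.006
    asymmetry_sd: float = 0.002
    allometry_coefficient: float = 0.32
    tangent_jitter_sd: float = 0.0
    size_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GENUS_SIZES)
    )
    n_fossils: int = 11
    fossil_from_genus: str = "Hoplodactylus"
    fossil_offset: np.ndarray | None = None
    fossil_size_scale: float = 1.15
    seed: int = 20210617

    def __post_init__(self) -> None:
        for name in ("bm_rate", "within_sd", "asymmetry_sd", "tangent_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        species_genera = {g for g, _, _ in self.species_table}
        if not species_genera <= set(self.size_means_sds):
            raise ValueError("size_means_sds missing genera from species_table")
        if self.fossil_from_genus not in species_genera:
            raise ValueError(f"fossil_from_genus {self.fossil_from_genus!r} unknown")
        tips = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        missing = {s for _, s, _ in self.species_table} - tips
        if missing:
            raise ValueError(f"species without tree tips: {sorted(missing)}")


def _random_rigid(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random proper rotation (QR of a Gaussian matrix) and translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q, rng.normal(0.0, 50.0, size=3)


def _emit(coords: np.ndarray, cs: float, rng: np.random.Generator) -> np.ndarray:
    """Scale a unit shape to centroid size ``cs`` and place it in a random
    rigid frame."""
    centred = coords - coords.mean(axis=0)
    unit = centred / np.sqrt((centred**2).sum())
    rot, trans = _random_rigid(rng)
    return cs * unit @ rot + trans


def _tangent_jitter(
    shape: np.ndarray, scheme: LandmarkScheme, sd: float, rng: np.random.Generator
) -> np.ndarray:
    out = shape.copy()
    for j, (p, n) in scheme.neighbours().items():
        t = shape[n] - shape[p]
        norm = np.linalg.norm(t)
        if norm > 0:
            out[j] += rng.normal(0.0, sd) * t / norm
    return out


def simulate_dataset(
    config: SimulationConfig | None = None,
) -> tuple[list[Configuration], list[Configuration], dict[str, str]]:
    """Generate the full synthetic study.

    Returns ``(modern, fossils, true_labels)``: modern configurations come as
    left+right pairs per individual; fossils are single-sided, labelled with
    genus/species "unknown"; ``true_labels`` maps fossil specimen ids to the
    genus that generated them.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    base = default_base_shape(cfg.scheme)
    species_means = simulate_bm_shapes(
        cfg.tree, base, cfg.bm_rate, seed=int(rng.integers(2**31))
    )
    # fixed allometry direction, shared by every individual
    direction = rng.normal(size=base.shape)
    direction /= np.linalg.norm(direction)

    genus_log_mean = {g: np.log(m) for g, (m, _) in cfg.size_means_sds.items()}

    def _individual(genus: str, species: str) -> tuple[np.ndarray, float]:
        mean_cs, sd_cs = cfg.size_means_sds[genus]
        cs = float(np.clip(rng.normal(mean_cs, sd_cs), mean_cs * 0.3, None))
        shape = (
            species_means[species]
            + rng.normal(0.0, cfg.within_sd, size=base.shape)
            + cfg.allometry_coefficient * (np.log(cs) - genus_log_mean[genus]) * direction
        )
        if cfg.tangent_jitter_sd > 0:
            shape = _tangent_jitter(shape, cfg.scheme, cfg.tangent_jitter_sd, rng)
        return shape, cs

    modern: list[Configuration] = []
    counter = 0
    for genus, species, n_ind in cfg.species_table:
        for _ in range(n_ind):
            counter += 1
            sid = f"M{counter:03d}"
            shape, cs = _individual(genus, species)
            asym = rng.normal(0.0, cfg.asymmetry_sd, size=base.shape)
            right = _emit(shape + asym, cs, rng)
            left = (shape - asym).copy()
            left[:, 0] *= -1  # anatomical left in its own frame
            left = _emit(left, cs, rng)
            for side, coords in (("right", right), ("left", left)):
                modern.append(
                    Configuration(
                        specimen_id=sid,
                        coords=coords,
                        species=species,
                        genus=genus,
                        side=side,
                        era="modern",
                    )
                )

    fossil_species = [
        s for g, s, _ in cfg.species_table if g == cfg.fossil_from_genus
    ]
    fossils: list[Configuration] = []
    true_labels: dict[str, str] = {}
    for i in range(cfg.n_fossils):
        sid = f"F{chr(ord('A') + i)}" if i < 26 else f"F{i:03d}"
        species = fossil_species[i % len(fossil_species)]
        shape, cs = _individual(cfg.fossil_from_genus, species)
        if cfg.fossil_offset is not None:
            shape = shape + np.asarray(cfg.fossil_offset, dtype=float)
        cs *= cfg.fossil_size_scale
        side = "right" if i % 2 == 0 else "left"
        coords = shape.copy()
        if side == "left":
            coords[:, 0] *= -1
        fossils.append(
            Configuration(
                specimen_id=sid,
                coords=_emit(coords, cs, rng),
                species="unknown",
                genus="unknown",
                side=side,
                era="subfossil",
            )
        )
        true_labels[sid] = cfg.fossil_from_genus
    return modern, fossils, true_labels
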