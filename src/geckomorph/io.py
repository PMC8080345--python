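"""Readers and writers for landmark data, schemes, trees and result tables.

File carriers use the community conventions: TPS records (Rohlf dialect,
``LM3=K`` blocks), long-format CSV/TSV tables, Newick trees with branch
lengths, and a small JSON dialect for landmark schemes. Landmark ids are
1-based in files and 0-based in memory; the converters here are the only
place the shift occurs.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core import Configuration, ConfigurationError, Curve, LandmarkScheme

__all__ = [
    "FormatError",
    "read_tps",
    "write_tps",
    "read_landmark_table",
    "write_landmark_table",
    "read_newick",
    "read_scheme_json",
    "write_scheme_json",
    "save_aligned_dataset",
    "load_aligned_dataset",
]

_META_KEYS = {"SPECIES", "GENUS", "SIDE", "ERA"}


class FormatError(ValueError):
    """A file does not conform to its declared carrier format."""


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def read_tps(path: str | Path, scheme: LandmarkScheme | None = None) -> list[Configuration]:
    """Read a TPS file of 3D landmark records.

    Each record is ``LM3=K`` followed by K whitespace-separated ``x y z``
    lines, an ``ID=`` line, and optional ``KEY=value`` metadata lines
    (``SPECIES``, ``GENUS``, ``SIDE``, ``ERA`` are recognised; unknown keys
    are preserved verbatim in ``Configuration.extra``).
    """
    text = Path(path).read_text(encoding="utf-8")
    records: list[Configuration] = []
    lines = [ln.strip() for ln in text.splitlines()]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if not ln:
            i += 1
            continue
        if not ln.upper().startswith("LM3="):
            raise FormatError(f"{path}: expected LM3= header at line {i + 1}, got {ln!r}")
        try:
            k = int(ln.split("=", 1)[1])
        except ValueError as e:
            raise FormatError(f"{path}: bad landmark count in {ln!r}") from e
        i += 1
        coords = np.empty((k, 3), dtype=float)
        for j in range(k):
            if i >= len(lines) or "=" in lines[i]:
                raise FormatError(
                    f"{path}: record starting near line {i - j} declares {k} "
                    f"points but only {j} coordinate lines found"
                )
            parts = lines[i].split()
            if len(parts) != 3:
                raise FormatError(f"{path}: line {i + 1}: expected 3 coordinates")
            coords[j] = [float(p) for p in parts]
            i += 1
        meta: dict[str, str] = {}
        while i < len(lines) and lines[i] and "=" in lines[i] and not lines[i].upper().startswith("LM3="):
            key, val = lines[i].split("=", 1)
            meta[key.strip().upper()] = val.strip()
            i += 1
        if "ID" not in meta:
            raise FormatError(f"{path}: record ending at line {i} has no ID= line")
        extra = {k_: v for k_, v in meta.items() if k_ not in _META_KEYS | {"ID"}}
        cfg = Configuration(
            specimen_id=meta["ID"],
            coords=coords,
            species=meta.get("SPECIES", ""),
            genus=meta.get("GENUS", ""),
            side=meta.get("SIDE", "unknown"),
            era=meta.get("ERA", "modern"),
            extra=extra,
        )
        if scheme is not None:
            try:
                cfg.validate_against(scheme)
            except ConfigurationError as e:
                raise FormatError(f"{path}: record {cfg.specimen_id!r}: {e}") from e
        records.append(cfg)
    return records


def write_tps(path: str | Path, configs: list[Configuration], precision: int = 10) -> None:
    """Write configurations as TPS records (inverse of :func:`read_tps`)."""
    out: list[str] = []
    for c in configs:
        out.append(f"LM3={c.n_landmarks}")
        for row in c.coords:
            out.append(" ".join(f"{v:.{precision}g}" for v in row))
        out.append(f"ID={c.specimen_id}")
        out.append(f"SPECIES={c.species}")
        out.append(f"GENUS={c.genus}")
        out.append(f"SIDE={c.side}")
        out.append(f"ERA={c.era}")
        for k, v in c.extra.items():
            out.append(f"{k}={v}")
        out.append("")
    Path(path).write_text("\n".join(out), encoding="utf-8")


# ---------------------------------------------------------------------------
# Long-format table
# ---------------------------------------------------------------------------

_TABLE_COLS = ["specimen_id", "species", "genus", "side", "era", "landmark_id", "x", "y", "z"]


def read_landmark_table(path: str | Path, scheme: LandmarkScheme | None = None) -> list[Configuration]:
    """Read a long-format landmark table (CSV or TSV by extension).

    Columns: specimen_id, species, genus, side, era, landmark_id (1-based),
    x, y, z. Rows are grouped into one Configuration per specimen with
    landmarks ordered by id.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing_cols = [c for c in _TABLE_COLS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing columns {missing_cols}")
    configs: list[Configuration] = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        ids = grp["landmark_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            dup = sorted(set(int(i) for i in ids[pd.Series(ids).duplicated()]))
            raise FormatError(f"{path}: specimen {sid}: duplicate landmark ids {dup}")
        k_expected = scheme.total_landmarks if scheme is not None else int(ids.max())
        expected = set(range(1, k_expected + 1))
        missing = sorted(expected - set(int(i) for i in ids))
        if missing:
            raise FormatError(f"{path}: specimen {sid}: missing landmark ids: {missing}")
        grp = grp.sort_values("landmark_id")
        coords = grp[["x", "y", "z"]].to_numpy(dtype=float)
        first = grp.iloc[0]
        cfg = Configuration(
            specimen_id=str(sid),
            coords=coords,
            species=str(first["species"]),
            genus=str(first["genus"]),
            side=str(first["side"]),
            era=str(first["era"]),
        )
        if scheme is not None:
            cfg.validate_against(scheme)
        configs.append(cfg)
    return configs


def write_landmark_table(path: str | Path, configs: list[Configuration]) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    rows = []
    for c in configs:
        for i, (x, y, z) in enumerate(c.coords, start=1):
            rows.append((c.specimen_id, c.species, c.genus, c.side, c.era, i, x, y, z))
    pd.DataFrame(rows, columns=_TABLE_COLS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Tips must be labelled; negative branch lengths are an error and
    zero-length branches produce a warning.
    """
    s = str(path_or_string)
    if "(" in s and ";" in s:
        tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=s, schema="newick", preserve_underscores=True)
    labels = [lf.taxon.label if lf.taxon else None for lf in tree.leaf_node_iter()]
    if any(lb is None or lb == "" for lb in labels):
        raise FormatError("tree has unlabeled tips")
    if len(set(labels)) != len(labels):
        raise FormatError("tree tip labels are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            continue
        if edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
        if edge.length == 0 and edge.head_node.parent_node is not None:
            warnings.warn("tree contains zero-length branches", stacklevel=2)
    return tree


# ---------------------------------------------------------------------------
# Scheme JSON
# ---------------------------------------------------------------------------

def read_scheme_json(path: str | Path) -> LandmarkScheme:
    """Read a landmark scheme from JSON (ids 1-based in the file)."""
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    curves = tuple(
        Curve(
            start=int(c["start"]) - 1,
            semilandmarks=tuple(int(s) - 1 for s in c["semis"]),
            end=int(c["end"]) - 1,
        )
        for c in d.get("curves", [])
    )
    return LandmarkScheme(
        n_fixed=int(d["n_fixed"]),
        curves=curves,
        dimension=int(d.get("dimension", 3)),
    )


def write_scheme_json(path: str | Path, scheme: LandmarkScheme) -> None:
    d = {
        "n_fixed": scheme.n_fixed,
        "dimension": scheme.dimension,
        "curves": [
            {
                "start": c.start + 1,
                "semis": [s + 1 for s in c.semilandmarks],
                "end": c.end + 1,
            }
            for c in scheme.curves
        ],
    }
    Path(path).write_text(json.dumps(d, indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# Aligned-dataset container (single-file JSON)
# ---------------------------------------------------------------------------

def save_aligned_dataset(path: str | Path, ds, provenance: dict | None = None) -> None:
    """Serialize an AlignedDataset (plus provenance) to a single JSON file."""
    d = {
        "shapes": ds.shapes.tolist(),
        "centroid_sizes": ds.centroid_sizes.tolist(),
        "consensus": ds.consensus.tolist(),
        "sliding_iterations_used": ds.sliding_iterations_used,
        "symmetrized": ds.symmetrized,
        "unpaired": None if ds.unpaired is None else ds.unpaired.astype(bool).tolist(),
        "scheme": {
            "n_fixed": ds.scheme.n_fixed,
            "dimension": ds.scheme.dimension,
            "curves": [
                {"start": c.start, "semis": list(c.semilandmarks), "end": c.end}
                for c in ds.scheme.curves
            ],
        },
        "metadata": [
            {
                "specimen_id": m.specimen_id,
                "species": m.species,
                "genus": m.genus,
                "side": m.side,
                "era": m.era,
            }
            for m in ds.metadata
        ],
        "provenance": provenance or {},
    }
    Path(path).write_text(json.dumps(d), encoding="utf-8")


def load_aligned_dataset(path: str | Path):
    from .core import AlignedDataset

    d = json.loads(Path(path).read_text(encoding="utf-8"))
    scheme = LandmarkScheme(
        n_fixed=d["scheme"]["n_fixed"],
        curves=tuple(
            Curve(c["start"], tuple(c["semis"]), c["end"]) for c in d["scheme"]["curves"]
        ),
        dimension=d["scheme"]["dimension"],
    )
    shapes = np.asarray(d["shapes"], dtype=float)
    metadata = [
        Configuration(
            specimen_id=m["specimen_id"],
            coords=shapes[i],
            species=m["species"],
            genus=m["genus"],
            side=m["side"],
            era=m["era"],
        )
        for i, m in enumerate(d["metadata"])
    ]
    return AlignedDataset(
        shapes=shapes,
        centroid_sizes=np.asarray(d["centroid_sizes"], dtype=float),
        consensus=np.asarray(d["consensus"], dtype=float),
        metadata=metadata,
        scheme=scheme,
        sliding_iterations_used=d["sliding_iterations_used"],
        symmetrized=d["symmetrized"],
        unpaired=None if d["unpaired"] is None else np.asarray(d["unpaired"], dtype=bool),
    )
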