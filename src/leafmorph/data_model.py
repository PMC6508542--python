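"""Core containers and I/O for heteroblastic leaf-series data.

A dataset is a :class:`LeafCollection` of :class:`LeafRecord` objects, one per
leaf.  Each record carries its identity (species, optional shape-class label,
vine, node along the shoot) together with one or more shape representations:
a 15-point landmark configuration, a closed outline polyline, and/or a set of
elliptical Fourier coefficients.

Node numbering follows the heteroblastic series: node 1 is the oldest leaf at
the shoot base.  Raw scans are often numbered the opposite way (1 = youngest
leaf at the growing tip); :func:`renumber_nodes` converts between the two
conventions per vine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateShapeError, FormatError, ValidationError

N_LANDMARKS = 15

BASE_FIRST = "base_first"
TIP_FIRST = "tip_first"
_NUMBERINGS = (BASE_FIRST, TIP_FIRST)


# ---------------------------------------------------------------------------
# shape containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandmarkConfig:
    """An ordered planar configuration of exactly 15 homologous landmarks.

    Landmark 1 is the petiolar junction; landmarks 1-6 mark the junction and
    the bases of the major veins.  The identities of the remaining landmarks
    (lobe tips, sinuses, vein tips) are configurable metadata, not code.
    """

    points: np.ndarray  # (15, 2) float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise ValidationError(
                f"landmark configuration must be ({N_LANDMARKS}, 2), got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def centroid_size(self) -> float:
        """Root of the summed squared distances of landmarks to the centroid."""
        return float(np.sqrt(((self.points - self.centroid()) ** 2).sum()))

    def __eq__(self, other: object) -> bool:  # value semantics
        return isinstance(other, LandmarkConfig) and np.array_equal(
            self.points, other.points
        )


@dataclass(frozen=True)
class Outline:
    """A closed, counter-clockwise polyline bounding a leaf.

    The first vertex implicitly follows the last.  Counter-clockwise is the
    mathematical convention: the shoelace signed area is positive.
    """

    points: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise DegenerateShapeError(
                f"outline needs >= 8 (x, y) vertices, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError("outline coordinates must be finite")
        seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        if np.any((seg == 0).all(axis=1)):
            raise DegenerateShapeError("outline has repeated consecutive vertices")
        if signed_area(pts) <= 0:
            raise ValidationError("outline must be counter-clockwise (signed area > 0)")
        object.__setattr__(self, "points", pts)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Outline) and np.array_equal(self.points, other.points)


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given by its vertices."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class EFDCoefficients:
    """Per-harmonic quadruples (a_n, b_n, c_n, d_n) of a closed contour.

    ``normalized`` marks first-harmonic normalization: size, rotation and
    starting point fixed so that a_1 = 1 and b_1 = c_1 = 0.
    """

    harmonics: np.ndarray  # (H, 4) float, rows ordered n = 1..H
    normalized: bool = False
    origin: tuple[float, float] = (0.0, 0.0)  # DC terms (A0, C0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.harmonics, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4 or arr.shape[0] < 1:
            raise ValidationError(f"harmonics must be (H, 4) with H >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("EFD coefficients must be finite")
        if self.normalized:
            a1, b1, c1, _ = arr[0]
            if abs(a1 - 1.0) > 1e-9 or abs(b1) > 1e-9 or abs(c1) > 1e-9:
                raise ValidationError(
                    "normalized EFDs require a1 = 1, b1 = c1 = 0 within 1e-9; "
                    f"got harmonic 1 = {arr[0]}"
                )
        object.__setattr__(self, "harmonics", arr)

    @property
    def n_harmonics(self) -> int:
        return int(self.harmonics.shape[0])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, EFDCoefficients)
            and self.normalized == other.normalized
            and np.array_equal(self.harmonics, other.harmonics)
        )


# ---------------------------------------------------------------------------
# records and collections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeafRecord:
    species: str
    vine_id: str
    node: int
    class_label: str | None = None
    landmarks: LandmarkConfig | None = None
    efd: EFDCoefficients | None = None
    outline: Outline | None = None

    def __post_init__(self) -> None:
        if self.node < 1:
            raise ValidationError(f"node must be >= 1, got {self.node}")
        if self.landmarks is None and self.efd is None and self.outline is None:
            raise ValidationError(
                "a leaf record needs at least one of landmarks, efd, outline"
            )


@dataclass(frozen=True)
class LeafCollection:
    """An ordered set of leaf records sharing one node-numbering convention."""

    records: tuple[LeafRecord, ...]
    numbering: str = BASE_FIRST

    def __post_init__(self) -> None:
        if self.numbering not in _NUMBERINGS:
            raise ValidationError(
                f"unknown numbering {self.numbering!r}; expected one of {_NUMBERINGS}"
            )
        object.__setattr__(self, "records", tuple(self.records))
        seen: set[tuple[str, int]] = set()
        for rec in self.records:
            key = (rec.vine_id, rec.node)
            if key in seen:
                raise ValidationError(f"duplicate (vine, node) pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LeafRecord]:
        return iter(self.records)

    def vines(self) -> dict[str, list[LeafRecord]]:
        out: dict[str, list[LeafRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.vine_id, []).append(rec)
        return out

    def species_labels(self) -> list[str]:
        return sorted({rec.species for rec in self.records})

    def nodes(self) -> list[int]:
        return sorted({rec.node for rec in self.records})


def renumber_nodes(collection: LeafCollection, target: str) -> LeafCollection:
    """Convert node numbering between tip-first and base-first, per vine.

    Within each vine the map is ``node -> max(node in vine) - node + 1``, an
    involution, so converting back restores the original numbering.  Gaps in a
    vine's node sequence are preserved.  Converting to the current convention
    is the identity.
    """
    if target not in _NUMBERINGS:
        raise ValidationError(f"unknown target numbering {target!r}")
    if target == collection.numbering:
        return collection
    vine_max = {
        vine: max(rec.node for rec in recs) for vine, recs in collection.vines().items()
    }
    flipped = tuple(
        replace(rec, node=vine_max[rec.vine_id] - rec.node + 1)
        for rec in collection.records
    )
    return LeafCollection(records=flipped, numbering=target)


# ---------------------------------------------------------------------------
# landmark tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TableDialect:
    """Column layout of a delimited landmark table.

    The deposited files' headers vary, so names are configurable.  Coordinate
    columns default to x1, y1, ..., x15, y15 in landmark order.
    """

    sep: str = ","
    species_col: str = "species"
    vine_col: str = "vine"
    node_col: str = "node"
    class_col: str | None = "class"
    numbering: str = BASE_FIRST

    def coord_cols(self) -> list[str]:
        cols: list[str] = []
        for i in range(1, N_LANDMARKS + 1):
            cols.extend([f"x{i}", f"y{i}"])
        return cols


def read_landmark_table(path, dialect: TableDialect | None = None) -> LeafCollection:
    """Read a one-leaf-per-row delimited landmark table.

    Each row must carry species, vine, node and 30 coordinate values.  Raises
    :class:`FormatError` naming the offending row for missing or non-numeric
    coordinates, and :class:`ValidationError` for duplicate (vine, node) pairs.
    """
    dialect = dialect or TableDialect()
    try:
        df = pd.read_csv(path, sep=dialect.sep)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"cannot parse landmark table {path}: {exc}") from exc
    needed = [dialect.species_col, dialect.vine_col, dialect.node_col]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"landmark table {path} lacks columns {missing}")
    coord_cols = dialect.coord_cols()
    missing_coords = [c for c in coord_cols if c not in df.columns]
    if missing_coords:
        raise FormatError(
            f"landmark table {path} lacks coordinate columns {missing_coords} "
            f"(need {2 * N_LANDMARKS} values per row)"
        )
    records = []
    for idx, row in df.iterrows():
        raw = row[coord_cols]
        vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            bad = [coord_cols[i] for i in np.flatnonzero(~np.isfinite(vals))]
            raise FormatError(
                f"row {idx} of {path}: non-numeric or missing coordinates {bad}"
            )
        cls = None
        if dialect.class_col and dialect.class_col in df.columns:
            val = row[dialect.class_col]
            cls = None if pd.isna(val) else str(val)
        records.append(
            LeafRecord(
                species=str(row[dialect.species_col]),
                vine_id=str(row[dialect.vine_col]),
                node=int(row[dialect.node_col]),
                class_label=cls,
                landmarks=LandmarkConfig(vals.reshape(N_LANDMARKS, 2)),
            )
        )
    return LeafCollection(records=tuple(records), numbering=dialect.numbering)


def write_landmark_table(collection: LeafCollection, path, dialect: TableDialect | None = None) -> None:
    """Write a collection's landmark configurations as a delimited table."""
    dialect = dialect or TableDialect(numbering=collection.numbering)
    rows = []
    for rec in collection.records:
        if rec.landmarks is None:
            raise ValidationError(
                f"record ({rec.vine_id}, node {rec.node}) has no landmarks to write"
            )
        row: dict[str, object] = {
            dialect.species_col: rec.species,
            dialect.vine_col: rec.vine_id,
            dialect.node_col: rec.node,
        }
        if dialect.class_col:
            row[dialect.class_col] = rec.class_label
        flat = rec.landmarks.points.reshape(-1)
        for col, val in zip(dialect.coord_cols(), flat):
            row[col] = repr(float(val))  # repr round-trips float64 exactly
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=dialect.sep, index=False)


# ---------------------------------------------------------------------------
# NEF files (normalized elliptical Fourier descriptors, SHAPE dialect)
# ---------------------------------------------------------------------------


def read_nef(path) -> dict[str, EFDCoefficients]:
    """Read a SHAPE-dialect NEF file.

    Layout per record: a name line, an integer harmonic-count line, then H
    lines of 4 whitespace-separated floats.  Windows line endings and repeated
    whitespace are tolerated.  All records must share the same harmonic count.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh.read().replace("\r\n", "\n").split("\n")]
    lines = [ln for ln in lines if ln]
    out: dict[str, EFDCoefficients] = {}
    i = 0
    shared_h: int | None = None
    while i < len(lines):
        name = lines[i]
        i += 1
        if i >= len(lines):
            raise FormatError(f"NEF record {name!r}: missing harmonic count")
        try:
            h = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(
                f"NEF record {name!r}: non-integer harmonic count {lines[i]!r}"
            ) from exc
        i += 1
        if h < 1:
            raise FormatError(f"NEF record {name!r}: harmonic count {h} < 1")
        if shared_h is None:
            shared_h = h
        elif h != shared_h:
            raise FormatError(
                f"NEF record {name!r}: harmonic count {h} differs from {shared_h}"
            )
        if i + h > len(lines):
            raise FormatError(f"NEF record {name!r}: truncated (expected {h} rows)")
        rows = []
        for j in range(h):
            toks = lines[i + j].split()
            if len(toks) != 4:
                raise FormatError(
                    f"NEF record {name!r}, harmonic {j + 1}: expected 4 values, "
                    f"got {len(toks)}"
                )
            try:
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise FormatError(
                    f"NEF record {name!r}, harmonic {j + 1}: non-numeric token"
                ) from exc
        i += h
        out[name] = EFDCoefficients(np.array(rows), normalized=True)
    return out


def write_nef(coeffs: Mapping[str, EFDCoefficients], path) -> None:
    """Write normalized EFDs in the SHAPE NEF dialect (lossless to 1e-12)."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, c in coeffs.items():
            fh.write(f"{name}\n{c.n_harmonics}\n")
            for row in c.harmonics:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# JSON round trip for pipeline stage isolation
# ---------------------------------------------------------------------------


def collection_to_json(collection: LeafCollection, path) -> None:
    payload = {
        "numbering": collection.numbering,
        "records": [
            {
                "species": r.species,
                "vine_id": r.vine_id,
                "node": r.node,
                "class_label": r.class_label,
                "landmarks": None if r.landmarks is None else r.landmarks.points.tolist(),
                "outline": None if r.outline is None else r.outline.points.tolist(),
                "efd": None
                if r.efd is None
                else {
                    "harmonics": r.efd.harmonics.tolist(),
                    "normalized": r.efd.normalized,
                    "origin": list(r.efd.origin),
                },
            }
            for r in collection.records
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def collection_from_json(path) -> LeafCollection:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    records = []
    for r in payload["records"]:
        efd = None
        if r["efd"] is not None:
            efd = EFDCoefficients(
                np.array(r["efd"]["harmonics"]),
                normalized=r["efd"]["normalized"],
                origin=tuple(r["efd"]["origin"]),
            )
        records.append(
            LeafRecord(
                species=r["species"],
                vine_id=r["vine_id"],
                node=r["node"],
                class_label=r["class_label"],
                landmarks=None
                if r["landmarks"] is None
                else LandmarkConfig(np.array(r["landmarks"])),
                outline=None if r["outline"] is None else Outline(np.array(r["outline"])),
                efd=efd,
            )
        )
    return LeafCollection(records=tuple(records), numbering=payload["numbering"])
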