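"""Skeletal mesh data model, mesh file I/O and the segment manifest.

A skeletal reconstruction is organised as a set of *functional units*
(head, neck, trunk, tail and the six limb segments per side), each holding
one or more triangular surface meshes of individual bones.  Alternative
articulations of the same skeleton ("pose variants": e.g. ``min``/``pref``/
``max`` intervertebral spacing and rib flaring) are expressed declaratively
through a :class:`SegmentManifest`: a table that assigns each mesh file to a
unit, a side, one or more pose labels, an optional unit-scale factor (for
scans delivered in millimetres) and an optional rigid transform.  Shared
geometry is never mutated between poses.

Canonical internal units are metres; masses downstream are kilograms.
Coordinates are right-handed with no anatomical axis enforced.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh as _trimesh

from .errors import (
    DegenerateMeshError,
    ManifestError,
    MeshFormatError,
    MissingUnitError,
)

#: Base vocabulary of functional-unit names.  Cervical subsegments are
#: written ``neck:1``, ``neck:2`` ...; the part before the colon must be in
#: this set.
UNIT_VOCABULARY = frozenset(
    {
        "head",
        "neck",
        "trunk",
        "tail",
        "upper arm",
        "forearm",
        "hand",
        "thigh",
        "shank",
        "foot",
    }
)

SIDES = frozenset({"left", "right", "axial"})


def _base_unit_name(name: str) -> str:
    return name.split(":", 1)[0].strip()


# ---------------------------------------------------------------------------
# TriMesh
# ---------------------------------------------------------------------------


@dataclass
class TriMesh:
    """Triangular surface mesh of one skeletal element (or one hull).

    Parameters
    ----------
    vertices : (n, 3) float array, metres.
    faces : (m, 3) int array of vertex-index triples.  Winding is *not*
        trusted; volume computation orients faces itself.
    label : free-text identifier.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DegenerateMeshError(
                f"vertices must be (n, 3); got {self.vertices.shape}"
            )
        if self.faces.size and (self.faces.ndim != 2 or self.faces.shape[1] != 3):
            raise DegenerateMeshError(f"faces must be (m, 3); got {self.faces.shape}")
        self.faces = self.faces.reshape(-1, 3)
        if not np.isfinite(self.vertices).all():
            raise DegenerateMeshError(f"non-finite coordinates in mesh {self.label!r}")
        if self.faces.size:
            lo, hi = self.faces.min(), self.faces.max()
            if lo < 0 or hi >= len(self.vertices):
                raise DegenerateMeshError(
                    f"face index out of range in mesh {self.label!r}: "
                    f"index {hi if hi >= len(self.vertices) else lo} "
                    f"with {len(self.vertices)} vertices"
                )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_degenerate(self, rel_tol: float = 1e-12) -> bool:
        """True if the vertex set cannot enclose a volume.

        Fewer than four vertices, or all vertices within ``rel_tol`` (of the
        bounding-box diagonal) of a common plane.
        """
        if self.n_vertices < 4:
            return True
        centred = self.vertices - self.vertices.mean(axis=0)
        sv = np.linalg.svd(centred, compute_uv=False)
        diag = float(np.linalg.norm(np.ptp(self.vertices, axis=0)))
        return bool(sv[-1] <= max(rel_tol * max(diag, 1.0), 0.0))

    def transformed(self, matrix: np.ndarray) -> "TriMesh":
        """Return a copy with a 4x4 homogeneous transform applied."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError(f"expected 4x4 transform, got {matrix.shape}")
        hom = np.c_[self.vertices, np.ones(len(self.vertices))]
        moved = hom @ matrix.T
        return TriMesh(moved[:, :3], self.faces.copy(), self.label)

    def scaled(self, factor: float) -> "TriMesh":
        return TriMesh(self.vertices * float(factor), self.faces.copy(), self.label)


# ---------------------------------------------------------------------------
# Mesh file I/O (Wavefront OBJ, PLY, STL via trimesh)
# ---------------------------------------------------------------------------

_EXT_TO_FORMAT = {
    ".obj": "obj",
    ".ply": "ply",
    ".stl": "stl",
}


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        base = fmt.split("_", 1)[0]
        if base not in ("obj", "ply", "stl"):
            raise MeshFormatError(f"unsupported mesh format {fmt!r}")
        return fmt
    try:
        return _EXT_TO_FORMAT[path.suffix.lower()]
    except KeyError:
        raise MeshFormatError(
            f"cannot infer mesh format from extension {path.suffix!r} ({path})"
        ) from None


def read_mesh(path: str | Path, fmt: str = "auto") -> TriMesh:
    """Read a triangular mesh from OBJ, PLY or STL.

    STL stores every triangle independently, so duplicated vertices are
    merged on load; OBJ/PLY vertex order and unreferenced vertices are
    preserved.  Coordinates are taken to be metres unless the manifest
    declares a per-file scale.
    """
    path = Path(path)
    fmt_base = _resolve_format(path, fmt).split("_", 1)[0]
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    try:
        loaded = _trimesh.load_mesh(
            str(path), file_type=fmt_base, process=(fmt_base == "stl")
        )
    except Exception as exc:  # trimesh raises many concrete types
        raise MeshFormatError(f"could not parse {path} as {fmt_base}: {exc}") from exc
    if isinstance(loaded, _trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise DegenerateMeshError(f"{path}: no geometry records")
        loaded = _trimesh.util.concatenate(geoms)
    faces = np.asarray(loaded.faces)
    if faces.size == 0:
        raise DegenerateMeshError(f"{path}: mesh has zero faces")
    return TriMesh(np.asarray(loaded.vertices, float), faces, label=path.stem)


def write_mesh(
    mesh: TriMesh, path: str | Path, fmt: str = "auto", encoding: str = "ascii"
) -> Path:
    """Write a mesh to OBJ, PLY or STL.

    ``encoding`` selects ASCII or binary for PLY/STL (OBJ is always text).
    OBJ is written with full double precision so that an OBJ round trip
    reproduces coordinates to better than 1e-9; PLY and STL store 32-bit
    floats and round-trip only to single precision.
    """
    path = Path(path)
    if mesh.n_faces == 0:
        raise DegenerateMeshError("refusing to write a mesh with zero faces")
    fmt = _resolve_format(path, fmt)
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    try:
        if fmt == "obj":
            text = _trimesh.exchange.obj.export_obj(tm, digits=17)
            path.write_text(text)
        elif fmt == "ply":
            data = _trimesh.exchange.ply.export_ply(tm, encoding=encoding)
            path.write_bytes(data)
        elif fmt in ("stl", "stl_ascii"):
            file_type = "stl_ascii" if (encoding == "ascii" or fmt == "stl_ascii") else "stl"
            tm.export(str(path), file_type=file_type)
        else:  # pragma: no cover - guarded by _resolve_format
            raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# Functional units and skeleton models
# ---------------------------------------------------------------------------


@dataclass
class FunctionalUnit:
    """One anatomical segment hulled as a single body.

    The bones of a unit pool their vertices into one convex hull, so a unit
    may hold any number of meshes (e.g. every rib plus vertebrae for the
    trunk).
    """

    name: str
    side: str = "axial"
    meshes: list[TriMesh] = field(default_factory=list)

    def __post_init__(self) -> None:
        base = _base_unit_name(self.name)
        if base not in UNIT_VOCABULARY:
            raise ValueError(
                f"unknown functional unit {self.name!r}; base name must be one of "
                f"{sorted(UNIT_VOCABULARY)}"
            )
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {sorted(SIDES)}, got {self.side!r}")

    @property
    def key(self) -> str:
        """Disambiguated unit name, e.g. ``'left thigh'`` or ``'neck:2'``."""
        return self.name if self.side == "axial" else f"{self.side} {self.name}"

    def pooled_vertices(self) -> np.ndarray:
        if not self.meshes:
            raise DegenerateMeshError(f"unit {self.key!r} holds no meshes")
        return np.vstack([m.vertices for m in self.meshes])


@dataclass
class SkeletonModel:
    """A named pose variant: an ordered collection of functional units."""

    pose_label: str
    units: list[FunctionalUnit] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self) -> None:
        keys = [u.key for u in self.units]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ValueError(
                f"duplicate unit keys in pose {self.pose_label!r}: {sorted(dupes)}"
            )

    def unit(self, key: str) -> FunctionalUnit:
        for u in self.units:
            if u.key == key:
                return u
        raise MissingUnitError(key)

    @property
    def unit_keys(self) -> list[str]:
        return [u.key for u in self.units]


# ---------------------------------------------------------------------------
# Segment manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["path", "unit", "side", "poses", "scale", "transform"]


@dataclass
class ManifestRow:
    """One mesh assignment: file -> (unit, side) for a set of pose labels.

    ``scale`` is a unit conversion (e.g. 0.001 for millimetre scans) applied
    before ``transform``, a 4x4 row-major rigid transform.
    """

    path: str
    unit: str
    side: str = "axial"
    poses: tuple[str, ...] = ()
    scale: float = 1.0
    transform: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ManifestError(f"bad side {self.side!r} for {self.path}")
        if _base_unit_name(self.unit) not in UNIT_VOCABULARY:
            raise ManifestError(f"unknown unit {self.unit!r} for {self.path}")
        if self.scale <= 0:
            raise ManifestError(f"scale must be positive, got {self.scale}")
        self.poses = tuple(self.poses)
        if self.transform is not None:
            t = np.asarray(self.transform, float)
            if t.shape != (4, 4):
                raise ManifestError(
                    f"transform for {self.path} must be 4x4, got {t.shape}"
                )
            rot = t[:3, :3]
            det = float(np.linalg.det(rot))
            if not (
                abs(det - 1.0) < 1e-6
                and np.allclose(rot @ rot.T, np.eye(3), atol=1e-6)
            ):
                raise ManifestError(
                    f"transform for {self.path} is not proper rigid "
                    f"(det={det:.6g}); use the scale column for unit changes"
                )
            if not np.allclose(t[3], [0, 0, 0, 1], atol=1e-12):
                raise ManifestError(f"transform for {self.path}: last row must be 0 0 0 1")
            self.transform = t


@dataclass
class SegmentManifest:
    """Assignment table mapping mesh files to functional units and poses."""

    rows: list[ManifestRow]
    base_dir: Path = Path(".")

    @property
    def pose_labels(self) -> list[str]:
        seen: list[str] = []
        for row in self.rows:
            for p in row.poses:
                if p not in seen:
                    seen.append(p)
        return seen

    def rows_for_pose(self, pose_label: str) -> list[ManifestRow]:
        return [r for r in self.rows if pose_label in r.poses]

    def validate_files(self) -> None:
        missing = [
            str(self.base_dir / r.path)
            for r in self.rows
            if not (self.base_dir / r.path).exists()
        ]
        if missing:
            raise ManifestError(f"manifest references missing files: {missing}")


def read_manifest(path: str | Path) -> SegmentManifest:
    """Read a manifest CSV.

    Columns: ``path, unit, side, poses, scale, transform``.  ``poses`` is a
    ``;``-separated list of pose labels; ``transform`` is 16 space-separated
    numbers (row-major 4x4) or empty.
    """
    path = Path(path)
    rows: list[ManifestRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "path" not in reader.fieldnames:
            raise ManifestError(f"{path}: missing header row with a 'path' column")
        for i, rec in enumerate(reader, start=2):
            try:
                poses = tuple(
                    p.strip() for p in (rec.get("poses") or "").split(";") if p.strip()
                )
                tf_text = (rec.get("transform") or "").strip()
                transform = (
                    np.array([float(x) for x in tf_text.split()]).reshape(4, 4)
                    if tf_text
                    else None
                )
                rows.append(
                    ManifestRow(
                        path=rec["path"].strip(),
                        unit=rec["unit"].strip(),
                        side=(rec.get("side") or "axial").strip(),
                        poses=poses,
                        scale=float(rec.get("scale") or 1.0),
                        transform=transform,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ManifestError(f"{path}:{i}: {exc}") from exc
    return SegmentManifest(rows=rows, base_dir=path.parent)


def write_manifest(manifest: SegmentManifest, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for r in manifest.rows:
            tf = (
                " ".join(repr(float(x)) for x in np.asarray(r.transform).ravel())
                if r.transform is not None
                else ""
            )
            writer.writerow([r.path, r.unit, r.side, ";".join(r.poses), repr(r.scale), tf])
    return path


def load_skeleton(
    manifest: SegmentManifest,
    pose_label: str,
    required_units: Iterable[str] | None = None,
) -> SkeletonModel:
    """Assemble the posed skeleton for one pose label.

    Each manifest row belonging to the pose is read, its unit scale and
    rigid transform applied, and the result grouped into functional units
    by (unit name, side).  ``required_units`` may list unit keys that must
    be present; a missing one raises :class:`MissingUnitError`.
    """
    rows = manifest.rows_for_pose(pose_label)
    if not rows:
        raise ManifestError(
            f"no manifest rows for pose {pose_label!r}; "
            f"available poses: {manifest.pose_labels}"
        )
    units: dict[tuple[str, str], FunctionalUnit] = {}
    for row in rows:
        mesh = read_mesh(manifest.base_dir / row.path)
        if row.scale != 1.0:
            mesh = mesh.scaled(row.scale)
        if row.transform is not None:
            mesh = mesh.transformed(row.transform)
        key = (row.unit, row.side)
        if key not in units:
            units[key] = FunctionalUnit(name=row.unit, side=row.side)
        units[key].meshes.append(mesh)
    model = SkeletonModel(pose_label=pose_label, units=list(units.values()))
    if required_units is not None:
        have = set(model.unit_keys)
        missing = [u for u in required_units if u not in have]
        if missing:
            raise MissingUnitError(
                f"pose {pose_label!r} is missing required units: {missing}"
            )
    return model
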