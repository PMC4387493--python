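"""Convex hulls per functional unit, hull volumes and the total C_vol.

The volumetric quantity of interest is C_vol: the sum over functional
units of the volume of the convex hull fitted to the pooled bone vertices
of that unit ("shrink-wrapping" each segment).  Hulls are fitted per unit
independently, with no overlap subtraction between adjacent units.

Hull construction delegates to Qhull via :class:`scipy.spatial.ConvexHull`.
Volumes are computed by the divergence theorem as a sum of tetrahedra from
the vertex centroid; because every mesh passed in is convex and the
centroid lies inside, each tetrahedron's unsigned volume is its outward-
oriented signed volume, so input face winding never matters.  Degenerate
(coplanar) point sets are hard errors rather than zero-volume hulls:
a silent zero would corrupt the total.

An independent Monte-Carlo containment oracle (:func:`mc_volume_oracle`)
provides verification of every volume the package computes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateInputError, TopologyError
from .geometry import FunctionalUnit, SkeletonModel, TriMesh

#: Containment / convexity tolerance, as a fraction of the bounding-box
#: diagonal of the point set under test.
CONTAINMENT_RTOL = 1e-8


@dataclass
class HullResult:
    """Convex hull of one functional unit with its volume (m^3)."""

    unit_key: str
    hull: TriMesh
    volume: float
    point_count: int


@dataclass
class SkeletonVolume:
    """Per-unit hull volumes for one pose and their total C_vol (m^3).

    The total is the plain left-to-right float sum of the unit volumes in
    the order listed; rounding happens only at reporting time.
    """

    pose_label: str
    unit_volumes: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        total = 0.0
        for v in self.unit_volumes.values():
            total += v
        return total

    def scaled(self, k: float) -> "SkeletonVolume":
        """Volumes under isotropic linear rescaling by factor ``k``."""
        if k <= 0:
            raise DegenerateInputError(f"scale factor must be positive, got {k}")
        return SkeletonVolume(
            pose_label=self.pose_label,
            unit_volumes={u: v * k**3 for u, v in self.unit_volumes.items()},
        )


def hull_of_points(points: np.ndarray, label: str = "hull") -> TriMesh:
    """Convex hull of a 3D point set as a triangular mesh.

    The returned mesh's vertices are exactly the subset of input points on
    the hull.  Coplanar or collinear input raises
    :class:`DegenerateInputError` — the enclosed volume is undefined, and
    returning a zero-volume sliver would silently corrupt segment totals.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise DegenerateInputError(f"expected (n, 3) points, got {points.shape}")
    if len(points) < 4:
        raise DegenerateInputError(
            f"need at least 4 points for a 3D hull, got {len(points)}"
        )
    if not np.isfinite(points).all():
        raise DegenerateInputError("non-finite coordinates in hull input")
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise DegenerateInputError(
            f"degenerate (coplanar/collinear) hull input: {exc}"
        ) from exc
    index_map = np.full(len(points), -1, dtype=np.int64)
    index_map[hull.vertices] = np.arange(len(hull.vertices))
    return TriMesh(
        vertices=points[hull.vertices],
        faces=index_map[hull.simplices],
        label=label,
    )


def _check_closed(faces: np.ndarray) -> None:
    edges = np.vstack(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]
    )
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    if (counts != 2).any():
        bad = int((counts != 2).sum())
        raise TopologyError(
            f"surface is not closed: {bad} edge(s) not shared by exactly two faces"
        )


def mesh_volume(mesh: TriMesh) -> float:
    """Volume (m^3) of a closed convex triangular mesh.

    Divergence-theorem sum of tetrahedra between each face and the vertex
    centroid.  Convexity guarantees the centroid is interior, so outward
    orientation is recovered per face by taking the unsigned tetrahedron
    volume; the result is invariant to input winding, vertex ordering and
    rigid motion.  An open surface (unpaired edges) raises
    :class:`TopologyError`.
    """
    if mesh.n_faces == 0:
        raise TopologyError("mesh has no faces")
    _check_closed(mesh.faces)
    centroid = mesh.vertices.mean(axis=0)
    tri = mesh.vertices[mesh.faces] - centroid  # (m, 3, 3)
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(np.abs(signed).sum())


def containment_violation(points: np.ndarray, hull_mesh: TriMesh) -> float:
    """Greatest signed distance of any point outside the hull (<= 0: all in).

    Used as the convexity/containment certificate: every input point must
    lie inside or on its unit's hull within ``CONTAINMENT_RTOL`` times the
    bounding-box diagonal.
    """
    eqs = ConvexHull(hull_mesh.vertices).equations  # outward normals, offsets
    dists = points @ eqs[:, :3].T + eqs[:, 3]
    return float(dists.max())


def unit_hull(unit: FunctionalUnit) -> HullResult:
    """Fit one convex hull to the pooled vertices of every mesh in a unit."""
    points = unit.pooled_vertices()
    hull = hull_of_points(points, label=f"hull[{unit.key}]")
    volume = mesh_volume(hull)
    diag = float(np.linalg.norm(np.ptp(points, axis=0)))
    worst = containment_violation(points, hull)
    if worst > CONTAINMENT_RTOL * max(diag, 1.0):
        raise DegenerateInputError(
            f"hull containment certificate failed for {unit.key!r}: "
            f"violation {worst:.3g} exceeds tolerance"
        )
    return HullResult(
        unit_key=unit.key, hull=hull, volume=volume, point_count=len(points)
    )


def skeleton_volume(model: SkeletonModel) -> SkeletonVolume:
    """Hull every functional unit of a pose and sum to the total C_vol."""
    volumes: dict[str, float] = {}
    for unit in model.units:
        try:
            volumes[unit.key] = unit_hull(unit).volume
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"unit {unit.key!r} in pose {model.pose_label!r}: {exc}"
            ) from exc
    return SkeletonVolume(pose_label=model.pose_label, unit_volumes=volumes)


def mc_volume_oracle(
    mesh: TriMesh,
    n_samples: int = 100_000,
    seed: int | np.random.Generator = 0,
    chunk: int = 65_536,
) -> tuple[float, float]:
    """Monte-Carlo containment estimate of a convex mesh's volume.

    Uniform points are drawn in the axis-aligned bounding box and tested
    against the hull's half-space description; the estimate is the hit
    fraction times the box volume, with binomial standard error
    ``box_vol * sqrt(p (1 - p) / n)``.  Deterministic given ``seed``.  This
    is the package's independent check on :func:`mesh_volume` and is never
    used as the production volume path.
    """
    if n_samples < 1000:
        raise ValueError(
            f"n_samples must be >= 1000 for a meaningful standard error, "
            f"got {n_samples}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    lo = mesh.vertices.min(axis=0)
    hi = mesh.vertices.max(axis=0)
    box_vol = float(np.prod(hi - lo))
    try:
        eqs = ConvexHull(mesh.vertices).equations
    except QhullError as exc:
        raise DegenerateInputError(f"mesh has no 3D extent: {exc}") from exc
    tol = 1e-12 * max(float(np.linalg.norm(hi - lo)), 1.0)
    # keep the (chunk x n_faces) distance matrix bounded (~2e7 doubles)
    chunk = max(256, min(chunk, int(2e7 // max(len(eqs), 1))))
    hits = 0
    remaining = int(n_samples)
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.uniform(lo, hi, size=(m, 3))
        inside = (pts @ eqs[:, :3].T + eqs[:, 3]).max(axis=1) <= tol
        hits += int(inside.sum())
        remaining -= m
    p = hits / n_samples
    estimate = p * box_vol
    se = box_vol * float(np.sqrt(p * (1.0 - p) / n_samples))
    return estimate, se
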