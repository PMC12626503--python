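"""Geometric primitives for condylar morphometry.

Everything downstream — the osteotomy cut, the seven-landmark construction,
the cephalometric indices — is built from a handful of exact-algebra
primitives on oriented planes plus discrete operations on triangle surface
meshes. Units are millimetres throughout; no unit metadata in mesh files is
trusted. Coordinates are right-handed with no global axis assumption: all
anatomical directions are derived from named cranial landmarks.

Two tolerance regimes are kept deliberately separate:

* ``TOL_EXACT`` (1e-9 mm) for identities that hold in exact arithmetic
  (plane fits, projections, frame orthogonality);
* ``TOL_MESH`` (1e-6 mm) for agreement of discrete-mesh results, with
  shape-approximation error additionally scaling with mesh edge length.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import trimesh

log = logging.getLogger("condylomorph")

# package-wide tolerances (mm)
TOL_EXACT = 1e-9
TOL_MESH = 1e-6
#: landmarks this close to the osteotomy plane are treated as cut artifacts
CAP_EXCLUSION_MM = 0.5
#: spacing for resampling cross-section contours before landmark searches
CONTOUR_STEP_MM = 0.1

#: canonical landmark-file keys (JSON mapping name -> [x, y, z] in mm)
LANDMARK_SCHEMA = (
    "porion_l", "porion_r", "orbitale", "s_l", "s_r",
    "nasion", "a_point", "b_point", "pogonion", "menton",
    "crista_galli", "zf_l", "zf_r",
)


class GeometryError(ValueError):
    """Degenerate or invalid geometric input."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"non-finite point: {p!r}")
    return a


def _unit(v, what: str = "vector") -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(a)
    if n < TOL_EXACT:
        raise GeometryError(f"cannot normalize near-zero {what}")
    return a / n


@dataclass(frozen=True)
class Plane:
    """Oriented infinite plane: a point on it and a unit normal."""

    origin: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_point(self.origin))
        object.__setattr__(self, "normal", _as_point(self.normal))
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise GeometryError("plane normal must have unit norm")

    def flipped(self) -> "Plane":
        return Plane(self.origin, -self.normal)

    def is_parallel_to(self, other: "Plane") -> bool:
        return abs(float(np.dot(self.normal, other.normal))) > 1.0 - 1e-9

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic in-plane orthonormal basis (u, v) with u x v = normal."""
        n = self.normal
        seed = np.zeros(3)
        seed[int(np.argmin(np.abs(n)))] = 1.0
        u = _unit(np.cross(seed, n))
        v = np.cross(n, u)
        return u, v

    def to_2d(self, points: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        d = np.atleast_2d(points) - self.origin
        return np.column_stack([d @ u, d @ v])

    def to_3d(self, coords2d: np.ndarray) -> np.ndarray:
        u, v = self.basis()
        c = np.atleast_2d(coords2d)
        return self.origin + np.outer(c[:, 0], u) + np.outer(c[:, 1], v)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-9 or np.linalg.det(R) < 0:
            raise GeometryError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float,
                        translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        ax = _unit(axis, "rotation axis")
        th = np.radians(angle_deg)
        K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass
class Polyline3:
    """Ordered 3D polyline; closed loops do not repeat the first point."""

    points: np.ndarray
    closed: bool = False

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.closed and len(self.points) < 3:
            raise GeometryError("closed polyline needs >= 3 points")

    def __len__(self) -> int:
        return len(self.points)

    def segment_lengths(self) -> np.ndarray:
        p = self.points
        nxt = np.roll(p, -1, axis=0) if self.closed else p[1:]
        cur = p if self.closed else p[:-1]
        return np.linalg.norm(nxt - cur, axis=1)

    @property
    def length(self) -> float:
        return float(self.segment_lengths().sum())

    def resample(self, step: float) -> np.ndarray:
        """Points at uniform arc-length spacing ``step`` along the polyline."""
        p = self.points
        if self.closed:
            p = np.vstack([p, p[:1]])
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        n = max(int(np.ceil(total / step)), len(self.points))
        t = np.linspace(0.0, total, n, endpoint=not self.closed)
        out = np.empty((len(t), 3))
        for k in range(3):
            out[:, k] = np.interp(t, s, p[:, k])
        return out


# ---------------------------------------------------------------------------
# plane algebra
# ---------------------------------------------------------------------------

def fit_frankfort_plane(porion_left, porion_right, orbitale,
                        superior_ref) -> Plane:
    """Fit the Frankfort horizontal plane through both porions and orbitale.

    The plane is exact through the three points; its normal is flipped so
    that ``superior_ref`` (any point the caller declares superior, e.g. a
    calvarial or condylar-head point) lies on the positive side.
    """
    pl, pr, orb = map(_as_point, (porion_left, porion_right, orbitale))
    ref = _as_point(superior_ref)
    n = np.cross(pr - pl, orb - pl)
    scale = max(np.linalg.norm(pr - pl), np.linalg.norm(orb - pl), 1.0)
    if np.linalg.norm(n) < 1e-9 * scale ** 2:
        raise GeometryError("porions and orbitale are collinear")
    plane = Plane(pl, _unit(n))
    d = signed_distance(ref, plane)
    if abs(d) < TOL_EXACT:
        raise GeometryError("superior reference lies on the Frankfort plane")
    return plane if d > 0 else plane.flipped()


def signed_distance(point, plane: Plane) -> float:
    """Perpendicular distance, positive on the plane's normal side (mm)."""
    return float(np.dot(_as_point(point) - plane.origin, plane.normal))


def signed_distances(points: np.ndarray, plane: Plane) -> np.ndarray:
    return (np.atleast_2d(points) - plane.origin) @ plane.normal


def project_to_plane(point, plane: Plane) -> np.ndarray:
    """Foot of the perpendicular from ``point`` onto ``plane``."""
    p = _as_point(point)
    return p - signed_distance(p, plane) * plane.normal


# ---------------------------------------------------------------------------
# mesh operations
# ---------------------------------------------------------------------------

def as_trimesh(mesh) -> trimesh.Trimesh:
    if isinstance(mesh, trimesh.Trimesh):
        return mesh
    vertices, faces = mesh
    return trimesh.Trimesh(vertices=np.asarray(vertices, dtype=float),
                           faces=np.asarray(faces, dtype=int), process=False)


def validate_watertight(mesh: trimesh.Trimesh, what: str = "mesh") -> None:
    if not mesh.is_watertight:
        edges, counts = np.unique(mesh.edges_sorted, axis=0, return_counts=True)
        n_open = int((counts != 2).sum())
        raise GeometryError(
            f"{what} is not watertight: {n_open} edges not shared by exactly 2 faces")


def cross_section(mesh, plane: Plane) -> list[Polyline3]:
    """Intersect a surface mesh with a plane.

    Returns one :class:`Polyline3` per intersection contour, each ordered
    counter-clockwise when viewed from the plane's normal side. Closed
    contours are returned for watertight meshes; an empty intersection gives
    an empty list.
    """
    m = as_trimesh(mesh)
    sec = m.section(plane_origin=plane.origin, plane_normal=plane.normal)
    if sec is None:
        return []
    out: list[Polyline3] = []
    for disc in sec.discrete:
        pts = np.asarray(disc, dtype=float)
        closed = bool(np.linalg.norm(pts[0] - pts[-1]) < 1e-8)
        if closed:
            pts = pts[:-1]
        # drop duplicate consecutive points
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
        pts = pts[keep]
        if len(pts) < 2:
            continue
        if closed and _shoelace_area(plane.to_2d(pts)) < 0:
            pts = pts[::-1]
        out.append(Polyline3(pts, closed=closed))
    return out


def _shoelace_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def apply_rigid(obj, t: RigidTransform):
    """Apply a rigid motion to points, a Plane, a Polyline3 or a mesh."""
    if isinstance(obj, Plane):
        return Plane(t.rotation @ obj.origin + t.translation,
                     t.rotation @ obj.normal)
    if isinstance(obj, Polyline3):
        return Polyline3(obj.points @ t.rotation.T + t.translation, obj.closed)
    if isinstance(obj, trimesh.Trimesh):
        return trimesh.Trimesh(vertices=obj.vertices @ t.rotation.T + t.translation,
                               faces=obj.faces.copy(), process=False)
    a = np.asarray(obj, dtype=float)
    return a @ t.rotation.T + t.translation


# ---------------------------------------------------------------------------
# polygon triangulation (cap construction)
# ---------------------------------------------------------------------------

def triangulate_polygon_2d(xy: np.ndarray) -> np.ndarray:
    """Ear-clipping triangulation of a simple polygon (CCW or CW input).

    Returns (m, 3) index triples into ``xy``, oriented CCW. Robust for the
    simple, possibly non-convex cut contours produced by plane slicing.
    """
    pts = np.asarray(xy, dtype=float)
    n = len(pts)
    if n < 3:
        raise GeometryError("polygon needs >= 3 vertices")
    idx = list(range(n))
    if _shoelace_area(pts) < 0:
        idx.reverse()

    def cross_z(a, b, c):
        return ((pts[b, 0] - pts[a, 0]) * (pts[c, 1] - pts[a, 1])
                - (pts[b, 1] - pts[a, 1]) * (pts[c, 0] - pts[a, 0]))

    def point_in_tri(p, a, b, c):
        d1 = (pts[p, 0] - pts[b, 0]) * (pts[a, 1] - pts[b, 1]) - (pts[a, 0] - pts[b, 0]) * (pts[p, 1] - pts[b, 1])
        d2 = (pts[p, 0] - pts[c, 0]) * (pts[b, 1] - pts[c, 1]) - (pts[b, 0] - pts[c, 0]) * (pts[p, 1] - pts[c, 1])
        d3 = (pts[p, 0] - pts[a, 0]) * (pts[c, 1] - pts[a, 1]) - (pts[c, 0] - pts[a, 0]) * (pts[p, 1] - pts[a, 1])
        neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
        pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
        return not (neg and pos)

    tris: list[tuple[int, int, int]] = []
    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 4 * n * n:  # degenerate input: finish with a fan
            log.warning("ear clipping stalled; finishing cap with a fan")
            break
        m = len(idx)
        clipped = False
        for k in range(m):
            a, b, c = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            if cross_z(a, b, c) <= 1e-14:
                continue  # reflex or degenerate corner
            if any(point_in_tri(p, a, b, c) for p in idx
                   if p not in (a, b, c)):
                continue
            tris.append((a, b, c))
            idx.pop(k)
            clipped = True
            break
        if not clipped:
            # numerically flat polygon remnant: fan it out
            log.warning("no ear found on %d-gon remnant; using fan", len(idx))
            break
    if len(idx) >= 3:
        for k in range(1, len(idx) - 1):
            tris.append((idx[0], idx[k], idx[k + 1]))
    return np.asarray(tris, dtype=int)


def boundary_loops(mesh: trimesh.Trimesh) -> list[np.ndarray]:
    """Vertex-index loops of the open boundary of a mesh."""
    edges, counts = np.unique(mesh.edges_sorted, axis=0, return_counts=True)
    open_edges = edges[counts == 1]
    if len(open_edges) == 0:
        return []
    adj: dict[int, list[int]] = {}
    for a, b in open_edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    loops = []
    seen: set[int] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nbrs = [v for v in adj[cur] if v != prev]
            if not nbrs:
                break
            nxt = nbrs[0]
            if nxt == start:
                break
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        if len(loop) >= 3:
            loops.append(np.asarray(loop, dtype=int))
    return loops


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load an STL or PLY surface; coordinates are taken to be millimetres."""
    m = trimesh.load(str(path), force="mesh")
    if not isinstance(m, trimesh.Trimesh) or len(m.faces) == 0:
        raise GeometryError(f"no triangle geometry in {path}")
    return m


def save_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    mesh.export(str(path))


def load_landmarks(path: str | Path) -> dict[str, np.ndarray]:
    """Read a landmark JSON file: name -> [x, y, z] in mm.

    ``orbitale`` may be given directly, or as ``orbitale_l``/``orbitale_r``
    (averaged when both are present): the Frankfort fit uses a single
    orbitale point by convention.
    """
    with open(path) as fh:
        raw = json.load(fh)
    lm = {k: _as_point(v) for k, v in raw.items()}
    if "orbitale" not in lm:
        sides = [lm[k] for k in ("orbitale_l", "orbitale_r") if k in lm]
        if sides:
            lm["orbitale"] = np.mean(sides, axis=0)
    return lm


def save_landmarks(lm: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: [float(x) for x in np.asarray(v)] for k, v in lm.items()},
                  fh, indent=1)


def require_landmarks(lm: dict, names: Iterable[str]) -> None:
    missing = [n for n in names if n not in lm]
    if missing:
        raise GeometryError(f"missing landmark(s): {', '.join(missing)}")
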