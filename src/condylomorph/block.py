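"""Osteotomy-plane construction and condylar block extraction.

The condylar block is separated from the (hemi)mandible by an osteotomy
plane C, parallel to the Frankfort horizontal and passing through *s*, the
lowest point of the mandibular sigmoid notch. The block is the watertight
region superior to C; its volume — computed by the divergence theorem on
the capped mesh — is the primary morphometric outcome.

All directional language ("medial", "posterior", ...) is anchored by a
:class:`CondylarFrame` derived from the cranial landmarks, never from the
coordinate axes of the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .geometry import (
    GeometryError,
    Plane,
    TOL_EXACT,
    _as_point,
    _unit,
    as_trimesh,
    boundary_loops,
    log,
    signed_distance,
    signed_distances,
    triangulate_polygon_2d,
    validate_watertight,
)

#: vertices closer than this to plane C are snapped onto it before cutting
SNAP_TOL_MM = 1e-6


@dataclass(frozen=True)
class CondylarFrame:
    """Orthonormal anatomical axes for one condyle.

    ``u_si`` points superior (the plane-C normal), ``u_ml`` medial-to-lateral
    for the declared side, ``u_ap`` posterior-to-anterior. ``u_ml`` and
    ``u_ap`` lie in plane C.
    """

    plane_c: Plane
    u_si: np.ndarray
    u_ml: np.ndarray
    u_ap: np.ndarray
    side: str

    def __post_init__(self):
        for a, b in (("u_si", "u_ml"), ("u_si", "u_ap"), ("u_ml", "u_ap")):
            if abs(np.dot(getattr(self, a), getattr(self, b))) > 1e-9:
                raise GeometryError(f"frame axes {a} and {b} are not orthogonal")


@dataclass
class CondylarBlock:
    """Watertight condylar block capped at plane C, with its frame and volume."""

    mesh: trimesh.Trimesh
    frame: CondylarFrame
    volume: float
    cap_area: float = 0.0
    n_components_above: int = 1

    @property
    def plane_c(self) -> Plane:
        return self.frame.plane_c

    def heights(self) -> np.ndarray:
        """Signed distance of every vertex above plane C (mm)."""
        return signed_distances(self.mesh.vertices, self.plane_c)


def build_cut_plane(fh: Plane, s, superior_ref) -> Plane:
    """Osteotomy plane C: parallel to the Frankfort plane, through point *s*.

    The normal is oriented so that ``superior_ref`` (a point on the condylar
    head) has positive signed distance.
    """
    s = _as_point(s)
    plane = Plane(s, fh.normal)
    d = signed_distance(superior_ref, plane)
    if abs(d) < TOL_EXACT:
        raise GeometryError("superior reference lies on plane C: "
                            "orientation is ambiguous")
    return plane if d > 0 else plane.flipped()


def build_frame(plane_c: Plane, porion_left, porion_right, orbitale,
                side: str) -> CondylarFrame:
    """Anatomical frame from the cranial landmarks.

    The inter-porion axis projected into plane C gives the mediolateral
    direction (signed to point laterally for ``side``); the porion-midpoint
    to orbitale direction, projected into C and re-orthogonalized, gives
    anteroposterior.
    """
    if side not in ("left", "right"):
        raise GeometryError(f"side must be 'left' or 'right', got {side!r}")
    pl, pr, orb = map(_as_point, (porion_left, porion_right, orbitale))
    n = plane_c.normal
    ip = pr - pl
    if np.linalg.norm(ip) < TOL_EXACT:
        raise GeometryError("porions coincide")
    w = ip - np.dot(ip, n) * n
    if np.linalg.norm(w) < 1e-9 * np.linalg.norm(ip):
        raise GeometryError("inter-porion axis is parallel to the plane normal")
    u_ml = _unit(w) if side == "right" else -_unit(w)
    v = orb - 0.5 * (pl + pr)
    v = v - np.dot(v, n) * n
    v = v - np.dot(v, u_ml) * u_ml
    if np.linalg.norm(v) < TOL_EXACT:
        raise GeometryError("orbitale direction degenerate in plane C")
    return CondylarFrame(plane_c=plane_c, u_si=n, u_ml=u_ml, u_ap=_unit(v),
                         side=side)


def _snap_vertices(mesh: trimesh.Trimesh, plane: Plane,
                   tol: float = SNAP_TOL_MM) -> trimesh.Trimesh:
    d = signed_distances(mesh.vertices, plane)
    close = np.abs(d) < tol
    if not close.any():
        return mesh
    v = mesh.vertices.copy()
    v[close] -= np.outer(d[close], plane.normal)
    return trimesh.Trimesh(vertices=v, faces=mesh.faces.copy(), process=False)


def _cap_open_mesh(mesh: trimesh.Trimesh, plane: Plane) -> tuple[trimesh.Trimesh, float]:
    """Close the cut boundary loops with ear-clipped cap triangles.

    Cap faces are oriented with outward normal along ``-plane.normal``
    (the cap is the inferior face of the block). Returns (mesh, cap area).
    """
    loops = boundary_loops(mesh)
    if not loops:
        return mesh, 0.0
    cap_faces = []
    cap_area = 0.0
    for loop in loops:
        pts3 = mesh.vertices[loop]
        if np.abs(signed_distances(pts3, plane)).max() > 1e-5:
            log.warning("cut boundary loop deviates from plane C by "
                        "%.2e mm", np.abs(signed_distances(pts3, plane)).max())
        xy = plane.to_2d(pts3)
        tris = triangulate_polygon_2d(xy)
        for a, b, c in tris:
            # CCW in plane coords has normal +plane.normal: flip for outward
            cap_faces.append((loop[a], loop[c], loop[b]))
            cap_area += 0.5 * abs(
                (xy[b, 0] - xy[a, 0]) * (xy[c, 1] - xy[a, 1])
                - (xy[b, 1] - xy[a, 1]) * (xy[c, 0] - xy[a, 0]))
    faces = np.vstack([mesh.faces, np.asarray(cap_faces, dtype=int)])
    capped = trimesh.Trimesh(vertices=mesh.vertices.copy(), faces=faces,
                             process=False)
    return capped, float(cap_area)


def cut_block(mandible, plane_c: Plane, frame: CondylarFrame) -> CondylarBlock:
    """Cut the condylar block off the mandible at plane C and cap it.

    If several connected components lie above C (coronoid process included in
    the mesh), the component whose centroid is most posterior along ``u_ap``
    is kept: plane C through the sigmoid notch separates the condyle
    (posterior) from the coronoid (anterior).
    """
    m = as_trimesh(mandible)
    validate_watertight(m, "mandible mesh")
    m = _snap_vertices(m, plane_c)
    d = signed_distances(m.vertices, plane_c)
    if d.max() <= SNAP_TOL_MM:
        raise GeometryError("no geometry above plane C: empty block")
    sliced = trimesh.intersections.slice_mesh_plane(
        m, plane_normal=plane_c.normal, plane_origin=plane_c.origin, cap=False)
    if sliced is None or len(sliced.faces) == 0:
        raise GeometryError("no geometry above plane C: empty block")
    sliced.merge_vertices(merge_tex=True, merge_norm=True)
    parts = sliced.split(only_watertight=False)
    if len(parts) == 0:
        parts = [sliced]
    n_comp = len(parts)
    if n_comp > 1:
        ap = [float(np.dot(p.vertices.mean(axis=0) - plane_c.origin, frame.u_ap))
              for p in parts]
        pick = int(np.argmin(ap))
        log.info("cut yielded %d components above C; keeping most posterior",
                 n_comp)
        part = parts[pick]
    else:
        part = parts[0]
    capped, cap_area = _cap_open_mesh(part, plane_c)
    if capped.volume < 0:
        capped.invert()
    validate_watertight(capped, "capped condylar block")
    vol = block_volume_mesh(capped)
    return CondylarBlock(mesh=capped, frame=frame, volume=vol,
                         cap_area=cap_area, n_components_above=n_comp)


def block_volume_mesh(mesh: trimesh.Trimesh) -> float:
    """Signed (divergence-theorem) volume of a watertight mesh, made positive.

    A negative signed volume indicates inward orientation; it is fixed in
    place and logged rather than raised.
    """
    validate_watertight(mesh, "mesh")
    vol = float(mesh.volume)
    if vol < 0:
        log.warning("mesh orientation inward (signed volume %.3f); flipping", vol)
        mesh.invert()
        vol = float(mesh.volume)
    return vol


def block_volume(block: CondylarBlock) -> float:
    """Volume of the condylar block in mm^3."""
    return block_volume_mesh(block.mesh)
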