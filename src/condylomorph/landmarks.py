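"""Seven-point condylar landmark construction.

Seven surface points summarize condylar topography: *i* and *o*, the
innermost and outermost points of the condylar crest; *up*, the highest
point of the condyle on the vertical plane M through *i* and *o*; *a* and
*p*, the "lowest edge" of the anterior and posterior slopes on the plane N
perpendicular to the projected segment IO through its midpoint; and *pi*,
*po*, the posterior-slope points on the two planes N1/N2 rotated +-45
degrees from N, labelled by proximity to *i* and *o*. Each point's height
is its perpendicular distance above the osteotomy plane C.

The "lowest edge of a slope" has no closed-form anatomical definition; here
it is operationalized as the head-neck concave-curvature inflection: walking
down the slope branch of the section contour from its apex, the first local
maximum of concavity (discrete curvature estimated over an arc-length window
of three mean mesh edge lengths). When no concave inflection exists the
lowest point of the branch above the cap-exclusion band is used, with a
logged warning. Points within ``CAP_EXCLUSION_MM`` of plane C are never
candidates, so cut-boundary artifacts cannot be selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .block import CondylarBlock
from .geometry import (
    CAP_EXCLUSION_MM,
    CONTOUR_STEP_MM,
    GeometryError,
    Plane,
    Polyline3,
    _unit,
    cross_section,
    log,
    project_to_plane,
    signed_distance,
    signed_distances,
)

POINT_NAMES = ("i", "o", "a", "p", "pi", "po", "up")


@dataclass
class SevenPointSet:
    """The seven condylar landmarks and their heights above plane C (mm)."""

    points: dict[str, np.ndarray]
    heights: dict[str, float]

    @property
    def d_io(self) -> float:
        """Height difference *i* minus *o* (mediolateral crest tilt)."""
        return self.heights["i"] - self.heights["o"]

    @property
    def d_pipo(self) -> float:
        """Height difference *pi* minus *po* (posteromedial vs posterolateral)."""
        return self.heights["pi"] - self.heights["po"]


@dataclass(frozen=True)
class HeightDifferences:
    d_io: float
    d_pipo: float


def _noncap_vertex_mask(block: CondylarBlock, tol: float = 1e-6) -> np.ndarray:
    return block.heights() > tol


def find_extreme_points(block: CondylarBlock) -> tuple[np.ndarray, np.ndarray]:
    """Innermost (*i*) and outermost (*o*) vertices of the condylar block.

    Extremes are taken along the mediolateral axis over all non-cap
    vertices; ties are broken by greater height, then by vertex index, so
    the search is deterministic.
    """
    mask = _noncap_vertex_mask(block)
    if not mask.any():
        raise GeometryError("block has no vertices above plane C")
    verts = block.mesh.vertices[mask]
    h = block.heights()[mask]
    ml = verts @ block.frame.u_ml
    order_i = np.lexsort((np.arange(len(verts)), -h, ml))
    order_o = np.lexsort((np.arange(len(verts)), -h, -ml))
    return verts[order_i[0]].copy(), verts[order_o[0]].copy()


def build_section_planes(i, o, plane_c: Plane
                         ) -> tuple[Plane, Plane, Plane, Plane, np.ndarray]:
    """Planes M, N, N1, N2 and the IO midpoint from *i*, *o* and plane C.

    M is perpendicular to C through *i* and *o*. IO is the projection of the
    segment *i*-*o* onto C; N is perpendicular to both IO and C through the
    IO midpoint; N1 and N2 are rotated +45 and -45 degrees from N about the
    plane-C normal through the same midpoint.
    """
    i_p = project_to_plane(i, plane_c)
    o_p = project_to_plane(o, plane_c)
    if np.linalg.norm(o_p - i_p) < 1e-9:
        raise GeometryError("i and o project to the same point on plane C")
    io_dir = _unit(o_p - i_p)
    mid = 0.5 * (i_p + o_p)
    n_c = plane_c.normal
    plane_m = Plane(np.asarray(i, dtype=float), _unit(np.cross(n_c, io_dir)))
    plane_n = Plane(mid, io_dir)

    def rot(vec, deg):
        th = np.radians(deg)
        return (vec * np.cos(th)
                + np.cross(n_c, vec) * np.sin(th)
                + n_c * np.dot(n_c, vec) * (1 - np.cos(th)))

    plane_n1 = Plane(mid, _unit(rot(io_dir, 45.0)))
    plane_n2 = Plane(mid, _unit(rot(io_dir, -45.0)))
    return plane_m, plane_n, plane_n1, plane_n2, mid


def _section_contour(block: CondylarBlock, section: Plane
                     ) -> tuple[np.ndarray, bool]:
    """Densely resampled section contour with the highest reach on the block.

    Closed contours are rotated to a canonical start (highest raw vertex,
    ties broken toward the positive in-plane horizontal axis) before
    resampling, so the sample phase — and hence every downstream landmark —
    is invariant under rigid motion of the whole scene.
    """
    contours = cross_section(block.mesh, section)
    if not contours:
        raise GeometryError("section plane does not intersect the block")
    best, best_h = None, -np.inf
    for c in contours:
        hmax = float(signed_distances(c.points, block.plane_c).max())
        if hmax > best_h:
            best, best_h = c, hmax
    if best.closed:
        h = signed_distances(best.points, block.plane_c)
        e_h = _unit(np.cross(section.normal, block.frame.u_si))
        e = best.points @ e_h
        start = int(np.lexsort((np.arange(len(h)), -e, -np.round(h, 9)))[0])
        best = Polyline3(np.roll(best.points, -start, axis=0), closed=True)
    return best.resample(CONTOUR_STEP_MM), best.closed


def find_up(block: CondylarBlock, plane_m: Plane) -> np.ndarray:
    """Highest point of the condylar contour on plane M (*up*).

    Ties at equal height are resolved toward the lateral side.
    """
    pts, _ = _section_contour(block, plane_m)
    h = signed_distances(pts, block.plane_c)
    ml = pts @ block.frame.u_ml
    order = np.lexsort((np.arange(len(pts)), -ml, -h))
    return pts[order[0]].copy()


def _mean_edge_length(block: CondylarBlock) -> float:
    return float(block.mesh.edges_unique_length.mean())


def _discrete_curvature(xy: np.ndarray, window_pts: int) -> np.ndarray:
    """Signed turning-rate estimate along an ordered 2D polyline.

    kappa_k = angle between the chords entering and leaving point k over the
    arc length spanned, using chord endpoints ``window_pts`` samples away.
    Positive sign = left turn in the (x, y) plane.
    """
    n = len(xy)
    w = max(window_pts, 1)
    kappa = np.zeros(n)
    for k in range(n):
        a, c = max(k - w, 0), min(k + w, n - 1)
        if a == k or c == k:
            continue
        v1 = xy[k] - xy[a]
        v2 = xy[c] - xy[k]
        l1, l2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if l1 < 1e-12 or l2 < 1e-12:
            continue
        cross = v1[0] * v2[1] - v1[1] * v2[0]
        dot = float(np.dot(v1, v2))
        kappa[k] = np.arctan2(cross, dot) / (0.5 * (l1 + l2))
    return kappa


def find_slope_point(block: CondylarBlock, section: Plane,
                     slope: str) -> np.ndarray:
    """"Lowest edge" point of the anterior or posterior slope on a section.

    The section contour is split at its apex (maximum height above plane C);
    the branch on the negative ``u_ap`` side of the apex is the posterior
    slope, the other the anterior slope. Walking from the apex down the
    requested branch, the returned point is the first local maximum of
    concave curvature (the head-neck inflection); if the branch shows no
    concave inflection above the cap-exclusion band, its lowest non-excluded
    point is returned with a warning.
    """
    if slope not in ("anterior", "posterior"):
        raise GeometryError(f"slope must be anterior|posterior, got {slope!r}")
    pts, closed = _section_contour(block, section)
    h = signed_distances(pts, block.plane_c)
    apex = int(np.argmax(h))
    n = len(pts)
    ap = (pts - pts[apex]) @ block.frame.u_ap

    if closed:
        fwd_idx = [(apex + k) % n for k in range(1, n)]
        bwd_idx = [(apex - k) % n for k in range(1, n)]
    else:
        fwd_idx = list(range(apex + 1, n))
        bwd_idx = list(range(apex - 1, -1, -1))

    def branch_side(idx_list):
        if not idx_list:
            return 0.0
        probe = idx_list[: max(3, len(idx_list) // 10)]
        return float(np.mean(ap[probe]))

    want_neg = slope == "posterior"
    sides = {tuple(fwd_idx): branch_side(fwd_idx),
             tuple(bwd_idx): branch_side(bwd_idx)}
    candidates = [list(k) for k, v in sides.items()
                  if k and ((v < 0) == want_neg)]
    if not candidates:
        # both branches start on the same side: pick by direction at depth
        def deep_side(idx_list):
            return float(np.mean(ap[idx_list])) if idx_list else 0.0
        pick = min((fwd_idx, bwd_idx), key=lambda b: deep_side(b)) if want_neg \
            else max((fwd_idx, bwd_idx), key=lambda b: deep_side(b))
        candidates = [pick]
    branch = max(candidates, key=len) if len(candidates) > 1 else candidates[0]

    # truncate the walk once the contour drops into the cap-exclusion band
    cut = next((k for k, j in enumerate(branch) if h[j] < CAP_EXCLUSION_MM),
               len(branch))
    branch = branch[:cut]
    if not branch:
        raise GeometryError(f"{slope} slope branch is empty above the "
                            f"cap-exclusion band")

    walk = [apex] + branch
    # 2D coordinates in the section plane: horizontal in-plane axis + height
    e_h = _unit(np.cross(section.normal, block.frame.u_si))
    xy = np.column_stack([pts[walk] @ e_h, h[walk]])
    window = max(int(round(3.0 * _mean_edge_length(block) / CONTOUR_STEP_MM)), 3)
    kappa = _discrete_curvature(xy, window)
    # convex sign from the apex region (the head is convex there)
    near_apex = kappa[1: 1 + max(window, 2)]
    ref = near_apex[np.abs(near_apex).argmax()] if len(near_apex) else 0.0
    convex_sign = np.sign(ref) if ref != 0 else 1.0
    concavity = -convex_sign * kappa

    pick = None
    m = len(walk)
    for k in range(1 + window, m - window):
        if concavity[k] <= 0:
            continue
        lo, hi = max(k - window, 0), min(k + window + 1, m)
        if concavity[k] >= concavity[lo:hi].max() - 1e-15:
            pick = k
            break
    if pick is None:
        log.warning("no concave inflection on %s slope; falling back to the "
                    "lowest non-excluded contour point", slope)
        pick = 1 + int(np.argmin(h[branch]))
    return pts[walk[pick]].copy()


def assemble_seven(block: CondylarBlock) -> SevenPointSet:
    """Run the full seven-point construction on a condylar block.

    The N1/N2 posterior-slope intersections are assigned to *pi*/*po* by
    proximity to *i* and *o* respectively, so the +-45-degree labels of the
    section planes never matter downstream.
    """
    i_pt, o_pt = find_extreme_points(block)
    plane_m, plane_n, plane_n1, plane_n2, _ = build_section_planes(
        i_pt, o_pt, block.plane_c)
    up = find_up(block, plane_m)
    a = find_slope_point(block, plane_n, "anterior")
    p = find_slope_point(block, plane_n, "posterior")
    q1 = find_slope_point(block, plane_n1, "posterior")
    q2 = find_slope_point(block, plane_n2, "posterior")
    if (np.linalg.norm(q1 - i_pt) + np.linalg.norm(q2 - o_pt)
            <= np.linalg.norm(q2 - i_pt) + np.linalg.norm(q1 - o_pt)):
        pi_pt, po_pt = q1, q2
    else:
        pi_pt, po_pt = q2, q1
    points = {"i": i_pt, "o": o_pt, "a": a, "p": p,
              "pi": pi_pt, "po": po_pt, "up": up}
    heights = {k: float(signed_distance(v, block.plane_c))
               for k, v in points.items()}
    return SevenPointSet(points=points, heights=heights)


def height_differences(s: SevenPointSet) -> HeightDifferences:
    return HeightDifferences(d_io=s.d_io, d_pipo=s.d_pipo)
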