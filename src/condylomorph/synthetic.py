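"""Synthetic condyles, remodeling fields and measurement-level cohorts.

No patient imaging is distributed with studies of this design, so every
stage of the pipeline is exercised on synthetic data with known ground
truth:

* **Condyle meshes** — a solid of revolution with elliptical cross-sections:
  an ellipsoidal head blended C1-continuously onto a hyperbolic neck whose
  waist (the concave head-neck inflection) sits at an analytically
  prescribed height above the cut plane, continued by a sub-notch stub
  below the plane. Cranial and cephalometric landmarks consistent with the
  mesh are emitted alongside, so the full landmark-driven pipeline runs.
* **Remodeling fields** — smooth, region-weighted displacement of the head
  surface along outward normals (apposition positive, resorption negative),
  emulating the posterolateral/lateral apposition seen after disc
  repositioning and posteromedial resorption under anterolateral
  displacement.
* **Measurement-level cohorts** — per-patient tables whose medians and IQRs
  are sized to the published scale of two-arm disc-displacement trials
  (summed bilateral T0 volumes ~2100-3400 mm^3, group volume-change medians
  ~30 vs ~280 mm^3, per-point height changes ~ -2 to +3.5 mm). Change
  distributions use a shifted (possibly reflected) log-logistic family so
  that median and mean differ, as in skewed clinical data. A ledger of all
  ground-truth draws is returned for parameter-recovery tests.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from scipy import integrate, optimize

from .block import CondylarFrame
from .geometry import CAP_EXCLUSION_MM, GeometryError, Plane, signed_distances

REGIONS = ("superior", "anterior", "posterior", "medial", "lateral",
           "posteromedial", "posterolateral")

#: world-frame layout shared by every generated patient (mm):
#: Frankfort plane is z = 0, osteotomy plane C is z = Z_CUT, condyles sit at
#: x = +/- CONDYLE_X. All anatomy is still *derived* from the landmarks by
#: the pipeline; these constants only place the synthetic skull.
Z_CUT = -26.0
CONDYLE_X = 47.0
CONDYLE_Y = 8.0


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass(frozen=True)
class CondyleParams:
    """Shape parameters of one synthetic condyle (mm, degrees).

    ``neck_length`` is the vertical gap between the head-neck inflection and
    the bottom of the ellipsoidal head. The special value 0 generates a
    head-only ellipsoid centered on the cut plane (no neck, no stub), the
    analytic half-ellipsoid limit used for volume validation.
    """

    head_ml: float = 8.0      # mediolateral head semi-axis
    head_ap: float = 4.8      # anteroposterior head semi-axis
    head_si: float = 4.8      # superoinferior head semi-axis
    neck_radius: float = 3.4  # waist radius of the neck hyperboloid
    neck_length: float = 1.5
    inflection_height: float = 5.0  # waist height above the cut plane
    stub_depth: float = 3.0   # sub-notch continuation below the cut plane
    head_tilt_deg: float = 0.0
    side: str = "right"
    subdivision: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise GeometryError(f"side must be left|right, got {self.side!r}")
        if self.subdivision < 1:
            raise GeometryError("subdivision must be >= 1")
        if self.neck_length == 0:
            return  # head-only limit: neck/stub parameters unused
        if not (min(self.head_ml, self.head_ap, self.head_si)
                > self.neck_radius > 0):
            raise GeometryError("need head semi-axes > neck radius > 0")
        if self.inflection_height <= CAP_EXCLUSION_MM:
            raise GeometryError("inflection height must exceed the "
                                f"cap-exclusion band ({CAP_EXCLUSION_MM} mm)")
        if self.neck_length < 0 or self.stub_depth <= 0:
            raise GeometryError("neck length must be >= 0, stub depth > 0")


@dataclass
class GeneratedCondyle:
    """A synthetic condyle in world coordinates with its ground truth."""

    mesh: trimesh.Trimesh
    landmarks: dict[str, np.ndarray]
    params: CondyleParams
    true_block_volume: float   # analytic volume above plane C (mm^3)
    inflection_height: float   # waist height above plane C (mm)
    apex_height: float         # head apex height above plane C (mm)
    mean_edge_length: float


# ---------------------------------------------------------------------------
# condyle profile
# ---------------------------------------------------------------------------

def _neck_join(p: CondyleParams) -> tuple[float, float, float, float]:
    """Solve the C1 join of the neck hyperbola onto the head ellipse.

    The neck profile is r(z) = A sqrt(1 + ((z - h*) / w)^2): its curvature
    is maximal at the waist z = h*, which is what the landmark search
    detects as the head-neck inflection. Returns (z_join, A, w, zc).
    Matching value and slope at a candidate join height gives closed forms
    w^2 = d r / r' - d^2 and A = r w / sqrt(w^2 + d^2) with d the height of
    the join above the waist; the join height is chosen so the waist radius
    A equals ``neck_radius`` when such a join exists.
    """
    a, c = p.head_ap, p.head_si
    h = p.inflection_height
    zc = h + p.neck_length + c

    def join_quantities(zj):
        u = (zj - zc) / c
        r = a * math.sqrt(max(1.0 - u * u, 1e-12))
        rp = a * (zc - zj) / (c * c * math.sqrt(max(1.0 - u * u, 1e-12)))
        d = zj - h
        w2 = d * r / rp - d * d
        if w2 <= 0 or d <= 0:
            return None
        w = math.sqrt(w2)
        return r * w / math.sqrt(w2 + d * d), w

    lo = max(zc - 0.97 * c, h + 0.05 * c)
    hi = zc - 0.05 * c
    grid = np.linspace(lo, hi, 200)
    best, best_err = None, np.inf
    prev = None
    for zj in grid:
        q = join_quantities(zj)
        if q is None:
            prev = None
            continue
        A, w = q
        err = A - p.neck_radius
        if prev is not None and prev[1] * err < 0:
            z_root = optimize.brentq(
                lambda z: join_quantities(z)[0] - p.neck_radius,
                prev[0], zj, xtol=1e-10)
            A, w = join_quantities(z_root)
            return z_root, A, w, zc
        if abs(err) < best_err:
            best, best_err = (zj, A, w), abs(err)
        prev = (zj, err)
    if best is None:
        raise GeometryError("no valid neck-head join for these parameters")
    zj, A, w = best
    return zj, A, w, zc


def _profile(p: CondyleParams):
    """Radius-vs-height profile r_ap(z) of the condyle in its local frame
    (cut plane z = 0, z superior). Returns (r(z) callable, z_join, zc, A, w)."""
    if p.neck_length == 0:
        zc = 0.0

        def r(z):
            u = z / p.head_si
            return p.head_ap * math.sqrt(max(1.0 - u * u, 0.0))
        return r, None, zc, None, None
    zj, A, w, zc = _neck_join(p)

    def r(z):
        if z >= zj:
            u = (z - zc) / p.head_si
            return p.head_ap * math.sqrt(max(1.0 - u * u, 0.0))
        return A * math.sqrt(1.0 + ((z - p.inflection_height) / w) ** 2)
    return r, zj, zc, A, w


def _analytic_block_volume(p: CondyleParams) -> float:
    """Volume of the region above the cut plane by 1D quadrature of the
    profile: V = pi (ml/ap) \\int r_ap(z)^2 dz."""
    r, zj, zc, _, _ = _profile(p)
    ratio = p.head_ml / p.head_ap
    z_top = zc + p.head_si
    if zj is None:
        lo = 0.0
        val, _ = integrate.quad(lambda z: r(z) ** 2, lo, z_top, limit=200)
    else:
        v1, _ = integrate.quad(lambda z: r(z) ** 2, 0.0, zj, limit=200)
        v2, _ = integrate.quad(lambda z: r(z) ** 2, zj, z_top, limit=200)
        val = v1 + v2
    return math.pi * ratio * val


def _revolve(p: CondyleParams) -> trimesh.Trimesh:
    """Build the watertight solid-of-revolution mesh in the local frame."""
    r, zj, zc, _, _ = _profile(p)
    s = p.subdivision
    ntheta = 16 * 2 ** (s - 1)
    ratio = p.head_ml / p.head_ap
    z_top = zc + p.head_si

    zs: list[float] = []
    if p.neck_length == 0:
        z_bot = -p.head_si
        phis = np.linspace(-np.pi / 2, np.pi / 2, 20 * 2 ** (s - 1) + 1)[1:-1]
        zs = list(zc + p.head_si * np.sin(phis))
    else:
        z_bot = -p.stub_depth
        n_neck = 10 * 2 ** (s - 1)
        zs.extend(np.linspace(z_bot, zj, n_neck, endpoint=False)[0:])
        phi_j = math.asin(max(min((zj - zc) / p.head_si, 1.0), -1.0))
        phis = np.linspace(phi_j, np.pi / 2, 12 * 2 ** (s - 1) + 1)[:-1]
        zs.extend(zc + p.head_si * np.sin(phis))

    theta = np.linspace(0, 2 * np.pi, ntheta, endpoint=False)
    rings = []
    for z in zs:
        rad = r(z)
        rings.append(np.column_stack([ratio * rad * np.cos(theta),
                                      rad * np.sin(theta),
                                      np.full(ntheta, z)]))
    verts = [np.array([[0.0, 0.0, z_bot]])] + rings + \
        [np.array([[0.0, 0.0, z_top]])]
    vertices = np.vstack(verts)
    n_rings = len(rings)
    faces = []
    # bottom fan (outward normal -z)
    first = 1
    for j in range(ntheta):
        faces.append((0, first + (j + 1) % ntheta, first + j))
    # side walls
    for k in range(n_rings - 1):
        a0 = 1 + k * ntheta
        b0 = 1 + (k + 1) * ntheta
        for j in range(ntheta):
            jn = (j + 1) % ntheta
            faces.append((a0 + j, a0 + jn, b0 + jn))
            faces.append((a0 + j, b0 + jn, b0 + j))
    # apex fan (outward normal +z)
    apex = 1 + n_rings * ntheta
    last = 1 + (n_rings - 1) * ntheta
    for j in range(ntheta):
        faces.append((apex, last + j, last + (j + 1) % ntheta))
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces),
                           process=False)
    if mesh.volume < 0:
        mesh.invert()
    if p.head_tilt_deg != 0.0 and p.neck_length > 0:
        h = p.inflection_height
        v = mesh.vertices.copy()
        t = _smoothstep((v[:, 2] - h) / max(zc - h, 1e-9))
        th = np.radians(p.head_tilt_deg) * t
        y, z = v[:, 1].copy(), v[:, 2] - h
        v[:, 1] = y * np.cos(th) - z * np.sin(th)
        v[:, 2] = y * np.sin(th) + z * np.cos(th) + h
        mesh = trimesh.Trimesh(vertices=v, faces=mesh.faces, process=False)
    return mesh


def _cranial_landmarks(anb_deg: float = 4.0, pn_mm: float = 3.0,
                       me_mm: float = 2.5) -> dict[str, np.ndarray]:
    """Consistent skull landmark set in the shared world frame.

    The Frankfort plane is exactly z = 0 (porions and orbitale lie on it);
    the facial midline is exactly x = 0; the A/N/B rays are constructed so
    the prescribed ANB angle, PN and ME distances are recovered exactly.
    """
    nasion = np.array([0.0, 68.0, -4.0])
    ray_a = np.array([0.0, 18.0, -36.0])
    th = np.radians(-anb_deg)
    ray_b = np.array([0.0,
                      ray_a[1] * np.cos(th) - ray_a[2] * np.sin(th),
                      ray_a[1] * np.sin(th) + ray_a[2] * np.cos(th)]) * 0.92
    lm = {
        "porion_l": np.array([-55.0, 0.0, 0.0]),
        "porion_r": np.array([55.0, 0.0, 0.0]),
        "orbitale": np.array([40.0, 62.0, 0.0]),
        "crista_galli": np.array([0.0, 48.0, 14.0]),
        "zf_l": np.array([-45.0, 40.0, 3.0]),
        "zf_r": np.array([45.0, 40.0, 3.0]),
        "nasion": nasion,
        "a_point": nasion + ray_a,
        "b_point": nasion + ray_b,
        "pogonion": nasion + np.array([0.0, pn_mm, 0.0]) + np.array([0.0, 0.0, -78.0]),
        "menton": np.array([me_mm, 70.0, -86.0]),
        "s_l": np.array([-(CONDYLE_X - 5.0), CONDYLE_Y + 6.0, Z_CUT]),
        "s_r": np.array([CONDYLE_X - 5.0, CONDYLE_Y + 6.0, Z_CUT]),
    }
    return lm


def generate_condyle(params: CondyleParams, anb_deg: float = 4.0,
                     pn_mm: float = 3.0, me_mm: float = 2.5
                     ) -> GeneratedCondyle:
    """Generate a synthetic condyle mesh plus a consistent landmark set.

    The mesh is placed in the shared world frame (cut plane z = Z_CUT,
    condyle at x = +/-CONDYLE_X); left-side condyles are the mirror image
    of right-side ones. Deterministic for fixed parameters.
    """
    local = _revolve(params)
    v = local.vertices.copy()
    f = local.faces.copy()
    if params.side == "left":
        v[:, 0] = -v[:, 0]
        f = f[:, ::-1]
    x0 = CONDYLE_X if params.side == "right" else -CONDYLE_X
    v = v + np.array([x0, CONDYLE_Y, Z_CUT])
    mesh = trimesh.Trimesh(vertices=v, faces=f, process=False)
    _, zj, zc, _, _ = _profile(params)
    return GeneratedCondyle(
        mesh=mesh,
        landmarks=_cranial_landmarks(anb_deg, pn_mm, me_mm),
        params=params,
        true_block_volume=_analytic_block_volume(params),
        inflection_height=params.inflection_height
        if params.neck_length > 0 else float("nan"),
        apex_height=zc + params.head_si,
        mean_edge_length=float(mesh.edges_unique_length.mean()),
    )


# ---------------------------------------------------------------------------
# remodeling fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RemodelingField:
    """Region-weighted surface remodeling: normal apposition plus growth.

    ``amplitudes`` displace vertices along their outward normals
    (apposition +, resorption -), changing volume to first order by the
    surface integral of the amplitude. ``growth`` displaces vertices along
    the superior axis, emulating condylar vertical growth (neck elongation
    and superior apposition): it is what raises landmark heights, since
    outward normals near the head-neck waist are nearly horizontal and
    normal apposition there cannot lift the detected inflection. Regions
    are 45-degree spherical-direction sectors around the head centroid
    (matching the 45-degree N1/N2 landmark construction); weights are
    blended with a Gaussian of angular scale ``smoothness_mm`` divided by
    the head radius, and taper to zero toward the cut plane so the cap
    never moves.
    """

    amplitudes: dict = field(default_factory=dict)
    growth: dict = field(default_factory=dict)
    smoothness_mm: float = 4.0
    noise_sd: float = 0.0

    def __post_init__(self):
        unknown = (set(self.amplitudes) | set(self.growth)) - set(REGIONS)
        if unknown:
            raise GeometryError(f"unknown remodeling regions: {sorted(unknown)}")
        if any(abs(a) > 5.0 for a in
               list(self.amplitudes.values()) + list(self.growth.values())):
            raise GeometryError("remodeling amplitudes limited to |a| <= 5 mm")
        if self.smoothness_mm <= 0:
            raise GeometryError("smoothness must be positive")


def _region_directions(frame: CondylarFrame) -> dict[str, np.ndarray]:
    ml, ap, si = frame.u_ml, frame.u_ap, frame.u_si
    d = {
        "superior": si,
        "anterior": ap,
        "posterior": -ap,
        "medial": -ml,
        "lateral": ml,
        "posteromedial": (-ap - ml) / np.sqrt(2.0),
        "posterolateral": (-ap + ml) / np.sqrt(2.0),
    }
    return d


def _region_weights(mesh: trimesh.Trimesh, frame: CondylarFrame,
                    smoothness_mm: float) -> tuple[dict, np.ndarray]:
    """Per-vertex angular weight of each region plus the height taper."""
    h = signed_distances(mesh.vertices, frame.plane_c)
    hmax = float(h.max())
    head = h >= 0.6 * hmax
    center = mesh.vertices[head].mean(axis=0)
    rel = mesh.vertices - center
    norms = np.linalg.norm(rel, axis=1)
    norms[norms < 1e-12] = 1.0
    dirs = rel / norms[:, None]
    r_head = float(np.linalg.norm(mesh.vertices[head] - center, axis=1).mean())
    sigma = smoothness_mm / max(r_head, 1e-9)
    weights = {}
    for region, d in _region_directions(frame).items():
        theta = np.arccos(np.clip(dirs @ d, -1.0, 1.0))
        weights[region] = np.exp(-0.5 * (theta / sigma) ** 2)
    taper = _smoothstep((h / hmax - 0.05) / 0.20)
    return weights, taper


def remodeling_displacement(mesh: trimesh.Trimesh, fld: RemodelingField,
                            frame: CondylarFrame,
                            rng: np.random.Generator | None = None
                            ) -> np.ndarray:
    """(n_vertices, 3) displacement vectors of the field on this mesh."""
    weights, taper = _region_weights(mesh, frame, fld.smoothness_mm)
    amp = np.zeros(len(mesh.vertices))
    for region, a in fld.amplitudes.items():
        if a != 0:
            amp = amp + a * weights[region]
    grow = np.zeros(len(mesh.vertices))
    for region, g in fld.growth.items():
        if g != 0:
            grow = grow + g * weights[region]
    if fld.noise_sd > 0 and rng is not None:
        amp = amp + rng.normal(0.0, fld.noise_sd, size=len(amp))
    return ((amp * taper)[:, None] * mesh.vertex_normals
            + (grow * taper)[:, None] * frame.u_si)


def apply_remodeling(mesh: trimesh.Trimesh, fld: RemodelingField,
                     frame: CondylarFrame,
                     seed: int | None = None) -> trimesh.Trimesh:
    """Displace the head surface under a remodeling field.

    Topology is unchanged, so watertightness is preserved; a face whose
    normal flips is treated as self-intersection and raises with a
    suggestion to reduce the amplitude.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    disp = remodeling_displacement(mesh, fld, frame, rng)
    out = trimesh.Trimesh(vertices=mesh.vertices + disp,
                          faces=mesh.faces.copy(), process=False)
    tri0 = mesh.triangles_cross
    tri1 = out.triangles_cross
    dots = np.einsum("ij,ij->i", tri0, tri1)
    if (dots < 0).any():
        raise GeometryError("remodeling field flips surface triangles; "
                            "reduce the amplitude or increase smoothness")
    return out


def first_order_volume_change(mesh: trimesh.Trimesh,
                              displacement: np.ndarray) -> float:
    """First-order (thin-shell) volume change of a surface displacement:
    the integral of the normal component over the surface."""
    va = np.zeros(len(mesh.vertices))
    np.add.at(va, mesh.faces.ravel(),
              np.repeat(mesh.area_faces / 3.0, 3))
    d = np.asarray(displacement)
    if d.ndim == 1:
        normal_comp = d
    else:
        normal_comp = np.einsum("ij,ij->i", d, mesh.vertex_normals)
    return float(np.dot(va, normal_comp))


# ---------------------------------------------------------------------------
# measurement-level cohorts
# ---------------------------------------------------------------------------

class QuartileSampler:
    """Sampler matched to a (median, q25, q75) triple.

    Fits a shifted log-logistic (reflected when left-skewed); falls back to
    a normal with sd = IQR/1.349 when the triple is (near) symmetric. The
    fitted distribution reproduces the three quartiles exactly in the
    log-logistic branch.
    """

    def __init__(self, median: float, q25: float, q75: float):
        if not (q25 <= median <= q75) or q75 <= q25:
            raise ValueError("need q25 <= median <= q75 with q75 > q25")
        self.median, self.q25, self.q75 = median, q25, q75
        iqr = q75 - q25
        skew = (q75 - median) - (median - q25)
        self.reflect = skew < 0
        m, lo, hi = ((-median, -q75, -q25) if self.reflect
                     else (median, q25, q75))
        if abs(skew) < 0.05 * iqr:
            self.kind = "normal"
            self.loc, self.scale = median, iqr / 1.349
            return
        denom = lo + hi - 2 * m
        loc = (lo * hi - m * m) / denom
        alpha = m - loc
        if alpha <= 0 or hi <= loc:
            self.kind = "normal"
            self.loc, self.scale = median, iqr / 1.349
            return
        self.kind = "fisk"
        self.loc, self.alpha = loc, alpha
        self.beta = math.log(3.0) / math.log((hi - loc) / alpha)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "normal":
            return rng.normal(self.loc, self.scale, size)
        u = rng.uniform(1e-4, 1 - 1e-4, size)
        x = self.loc + self.alpha * (u / (1 - u)) ** (1.0 / self.beta)
        return -x if self.reflect else x


#: published-scale defaults for the measurement-level cohort generator:
#: (median, q25, q75) per group for the summed per-patient quantities.
DEFAULT_CHANGE_TRIPLES = {
    "volume": {"DD": (29.5, -138.4, 93.8), "DR": (279.6, 149.5, 434.1)},
    "h_i": {"DD": (-0.040, -1.085, 1.683), "DR": (1.020, -0.127, 2.043)},
    "h_o": {"DD": (-1.000, -1.955, 0.720), "DR": (0.425, -0.997, 1.793)},
    "h_p": {"DD": (0.560, -0.102, 1.440), "DR": (1.230, -0.272, 2.655)},
    "h_pi": {"DD": (0.705, -0.235, 1.830), "DR": (1.595, 0.237, 3.405)},
    "h_po": {"DD": (0.370, -0.975, 0.780), "DR": (1.330, 0.670, 2.640)},
    "h_up": {"DD": (0.175, -0.437, 0.657), "DR": (0.940, -0.222, 2.090)},
    "h_a": {"DD": (0.145, -0.737, 0.730), "DR": (0.870, -0.370, 2.920)},
}
DEFAULT_CEPHALO_TRIPLES = {
    "me": {"DD": (0.975, 0.328, 1.920), "DR": (-0.515, -1.415, 0.108)},
    "anb": {"DD": (0.015, -1.078, 1.005), "DR": (-0.400, -1.883, 0.153)},
    "pn": {"DD": (3.945, -1.233, 5.580), "DR": (-0.145, -4.760, 3.300)},
}
DEFAULT_V_T0_TRIPLE = (2600.0, 2150.0, 3240.0)
#: per-joint baseline crest-tilt (mean, sd) by disc-displacement direction
DEFAULT_DIRECTION_EFFECTS = {
    "anteromedial": {"d_io": (2.753, 1.713), "d_pipo": (-0.151, 1.197)},
    "anterolateral": {"d_io": (1.719, 2.589), "d_pipo": (-1.068, 1.333)},
    "pure_anterior": {"d_io": (2.2, 2.0), "d_pipo": (-0.4, 1.2)},
    "none": {"d_io": (2.2, 1.5), "d_pipo": (-0.2, 1.0)},
}
#: summed baseline heights per point: (mean, sd)
DEFAULT_T0_HEIGHTS = {
    "h_i": (17.0, 2.0), "h_o": (15.0, 2.0), "h_a": (12.0, 2.0),
    "h_p": (12.0, 2.0), "h_pi": (13.0, 2.0), "h_po": (13.0, 2.0),
    "h_up": (22.0, 2.5),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a measurement-level synthetic cohort (study conditions)."""

    n_per_group: int = 30
    female_frac: float = 0.9
    young_frac: float = 0.65
    unilateral_frac: float = 34 / 60
    direction_mix: tuple = (("anteromedial", 23 / 86),
                            ("anterolateral", 18 / 86),
                            ("pure_anterior", 45 / 86))
    v_t0_triple: tuple = DEFAULT_V_T0_TRIPLE
    change_triples: dict = field(default_factory=lambda: DEFAULT_CHANGE_TRIPLES)
    cephalo_triples: dict = field(default_factory=lambda: DEFAULT_CEPHALO_TRIPLES)
    rater_noise_sd: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


def simulate_cohort(spec: CohortSpec, seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a measurement-level cohort table plus its ground-truth ledger.

    Returns ``(table, ledger)``: ``table`` has one row per condyle per
    timepoint in the measurement schema; ``ledger`` has one row per patient
    with every summed draw the table was assembled from, so recovery tests
    can compare pipeline aggregation against the generator's bookkeeping.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    v_t0_sampler = QuartileSampler(*spec.v_t0_triple)
    change_samplers = {k: {g: QuartileSampler(*t) for g, t in d.items()}
                       for k, d in spec.change_triples.items()}
    ceph_samplers = {k: {g: QuartileSampler(*t) for g, t in d.items()}
                     for k, d in spec.cephalo_triples.items()}
    dir_names = [d for d, _ in spec.direction_mix]
    dir_probs = np.array([p for _, p in spec.direction_mix], dtype=float)
    dir_probs = dir_probs / dir_probs.sum()

    rows, ledger = [], []
    pid = 0
    for group in ("DD", "DR"):
        for _ in range(spec.n_per_group):
            pid += 1
            gender = "female" if rng.uniform() < spec.female_frac else "male"
            age_band = "10-18" if rng.uniform() < spec.young_frac else "19-25"
            unilat = rng.uniform() < spec.unilateral_frac
            diagnosis = "unilateral" if unilat else "bilateral"
            affected_side = rng.choice(["left", "right"]) if unilat else None

            v_t0 = float(v_t0_sampler.sample(rng, 1)[0])
            v_change = float(change_samplers["volume"][group].sample(rng, 1)[0])
            h_t0 = {k: float(rng.normal(*DEFAULT_T0_HEIGHTS[k]))
                    for k in DEFAULT_T0_HEIGHTS}
            h_change = {k: float(change_samplers[k][group].sample(rng, 1)[0])
                        for k in DEFAULT_T0_HEIGHTS}
            ceph_t0 = {"anb": float(rng.normal(3.0, 2.0)),
                       "pn": abs(float(rng.normal(3.0, 2.0))),
                       "me": abs(float(rng.normal(2.0, 1.5)))}
            ceph_change = {k: float(ceph_samplers[k][group].sample(rng, 1)[0])
                           for k in ceph_samplers}

            frac = float(np.clip(rng.normal(0.5, 0.03), 0.4, 0.6))
            led = {"patient_id": f"P{pid:03d}", "group": group,
                   "gender": gender, "age_band": age_band,
                   "diagnosis": diagnosis, "v_t0": v_t0,
                   "volume_change": v_change}
            for k in DEFAULT_T0_HEIGHTS:
                led[f"{k}_t0"] = h_t0[k]
                led[f"{k}_change"] = h_change[k]
            for k in ceph_change:
                led[f"{k}_change"] = ceph_change[k]
            ledger.append(led)

            for side in ("left", "right"):
                f = frac if side == "left" else 1.0 - frac
                if unilat:
                    direction = (str(rng.choice(dir_names, p=dir_probs))
                                 if side == affected_side else "none")
                else:
                    direction = str(rng.choice(dir_names, p=dir_probs))
                eff = DEFAULT_DIRECTION_EFFECTS[direction]
                d_io = float(rng.normal(*eff["d_io"]))
                d_pipo = float(rng.normal(*eff["d_pipo"]))
                for tp in ("T0", "T1"):
                    dv = v_change * f if tp == "T1" else 0.0
                    row = {
                        "patient_id": f"P{pid:03d}", "group": group,
                        "gender": gender, "age_band": age_band,
                        "diagnosis": diagnosis, "side": side,
                        "timepoint": tp,
                        "volume": v_t0 * f + dv,
                        "disc_direction": direction,
                    }
                    for k in DEFAULT_T0_HEIGHTS:
                        base = h_t0[k] * f
                        delta = h_change[k] * f if tp == "T1" else 0.0
                        row[k] = base + delta
                    # per-joint crest-tilt differences consistent with i/o
                    half_io = d_io / 2.0
                    half_pipo = d_pipo / 2.0
                    row["h_i"] = row["h_i"] + half_io / 2
                    row["h_o"] = row["h_o"] - half_io / 2
                    row["h_pi"] = row["h_pi"] + half_pipo / 2
                    row["h_po"] = row["h_po"] - half_pipo / 2
                    row["d_io"] = row["h_i"] - row["h_o"]
                    row["d_pipo"] = row["h_pi"] - row["h_po"]
                    for k in ceph_t0:
                        row[k] = ceph_t0[k] + (ceph_change[k] if tp == "T1"
                                               else 0.0)
                    rows.append(row)
    return pd.DataFrame(rows), pd.DataFrame(ledger)


def simulate_raters(values, noise_sd: float, seed: int = 0,
                    n_raters: int = 2) -> np.ndarray:
    """Independent-rater measurements: truth plus iid Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    x = np.asarray(values, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    return x[:, None] + rng.normal(0.0, noise_sd, size=(len(x), n_raters))


# ---------------------------------------------------------------------------
# mesh-level cohorts
# ---------------------------------------------------------------------------

#: remodeling-field draws (mean, sd) per region for the mesh-level cohort:
#: the repositioned group gains bone posterolaterally/laterally/superiorly
#: (normal apposition driving volume, vertical growth driving heights);
#: the displaced group changes little.
MESH_COHORT_FIELDS = {
    "DR": {"amplitudes": {"posterior": (0.25, 0.08), "lateral": (0.25, 0.08),
                          "posterolateral": (0.25, 0.08)},
           "growth": {"posterolateral": (0.65, 0.2), "lateral": (0.45, 0.15),
                      "superior": (0.45, 0.15)}},
    "DD": {"amplitudes": {"posterior": (0.03, 0.05), "lateral": (0.03, 0.05),
                          "posterolateral": (0.03, 0.05)},
           "growth": {"posterolateral": (0.05, 0.1), "lateral": (0.05, 0.1),
                      "superior": (0.05, 0.1)}},
}


@dataclass
class MeshPatient:
    patient_id: str
    group: str
    sides: dict  # side -> dict(t0=GeneratedCondyle, t1_mesh=Trimesh, field=RemodelingField)


def simulate_mesh_cohort(n_per_group: int, seed: int = 0, subdivision: int = 2,
                         fields: dict = MESH_COHORT_FIELDS
                         ) -> tuple[list[MeshPatient], pd.DataFrame]:
    """Paired T0/T1 meshes for a small cohort, with a ground-truth ledger.

    Each patient gets two condyles with jittered head proportions; the T1
    mesh is the T0 mesh under a group-specific remodeling field. The ledger
    records the analytic T0 block volume per side and the drawn amplitudes.
    """
    from .block import build_cut_plane, build_frame
    from .geometry import fit_frankfort_plane

    rng = np.random.default_rng(seed)
    patients, led = [], []
    pid = 0
    for group in ("DD", "DR"):
        for _ in range(n_per_group):
            pid += 1
            sides = {}
            for side in ("left", "right"):
                jit = rng.normal(1.0, 0.04, size=3)
                params = CondyleParams(
                    head_ml=8.0 * float(jit[0]), head_ap=4.8 * float(jit[1]),
                    head_si=4.8 * float(jit[2]),
                    side=side, subdivision=subdivision,
                    seed=int(rng.integers(0, 2 ** 31 - 1)))
                gen = generate_condyle(params)
                lm = gen.landmarks
                fh = fit_frankfort_plane(lm["porion_l"], lm["porion_r"],
                                         lm["orbitale"], lm["crista_galli"])
                plane_c = build_cut_plane(fh, lm[f"s_{side[0]}"],
                                          lm["crista_galli"])
                frame = build_frame(plane_c, lm["porion_l"], lm["porion_r"],
                                    lm["orbitale"], side)
                amps = {region: float(rng.normal(mu, sd))
                        for region, (mu, sd)
                        in fields[group]["amplitudes"].items()}
                grow = {region: float(rng.normal(mu, sd))
                        for region, (mu, sd)
                        in fields[group]["growth"].items()}
                fld = RemodelingField(amplitudes=amps, growth=grow)
                t1 = apply_remodeling(gen.mesh, fld, frame)
                sides[side] = {"t0": gen, "t1_mesh": t1, "field": fld,
                               "frame": frame}
                led.append({"patient_id": f"M{pid:03d}", "group": group,
                            "side": side,
                            "true_v_t0": gen.true_block_volume,
                            **{f"amp_{r}": a for r, a in amps.items()},
                            **{f"grow_{r}": g for r, g in grow.items()}})
            patients.append(MeshPatient(patient_id=f"M{pid:03d}", group=group,
                                        sides=sides))
    return patients, pd.DataFrame(led)
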