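"""Cephalometric deformity and asymmetry indices: ANB, PN, ME.

ANB is the sagittal angle at nasion between the rays to A point
(subspinale) and B point (supramentale); PN is the distance from pogonion
to the vertical line through nasion perpendicular to the Frankfort plane;
ME is the distance from menton to the facial midline — the plane through
the crista galli perpendicular to the line joining the left and right
zygomatico-frontal / lateral-orbital intersection points.

ANB is computed after projecting A, nasion and B onto the midsagittal
(facial midline) plane, which reproduces the standard lateral-cephalogram
convention when the inputs are 3D landmarks. ME and PN are reported
unsigned by default (the deviation direction is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    GeometryError,
    Plane,
    TOL_EXACT,
    _as_point,
    _unit,
    project_to_plane,
    signed_distance,
)


@dataclass
class CephaloLandmarks:
    nasion: np.ndarray
    a_point: np.ndarray
    b_point: np.ndarray
    pogonion: np.ndarray
    menton: np.ndarray
    crista_galli: np.ndarray
    zf_left: np.ndarray
    zf_right: np.ndarray
    fh: Plane

    def __post_init__(self):
        for name in ("nasion", "a_point", "b_point", "pogonion", "menton",
                     "crista_galli", "zf_left", "zf_right"):
            setattr(self, name, _as_point(getattr(self, name)))
        if np.linalg.norm(self.zf_right - self.zf_left) < TOL_EXACT:
            raise GeometryError("zygomatico-frontal points coincide")

    @classmethod
    def from_dict(cls, lm: dict, fh: Plane) -> "CephaloLandmarks":
        return cls(nasion=lm["nasion"], a_point=lm["a_point"],
                   b_point=lm["b_point"], pogonion=lm["pogonion"],
                   menton=lm["menton"], crista_galli=lm["crista_galli"],
                   zf_left=lm["zf_l"], zf_right=lm["zf_r"], fh=fh)


@dataclass(frozen=True)
class CephaloIndices:
    anb: float  # degrees, signed (+ = A anterior to B)
    pn: float   # mm
    me: float   # mm


def _in_fh(v: np.ndarray, fh: Plane) -> np.ndarray:
    return v - np.dot(v, fh.normal) * fh.normal


def facial_midline(lm: CephaloLandmarks) -> Plane:
    """Midsagittal plane: through crista galli, normal along the in-FH
    component of the inter-zygomatico-frontal axis."""
    w = _in_fh(lm.zf_right - lm.zf_left, lm.fh)
    if np.linalg.norm(w) < 1e-9 * np.linalg.norm(lm.zf_right - lm.zf_left):
        raise GeometryError("zygomatico-frontal axis parallel to FH normal")
    return Plane(lm.crista_galli, _unit(w))


def compute_me(lm: CephaloLandmarks, signed: bool = False) -> float:
    """Distance from menton to the facial midline (mm)."""
    d = signed_distance(lm.menton, facial_midline(lm))
    return float(d) if signed else abs(float(d))


def compute_pn(lm: CephaloLandmarks, signed: bool = False) -> float:
    """Distance from pogonion to the FH-perpendicular line through nasion (mm).

    With ``signed=True`` the distance is signed by the anterior direction
    (positive when pogonion lies anterior to the nasion vertical).
    """
    v = lm.pogonion - lm.nasion
    perp = v - np.dot(v, lm.fh.normal) * lm.fh.normal
    d = float(np.linalg.norm(perp))
    if not signed:
        return d
    return d * np.sign(np.dot(perp, _anterior_direction(lm))) if d > 0 else 0.0


def _anterior_direction(lm: CephaloLandmarks) -> np.ndarray:
    """Anterior unit direction: in-FH, in-midsagittal component of
    crista galli -> nasion (nasion is the anterior of the two)."""
    mid = facial_midline(lm)
    v = _in_fh(lm.nasion - lm.crista_galli, lm.fh)
    v = v - np.dot(v, mid.normal) * mid.normal
    if np.linalg.norm(v) < TOL_EXACT:
        raise GeometryError("cannot orient the anterior direction: nasion and "
                            "crista galli coincide in projection")
    return _unit(v)


def compute_anb(lm: CephaloLandmarks) -> float:
    """ANB angle (degrees), signed positive when A is anterior to B.

    A, nasion and B are first projected onto the facial midline plane, then
    the angle at nasion between the two projected rays is measured.
    """
    mid = facial_midline(lm)
    a = project_to_plane(lm.a_point, mid)
    n = project_to_plane(lm.nasion, mid)
    b = project_to_plane(lm.b_point, mid)
    ra, rb = a - n, b - n
    if np.linalg.norm(ra) < TOL_EXACT or np.linalg.norm(rb) < TOL_EXACT:
        raise GeometryError("A or B point coincides with nasion after "
                            "midsagittal projection")
    ra, rb = _unit(ra), _unit(rb)
    ang = np.degrees(np.arctan2(np.linalg.norm(np.cross(ra, rb)),
                                float(np.dot(ra, rb))))
    sign = np.sign(np.dot(ra - rb, _anterior_direction(lm)))
    return float(ang * (sign if sign != 0 else 1.0))


def compute_indices(lm: CephaloLandmarks, signed: bool = False) -> CephaloIndices:
    return CephaloIndices(anb=compute_anb(lm),
                          pn=compute_pn(lm, signed=signed),
                          me=compute_me(lm, signed=signed))
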