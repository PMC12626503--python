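"""End-to-end orchestration: measure condyles, aggregate, analyze.

``measure_condyle`` runs the full geometric protocol on one condyle
(Frankfort fit from the landmark file, osteotomy plane C through *s*,
anatomical frame, block cut, volume, seven landmark heights);
``measure_patient`` assembles per-condyle, per-timepoint measurement rows;
``run_full_analysis`` produces the cohort result tables: group quartile
summaries and rank tests for summed volume and heights, the unilateral
per-joint comparison, the dummy-coded linear model, cephalometric change
comparisons, the baseline directional-resorption contrast, and the
demographic / displacement-direction proportions.

Numbers in emitted tables are stored at full precision; rounding to the
customary display precision (volumes one decimal, heights three) is left
to the serialization layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .block import build_cut_plane, build_frame, cut_block
from .cephalo import CephaloLandmarks, compute_indices
from .geometry import (
    GeometryError,
    fit_frankfort_plane,
    load_landmarks,
    load_mesh,
    log,
    require_landmarks,
)
from .landmarks import assemble_seven
from .stats import (
    HEIGHT_COLS,
    StatsError,
    directional_displacement_proportion,
    directional_resorption_analysis,
    mann_whitney,
    ols_dummy_regression,
    quartiles,
    sum_bilateral,
)

#: landmark names required to run the geometric protocol on one side
GEOMETRY_LANDMARKS = ("porion_l", "porion_r", "orbitale", "crista_galli")
CEPHALO_LANDMARKS = ("nasion", "a_point", "b_point", "pogonion", "menton",
                     "crista_galli", "zf_l", "zf_r")


@dataclass
class RunConfig:
    mwu_mode: str = "auto"
    t_variant: str = "pooled"
    signed_indices: bool = False
    seed: int = 0


def measure_condyle(mesh, landmarks: dict, side: str) -> dict:
    """Volume and seven-point heights for one condyle at one timepoint.

    ``landmarks`` must contain the cranial set plus the sigmoid-notch point
    ``s_l``/``s_r`` for the requested side; ``crista_galli`` serves as the
    superior reference orienting the Frankfort and osteotomy planes.
    """
    s_key = f"s_{side[0]}"
    require_landmarks(landmarks, GEOMETRY_LANDMARKS + (s_key,))
    fh = fit_frankfort_plane(landmarks["porion_l"], landmarks["porion_r"],
                             landmarks["orbitale"], landmarks["crista_galli"])
    plane_c = build_cut_plane(fh, landmarks[s_key], landmarks["crista_galli"])
    frame = build_frame(plane_c, landmarks["porion_l"], landmarks["porion_r"],
                        landmarks["orbitale"], side)
    block = cut_block(mesh, plane_c, frame)
    seven = assemble_seven(block)
    log.debug("measured side=%s: volume=%.3f heights=%s", side, block.volume,
              {k: round(v, 3) for k, v in seven.heights.items()})
    out = {"volume": block.volume, "cap_area": block.cap_area,
           "n_components_above": block.n_components_above,
           "d_io": seven.d_io, "d_pipo": seven.d_pipo}
    for name, h in seven.heights.items():
        out[f"h_{name}"] = h
    out["points"] = {k: v.tolist() for k, v in seven.points.items()}
    return out


def measure_cephalo(landmarks: dict, signed: bool = False) -> dict:
    require_landmarks(landmarks, CEPHALO_LANDMARKS + ("porion_l", "porion_r",
                                                      "orbitale"))
    fh = fit_frankfort_plane(landmarks["porion_l"], landmarks["porion_r"],
                             landmarks["orbitale"], landmarks["crista_galli"])
    lm = CephaloLandmarks.from_dict(landmarks, fh)
    idx = compute_indices(lm, signed=signed)
    return {"anb": idx.anb, "pn": idx.pn, "me": idx.me}


def measure_patient(meshes: dict, landmarks: dict, metadata: dict,
                    config: RunConfig | None = None) -> pd.DataFrame:
    """Measurement rows for one patient.

    ``meshes`` maps (timepoint, side) to a mesh (or a path); ``landmarks``
    maps timepoint to a landmark dict (or a path). ``metadata`` carries
    patient_id, group, gender, age_band, diagnosis and optional per-side
    disc_direction labels. Errors are re-raised with patient/side/timepoint
    context.
    """
    config = config or RunConfig()
    rows = []
    for (tp, side), mesh in sorted(meshes.items()):
        lm = landmarks[tp] if tp in landmarks else landmarks
        if isinstance(lm, (str, bytes)) or hasattr(lm, "__fspath__"):
            lm = load_landmarks(lm)
        if isinstance(mesh, (str, bytes)) or hasattr(mesh, "__fspath__"):
            mesh = load_mesh(mesh)
        try:
            meas = measure_condyle(mesh, lm, side)
        except (GeometryError, KeyError) as e:
            raise GeometryError(
                f"patient {metadata.get('patient_id')!r} side {side} "
                f"timepoint {tp}: {e}") from e
        row = {"patient_id": metadata.get("patient_id"),
               "group": metadata.get("group"),
               "gender": metadata.get("gender"),
               "age_band": metadata.get("age_band"),
               "diagnosis": metadata.get("diagnosis"),
               "side": side, "timepoint": tp,
               "disc_direction": metadata.get("disc_direction", {}).get(
                   side, "none") if isinstance(
                       metadata.get("disc_direction"), dict)
               else metadata.get("disc_direction", "none")}
        row.update({k: v for k, v in meas.items() if k != "points"})
        try:
            row.update(measure_cephalo(lm, signed=config.signed_indices))
        except GeometryError:
            pass  # cephalometric landmark set is optional
        rows.append(row)
    return pd.DataFrame(rows)


def _summary_row(measure: str, group: str, values) -> dict:
    s = quartiles(values)
    return {"measure": measure, "group": group, "n": s.n, "median": s.median,
            "q25": s.q25, "q75": s.q75, "mean": s.mean, "sd": s.sd}


def _two_group(per_patient: pd.DataFrame, col: str, label: str,
               mode: str) -> tuple[list[dict], dict]:
    rows, groups = [], {}
    for g in ("DD", "DR"):
        vals = per_patient.loc[per_patient.group == g, col].to_numpy()
        groups[g] = vals
        rows.append(_summary_row(label, g, vals))
    res = mann_whitney(groups["DD"], groups["DR"], mode=mode)
    return rows, {"measure": label, "statistic": res.statistic,
                  "p_value": res.p_value, "method": res.method}


def run_full_analysis(table: pd.DataFrame,
                      config: RunConfig | None = None) -> dict:
    """Full cohort analysis of a per-condyle, per-timepoint table.

    Returns a dict of DataFrames keyed ``summed_volume``, ``unilateral``,
    ``regression``, ``cephalo``, ``heights``, ``directional``,
    ``proportions`` (plus ``tests`` rows inside each comparison table).
    """
    config = config or RunConfig()
    per_patient = sum_bilateral(table)

    out: dict = {}
    # summed volume at T0 and its change (primary outcome)
    srows, tests = [], []
    r, t = _two_group(per_patient, "v_t0", "V_T0", config.mwu_mode)
    srows += r
    tests.append(t)
    r, t = _two_group(per_patient, "volume_change", "V_T1-T0", config.mwu_mode)
    srows += r
    tests.append(t)
    out["summed_volume"] = pd.DataFrame(srows)
    out["summed_volume_tests"] = pd.DataFrame(tests)

    # per-joint analysis of unilateral patients: affected vs normal joints
    uni = table[(table.diagnosis == "unilateral")]
    urows, utests = [], []
    if len(uni):
        piv = uni.pivot_table(index=["patient_id", "group", "side",
                                     "disc_direction"],
                              columns="timepoint", values="volume",
                              aggfunc="first").reset_index()
        piv["v_change"] = piv["T1"] - piv["T0"]
        piv["joint"] = np.where(piv.disc_direction.eq("none"), "normal",
                                "ADDwoR")
        for joint in ("normal", "ADDwoR"):
            sub = piv[piv.joint == joint]
            gvals = {}
            for g in ("DD", "DR"):
                vals = sub.loc[sub.group == g, "v_change"].to_numpy()
                gvals[g] = vals
                if len(vals):
                    urows.append(_summary_row(f"{joint} joint V_T1-T0", g,
                                              vals))
            if len(gvals["DD"]) and len(gvals["DR"]):
                res = mann_whitney(gvals["DD"], gvals["DR"],
                                   mode=config.mwu_mode)
                utests.append({"measure": f"{joint} joint V_T1-T0",
                               "statistic": res.statistic,
                               "p_value": res.p_value, "method": res.method})
    out["unilateral"] = pd.DataFrame(urows)
    out["unilateral_tests"] = pd.DataFrame(utests)

    # dummy-coded general linear model on summed volume change
    try:
        reg = ols_dummy_regression(per_patient, response="volume_change")
        out["regression"] = pd.DataFrame([dataclasses.asdict(r) for r in reg])
    except StatsError as e:
        log.warning("regression skipped: %s", e)
        out["regression"] = pd.DataFrame()

    # cephalometric index changes
    crow, ctest = [], []
    for ceph in ("me", "anb", "pn"):
        col = f"{ceph}_change"
        if col not in per_patient.columns:
            continue
        r, t = _two_group(per_patient, col, f"{ceph.upper()}_T1-T0",
                          config.mwu_mode)
        crow += r
        ctest.append(t)
    out["cephalo"] = pd.DataFrame(crow)
    out["cephalo_tests"] = pd.DataFrame(ctest)

    # seven-point summed height changes
    hrow, htest = [], []
    for hc in HEIGHT_COLS:
        r, t = _two_group(per_patient, f"{hc}_change",
                          f"D_T1-T0-{hc[2:]}", config.mwu_mode)
        hrow += r
        htest.append(t)
    out["heights"] = pd.DataFrame(hrow)
    out["heights_tests"] = pd.DataFrame(htest)

    # baseline directional-resorption contrast
    try:
        d = directional_resorption_analysis(table, variant=config.t_variant)
        drows = []
        for direction, g in d["groups"].items():
            for meas in ("d_io", "d_pipo"):
                s = g[meas]
                drows.append({"disc_position": direction, "measure": meas,
                              "n": g["n"], "mean": s.mean, "sd": s.sd,
                              "t": d["tests"][meas].statistic,
                              "p_value": d["tests"][meas].p_value})
        out["directional"] = pd.DataFrame(drows)
    except StatsError as e:
        log.warning("directional analysis skipped: %s", e)
        out["directional"] = pd.DataFrame()

    # demographics and displacement-direction proportions
    pats = table.drop_duplicates("patient_id")
    n_pat = len(pats)
    t0 = table[table.timepoint == "T0"]
    n_am = int(t0.disc_direction.eq("anteromedial").sum())
    n_al = int(t0.disc_direction.eq("anterolateral").sum())
    n_uni = int(pats.diagnosis.eq("unilateral").sum())
    n_bil = int(pats.diagnosis.eq("bilateral").sum())
    prop = {}
    try:
        prop["directional_displacement_pct"] = directional_displacement_proportion(
            n_uni, n_bil, n_am, n_al)
    except StatsError:
        prop["directional_displacement_pct"] = float("nan")
    prop.update({
        "n_patients": n_pat,
        "pct_female": 100.0 * pats.gender.eq("female").sum() / n_pat,
        "pct_age_10_18": 100.0 * pats.age_band.eq("10-18").sum() / n_pat,
        "pct_unilateral": 100.0 * n_uni / n_pat,
        "n_affected_joints": n_uni + 2 * n_bil,
    })
    out["proportions"] = pd.DataFrame([prop])
    return out


def cohort_demographics(n_female: int, n_total: int, n_young: int) -> dict:
    """Percentages from trial enrolment counts."""
    if n_total <= 0:
        raise StatsError("empty cohort")
    return {"pct_female": 100.0 * n_female / n_total,
            "pct_age_10_18": 100.0 * n_young / n_total}
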