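"""Postero-anterior cephalometric analysis from named 2D landmarks.

Implements the 28 transverse skeletal asymmetry measurements used in frontal
cephalometry: distances along and from the facial midline (crista galli to
anterior nasal spine, or crista galli to the upper incisor midpoint),
perpendicular distances from the bilateral-orbitale (Lo) line, facial-plane
(FP) distances, mandibular body lengths, and the four cant/deviation angles.

Landmark sides are tagged ``_a`` (deviated side) and ``_b`` (contralateral
side); all coordinates are film-plane millimetres. Component distances are
unsigned; side differences are signed ``a − b``; the midline–U1 distance is
signed positive toward the deviated side; angles are unsigned in [0°, 90°].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .geometry import GeometryError, MissingLandmarkError

__all__ = [
    "CephLandmarks2D",
    "Line2D",
    "CephMeasurements",
    "MEASUREMENT_IDS",
    "MEASUREMENT_LABELS",
    "midline",
    "point_line_distance",
    "angle_to_midline_perpendicular",
    "angle_mea",
    "measure_all",
]

#: Required landmark names (bilateral points carry _a / _b side tags).
CEPH_LANDMARK_NAMES = (
    "CG", "ANS", "U1", "Me",
    "Lo_a", "Lo_b", "J_a", "J_b", "Mo_a", "Mo_b",
    "Go_a", "Go_b", "Ag_a", "Ag_b", "L6_a", "L6_b",
)

#: Canonical measurement ids in tabulated order.
MEASUREMENT_IDS = (
    "lo_line", "fp_a", "fp_b",
    "loline_j_a", "loline_j_b", "loline_j_diff",
    "loline_mo_a", "loline_mo_b", "loline_mo_diff",
    "midline_j_a", "midline_j_b", "midline_j_diff",
    "midline_mo_a", "midline_mo_b", "midline_mo_diff",
    "midline_u1",
    "go_a_me", "go_b_me", "go_me_diff",
    "midline_me",
    "l6_a_fp", "l6_b_fp", "l6_a_midline", "l6_b_midline",
    "ang_fmp", "ang_j", "ang_ocl", "ang_mea",
)

#: Human-readable labels with the conventional circled numbering.
MEASUREMENT_LABELS = {
    "lo_line": "① Lo line", "fp_a": "② FP(a)", "fp_b": "③ FP(b)",
    "loline_j_a": "④ Lo line–J(a)", "loline_j_b": "⑤ Lo line–J(b)",
    "loline_j_diff": "⑥ Lo line–J diff",
    "loline_mo_a": "⑦ Lo line–Mo(a)", "loline_mo_b": "⑧ Lo line–Mo(b)",
    "loline_mo_diff": "⑨ Lo line–Mo diff",
    "midline_j_a": "⑩ Midline–J(a)", "midline_j_b": "⑪ Midline–J(b)",
    "midline_j_diff": "⑫ Midline–J diff",
    "midline_mo_a": "⑬ Midline–Mo(a)", "midline_mo_b": "⑭ Midline–Mo(b)",
    "midline_mo_diff": "⑮ Midline–Mo diff",
    "midline_u1": "⑯ Midline–U1",
    "go_a_me": "⑰ Go(a)–Me", "go_b_me": "⑱ Go(b)–Me",
    "go_me_diff": "⑲ Go–Me diff",
    "midline_me": "⑳ Midline–Me",
    "l6_a_fp": "㉑ L6(a)–FP", "l6_b_fp": "㉒ L6(b)–FP′",
    "l6_a_midline": "㉓ L6(a)–Midline", "l6_b_midline": "㉔ L6(b)–Midline",
    "ang_fmp": "㉕ ∠Fmp", "ang_j": "㉖ ∠J", "ang_ocl": "㉗ ∠Ocl",
    "ang_mea": "㉘ ∠Mea",
}

ANGULAR_IDS = ("ang_fmp", "ang_j", "ang_ocl", "ang_mea")
DIFF_IDS = ("loline_j_diff", "loline_mo_diff", "midline_j_diff",
            "midline_mo_diff", "go_me_diff")


class CephLandmarks2D(dict):
    """Named 2D PA-cephalometric landmarks, ``name -> (x, y)`` in mm."""

    def __setitem__(self, key: str, value) -> None:
        p = np.asarray(value, dtype=float)
        if p.shape != (2,) or not np.all(np.isfinite(p)):
            raise ValueError(f"landmark {key!r} must be a finite 2-vector")
        super().__setitem__(str(key), p)

    def require(self, *names: str) -> list[np.ndarray]:
        missing = [n for n in names if n not in self]
        if missing:
            raise MissingLandmarkError(f"missing landmark(s): {', '.join(missing)}")
        return [self[n] for n in names]

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "CephLandmarks2D":
        out = cls()
        for k, v in mapping.items():
            out[k] = v
        return out

    @classmethod
    def from_json(cls, path: str | Path) -> "CephLandmarks2D":
        with open(path) as fh:
            return cls.from_mapping(json.load(fh))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CephLandmarks2D":
        import pandas as pd

        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        name_col = cols.get("name", df.columns[0])
        out = cls()
        for _, row in df.iterrows():
            out[row[name_col]] = (row[cols["x"]], row[cols["y"]])
        return out

    @classmethod
    def load(cls, path: str | Path) -> "CephLandmarks2D":
        path = Path(path)
        if path.suffix.lower() == ".json":
            return cls.from_json(path)
        return cls.from_csv(path)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({k: list(map(float, v)) for k, v in self.items()}, fh, indent=1)


@dataclass(frozen=True)
class Line2D:
    """An infinite 2D line through two distinct anchor points."""

    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=float))
        object.__setattr__(self, "p2", np.asarray(self.p2, dtype=float))
        if np.linalg.norm(self.p2 - self.p1) < 1e-12:
            raise GeometryError("line anchors are coincident")

    @property
    def direction(self) -> np.ndarray:
        d = self.p2 - self.p1
        return d / np.linalg.norm(d)

    @property
    def normal(self) -> np.ndarray:
        d = self.direction
        return np.array([-d[1], d[0]])

    def signed_distance(self, p: np.ndarray) -> float:
        return float((np.asarray(p, dtype=float) - self.p1) @ self.normal)


def midline(landmarks: CephLandmarks2D, convention: str = "cg_ans") -> Line2D:
    """The facial midline reference line.

    Two conventions are in clinical use: crista galli to the anterior nasal
    spine (``cg_ans``, the default) and crista galli to the upper incisor
    midpoint (``cg_u1``). They coincide on a symmetric dentition but can
    differ when maxillary asymmetry displaces the incisor midpoint.
    """
    if convention == "cg_ans":
        cg, ans = landmarks.require("CG", "ANS")
        return Line2D(cg, ans)
    if convention == "cg_u1":
        cg, u1 = landmarks.require("CG", "U1")
        return Line2D(cg, u1)
    raise ValueError(f"unknown midline convention {convention!r}")


def point_line_distance(p: np.ndarray, line: Line2D) -> float:
    """Unsigned perpendicular distance from a point to an infinite line, mm."""
    return abs(line.signed_distance(p))


def _acute_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Acute angle between two directions, degrees in [0, 90]."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("cannot measure an angle with a zero direction")
    c = abs(float(u @ v)) / (nu * nv)
    return math.degrees(math.acos(min(1.0, c)))


def angle_to_midline_perpendicular(p1: np.ndarray, p2: np.ndarray, mid: Line2D) -> float:
    """Acute angle between segment p1–p2 and the perpendicular to the midline."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.linalg.norm(p2 - p1) < 1e-12:
        raise GeometryError("segment endpoints are coincident")
    return _acute_angle_deg(p2 - p1, mid.normal)


def angle_mea(landmarks: CephLandmarks2D, mid: Line2D) -> float:
    """Acute angle between the ANS–Me segment and the midline (chin-deviation
    angle)."""
    ans, me = landmarks.require("ANS", "Me")
    if np.linalg.norm(me - ans) < 1e-12:
        raise GeometryError("ANS and Me are coincident")
    return _acute_angle_deg(me - ans, mid.direction)


@dataclass
class CephMeasurements:
    """The 28 PA-cephalometric values: linear in mm, angular in degrees.

    ``midline_convention`` records which reference line produced the
    midline-based values.
    """

    lo_line: float
    fp_a: float
    fp_b: float
    loline_j_a: float
    loline_j_b: float
    loline_j_diff: float
    loline_mo_a: float
    loline_mo_b: float
    loline_mo_diff: float
    midline_j_a: float
    midline_j_b: float
    midline_j_diff: float
    midline_mo_a: float
    midline_mo_b: float
    midline_mo_diff: float
    midline_u1: float
    go_a_me: float
    go_b_me: float
    go_me_diff: float
    midline_me: float
    l6_a_fp: float
    l6_b_fp: float
    l6_a_midline: float
    l6_b_midline: float
    ang_fmp: float
    ang_j: float
    ang_ocl: float
    ang_mea: float
    midline_convention: str = "cg_ans"

    def as_dict(self) -> dict[str, float]:
        return {mid_: getattr(self, mid_) for mid_ in MEASUREMENT_IDS}


def measure_all(landmarks: CephLandmarks2D, convention: str = "cg_ans") -> CephMeasurements:
    """Compute all 28 measurements from a complete PA landmark set.

    The deviated-side direction used to sign the midline–U1 distance is taken
    from the side of Me relative to the midline; with Me exactly on the
    midline the direction of Go(a) is used instead.
    """
    landmarks.require(*CEPH_LANDMARK_NAMES)
    mid = midline(landmarks, convention)
    lm = landmarks
    dist = np.linalg.norm

    lo_a, lo_b = lm["Lo_a"], lm["Lo_b"]
    lo_line_ref = Line2D(lo_a, lo_b)
    fp_line = Line2D(lo_a, lm["Ag_a"])
    fp_prime = Line2D(lo_b, lm["Ag_b"])

    d_mid = lambda p: point_line_distance(p, mid)
    d_lo = lambda p: point_line_distance(p, lo_line_ref)

    # signed direction toward the deviated side
    s_me = mid.signed_distance(lm["Me"])
    s_dev = math.copysign(1.0, s_me if abs(s_me) > 1e-12 else mid.signed_distance(lm["Go_a"]))

    vals = dict(
        lo_line=float(dist(lo_a - lo_b)),
        fp_a=float(dist(lo_a - lm["Ag_a"])),
        fp_b=float(dist(lo_b - lm["Ag_b"])),
        loline_j_a=d_lo(lm["J_a"]),
        loline_j_b=d_lo(lm["J_b"]),
        loline_mo_a=d_lo(lm["Mo_a"]),
        loline_mo_b=d_lo(lm["Mo_b"]),
        midline_j_a=d_mid(lm["J_a"]),
        midline_j_b=d_mid(lm["J_b"]),
        midline_mo_a=d_mid(lm["Mo_a"]),
        midline_mo_b=d_mid(lm["Mo_b"]),
        midline_u1=mid.signed_distance(lm["U1"]) * s_dev,
        go_a_me=float(dist(lm["Go_a"] - lm["Me"])),
        go_b_me=float(dist(lm["Go_b"] - lm["Me"])),
        midline_me=d_mid(lm["Me"]),
        l6_a_fp=point_line_distance(lm["L6_a"], fp_line),
        l6_b_fp=point_line_distance(lm["L6_b"], fp_prime),
        l6_a_midline=d_mid(lm["L6_a"]),
        l6_b_midline=d_mid(lm["L6_b"]),
        ang_fmp=angle_to_midline_perpendicular(lm["Go_a"], lm["Go_b"], mid),
        ang_j=angle_to_midline_perpendicular(lm["J_a"], lm["J_b"], mid),
        ang_ocl=angle_to_midline_perpendicular(lm["Mo_a"], lm["Mo_b"], mid),
        ang_mea=angle_mea(lm, mid),
    )
    vals["loline_j_diff"] = vals["loline_j_a"] - vals["loline_j_b"]
    vals["loline_mo_diff"] = vals["loline_mo_a"] - vals["loline_mo_b"]
    vals["midline_j_diff"] = vals["midline_j_a"] - vals["midline_j_b"]
    vals["midline_mo_diff"] = vals["midline_mo_a"] - vals["midline_mo_b"]
    vals["go_me_diff"] = vals["go_a_me"] - vals["go_b_me"]
    return CephMeasurements(midline_convention=convention, **vals)
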