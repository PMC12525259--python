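"""Synthetic study inputs: parametric faces, PA landmark sets, and cohorts.

Everything the analysis chain consumes can be generated here with known
ground truth:

* :func:`generate_face` builds a stylized facial surface (elliptic dome with
  a nasal ridge) that is exactly mirror-symmetric until unilateral
  deformations — hemispherical bumps or smoothly windowed lateral shifts —
  of analytically known displaced volume are injected, together with a
  consistent 3D soft-tissue landmark set.
* :func:`generate_pa_landmarks` emits a schematic frontal-cephalogram
  landmark set whose measured values reproduce requested asymmetry
  parameters (menton offset, occlusal/gonial/jugale cants) exactly.
* :func:`generate_cohort` draws multivariate-normal cohorts whose means and
  SDs follow the reference descriptive statistics and whose
  measurement-to-volume correlations hit requested R² targets exactly, via a
  factor construction in which measurements are conditionally independent
  given the three regional volumes.
* :func:`generate_repeated_measures` simulates two-session test–retest
  tables with a prescribed true technical error of measurement.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .ceph import CephLandmarks2D, MEASUREMENT_IDS
from .geometry import LandmarkSet3D

logger = logging.getLogger("facesym")

__all__ = [
    "Deformation",
    "FaceSpec",
    "GeneratedFace",
    "generate_face",
    "PAAsymmetryParams",
    "generate_pa_landmarks",
    "CohortSpec",
    "generate_cohort",
    "generate_repeated_measures",
    "TABLE_MEANS",
    "TABLE_SDS",
    "R2_DEFAULTS",
    "VOLUME_MEANS",
    "VOLUME_SDS",
]


# ---------------------------------------------------------------------------
# Reference descriptive statistics (clinical PA-cephalometric cohort) used as
# calibration defaults: mean and SD per measurement (mm / degrees), and the
# regional asymmetry volume statistics (cm³).
# ---------------------------------------------------------------------------

TABLE_MEANS = {
    "lo_line": 93.35, "fp_a": 97.62, "fp_b": 98.85,
    "loline_j_a": 61.15, "loline_j_b": 61.92, "loline_j_diff": -0.78,
    "loline_mo_a": 81.64, "loline_mo_b": 83.39, "loline_mo_diff": -1.75,
    "midline_j_a": 33.74, "midline_j_b": 33.30, "midline_j_diff": 0.45,
    "midline_mo_a": 24.66, "midline_mo_b": 21.98, "midline_mo_diff": 2.68,
    "midline_u1": 0.93,
    "go_a_me": 61.18, "go_b_me": 65.37, "go_me_diff": -4.19,
    "midline_me": 4.26,
    "l6_a_fp": 24.67, "l6_b_fp": 24.46, "l6_a_midline": 23.82,
    "l6_b_midline": 21.01,
    "ang_fmp": 1.88, "ang_j": 1.64, "ang_ocl": 1.94, "ang_mea": 3.68,
}

TABLE_SDS = {
    "lo_line": 3.67, "fp_a": 6.39, "fp_b": 6.04,
    "loline_j_a": 5.25, "loline_j_b": 5.63, "loline_j_diff": 2.36,
    "loline_mo_a": 5.43, "loline_mo_b": 5.50, "loline_mo_diff": 1.82,
    "midline_j_a": 3.66, "midline_j_b": 3.28, "midline_j_diff": 2.47,
    "midline_mo_a": 2.84, "midline_mo_b": 2.61, "midline_mo_diff": 4.07,
    "midline_u1": 1.03,
    "go_a_me": 6.53, "go_b_me": 5.63, "go_me_diff": 4.12,
    "midline_me": 3.43,
    "l6_a_fp": 3.77, "l6_b_fp": 2.50, "l6_a_midline": 3.17,
    "l6_b_midline": 2.75,
    "ang_fmp": 2.12, "ang_j": 1.59, "ang_ocl": 2.36, "ang_mea": 2.14,
}

VOLUME_MEANS = {"whole": 11.32, "mid": 1.90, "lower": 7.99}
VOLUME_SDS = {"whole": 8.06, "mid": 3.08, "lower": 5.99}

#: Calibration R² targets per measurement, region order (whole, mid, lower).
#: Entries reported below the printing precision are carried as 0.0005.
R2_DEFAULTS = {
    "lo_line": (0.004, 0.005, 0.0005),
    "fp_a": (0.0005, 0.000, 0.003),
    "fp_b": (0.005, 0.006, 0.0005),
    "loline_j_a": (0.011, 0.001, 0.007),
    "loline_j_b": (0.004, 0.000, 0.003),
    "loline_j_diff": (0.007, 0.002, 0.003),
    "loline_mo_a": (0.009, 0.008, 0.004),
    "loline_mo_b": (0.0005, 0.004, 0.002),
    "loline_mo_diff": (0.095, 0.008, 0.106),
    "midline_j_a": (0.171, 0.186, 0.125),
    "midline_j_b": (0.006, 0.052, 0.001),
    "midline_j_diff": (0.260, 0.112, 0.226),
    "midline_mo_a": (0.180, 0.015, 0.168),
    "midline_mo_b": (0.216, 0.041, 0.159),
    "midline_mo_diff": (0.353, 0.046, 0.295),
    "midline_u1": (0.077, 0.001, 0.115),
    "go_a_me": (0.021, 0.012, 0.041),
    "go_b_me": (0.012, 0.028, 0.007),
    "go_me_diff": (0.145, 0.003, 0.187),
    "midline_me": (0.630, 0.129, 0.629),
    "l6_a_fp": (0.003, 0.011, 0.001),
    "l6_b_fp": (0.010, 0.000, 0.013),
    "l6_a_midline": (0.246, 0.029, 0.237),
    "l6_b_midline": (0.262, 0.061, 0.203),
    "ang_fmp": (0.035, 0.002, 0.034),
    "ang_j": (0.015, 0.014, 0.019),
    "ang_ocl": (0.003, 0.000, 0.0005),
    "ang_mea": (0.342, 0.036, 0.292),
}

REGIONS = ("whole", "mid", "lower")


class SpecError(ValueError):
    """Invalid generator specification."""


# ---------------------------------------------------------------------------
# Parametric face
# ---------------------------------------------------------------------------

#: Deformation site centres in the face (x, z) parameter plane, mm.
DEFORMATION_SITES = {
    "chin": (0.0, -60.0),
    "cheek_left": (35.0, 0.0),
    "cheek_right": (-35.0, 0.0),
    "jaw_left": (45.0, -40.0),
    "jaw_right": (-45.0, -40.0),
}

#: Radial window radius (mm) for lateral-shift deformations.
SHIFT_WINDOW_RADIUS = 25.0


@dataclass(frozen=True)
class Deformation:
    """One unilateral deformation.

    ``shape='bump'``: hemispherical outward bump; ``magnitude`` is the radius
    in mm and the one-sided displaced volume is (2/3)·π·r³.
    ``shape='lateral_shift'``: smooth C¹ transverse displacement toward +x
    with quartic radial window ``(1 − (ρ/ρ₀)²)²``; ``magnitude`` is the peak
    shift in mm and the nominal planar displaced volume is ``s·π·ρ₀²/3``.
    """

    site: str
    shape: str = "bump"
    magnitude: float = 6.0

    def __post_init__(self):
        if self.site not in DEFORMATION_SITES:
            raise SpecError(f"unknown deformation site {self.site!r}")
        if self.shape not in ("bump", "lateral_shift"):
            raise SpecError(f"unknown deformation shape {self.shape!r}")
        if self.magnitude < 0:
            raise SpecError("deformation magnitude must be >= 0")

    @property
    def radius(self) -> float:
        return self.magnitude if self.shape == "bump" else SHIFT_WINDOW_RADIUS

    @property
    def displaced_volume_mm3(self) -> float:
        if self.shape == "bump":
            return (2.0 / 3.0) * np.pi * self.magnitude**3
        return self.magnitude * np.pi * SHIFT_WINDOW_RADIUS**2 / 3.0

    @property
    def region(self) -> str:
        return "mid" if self.site.startswith("cheek") else "lower"


@dataclass
class FaceSpec:
    """Parameters of the synthetic face.

    The surface is the front half of an ellipsoid-like dome: lateral
    half-width ``half_width_mm``, vertical half-height ``half_height_mm``
    (centred 10 mm above the tragion level), peak depth ``depth_mm``, with a
    Gaussian nasal ridge on the midline. ``target_faces`` controls mesh
    resolution; the default (40 000 triangles, ≈1 mm spacing) mimics the
    geometric resolution of clinical stereophotogrammetry.
    """

    half_width_mm: float = 70.0
    half_height_mm: float = 85.0
    depth_mm: float = 80.0
    nose_height_mm: float = 12.0
    target_faces: int = 40_000
    deformations: tuple[Deformation, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.target_faces < 500:
            raise SpecError("target_faces must be >= 500")
        self.deformations = tuple(self.deformations)
        sites = [DEFORMATION_SITES[d.site] for d in self.deformations]
        for i in range(len(self.deformations)):
            for j in range(i + 1, len(self.deformations)):
                di, dj = self.deformations[i], self.deformations[j]
                gap = np.hypot(sites[i][0] - sites[j][0], sites[i][1] - sites[j][1])
                if gap < di.radius + dj.radius:
                    raise SpecError(
                        f"overlapping deformation sites {di.site!r} and {dj.site!r}"
                    )


@dataclass
class GeneratedFace:
    """A generated face plus its analytically known deformation volumes."""

    mesh: trimesh.Trimesh
    landmarks: LandmarkSet3D
    spec: FaceSpec
    ground_truth: tuple[dict, ...]  # per deformation: site/shape/volume_mm3/region


_Z_CENTER = 10.0  # dome centre above the tragion level, mm


def _base_depth(spec: FaceSpec, x: np.ndarray, z: np.ndarray) -> np.ndarray:
    arg = 1.0 - (x / spec.half_width_mm) ** 2 - ((z - _Z_CENTER) / spec.half_height_mm) ** 2
    y = spec.depth_mm * np.sqrt(np.maximum(arg, 0.0))
    # nasal ridge: Gaussian in both directions, centred between the eyes
    y = y + spec.nose_height_mm * np.exp(-((x / 8.0) ** 2) - (((z - 15.0) / 14.0) ** 2))
    return y


def _deform(spec: FaceSpec, x: np.ndarray, y: np.ndarray, z: np.ndarray):
    """Apply the deformation list to coordinate arrays in place."""
    for d in spec.deformations:
        cx, cz = DEFORMATION_SITES[d.site]
        rho2 = (x - cx) ** 2 + (z - cz) ** 2
        if d.shape == "bump":
            y += np.sqrt(np.maximum(d.magnitude**2 - rho2, 0.0))
        else:
            q2 = rho2 / SHIFT_WINDOW_RADIUS**2
            w = np.where(q2 < 1.0, (1.0 - np.minimum(q2, 1.0)) ** 2, 0.0)
            x += d.magnitude * w
    return x, y, z


def generate_face(spec: FaceSpec) -> GeneratedFace:
    """Generate the parametric face mesh and its landmark set.

    With no deformations the mesh is exactly mirror-symmetric about x = 0
    (grid coordinates are stored antisymmetrically, and the depth field is an
    even function of x), so the mirror-superimposition pipeline must report
    zero asymmetry on it up to floating-point noise. Identical specs produce
    bitwise-identical meshes.
    """
    A, C = spec.half_width_mm, spec.half_height_mm
    z_lo, z_hi = _Z_CENTER - C, _Z_CENTER + C

    n_cells = spec.target_faces / 4.0 / (np.pi / 4.0)
    nx = max(8, int(round(np.sqrt(n_cells * (2 * A) / (z_hi - z_lo)))))
    nz = max(8, int(round(n_cells / nx)))
    xs = np.linspace(-A, A, nx + 1)
    xs = (xs - xs[::-1]) / 2.0  # exactly antisymmetric
    zs = np.linspace(z_lo, z_hi, nz + 1)

    XX, ZZ = np.meshgrid(xs, zs, indexing="ij")
    inside = (XX / A) ** 2 + ((ZZ - _Z_CENTER) / C) ** 2 <= 0.995
    cell_ok = inside[:-1, :-1] & inside[1:, :-1] & inside[1:, 1:] & inside[:-1, 1:]
    ci, cj = np.nonzero(cell_ok)
    if len(ci) == 0:
        raise SpecError("no grid cells fall inside the face domain")

    # corner vertices used by at least one kept cell
    corner_used = np.zeros_like(inside)
    for di, dj in ((0, 0), (1, 0), (1, 1), (0, 1)):
        corner_used[ci + di, cj + dj] = True
    corner_index = -np.ones(inside.shape, dtype=np.int64)
    ui, uj = np.nonzero(corner_used)
    corner_index[ui, uj] = np.arange(len(ui))
    n_corner = len(ui)

    corner_x, corner_z = XX[ui, uj], ZZ[ui, uj]
    center_x = 0.5 * (xs[ci] + xs[ci + 1])
    center_z = 0.5 * (zs[cj] + zs[cj + 1])

    vx = np.concatenate([corner_x, center_x])
    vz = np.concatenate([corner_z, center_z])
    vy = _base_depth(spec, vx, vz)
    vx, vy, vz = _deform(spec, vx.copy(), vy, vz.copy())
    vertices = np.column_stack([vx, vy, vz])

    c00 = corner_index[ci, cj]
    c10 = corner_index[ci + 1, cj]
    c11 = corner_index[ci + 1, cj + 1]
    c01 = corner_index[ci, cj + 1]
    cc = n_corner + np.arange(len(ci))
    # wound so that face normals point outward (+y component)
    faces = np.concatenate(
        [
            np.column_stack([c00, cc, c10]),
            np.column_stack([c10, cc, c11]),
            np.column_stack([c11, cc, c01]),
            np.column_stack([c01, cc, c00]),
        ]
    )
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if mesh.face_normals[:, 1].mean() < 0:  # safeguard; winding above is outward
        mesh = trimesh.Trimesh(vertices=vertices, faces=faces[:, ::-1], process=False)

    landmarks = _face_landmarks(spec)
    truth = tuple(
        {
            "site": d.site,
            "shape": d.shape,
            "magnitude_mm": d.magnitude,
            "volume_mm3": d.displaced_volume_mm3,
            "region": d.region,
        }
        for d in spec.deformations
    )
    return GeneratedFace(mesh=mesh, landmarks=landmarks, spec=spec, ground_truth=truth)


#: Landmark positions in the (x, z) parameter plane (depth is analytic).
_LANDMARK_XZ = {
    "exocanthion_l": (42.0, 30.0),
    "exocanthion_r": (-42.0, 30.0),
    "sellion": (0.0, 28.0),
    "subnasale": (0.0, -5.0),
    "alare_l": (12.0, -2.0),
    "alare_r": (-12.0, -2.0),
    "cheilion_l": (24.0, -30.0),
    "cheilion_r": (-24.0, -30.0),
    "menton": (0.0, -60.0),
}


def _face_landmarks(spec: FaceSpec) -> LandmarkSet3D:
    lms = LandmarkSet3D()
    # tragia sit at the lateral ear points, at the exocanthion level so that
    # the fitted head frame of the neutral face is axis-aligned
    lms["tragion_l"] = (spec.half_width_mm, 0.0, 30.0)
    lms["tragion_r"] = (-spec.half_width_mm, 0.0, 30.0)
    names = list(_LANDMARK_XZ)
    x = np.array([_LANDMARK_XZ[n][0] for n in names])
    z = np.array([_LANDMARK_XZ[n][1] for n in names])
    y = _base_depth(spec, x, z)
    x, y, z = _deform(spec, x.copy(), y, z.copy())
    for i, n in enumerate(names):
        lms[n] = (x[i], y[i], z[i])
    return lms


# ---------------------------------------------------------------------------
# PA-cephalogram landmark generator
# ---------------------------------------------------------------------------


@dataclass
class PAAsymmetryParams:
    """Controllable asymmetry of the schematic PA landmark set.

    Each parameter maps exactly onto one measurement of the analysis:
    ``menton_offset_mm`` → midline–Me, ``occlusal_cant_deg`` → ∠Ocl,
    ``gonial_cant_deg`` → ∠Fmp, ``jugale_cant_deg`` → ∠J. ``jitter_sd_mm``
    adds isotropic Gaussian noise to every landmark afterwards.
    """

    menton_offset_mm: float = 0.0
    occlusal_cant_deg: float = 0.0
    gonial_cant_deg: float = 0.0
    jugale_cant_deg: float = 0.0
    jitter_sd_mm: float = 0.0


#: Symmetric base landmark coordinates (film-plane mm); the deviated side
#: 'a' is the +x side. Scaled to clinically plausible magnitudes.
_PA_BASE = {
    "CG": (0.0, 110.0),
    "ANS": (0.0, 45.0),
    "U1": (0.0, 38.0),
    "Me": (0.0, -60.0),
    "Lo_a": (46.675, 80.0), "Lo_b": (-46.675, 80.0),
    "J_a": (33.52, 18.47), "J_b": (-33.52, 18.47),
    "Mo_a": (23.32, -2.52), "Mo_b": (-23.32, -2.52),
    "Go_a": (48.0, -18.7), "Go_b": (-48.0, -18.7),
    "Ag_a": (40.0, -18.0), "Ag_b": (-40.0, -18.0),
    "L6_a": (22.42, -8.0), "L6_b": (-22.42, -8.0),
}


def generate_pa_landmarks(
    params: PAAsymmetryParams | None = None, seed: int = 0
) -> CephLandmarks2D:
    """Schematic PA-cephalometric landmark set with controlled asymmetry.

    With all parameters zero and no jitter the set is perfectly symmetric
    about the vertical midline, so every side difference and every angle
    measures zero.
    """
    params = params or PAAsymmetryParams()
    lm = {k: np.array(v, dtype=float) for k, v in _PA_BASE.items()}
    lm["Me"][0] += params.menton_offset_mm

    def _cant(pair: str, degrees: float) -> None:
        ya = np.tan(np.radians(degrees))
        for side, sign in (("a", 1.0), ("b", -1.0)):
            p = lm[f"{pair}_{side}"]
            p[1] += sign * abs(p[0]) * ya

    _cant("Mo", params.occlusal_cant_deg)
    _cant("Go", params.gonial_cant_deg)
    _cant("J", params.jugale_cant_deg)

    if params.jitter_sd_mm > 0:
        rng = np.random.default_rng(seed)
        for k in lm:
            lm[k] = lm[k] + rng.normal(0.0, params.jitter_sd_mm, 2)
    return CephLandmarks2D.from_mapping(lm)


# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------


def _default_volume_correlations(shrink: float = 0.05) -> np.ndarray:
    """Correlation matrix of (whole, mid, lower) asymmetry volumes.

    Treating the whole-face volume as the sum of midface and lower-face
    volumes, the reference SDs imply cov(mid, lower) =
    (var_whole − var_mid − var_lower)/2 and hence all three pairwise
    correlations. That matrix is exactly singular (rank 2), so it is shrunk
    slightly toward the identity to give the attached measurement
    correlations room to be realized.
    """
    sw, sm, sl = VOLUME_SDS["whole"], VOLUME_SDS["mid"], VOLUME_SDS["lower"]
    cov_ml = (sw**2 - sm**2 - sl**2) / 2.0
    S = np.array(
        [
            [1.0, (sm**2 + cov_ml) / (sw * sm), (sl**2 + cov_ml) / (sw * sl)],
            [(sm**2 + cov_ml) / (sw * sm), 1.0, cov_ml / (sm * sl)],
            [(sl**2 + cov_ml) / (sw * sl), cov_ml / (sm * sl), 1.0],
        ]
    )
    return (1.0 - shrink) * S + shrink * np.eye(3)


@dataclass
class CohortSpec:
    """Specification of a simulated measurement cohort.

    Defaults calibrate every mean, SD and measurement↔volume R² to the
    reference clinical cohort (n = 33). ``r2_targets`` maps measurement id →
    (R²_whole, R²_mid, R²_lower); correlation signs are positive unless
    overridden in ``sign_targets`` (only effect magnitudes are published for
    the reference data, so signs are a modelling choice).
    """

    n_subjects: int = 33
    means: dict = field(default_factory=lambda: dict(TABLE_MEANS))
    sds: dict = field(default_factory=lambda: dict(TABLE_SDS))
    volume_means: dict = field(default_factory=lambda: dict(VOLUME_MEANS))
    volume_sds: dict = field(default_factory=lambda: dict(VOLUME_SDS))
    r2_targets: dict = field(default_factory=lambda: dict(R2_DEFAULTS))
    sign_targets: dict = field(default_factory=dict)
    volume_correlations: np.ndarray = field(default_factory=_default_volume_correlations)
    clip_volumes_at_zero: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise SpecError("need at least 2 subjects")
        for d in (self.sds, self.volume_sds):
            if any(v <= 0 for v in d.values()):
                raise SpecError("all SDs must be positive")
        for k, v in self.r2_targets.items():
            if np.any(np.asarray(v) < 0) or np.any(np.asarray(v) >= 1):
                raise SpecError(f"R² targets must lie in [0, 1): {k}")


def _attach_rows(spec: CohortSpec):
    """Loadings realizing the target measurement↔volume correlations.

    Each measurement m_i is modelled as b_i'·f + e_i with f the standardized
    volume factor vector; b_i = Σ_v⁻¹ ρ_i reproduces corr(m_i, f) = ρ_i
    exactly. Rows whose implied explained variance exceeds 1 are infeasible
    jointly with Σ_v and are scaled back (with a warning naming the offending
    pairs — the repair step of the calibration).
    """
    Sv = np.asarray(spec.volume_correlations, dtype=float)
    if np.linalg.eigvalsh(Sv).min() <= 0:
        raise SpecError("volume correlation matrix must be positive definite")
    Svi = np.linalg.inv(Sv)
    loadings, resid = {}, {}
    moved = []
    for var, r2s in spec.r2_targets.items():
        signs = np.asarray(spec.sign_targets.get(var, (1.0, 1.0, 1.0)), dtype=float)
        rho = signs * np.sqrt(np.asarray(r2s, dtype=float))
        q = float(rho @ Svi @ rho)
        if q > 0.999:
            scale = np.sqrt(0.999 / q)
            if np.max(np.abs(rho - scale * rho)) > 0.02:
                moved.append(var)
            rho = scale * rho
            q = 0.999
        loadings[var] = Svi @ rho
        resid[var] = np.sqrt(1.0 - q)
    if moved:
        warnings.warn(
            "infeasible correlation targets scaled back by > 0.02 for: "
            + ", ".join(moved),
            stacklevel=3,
        )
    return Sv, loadings, resid


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a multivariate-normal cohort table.

    Columns are the 28 canonical measurement ids plus ``volume_whole``,
    ``volume_mid`` and ``volume_lower``. Measurement↔volume correlations are
    √R² with configurable signs; measurements are conditionally independent
    given the volumes. Volumes can optionally be clipped at zero
    (``clip_volumes_at_zero``), which slightly attenuates the realized
    correlations and is therefore off by default.
    """
    spec = spec or CohortSpec()
    Sv, loadings, resid = _attach_rows(spec)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    L = np.linalg.cholesky(Sv)
    f = rng.standard_normal((n, 3)) @ L.T  # standardized volume factors

    data = {}
    for region, col in zip(REGIONS, f.T):
        v = spec.volume_means[region] + spec.volume_sds[region] * col
        if spec.clip_volumes_at_zero:
            v = np.maximum(v, 0.0)
        data[f"volume_{region}"] = v
    for var in spec.r2_targets:
        e = rng.standard_normal(n)
        z = f @ loadings[var] + resid[var] * e
        data[var] = spec.means[var] + spec.sds[var] * z

    cols = [m for m in MEASUREMENT_IDS if m in data] + [f"volume_{r}" for r in REGIONS]
    return pd.DataFrame(data)[cols]


# ---------------------------------------------------------------------------
# Repeated measures
# ---------------------------------------------------------------------------


def generate_repeated_measures(
    n: int, true_values, tem_true: float, seed: int = 0
) -> pd.DataFrame:
    """Two-session test–retest table with a prescribed true TEM.

    Each session observes truth plus independent Gaussian error with SD equal
    to ``tem_true``; the expected Dahlberg TEM of the two sessions then
    equals ``tem_true``.
    """
    if tem_true < 0:
        raise SpecError("tem_true must be >= 0")
    truth = np.broadcast_to(np.asarray(true_values, dtype=float), (n,)).copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, tem_true, (n, 2)) if tem_true > 0 else np.zeros((n, 2))
    return pd.DataFrame(
        {
            "truth": truth,
            "session1": truth + noise[:, 0],
            "session2": truth + noise[:, 1],
        }
    )
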