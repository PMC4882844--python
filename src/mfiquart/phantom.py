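"""Synthetic axial-slice phantoms and simulated rater behavior.

Real cohort images are not distributable, so validation runs on phantoms:
a grayscale axial slice carrying two elliptical "paravertebral muscle"
compartments flanking the midline and small circular subcutaneous-fat
reference regions, with known quartile-wise fat fractions.

Muscle signal follows a linear two-compartment mixture,
``intensity = (1 - f) * base + f * fat``, with the fat fraction ``f`` a step
function of medial->lateral position: the muscle pixels are split into four
equal-count slabs along the lateral axis (matching the measurement's own
definition of a quartile) and slab q carries fraction ``f_q``.  The
analytically expected quartile MFI% is then

    MFI_q = 100 * ((1 - f_q) * base + f_q * fat) / fat

exactly, before noise.  This is a simulation convention consistent with
fat being hyperintense on T1-weighted images, not a model of scanner
physics.

All randomness flows from one user seed through named independent
substreams (image noise, rater jitter, table simulation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import GeometryError, JitterError
from .io import LEVELS, AxialSlice, RoiPolygon, rasterize_polygon
from .quartiles import lateral_direction
from .tables import CSV_COLUMNS, MeasurementTable

_STREAM_IMAGE, _STREAM_JITTER, _STREAM_TABLE, _STREAM_STUDY = 11, 23, 37, 53


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned-parameterized ellipse: center (row, col), semi-axes, rotation (rad)."""

    center: tuple[float, float]
    semi_row: float
    semi_col: float
    rotation: float = 0.0

    def polygon_vertices(self, n_vertices: int = 64) -> np.ndarray:
        t = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
        r = self.semi_row * np.sin(t)
        c = self.semi_col * np.cos(t)
        rot_r = r * math.cos(self.rotation) - c * math.sin(self.rotation)
        rot_c = r * math.sin(self.rotation) + c * math.cos(self.rotation)
        return np.column_stack([self.center[0] + rot_r, self.center[1] + rot_c])


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and signal model of one synthetic axial slice.

    Defaults emulate a 160x160, 1 mm isotropic slice with ~1800-pixel muscle
    compartments, T1-bright fat (muscle:fat base signal 300:1000 ~= the
    ~30% MFI scale reported for healthy paravertebral muscle), a medially
    increasing fat gradient across quartiles, and mild additive noise
    (SD 10 ~= SNR 30 for muscle).
    """

    shape: tuple[int, int] = (160, 160)
    row_spacing_mm: float = 1.0
    col_spacing_mm: float = 1.0
    muscle_right: Ellipse = Ellipse((95.0, 45.5), 22.0, 26.0)
    muscle_left: Ellipse = Ellipse((95.0, 113.5), 22.0, 26.0)
    fat_right: Ellipse = Ellipse((135.0, 24.5), 6.0, 6.0)
    fat_left: Ellipse = Ellipse((135.0, 134.5), 6.0, 6.0)
    base_muscle_intensity: float = 300.0
    fat_intensity: float = 1000.0
    background_intensity: float = 40.0
    fat_fractions: tuple[float, float, float, float] = (0.0, 0.2, 0.4, 0.6)
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if any(not 0 <= f <= 1 for f in self.fat_fractions):
            raise ValueError("fat fractions must lie in [0, 1]")
        if min(self.base_muscle_intensity, self.fat_intensity) <= 0:
            raise ValueError("intensities must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass(frozen=True)
class RaterSimSpec:
    """Simulated rater behavior.

    boundary_jitter_sd: per-vertex displacement SD along the outward normal,
    pixels.  measurement_noise_sd: additive noise on each reported MFI%,
    independent of the image.  rater_bias: systematic MFI% offset per rater.
    """

    boundary_jitter_sd: float = 0.5
    measurement_noise_sd: float = 0.5
    rater_bias: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_sd < 0 or self.measurement_noise_sd < 0:
            raise ValueError("jitter and noise SDs must be non-negative")


@dataclass(frozen=True)
class PhantomResult:
    """Generated slice, its ground-truth ROIs, and expected quartile MFI%."""

    slice: AxialSlice
    rois: list
    expected_mfi: dict  # side -> {"Q1"..: value, "Qmean": value}


def _roi_polygons(spec: PhantomSpec, level, rater_id, session_id) -> list[RoiPolygon]:
    return [
        RoiPolygon(spec.muscle_right.polygon_vertices(), "muscle", "right",
                   level, rater_id, session_id),
        RoiPolygon(spec.muscle_left.polygon_vertices(), "muscle", "left",
                   level, rater_id, session_id),
        RoiPolygon(spec.fat_right.polygon_vertices(), "fat_reference", "right",
                   level, rater_id, session_id),
        RoiPolygon(spec.fat_left.polygon_vertices(), "fat_reference", "left",
                   level, rater_id, session_id),
    ]


def generate_phantom(
    spec: PhantomSpec,
    subject_id: str = "P0001",
    level: str = "L3",
    rater_id: str = "R1",
    session_id: str = "S1",
    seed: int = 0,
    patient_left_is_image_right: bool = True,
) -> PhantomResult:
    """Build one synthetic slice with known quartile-wise fat fractions.

    Deterministic given ``seed``.  Raises :class:`GeometryError` when the
    compartments overlap or leave the grid.
    """
    rows, cols = spec.shape
    rois = _roi_polygons(spec, level, rater_id, session_id)

    shapes = [_ShapelyPolygon(r.vertices[:, ::-1]) for r in rois]
    for i in range(len(shapes)):
        for j in range(i + 1, len(shapes)):
            if shapes[i].intersects(shapes[j]):
                raise GeometryError(
                    f"phantom compartments {i} and {j} overlap"
                )

    img = np.full(spec.shape, spec.background_intensity, dtype=float)
    expected: dict[str, dict[str, float]] = {}
    for roi in rois:
        mask = rasterize_polygon(roi, rows, cols)
        if roi.kind == "fat_reference":
            img[mask.pixels[:, 0], mask.pixels[:, 1]] = spec.fat_intensity
            continue
        # step-function fat fraction over four equal-count lateral slabs
        direction = lateral_direction(roi.side, patient_left_is_image_right)
        coords = mask.pixels
        proj = coords.astype(float) @ direction
        order = np.lexsort((coords[:, 1], coords[:, 0], proj))
        n = len(order)
        base_n, rem = divmod(n, 4)
        sizes = [base_n + 1 if i < rem else base_n for i in range(4)]
        bounds = np.cumsum([0] + sizes)
        side_expect = {}
        q_vals = []
        for q in range(4):
            f = spec.fat_fractions[q]
            slab = coords[order[bounds[q]:bounds[q + 1]]]
            value = (1 - f) * spec.base_muscle_intensity + f * spec.fat_intensity
            img[slab[:, 0], slab[:, 1]] = value
            mfi = 100.0 * value / spec.fat_intensity
            side_expect[f"Q{q + 1}"] = mfi
            q_vals.append(mfi)
        side_expect["Qmean"] = float(np.mean(q_vals))
        expected[roi.side] = side_expect

    if spec.noise_sd > 0:
        rng = np.random.default_rng([seed, _STREAM_IMAGE])
        img = np.clip(img + rng.normal(0.0, spec.noise_sd, img.shape), 0.0, None)

    slice_ = AxialSlice(
        pixels=img,
        row_spacing_mm=spec.row_spacing_mm,
        col_spacing_mm=spec.col_spacing_mm,
        level=level,
        subject_id=subject_id,
        patient_left_is_image_right=patient_left_is_image_right,
    )
    return PhantomResult(slice=slice_, rois=rois, expected_mfi=expected)


# ---------------------------------------------------------------------------
# rater simulation
# ---------------------------------------------------------------------------

def jitter_roi(
    poly: RoiPolygon,
    sim: RaterSimSpec,
    draw_index: int = 0,
    max_retries: int = 25,
) -> RoiPolygon:
    """Displace each vertex along its local outward normal by seeded noise.

    ``draw_index`` selects an independent substream, so distinct draws under
    one seed give distinct, reproducible polygons.  SD 0 returns the input
    unchanged.  Redraws (bounded) until the jittered polygon is simple.
    """
    if sim.boundary_jitter_sd == 0:
        return poly
    v = poly.vertices
    m = len(v)
    centroid = v.mean(axis=0)
    # outward normal from the edge tangent, sign-checked against the centroid
    tangents = np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normals /= norms
    outward = np.sign(((v - centroid) * normals).sum(axis=1))
    outward[outward == 0] = 1.0
    normals *= outward[:, None]

    for attempt in range(max_retries):
        rng = np.random.default_rng([sim.seed, _STREAM_JITTER, draw_index, attempt])
        disp = rng.normal(0.0, sim.boundary_jitter_sd, m)
        cand = v + disp[:, None] * normals
        shp = _ShapelyPolygon(cand[:, ::-1])
        if shp.is_valid and shp.area > 0:
            return RoiPolygon(cand, poly.kind, poly.side, poly.level,
                              poly.rater_id, poly.session_id)
    raise JitterError(
        f"could not produce a simple polygon in {max_retries} attempts "
        f"(jitter SD {sim.boundary_jitter_sd})"
    )


def simulate_two_way_table(
    n_subjects: int,
    variance_components: tuple[float, float, float],
    k: int = 2,
    design: str = "inter",
    mu: float = 50.0,
    seed: int = 0,
) -> MeasurementTable:
    """Draw a null-model two-way table ``y_ij = mu + s_i + r_j + e_ij``.

    ``variance_components`` are (subject, rater, error) variances; the
    theoretical absolute-agreement ICC, ``var_s / (var_s + var_r + var_e)``,
    is attached as ``metadata["true_icc"]``.  For ``design="inter"`` the k
    repeated measurements are raters (one session); for ``"intra"`` they are
    sessions of a single rater.
    """
    var_s, var_r, var_e = variance_components
    if min(var_s, var_r, var_e) < 0:
        raise ValueError("variance components must be non-negative")
    if design not in ("intra", "inter"):
        raise ValueError(f"design must be 'intra' or 'inter', got {design!r}")
    rng = np.random.default_rng([seed, _STREAM_TABLE])
    s = rng.normal(0.0, math.sqrt(var_s), n_subjects)
    r = rng.normal(0.0, math.sqrt(var_r), k)
    e = rng.normal(0.0, math.sqrt(var_e), (n_subjects, k))
    y = np.clip(mu + s[:, None] + r[None, :] + e, 0.0, None)

    rows = []
    for i in range(n_subjects):
        for j in range(k):
            rows.append({
                "subject_id": f"S{i + 1:04d}",
                "level": "L3",
                "side": "right",
                "quartile": "Q1",
                "rater_id": f"R{j + 1}" if design == "inter" else "R1",
                "session_id": "S1" if design == "inter" else f"S{j + 1}",
                "mfi_percent": float(y[i, j]),
            })
    true_icc = var_s / (var_s + var_r + var_e) if (var_s + var_r + var_e) > 0 else float("nan")
    return MeasurementTable(
        pd.DataFrame(rows, columns=CSV_COLUMNS),
        metadata={"true_icc": true_icc, "variance_components": (var_s, var_r, var_e)},
    )


def simulate_reliability_study(
    n_subjects: int = 10,
    base_spec: PhantomSpec | None = None,
    rater_sim: RaterSimSpec | None = None,
    raters: tuple[str, ...] = ("R1", "R2"),
    sessions: tuple[str, ...] = ("S1", "S2"),
    levels: tuple[str, ...] = LEVELS,
    subject_fraction_sd: float = 0.08,
    seed: int = 0,
    axis: str = "column",
) -> MeasurementTable:
    """Full pipeline simulation: phantoms measured by jittered raters.

    Each subject gets its own severity: the quartile fat fractions are the
    base spec's shifted by a common subject offset (clipped to [0, 1]),
    giving true between-subject variance.  Every (rater, session) repeats
    the measurement with independently jittered ROI boundaries plus
    measurement noise and per-rater bias, then everything is quantified
    through the standard pipeline into one long-format table.
    """
    from .quantify import quantify_slice

    base_spec = base_spec or PhantomSpec()
    rater_sim = rater_sim or RaterSimSpec()
    master = np.random.default_rng([seed, _STREAM_STUDY])

    rows = []
    for i in range(n_subjects):
        subject = f"P{i + 1:04d}"
        offset = master.normal(0.0, subject_fraction_sd)
        fracs = tuple(float(np.clip(f + offset, 0.0, 1.0))
                      for f in base_spec.fat_fractions)
        for li, level in enumerate(levels):
            spec = replace(base_spec, fat_fractions=fracs)
            ph = generate_phantom(
                spec, subject_id=subject, level=level,
                seed=int(master.integers(2 ** 31)),
            )
            for rj, rater in enumerate(raters):
                bias = rater_sim.rater_bias.get(rater, 0.0)
                for sj, session in enumerate(sessions):
                    draw = ((i * len(levels) + li) * len(raters) + rj) \
                        * len(sessions) + sj
                    rois = [
                        jitter_roi(
                            RoiPolygon(r.vertices, r.kind, r.side, r.level,
                                       rater, session),
                            rater_sim, draw_index=draw * 8 + ri,
                        )
                        for ri, r in enumerate(ph.rois)
                    ]
                    for meas in quantify_slice(ph.slice, rois, axis=axis):
                        noise = 0.0
                        if rater_sim.measurement_noise_sd > 0:
                            noise = float(master.normal(
                                0.0, rater_sim.measurement_noise_sd))
                        rows.append({
                            **vars(meas),
                            "mfi_percent": max(0.0, meas.mfi_percent + bias + noise),
                        })
    return MeasurementTable(pd.DataFrame(rows, columns=CSV_COLUMNS))
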