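"""Synthetic ocular imaging data with known ground truth.

Every input the analysis pipeline consumes can be generated here with a
planted, exactly-known answer, so each downstream stage is testable
without any image download:

* peripapillary OCT ring scans with a bright outer-retina band and
  multiplicative column shadows (plus 1-2 px ciliary shadows that the
  counter must exclude);
* ultra-widefield vessel scenes: centerlines with a prescribed linear
  taper ``w(d) = WI + WG * d`` and tortuosity class, rendered into a
  binary map by stamping discs (no anti-aliasing, so the binary truth is
  exact);
* analytic fractal fixtures (line, filled square, Sierpinski carpet)
  with known Hausdorff dimension;
* OCT choroid volumes: dark elliptical lumina on bright stroma between
  two smooth boundary polylines, packed to a requested luminal fraction;
* paired-eye cohort tables with a shared participant-level random effect
  producing an exchangeable within-participant correlation and planted
  group effects.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .cvi import ChoroidVolume
from .ringscan import DEFAULT_TRANSVERSE_SCALE_UM, OCTRingScan
from .uwf import Centerline, Landmarks, VesselScene

__all__ = [
    "RingScanTruth",
    "VesselTruth",
    "ChoroidTruth",
    "OutcomeSpec",
    "CohortSpec",
    "gen_ring_scan",
    "gen_vessel_scene",
    "gen_fractal_fixture",
    "gen_choroid_volume",
    "gen_cohort",
]


# ---------------------------------------------------------------------------
# ring scans
# ---------------------------------------------------------------------------

@dataclass
class RingScanTruth:
    vessel_count: int
    shadow_intervals: list[tuple[int, int]]     # (start_column, width_px)
    ciliary_intervals: list[tuple[int, int]]    # widths 1-2 px


def _pack_circular_intervals(
    widths: np.ndarray, n_cols: int, min_gap: int, rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Place non-overlapping circular intervals separated by >= min_gap columns."""
    n = len(widths)
    if n == 0:
        return []
    occupied = int(widths.sum()) + n * min_gap
    if occupied > n_cols:
        raise ValueError(
            f"cannot pack {n} shadows totalling {int(widths.sum())} px plus gaps "
            f"into {n_cols} columns")
    slack = n_cols - occupied
    extra = rng.multinomial(slack, np.full(n, 1.0 / n))
    order = rng.permutation(n)
    offset = int(rng.integers(0, n_cols))
    starts = []
    pos = offset
    for i in order:
        starts.append((i, pos % n_cols))
        pos += int(widths[i]) + min_gap + int(extra[i])
    out: list[tuple[int, int]] = [(0, 0)] * n
    for i, s in starts:
        out[i] = (s, int(widths[i]))
    return out


def gen_ring_scan(
    n_vessels: int,
    n_ciliary: int = 0,
    width_range_px: tuple[int, int] = (3, 8),
    snr: float = 20.0,
    seed: int = 0,
    n_cols: int = 768,
    n_rows: int = 128,
    attenuation: float = 0.45,
    min_gap_px: int = 4,
    transverse_scale_um: float = DEFAULT_TRANSVERSE_SCALE_UM,
) -> tuple[OCTRingScan, RingScanTruth]:
    """Synthesize a peripapillary ring scan with planted vessel shadows.

    The B-scan has a bright sub-retinal band; each planted vessel
    multiplies the band (and everything below it) by ``attenuation`` over
    its column interval.  Columns are circular, so an interval may span
    the wrap point.  ``snr`` is band intensity over noise SD; use a large
    value (or ``np.inf``) for effectively noiseless scans.
    """
    if n_vessels < 0 or n_ciliary < 0:
        raise ValueError("shadow counts must be non-negative")
    rng = np.random.default_rng(seed)
    w_lo, w_hi = width_range_px
    if w_lo < 3:
        raise ValueError("vessel shadows must be >= 3 px wide (thinner ones are "
                         "ciliary by definition)")
    widths = np.concatenate([
        rng.integers(w_lo, w_hi + 1, size=n_vessels),
        rng.integers(1, 3, size=n_ciliary),
    ])
    intervals = _pack_circular_intervals(widths, n_cols, min_gap_px, rng)
    vessel_intervals = sorted(intervals[:n_vessels])
    ciliary_intervals = sorted(intervals[n_vessels:])

    background, band_level = 25.0, 210.0
    band_top = n_rows // 2 - n_rows // 16
    band_bot = n_rows // 2 + n_rows // 16 + 1
    img = np.full((n_rows, n_cols), background)
    img[band_top:band_bot, :] = band_level

    atten = np.ones(n_cols)
    for start, width in vessel_intervals + ciliary_intervals:
        cols = (np.arange(start, start + width)) % n_cols
        atten[cols] = attenuation
    img[band_top:, :] *= atten[None, :]

    if np.isfinite(snr) and snr > 0:
        img = img + rng.normal(0.0, band_level / snr, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    scan = OCTRingScan(image=img, transverse_scale_um=transverse_scale_um)
    truth = RingScanTruth(vessel_count=n_vessels,
                          shadow_intervals=vessel_intervals,
                          ciliary_intervals=ciliary_intervals)
    return scan, truth


# ---------------------------------------------------------------------------
# UWF vessel scenes
# ---------------------------------------------------------------------------

@dataclass
class VesselTruth:
    """Ground-truth description of one rendered vessel."""

    width_intercept_um: float                  # caliber at the disc edge
    width_gradient_um_per_mm: float            # <= 0 for tapering vessels
    tortuosity: str = "straight"               # straight | arc | sinusoid
    amplitude_mm: float = 0.0
    periods: int = 0                           # sinusoid periods
    quadrant: str = "ST"
    vessel_class: str = "arteriole"
    length_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.width_intercept_um <= 0:
            raise ValueError("width intercept must be positive")
        if self.tortuosity not in ("straight", "arc", "sinusoid"):
            raise ValueError(f"unknown tortuosity class {self.tortuosity!r}")


_QUADRANT_DIRS = {               # (row, col) unit vectors; superior is -row,
    "ST": (-1.0, -1.0),          # temporal is -col (toward the fovea)
    "SN": (-1.0, +1.0),
    "IT": (+1.0, -1.0),
    "IN": (+1.0, +1.0),
}


def _centerline_points(
    truth: VesselTruth,
    landmarks: Landmarks,
    mm_per_px: float,
    step_px: float = 1.0,
) -> np.ndarray:
    u = np.array(_QUADRANT_DIRS[truth.quadrant])
    u = u / np.hypot(*u)
    v = np.array([-u[1], u[0]])
    start = np.asarray(landmarks.disc_center) + u * landmarks.disc_radius_px
    L = truth.length_mm / mm_per_px
    a = truth.amplitude_mm / mm_per_px
    t = np.arange(0.0, L + 1e-9, step_px)
    if truth.tortuosity == "straight":
        off = np.zeros_like(t)
    elif truth.tortuosity == "arc":
        off = a * np.sin(math.pi * t / L)
    else:
        off = a * np.sin(2 * math.pi * truth.periods * t / L)
    return start[None, :] + t[:, None] * u[None, :] + off[:, None] * v[None, :]


def gen_vessel_scene(
    vessels: list[VesselTruth],
    image_shape: tuple[int, int] = (1500, 1500),
    pixel_scale_um: float = 10.0,
    disc_radius_mm: float = 0.8,
    disc_fovea_mm: float = 4.7,
    seed: int = 0,
) -> tuple[VesselScene, list[VesselTruth]]:
    """Render vessels with a prescribed linear taper into a binary UWF scene.

    Each centerline starts at the optic-disc edge and runs into its
    quadrant; the local full width at arclength ``d`` mm from the start
    is ``WI + WG * d`` um, rendered by stamping discs (anti-aliasing off,
    so the binary truth is exact).  Raises if any rendered width would be
    non-positive or a path leaves the image.
    """
    mm = pixel_scale_um / 1000.0
    center = (image_shape[0] / 2.0, image_shape[1] / 2.0)
    fovea = (center[0], center[1] - disc_fovea_mm / mm)   # temporal = -col
    landmarks = Landmarks(disc_center=center,
                          disc_radius_px=disc_radius_mm / mm,
                          fovea=fovea)
    vessel_map = np.zeros(image_shape, dtype=bool)
    centerlines = []
    for vid, truth in enumerate(vessels):
        pts = _centerline_points(truth, landmarks, mm)
        d_mm = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))]) * mm
        w_um = truth.width_intercept_um + truth.width_gradient_um_per_mm * d_mm
        if w_um.min() <= 0:
            raise ValueError(
                f"vessel {vid}: rendered width becomes non-positive "
                f"({w_um.min():.1f} um) along the path")
        radii_px = w_um / pixel_scale_um / 2.0
        margin = radii_px.max() + 1
        if (pts[:, 0].min() < margin or pts[:, 1].min() < margin
                or pts[:, 0].max() > image_shape[0] - margin
                or pts[:, 1].max() > image_shape[1] - margin):
            raise ValueError(f"vessel {vid}: path leaves the image")
        for (r, c), rad in zip(pts, radii_px):
            rr, cc = draw_disk((r, c), max(rad, 0.51), shape=image_shape)
            vessel_map[rr, cc] = True
        centerlines.append(Centerline(points=pts, vessel_class=truth.vessel_class,
                                      quadrant=truth.quadrant, vessel_id=vid))
    scene = VesselScene(vessel_map=vessel_map, centerlines=centerlines,
                        landmarks=landmarks, pixel_scale_um=pixel_scale_um)
    return scene, list(vessels)


# ---------------------------------------------------------------------------
# fractal fixtures
# ---------------------------------------------------------------------------

def gen_fractal_fixture(kind: str, depth: int = 5) -> tuple[np.ndarray, float]:
    """Binary fixture with an analytically known fractal dimension.

    ``line`` -> 1.0; ``filled_square`` -> 2.0; ``sierpinski_carpet`` ->
    log 8 / log 3.  All fixtures are 3**depth pixels on a side.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    size = 3 ** depth
    if kind == "line":
        img = np.zeros((size, size), dtype=bool)
        img[size // 2, :] = True
        return img, 1.0
    if kind == "filled_square":
        return np.ones((size, size), dtype=bool), 2.0
    if kind == "sierpinski_carpet":
        cell = np.ones((3, 3), dtype=np.uint8)
        cell[1, 1] = 0
        img = np.ones((1, 1), dtype=np.uint8)
        for _ in range(depth):
            img = np.kron(img, cell)
        return img.astype(bool), math.log(8) / math.log(3)
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# choroid volumes
# ---------------------------------------------------------------------------

@dataclass
class ChoroidTruth:
    luminal_fraction: float                     # realized over the whole volume
    lumen_shapes: list[list[tuple]] = field(default_factory=list)
    per_bscan_fraction: list[float] = field(default_factory=list)


def _pack_lumina(
    mask: np.ndarray,
    target_fraction: float,
    rng: np.random.Generator,
    margin_px: float = 5.0,
    tol_fraction: float = 0.005,
    max_proposals: int = 40000,
) -> tuple[np.ndarray, list[tuple]]:
    """Place dark elliptical lumina until the union area hits the target fraction.

    Ellipses may overlap; the rendered union is tracked incrementally and
    the final ellipse is shrunk so the realized fraction lands within
    ``tol_fraction`` of the request.  Every ellipse lies wholly at least
    ``margin_px`` inside the choroid mask.
    """
    area = int(mask.sum())
    target = target_fraction * area
    tol = tol_fraction * area
    lumen = np.zeros_like(mask)
    shapes: list[tuple] = []
    if target <= tol:
        return lumen, shapes
    region = distance_transform_edt(mask) > margin_px
    candidates = np.argwhere(region)
    if len(candidates) == 0:
        raise ValueError("choroid too thin for the requested lumen margin")
    current = 0
    for _ in range(max_proposals):
        deficit = target - current
        if deficit <= tol:
            break
        r0, c0 = candidates[rng.integers(len(candidates))]
        a_ax = rng.uniform(4.0, 11.0)
        b_ax = rng.uniform(3.0, 7.0)
        if math.pi * a_ax * b_ax > deficit + tol:
            shrink = math.sqrt(max(deficit, 8.0) / (math.pi * a_ax * b_ax))
            a_ax = max(a_ax * shrink, 1.4)
            b_ax = max(b_ax * shrink, 1.2)
        angle = rng.uniform(0.0, math.pi)
        rr, cc = draw_ellipse(r0, c0, b_ax, a_ax, rotation=angle, shape=mask.shape)
        if len(rr) == 0 or not region[rr, cc].all():
            continue
        new = int((~lumen[rr, cc]).sum())
        if current + new > target + tol:
            continue
        lumen[rr, cc] = True
        current += new
        shapes.append(((float(r0), float(c0)), (float(a_ax), float(b_ax)),
                       float(angle)))
    realized = current / area
    if abs(realized - target_fraction) > 2 * tol_fraction:
        raise RuntimeError(
            f"lumen packing stalled at fraction {realized:.3f} "
            f"(requested {target_fraction:.3f})")
    return lumen, shapes


def gen_choroid_volume(
    n_bscans: int = 25,
    luminal_fraction: float = 0.4,
    contrast: float = 80.0,
    noise_sd: float = 10.0,
    seed: int = 0,
    n_cols: int = 768,
    n_rows: int = 320,
    thickness_px: float = 110.0,
    bscan_spacing_mm: float = 0.25,
    col_pitch_mm: float | None = None,
    scan_width_mm: float = 9.0,
) -> tuple[ChoroidVolume, ChoroidTruth]:
    """Synthesize an OCT volume whose choroid has a known luminal fraction.

    Each B-scan carries smooth, non-crossing boundary polylines with a
    bright stroma in between and dark elliptical lumina (intensity
    ``stroma - contrast``) packed to the requested fraction (realized
    within +-0.01 by construction).  Gaussian noise of SD ``noise_sd`` is
    added on top.
    """
    if not (0.0 <= luminal_fraction <= 0.8):
        raise ValueError("luminal_fraction must lie in [0, 0.8]")
    rng = np.random.default_rng(seed)
    col_pitch_mm = col_pitch_mm if col_pitch_mm is not None else scan_width_mm / n_cols
    x = np.arange(n_cols)
    stroma, retina, sclera = 170.0, 110.0, 90.0

    images = np.empty((n_bscans, n_rows, n_cols), dtype=np.uint8)
    inner_b = np.empty((n_bscans, n_cols))
    outer_b = np.empty((n_bscans, n_cols))
    shapes_all, fractions = [], []
    lumen_area = choroid_area = 0
    for i in range(n_bscans):
        base = n_rows * 0.25 + 8.0 * np.sin(2 * math.pi * x / n_cols
                                            + rng.uniform(0, 2 * math.pi))
        thick = thickness_px + 5.0 * np.sin(2 * math.pi * x / n_cols
                                            + rng.uniform(0, 2 * math.pi))
        inner = base
        outer = base + np.maximum(thick, 8.0)
        if (inner >= outer).any():
            raise ValueError("boundary construction produced crossing polylines")
        rows = np.arange(n_rows)[:, None]
        mask = (rows > inner[None, :]) & (rows < outer[None, :])
        lumen, shapes = _pack_lumina(mask, luminal_fraction, rng)
        img = np.full((n_rows, n_cols), retina)
        img[rows.ravel()[:, None] >= outer[None, :]] = sclera
        img[mask] = stroma
        img[lumen] = stroma - contrast
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        images[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
        inner_b[i], outer_b[i] = inner, outer
        shapes_all.append(shapes)
        fractions.append(float(lumen.sum() / mask.sum()))
        lumen_area += int(lumen.sum())
        choroid_area += int(mask.sum())

    y0 = -(n_bscans - 1) * bscan_spacing_mm / 2.0
    volume = ChoroidVolume(
        images=images, inner_bounds=inner_b, outer_bounds=outer_b,
        col_pitch_mm=col_pitch_mm,
        bscan_y_mm=y0 + np.arange(n_bscans) * bscan_spacing_mm,
        x0_mm=-(n_cols - 1) * col_pitch_mm / 2.0,
    )
    truth = ChoroidTruth(luminal_fraction=lumen_area / choroid_area,
                         lumen_shapes=shapes_all, per_bscan_fraction=fractions)
    return volume, truth


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

@dataclass
class OutcomeSpec:
    """One outcome column of the synthetic cohort.

    ``beta_group`` is the planted DS-vs-CTRL effect on the linear
    predictor scale (mean difference for gaussian outcomes, log odds
    ratio for binomial ones).
    """

    name: str
    family: str = "gaussian"            # "gaussian" | "binomial"
    beta_group: float = 0.0
    intercept: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0               # effect of female vs male
    residual_sd: float = 1.0            # total SD (gaussian only)


@dataclass
class CohortSpec:
    """Design of a synthetic paired-eye cohort.

    Two eyes per participant (unless ``missing_eye_rate`` > 0) share a
    participant-level random effect ``b`` sized so that
    ``Var(b) / (Var(b) + Var(eps)) = rho`` -- the exchangeable
    within-participant correlation.  Age and sex distributions default to
    the study cohort (DS 39 +- 7 y, 37.5% female; CTRL 36 +- 9 y, 52.9%
    female).
    """

    n_per_group: int
    outcomes: list[OutcomeSpec]
    rho: float = 0.5
    missing_eye_rate: float = 0.0
    age_mean: tuple[float, float] = (36.0, 39.0)    # (CTRL, DS)
    age_sd: tuple[float, float] = (9.0, 7.0)
    p_female: tuple[float, float] = (0.529, 0.375)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 participants per group")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Generate an eye-level cohort table with planted group effects.

    Gaussian outcomes follow
    ``y = b0 + beta*group + ba*age + bs*sex + b_participant + eps`` with
    ``Var(b)/(Var(b)+Var(eps)) = rho`` and total residual SD as
    specified; binomial outcomes use the logistic analogue (random
    effect variance ``rho/(1-rho) * pi^2/3``).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    effects = {}
    for g_idx, group in enumerate(("CTRL", "DS")):
        for k in range(spec.n_per_group):
            pid = f"{group}{k:04d}"
            age = rng.normal(spec.age_mean[g_idx], spec.age_sd[g_idx])
            sex = "F" if rng.random() < spec.p_female[g_idx] else "M"
            eyes = ["OD", "OS"]
            if spec.missing_eye_rate > 0 and rng.random() < spec.missing_eye_rate:
                eyes = [eyes[int(rng.integers(2))]]
            b = {}
            for out in spec.outcomes:
                if out.family == "gaussian":
                    sd_b = math.sqrt(spec.rho) * out.residual_sd
                else:
                    sd_b = math.sqrt(spec.rho / (1 - spec.rho) * math.pi ** 2 / 3)
                b[out.name] = rng.normal(0.0, sd_b)
            for eye in eyes:
                row = {"participant_id": pid, "eye": eye, "group": group,
                       "age": age, "sex": sex}
                for out in spec.outcomes:
                    lp = (out.intercept + out.beta_group * (group == "DS")
                          + out.beta_age * age + out.beta_sex * (sex == "F")
                          + b[out.name])
                    if out.family == "gaussian":
                        sd_e = math.sqrt(1 - spec.rho) * out.residual_sd
                        row[out.name] = lp + rng.normal(0.0, sd_e)
                    else:
                        row[out.name] = int(rng.random() < 1 / (1 + math.exp(-lp)))
                rows.append(row)
        for out in spec.outcomes:
            effects[out.name] = out.beta_group
    table = pd.DataFrame(rows)
    truth = {"beta_group": effects, "rho": spec.rho,
             "n_per_group": spec.n_per_group}
    return table, truth
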