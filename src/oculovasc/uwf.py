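"""Ultra-widefield vessel-tree metrics.

Works on a :class:`VesselScene`: a binary vessel map plus labelled
arteriole/venule centerlines and anatomical landmarks (optic disc centre
and radius, fovea).  Four families of metrics are computed:

* **FD** -- fractal (branching-complexity) dimension of the vessel map by
  the sandbox method, within standard / posterior / mid-periphery regions
  of interest aligned to the disc-fovea axis;
* **WG / WI** -- width gradient (um/mm of taper along the path) and width
  intercept (caliber extrapolated to the disc edge, um), from a robust
  linear regression of caliber on arclength;
* **TORT** -- tortuosity density: the path is smoothed, split at
  inflection points of its discrete curvature, and each curve's
  arc-to-chord excess is accumulated;
* quadrant aggregation into temporal / nasal / global summaries per
  vessel class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_cdt, map_coordinates, uniform_filter1d

__all__ = [
    "Landmarks",
    "Centerline",
    "VesselScene",
    "ROISet",
    "WidthProfile",
    "build_roi_masks",
    "sandbox_fd",
    "box_count_fd",
    "sample_widths_along_path",
    "RobustWidthModel",
    "fit_width_model",
    "tortuosity_density",
    "aggregate_vessel_metrics",
]

QUADRANTS = ("ST", "SN", "IT", "IN")
TEMPORAL_QUADRANTS = ("ST", "IT")
NASAL_QUADRANTS = ("SN", "IN")


@dataclass
class Landmarks:
    """Anatomical landmarks in pixel coordinates (row, col)."""

    disc_center: tuple[float, float]
    disc_radius_px: float
    fovea: tuple[float, float]


@dataclass
class Centerline:
    """An ordered vessel path starting at the optic-disc edge."""

    points: np.ndarray                 # (n, 2) float, (row, col)
    vessel_class: str                  # "arteriole" | "venule"
    quadrant: str                      # ST | SN | IT | IN
    vessel_id: int = 0


@dataclass
class VesselScene:
    """Binary UWF vessel map with centerlines and landmarks."""

    vessel_map: np.ndarray             # 2-D bool
    centerlines: list[Centerline]
    landmarks: Landmarks
    pixel_scale_um: float = 10.0       # isotropic um per pixel

    def __post_init__(self) -> None:
        self.vessel_map = np.asarray(self.vessel_map, dtype=bool)

    @property
    def mm_per_px(self) -> float:
        return self.pixel_scale_um / 1000.0

    def centerline(self, vessel_id: int) -> Centerline:
        for c in self.centerlines:
            if c.vessel_id == vessel_id:
                return c
        raise KeyError(f"no centerline with vessel_id={vessel_id}")


@dataclass
class ROISet:
    """Binary region-of-interest masks; posterior and midperiphery partition standard."""

    standard: np.ndarray
    posterior: np.ndarray
    midperiphery: np.ndarray


@dataclass
class ROIGeometry:
    """Geometry of the analysis regions, in mm on the retina.

    The posterior region is an annulus from the disc edge out to
    ``posterior_radius_mm`` around the disc centre; the mid-periphery is
    the remainder of the standard region, a fovea-centred ellipse whose
    minor semi-axis (``mid_semi_minor_mm``) is perpendicular to the
    disc-fovea axis and whose major semi-axis lies along it.
    """

    posterior_radius_mm: float = 5.2
    mid_semi_minor_mm: float = 8.5
    standard_semi_major_mm: float = 12.0


def build_roi_masks(
    image_shape: tuple[int, int],
    landmarks: Landmarks,
    pixel_scale_um: float = 10.0,
    geometry: ROIGeometry | None = None,
) -> ROISet:
    """Build standard / posterior / mid-periphery masks aligned to the disc-fovea axis.

    The standard region is the union of the fovea-centred ellipse and the
    posterior annulus, always excluding the optic disc; posterior and
    mid-periphery partition it.
    """
    geometry = geometry or ROIGeometry()
    mm = pixel_scale_um / 1000.0
    dc = np.asarray(landmarks.disc_center, dtype=float)
    fv = np.asarray(landmarks.fovea, dtype=float)
    axis = fv - dc
    axis_len = np.hypot(*axis)
    if axis_len < 1e-9:
        raise ValueError("disc centre and fovea coincide; cannot orient the ROI axis")
    u = axis / axis_len                      # unit vector disc -> fovea
    v = np.array([-u[1], u[0]])              # perpendicular

    rows, cols = np.indices(image_shape)
    d_rows = (rows - fv[0]) * mm
    d_cols = (cols - fv[1]) * mm
    along = d_rows * u[0] + d_cols * u[1]    # mm along the disc-fovea axis
    across = d_rows * v[0] + d_cols * v[1]   # mm perpendicular to it
    ellipse = (along / geometry.standard_semi_major_mm) ** 2 + (
        across / geometry.mid_semi_minor_mm
    ) ** 2 <= 1.0

    disc_dist = np.hypot((rows - dc[0]) * mm, (cols - dc[1]) * mm)
    disc = disc_dist <= landmarks.disc_radius_px * mm
    annulus = (disc_dist <= geometry.posterior_radius_mm) & ~disc

    standard = (ellipse | annulus) & ~disc
    posterior = annulus
    midperiphery = standard & ~posterior
    return ROISet(standard=standard, posterior=posterior, midperiphery=midperiphery)


# ---------------------------------------------------------------------------
# fractal dimension
# ---------------------------------------------------------------------------

def _integral_image(img: np.ndarray) -> np.ndarray:
    s = np.zeros((img.shape[0] + 1, img.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=s[1:, 1:])
    return s


def _box_sums(integral: np.ndarray, centers: np.ndarray, r: int) -> np.ndarray:
    """Pixel counts in (2r+1)-squares centred on ``centers`` (clipped at edges)."""
    h, w = integral.shape[0] - 1, integral.shape[1] - 1
    r0 = np.clip(centers[:, 0] - r, 0, h)
    r1 = np.clip(centers[:, 0] + r + 1, 0, h)
    c0 = np.clip(centers[:, 1] - r, 0, w)
    c1 = np.clip(centers[:, 1] + r + 1, 0, w)
    return (integral[r1, c1] - integral[r0, c1]
            - integral[r1, c0] + integral[r0, c0])


def sandbox_fd(
    vessel_map: np.ndarray,
    roi_mask: np.ndarray | None = None,
    n_seeds: int = 500,
    radii: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    min_vessel_px: int = 100,
) -> float:
    """Sandbox-count fractal dimension of a binary structure.

    Seed pixels are drawn uniformly from structure pixels around which the
    largest sandbox still fits inside the region of interest.  For each
    half-width ``r`` the mean structure mass ``<M(r)>`` inside the
    (2r+1)-square is recorded; the dimension is the least-squares slope of
    ``log <M>`` against ``log (2r+1)``.  For an ideal fractal
    ``M ~ size^D``, so a 1-px line gives 1, a filled plane gives 2 and the
    Sierpinski carpet gives log 8 / log 3.

    Parameters
    ----------
    radii : array of int, optional
        Geometric series of half-widths.  Default: powers of two from 2 to
        the largest of {2,...,64} that admits at least one seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vessel_map = np.asarray(vessel_map, dtype=bool)
    if roi_mask is None:
        roi_mask = np.ones_like(vessel_map)
    roi_mask = np.asarray(roi_mask, dtype=bool)

    in_roi = vessel_map & roi_mask
    if in_roi.sum() < min_vessel_px:
        raise ValueError(
            f"too few structure pixels in ROI ({int(in_roi.sum())} < {min_vessel_px})")

    # chessboard distance to the ROI boundary (image border counts as boundary):
    # a box of half-width r centred on a pixel fits inside the ROI iff dist > r
    padded = np.pad(roi_mask, 1, constant_values=False)
    dist = distance_transform_cdt(padded, metric="chessboard")[1:-1, 1:-1]

    explicit = radii is not None
    if explicit:
        radii = np.asarray(sorted(int(r) for r in radii))
    else:
        # boxes wider than ~1/4 of the ROI extent mostly sense the region
        # boundary rather than the structure's scaling, so cap the series there
        rows_any = np.flatnonzero(roi_mask.any(axis=1))
        cols_any = np.flatnonzero(roi_mask.any(axis=0))
        extent = min(rows_any[-1] - rows_any[0], cols_any[-1] - cols_any[0]) + 1
        radii = np.array([r for r in (2, 4, 8, 16, 32, 64)
                          if 2 * r + 1 <= max(extent // 4, 11)])

    def admissible(r_max: int) -> np.ndarray:
        ok = in_roi & (dist > r_max)
        return np.argwhere(ok)

    seeds = admissible(int(radii[-1]))
    if explicit:
        if len(seeds) == 0:
            raise ValueError(
                f"no seed pixel admits the largest sandbox (half-width {radii[-1]}) "
                "inside the ROI")
    else:
        while len(seeds) == 0 and len(radii) > 3:
            radii = radii[:-1]
            seeds = admissible(int(radii[-1]))
        if len(seeds) == 0:
            raise ValueError("ROI too small: no seed admits a sandbox of half-width "
                             f"{radii[-1]}")

    if len(seeds) > n_seeds:
        idx = rng.choice(len(seeds), size=n_seeds, replace=False)
        seeds = seeds[idx]

    integral = _integral_image(in_roi.astype(np.int64))
    masses = [float(np.mean(_box_sums(integral, seeds, int(r)))) for r in radii]
    sizes = 2 * radii + 1
    slope, _ = np.polyfit(np.log(sizes), np.log(masses), 1)
    return float(slope)


def box_count_fd(binary: np.ndarray, sizes: np.ndarray | None = None) -> float:
    """Grid box-counting dimension: slope of log N(eps) vs log(1/eps).

    Independent of the sandbox estimator; used as a cross-check oracle.
    """
    binary = np.asarray(binary, dtype=bool)
    n = min(binary.shape)
    if sizes is None:
        sizes, s = [], 1
        while s <= n // 3:
            sizes.append(s)
            s *= 3
        sizes = np.array(sizes)
    counts = []
    for s in sizes:
        h = (binary.shape[0] // s) * s
        w = (binary.shape[1] // s) * s
        blocks = binary[:h, :w].reshape(h // s, s, w // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    slope, _ = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)), np.log(counts), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# vessel width profile and robust width model
# ---------------------------------------------------------------------------

@dataclass
class WidthProfile:
    """Caliber samples at regular arclength intervals along one vessel."""

    distances_mm: np.ndarray           # strictly increasing, from the disc edge
    widths_um: np.ndarray
    vessel_id: int = 0
    vessel_class: str = "arteriole"
    quadrant: str = "ST"


def _arclength(points: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample(points: np.ndarray, step_px: float) -> np.ndarray:
    s = _arclength(points)
    total = s[-1]
    if total <= 0:
        raise ValueError("zero-length centerline")
    t = np.arange(0.0, total + 1e-9, step_px)
    rows = np.interp(t, s, points[:, 0])
    cols = np.interp(t, s, points[:, 1])
    return np.column_stack([rows, cols])


def sample_widths_along_path(
    scene: VesselScene,
    vessel_id: int,
    interval_mm: float = 0.25,
    max_width_um: float = 600.0,
) -> WidthProfile:
    """Record vessel caliber at regular arclength intervals along the path.

    At each sample point the width is the edge-to-edge extent of the
    binary map along the local normal (bilinear interpolation, 0.5 level),
    converted to micrometres; the distance axis is arclength from the
    first centerline point (at the disc edge).
    """
    cl = scene.centerline(vessel_id)
    mm = scene.mm_per_px
    step_px = interval_mm / mm
    s_total = _arclength(cl.points)[-1]
    if s_total < 3 * step_px:
        raise ValueError("centerline shorter than 3 sampling intervals")

    samples = _resample(cl.points, step_px)
    # tangent via smoothed central differences
    smooth = uniform_filter1d(samples, size=3, axis=0, mode="nearest")
    tangents = np.gradient(smooth, axis=0)
    norms = np.hypot(*tangents.T)
    tangents /= np.where(norms == 0, 1, norms)[:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])

    img = scene.vessel_map.astype(float)
    probe_step = 0.2                       # px
    max_steps = int(max_width_um / scene.pixel_scale_um / probe_step) + 2
    offsets = np.arange(1, max_steps + 1) * probe_step

    widths_px = np.empty(len(samples))
    for i, (p, nrm) in enumerate(zip(samples, normals)):
        center_val = map_coordinates(img, [[p[0]], [p[1]]], order=1, mode="constant")[0]
        if center_val < 0.5:
            raise ValueError(
                f"centerline of vessel {vessel_id} leaves the vessel map at "
                f"sample {i} (row={p[0]:.1f}, col={p[1]:.1f})")
        extent = 0.0
        for sign in (+1.0, -1.0):
            pts = p[None, :] + sign * offsets[:, None] * nrm[None, :]
            vals = map_coordinates(img, [pts[:, 0], pts[:, 1]], order=1,
                                   mode="constant", cval=0.0)
            off_edge = np.flatnonzero(vals < 0.5)
            k = off_edge[0] if len(off_edge) else len(offsets)
            extent += k * probe_step
        widths_px[i] = extent

    distances = np.arange(len(samples)) * interval_mm
    return WidthProfile(
        distances_mm=distances,
        widths_um=widths_px * scene.pixel_scale_um,
        vessel_id=vessel_id,
        vessel_class=cl.vessel_class,
        quadrant=cl.quadrant,
    )


class RobustWidthModel:
    """Robust linear model of vessel caliber versus distance along the path.

    Fits ``width = WI + WG * distance`` with an M-estimator using the
    Tukey bisquare loss (tuning constant 4.685), iterated to convergence.
    The slope ``WG`` (um/mm; negative for tapering vessels) is the width
    gradient and the intercept ``WI`` (um) estimates caliber at the optic
    disc edge.

    Follows the scikit-learn estimator protocol: :meth:`fit` returns
    ``self`` and sets ``slope_`` / ``intercept_``.
    """

    def __init__(self, tuning_constant: float = 4.685, tol: float = 1e-8,
                 max_iter: int = 200):
        self.tuning_constant = tuning_constant
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"tuning_constant": self.tuning_constant, "tol": self.tol,
                "max_iter": self.max_iter}

    def set_params(self, **params) -> "RobustWidthModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, distances_mm, widths_um) -> "RobustWidthModel":
        import statsmodels.api as sm

        d = np.asarray(distances_mm, dtype=float).ravel()
        w = np.asarray(widths_um, dtype=float).ravel()
        if len(d) != len(w):
            raise ValueError("distances and widths differ in length")
        if len(d) < 5:
            raise ValueError("need at least 5 caliber samples")
        if np.ptp(d) < 1e-12:
            raise ValueError("degenerate profile: all distances equal")

        X = np.column_stack([np.ones_like(d), d])
        ols_coef, *_ = np.linalg.lstsq(X, w, rcond=None)
        resid = w - X @ ols_coef
        scale_ref = max(np.abs(w).max(), 1.0)
        if np.abs(resid).max() < 1e-9 * scale_ref:
            # exactly linear data: the M-estimator scale is zero, OLS is the MLE
            self.intercept_, self.slope_ = float(ols_coef[0]), float(ols_coef[1])
            self.n_samples_ = len(d)
            return self

        model = sm.RLM(w, X, M=sm.robust.norms.TukeyBiweight(c=self.tuning_constant))
        res = model.fit(maxiter=self.max_iter, tol=self.tol, conv="coefs",
                        start_params=ols_coef)
        self.intercept_, self.slope_ = float(res.params[0]), float(res.params[1])
        self.n_samples_ = len(d)
        return self

    def predict(self, distances_mm) -> np.ndarray:
        d = np.asarray(distances_mm, dtype=float)
        return self.intercept_ + self.slope_ * d


def fit_width_model(profile: WidthProfile, **kwargs) -> tuple[float, float]:
    """Return ``(WG, WI)`` = (slope um/mm, intercept um) for one profile."""
    m = RobustWidthModel(**kwargs).fit(profile.distances_mm, profile.widths_um)
    return m.slope_, m.intercept_


# ---------------------------------------------------------------------------
# tortuosity density
# ---------------------------------------------------------------------------

def tortuosity_density(
    points: np.ndarray,
    mm_per_px: float = 1.0,
    smooth_window: int = 5,
    curvature_eps: float = 1e-9,
) -> float:
    """Tortuosity density of a vessel path.

    The path is smoothed with a moving average, split into ``n`` curve
    segments at inflection points (sign changes of the discrete
    curvature), and scored as::

        TORT = ((n - 1) / n) * (1 / L_total) * sum_i (L_arc_i / L_chord_i - 1)

    with lengths in mm.  A path with no inflection (straight line, single
    arc) has n <= 1 and scores 0.
    """
    pts = np.asarray(points, dtype=float) * mm_per_px
    if len(pts) < 10:
        raise ValueError("need at least 10 path points")
    total_len = _arclength(pts)[-1]
    if total_len <= 0:
        raise ValueError("zero-length path")

    smooth = uniform_filter1d(pts, size=max(1, smooth_window), axis=0, mode="nearest")

    # discrete curvature sign via the cross product of successive segments
    d1 = np.diff(smooth, axis=0)
    cross = d1[:-1, 0] * d1[1:, 1] - d1[:-1, 1] * d1[1:, 0]
    seg_scale = np.hypot(*d1.T).mean()
    signs = np.zeros(len(cross), dtype=int)
    signs[cross > curvature_eps * max(seg_scale, 1e-12) ** 2] = 1
    signs[cross < -curvature_eps * max(seg_scale, 1e-12) ** 2] = -1

    # inflection = sign change between consecutive non-zero curvature samples
    nz = np.flatnonzero(signs)
    boundaries = []
    for a, b in zip(nz[:-1], nz[1:]):
        if signs[a] != signs[b]:
            boundaries.append((a + b) // 2 + 1)   # vertex index in `smooth`
    n_curves = len(boundaries) + 1
    if n_curves <= 1:
        return 0.0

    cuts = [0] + boundaries + [len(smooth) - 1]
    excess = 0.0
    for a, b in zip(cuts[:-1], cuts[1:]):
        seg = smooth[a:b + 1]
        arc = _arclength(seg)[-1]
        chord = float(np.hypot(*(seg[-1] - seg[0])))
        if chord > 0:
            excess += arc / chord - 1.0
    return float((n_curves - 1) / n_curves / total_len * excess)


# ---------------------------------------------------------------------------
# quadrant aggregation
# ---------------------------------------------------------------------------

def aggregate_vessel_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Average per-vessel metrics into temporal / nasal / global scopes per class.

    ``records`` must carry columns ``vessel_class``, ``quadrant`` and one
    or more metric columns (e.g. WG, WI, TORT).  Temporal averages the
    {ST, IT} quadrants, nasal {SN, IN}, global all four.  A scope with no
    vessels yields NaN, never zero.
    """
    records = pd.DataFrame(records)
    required = {"vessel_class", "quadrant"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    metrics = [c for c in records.columns if c not in ("vessel_class", "quadrant",
                                                       "vessel_id")]
    scopes = {
        "temporal": list(TEMPORAL_QUADRANTS),
        "nasal": list(NASAL_QUADRANTS),
        "global": list(QUADRANTS),
    }
    rows = []
    for vclass, sub in records.groupby("vessel_class"):
        for scope, quads in scopes.items():
            sel = sub[sub["quadrant"].isin(quads)]
            row = {"vessel_class": vclass, "scope": scope}
            for m in metrics:
                row[m] = float(sel[m].mean()) if len(sel) else np.nan
            rows.append(row)
    return pd.DataFrame(rows).set_index(["vessel_class", "scope"])
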