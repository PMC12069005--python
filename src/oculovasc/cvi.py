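"""Choroidal vascularity index (CVI) from OCT macular volumes.

The choroid lies between Bruch's membrane (inner boundary) and the
choroidal-scleral interface (outer boundary).  On an OCT B-scan its
vessel lumina appear dark and the stroma bright; the CVI is the luminal
fraction of the total choroidal area.

Per B-scan the pipeline is: crop the choroid between the two boundary
polylines, Gaussian-smooth (sigma = 0.5 px), rescale to 8 bit within the
choroid mask, and binarize by local Otsu thresholding at multiple
neighborhood scales.  At each scale ``r`` only dark (sub-threshold)
pixels lying deeper than ``r`` from the choroid edge are accepted, which
suppresses boundary artifacts where the Otsu window leaves the tissue.
Accepted pixels from all scales are accumulated into one image before a
single morphological opening (3x3 cross) and small-component removal.
The result is the luminal area (LA); the stromal area (SA) is its
complement within the mask.

Per-column luminal/total counts are projected onto an en-face map (one
row per B-scan, no interpolation between scans) and pooled per sector of
the fovea-centred ETDRS grid (circles of 1, 3 and 6 mm diameter split by
the +-45 degree diagonals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt, gaussian_filter
from skimage.filters.rank import maximum as rank_maximum
from skimage.filters.rank import minimum as rank_minimum
from skimage.filters.rank import otsu as rank_otsu
from skimage.morphology import dilation, erosion, remove_small_objects

__all__ = [
    "ChoroidVolume",
    "ChoroidStrip",
    "BinarizedChoroid",
    "CVIMap",
    "crop_choroid",
    "binarize_choroid",
    "compute_cvi",
    "build_cvi_map",
    "etdrs_sector_stats",
    "volume_cvi",
]

DEFAULT_SCALES_PX = (4, 8, 16, 32)
ETDRS_SECTORS = ("CC", "SI", "NI", "II", "TI", "SO", "NO", "IO", "TO",
                 "inner_ring", "outer_ring", "global")

_CROSS = np.array([[0, 1, 0],
                   [1, 1, 1],
                   [0, 1, 0]], dtype=bool)


@dataclass
class ChoroidVolume:
    """An OCT macular volume with per-B-scan choroid boundary polylines.

    ``inner_bounds`` / ``outer_bounds`` give, for each B-scan and A-scan
    column, the row of Bruch's membrane and of the choroidal-scleral
    interface.  ``bscan_y_mm`` locates each B-scan on the fundus;
    ``col_pitch_mm`` is the A-scan pitch.
    """

    images: np.ndarray                 # (n_bscans, n_rows, n_cols) grayscale
    inner_bounds: np.ndarray           # (n_bscans, n_cols) float rows
    outer_bounds: np.ndarray           # (n_bscans, n_cols) float rows
    col_pitch_mm: float
    bscan_y_mm: np.ndarray             # (n_bscans,) fundus y per B-scan
    x0_mm: float = 0.0                 # fundus x of column 0

    @property
    def n_bscans(self) -> int:
        return self.images.shape[0]


@dataclass
class ChoroidStrip:
    """One B-scan's choroid: intensities plus the mask between the boundaries."""

    image: np.ndarray                  # full-height B-scan intensities (float)
    mask: np.ndarray                   # bool, True strictly between the boundaries
    inner: np.ndarray                  # per-column inner boundary rows
    outer: np.ndarray


@dataclass
class BinarizedChoroid:
    """Luminal/stromal partition of one choroid strip (LA | SA = mask)."""

    la: np.ndarray                     # bool luminal (dark) pixels
    sa: np.ndarray                     # bool stromal (bright) pixels
    mask: np.ndarray = field(repr=False, default=None)


@dataclass
class CVIMap:
    """En-face grid of per-cell (luminal, total) choroid pixel counts."""

    la: np.ndarray                     # (n_bscans, n_cols) luminal counts
    total: np.ndarray                  # (n_bscans, n_cols) choroid counts
    x_mm: np.ndarray                   # (n_cols,) fundus x per column
    y_mm: np.ndarray                   # (n_bscans,) fundus y per row

    @property
    def cvi(self) -> np.ndarray:
        """Per-cell luminal fraction; NaN where the cell carries no data."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.la / self.total, np.nan)


def crop_choroid(
    bscan: np.ndarray,
    inner_boundary: np.ndarray,
    outer_boundary: np.ndarray,
) -> ChoroidStrip:
    """Mask the pixels strictly between the two boundary polylines.

    Raises if the boundaries cross (inner at or below outer) at any
    A-scan, naming the first offending column, or if the mask is empty.
    """
    bscan = np.asarray(bscan, dtype=float)
    inner = np.asarray(inner_boundary, dtype=float)
    outer = np.asarray(outer_boundary, dtype=float)
    if inner.shape != (bscan.shape[1],) or outer.shape != (bscan.shape[1],):
        raise ValueError("boundaries must give one row per A-scan column")
    crossing = np.flatnonzero(inner >= outer)
    if len(crossing):
        raise ValueError(
            f"boundaries cross at A-scan column {int(crossing[0])} "
            f"(inner={inner[crossing[0]]:.1f} >= outer={outer[crossing[0]]:.1f})")
    rows = np.arange(bscan.shape[0])[:, None]
    mask = (rows > inner[None, :]) & (rows < outer[None, :])
    if not mask.any():
        raise ValueError("choroid mask is empty: boundaries enclose no pixel rows")
    return ChoroidStrip(image=bscan, mask=mask, inner=inner, outer=outer)


def _to_uint8_in_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max rescale within the mask to 8 bit (Otsu is affine-invariant)."""
    vals = image[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.uint8)
    out = np.clip((image - lo) / (hi - lo), 0.0, 1.0)
    return np.round(out * 255).astype(np.uint8)


def binarize_choroid(
    strip: ChoroidStrip,
    scales: tuple[int, ...] = DEFAULT_SCALES_PX,
    min_region_px: int = 10,
    sigma: float = 0.5,
    local_contrast_min: float = 0.4,
) -> BinarizedChoroid:
    """Multi-scale local-Otsu binarization of the choroid with distance gating.

    See the module docstring for the full recipe.  ``scales`` are the
    Otsu neighborhood radii in pixels; each must be smaller than the
    minimum strip thickness.

    Otsu assumes the window is bimodal; in a window containing only
    stroma it would simply split the noise.  A window therefore
    contributes dark pixels only when its local dynamic range exceeds
    ``local_contrast_min`` of the 8-bit range (the within-mask tissue
    range, so the gate -- like Otsu itself -- is invariant to affine
    intensity rescaling).
    """
    if not scales:
        raise ValueError("need at least one Otsu scale")
    mask = strip.mask
    thickness = (strip.outer - strip.inner - 1).min()
    if max(scales) >= thickness:
        raise ValueError(
            f"Otsu radius {max(scales)} px >= minimum strip thickness "
            f"{thickness:.0f} px")

    smoothed = gaussian_filter(strip.image.astype(float), sigma=sigma)
    img8 = _to_uint8_in_mask(smoothed, mask)
    dist = distance_transform_edt(mask)

    accepted = np.zeros(mask.shape, dtype=bool)
    mask_u8 = mask.astype(np.uint8)
    gate_levels = local_contrast_min * 255.0
    for r in scales:
        footprint = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        thresh = rank_otsu(img8, footprint=footprint, mask=mask_u8)
        local_range = (rank_maximum(img8, footprint=footprint, mask=mask_u8).astype(int)
                       - rank_minimum(img8, footprint=footprint, mask=mask_u8).astype(int))
        dark = (img8 <= thresh) & mask & (local_range >= gate_levels)
        accepted |= dark & (dist > r)

    opened = dilation(erosion(accepted, _CROSS), _CROSS)
    # drop components smaller than min_region_px (max_size is inclusive)
    la = remove_small_objects(opened, max_size=min_region_px - 1) & mask
    sa = mask & ~la
    return BinarizedChoroid(la=la, sa=sa, mask=mask)


def compute_cvi(binarized: BinarizedChoroid, region: np.ndarray | None = None) -> float:
    """Luminal fraction |LA & region| / |choroid & region| (region defaults to all)."""
    mask = binarized.mask if binarized.mask is not None else binarized.la | binarized.sa
    if region is None:
        region = np.ones_like(mask)
    denom = int((mask & region).sum())
    if denom == 0:
        raise ValueError("region does not intersect the choroid mask")
    return float((binarized.la & region).sum() / denom)


def build_cvi_map(
    binarized: list[BinarizedChoroid],
    volume: ChoroidVolume,
) -> CVIMap:
    """Project per-column luminal/total counts onto the en-face grid.

    One map row per B-scan at its fundus y; cells between B-scans carry
    no data (total = 0), with no interpolation.
    """
    if len(binarized) < 2:
        raise ValueError("need at least 2 B-scans for a map")
    widths = {b.la.shape[1] for b in binarized}
    if len(widths) != 1:
        raise ValueError(f"inconsistent per-B-scan widths: {sorted(widths)}")
    n_cols = widths.pop()
    la = np.stack([b.la.sum(axis=0) for b in binarized])
    total = np.stack([(b.la | b.sa).sum(axis=0) for b in binarized])
    x_mm = volume.x0_mm + np.arange(n_cols) * volume.col_pitch_mm
    return CVIMap(la=la.astype(np.int64), total=total.astype(np.int64),
                  x_mm=x_mm, y_mm=np.asarray(volume.bscan_y_mm, dtype=float))


def _etdrs_sector_of(dx: np.ndarray, dy: np.ndarray,
                     diameters: tuple[float, float, float]) -> np.ndarray:
    """Sector label per cell; '' outside the grid.  +x nasal, +y superior."""
    r_cc, r_in, r_out = (d / 2.0 for d in diameters)
    d = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    quad = np.full(d.shape, "T", dtype="<U1")
    quad[(ang >= 45.0) & (ang < 135.0)] = "S"
    quad[(ang >= 135.0) & (ang < 225.0)] = "T"
    quad[(ang >= 225.0) & (ang < 315.0)] = "I"
    quad[(ang >= 315.0) | (ang < 45.0)] = "N"
    out = np.full(d.shape, "", dtype="<U2")
    out[d <= r_cc] = "CC"
    ring_in = (d > r_cc) & (d <= r_in)
    ring_out = (d > r_in) & (d <= r_out)
    out[ring_in] = np.char.add(quad[ring_in], "I")
    out[ring_out] = np.char.add(quad[ring_out], "O")
    return out


def etdrs_sector_stats(
    cvi_map: CVIMap,
    fovea_xy_mm: tuple[float, float],
    diameters: tuple[float, float, float] = (1.0, 3.0, 6.0),
    nasal_positive_x: bool = True,
) -> pd.Series:
    """Pooled CVI per ETDRS sector, ring and globally.

    Sector CVI is ``sum(LA) / sum(total)`` over populated cells inside
    the sector footprint -- rings and the global value pool cells rather
    than averaging sector means.  A sector with no populated cell yields
    NaN.  ``nasal_positive_x=False`` mirrors the grid for left eyes.
    """
    fx, fy = fovea_xy_mm
    dx = cvi_map.x_mm[None, :] - fx
    dy = cvi_map.y_mm[:, None] - fy
    dx, dy = np.broadcast_arrays(dx, dy)
    if not nasal_positive_x:
        dx = -dx
    populated = cvi_map.total > 0
    if not (populated & (np.hypot(dx, dy) <= diameters[2] / 2)).any():
        raise ValueError("map does not cover the ETDRS grid footprint")
    labels = _etdrs_sector_of(dx, dy, diameters)

    def pooled(sel: np.ndarray) -> float:
        sel = sel & populated
        tot = cvi_map.total[sel].sum()
        return float(cvi_map.la[sel].sum() / tot) if tot > 0 else math.nan

    stats = {}
    for sector in ("CC", "SI", "NI", "II", "TI", "SO", "NO", "IO", "TO"):
        stats[sector] = pooled(labels == sector)
    inner = np.isin(labels, ["SI", "NI", "II", "TI"])
    outer = np.isin(labels, ["SO", "NO", "IO", "TO"])
    stats["inner_ring"] = pooled(inner)
    stats["outer_ring"] = pooled(outer)
    stats["global"] = pooled(labels != "")
    return pd.Series(stats, name="cvi")


def volume_cvi(
    volume: ChoroidVolume,
    scales: tuple[int, ...] = DEFAULT_SCALES_PX,
    min_region_px: int = 10,
) -> tuple[list[BinarizedChoroid], CVIMap, float]:
    """Binarize every B-scan of a volume; return (per-scan results, map, global CVI)."""
    binarized = []
    for i in range(volume.n_bscans):
        strip = crop_choroid(volume.images[i], volume.inner_bounds[i],
                             volume.outer_bounds[i])
        binarized.append(binarize_choroid(strip, scales=scales,
                                          min_region_px=min_region_px))
    cvi_map = build_cvi_map(binarized, volume)
    total_la = sum(int(b.la.sum()) for b in binarized)
    total = sum(int((b.la | b.sa).sum()) for b in binarized)
    return binarized, cvi_map, total_la / total
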