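"""Reading and writing the pipeline's file formats.

Images travel as 8-bit grayscale TIFF or PNG; geometry (boundary
polylines, centerlines, landmarks, pixel scales) as JSON sidecars;
tables as CSV.  These mirror a scanner-export workflow where images and
their coordinate metadata arrive as separate files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .cvi import ChoroidVolume, CVIMap
from .ringscan import OCTRingScan
from .uwf import Centerline, Landmarks, VesselScene

__all__ = [
    "save_ring_scan", "load_ring_scan",
    "save_vessel_scene", "load_vessel_scene",
    "save_choroid_volume", "load_choroid_volume",
    "save_cvi_map_png",
]


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2))


def save_ring_scan(scan: OCTRingScan, image_path, meta_path) -> None:
    tifffile.imwrite(str(image_path), np.asarray(scan.image, dtype=np.uint8))
    _write_json(Path(meta_path), {
        "transverse_scale_um": scan.transverse_scale_um,
        "axial_scale_um": scan.axial_scale_um,
        "ring_diameter_mm": scan.ring_diameter_mm,
    })


def load_ring_scan(image_path, meta_path) -> OCTRingScan:
    img = tifffile.imread(str(image_path))
    meta = json.loads(Path(meta_path).read_text())
    return OCTRingScan(image=img, **meta)


def save_vessel_scene(scene: VesselScene, image_path, sidecar_path) -> None:
    Image.fromarray((scene.vessel_map.astype(np.uint8)) * 255).save(str(image_path))
    _write_json(Path(sidecar_path), {
        "pixel_scale_um": scene.pixel_scale_um,
        "landmarks": {
            "disc_center": list(scene.landmarks.disc_center),
            "disc_radius_px": scene.landmarks.disc_radius_px,
            "fovea": list(scene.landmarks.fovea),
        },
        "centerlines": [
            {"vessel_id": c.vessel_id, "vessel_class": c.vessel_class,
             "quadrant": c.quadrant, "points": np.asarray(c.points).tolist()}
            for c in scene.centerlines
        ],
    })


def load_vessel_scene(image_path, sidecar_path) -> VesselScene:
    img = np.asarray(Image.open(str(image_path))) > 127
    meta = json.loads(Path(sidecar_path).read_text())
    lm = meta["landmarks"]
    return VesselScene(
        vessel_map=img,
        centerlines=[
            Centerline(points=np.asarray(c["points"], dtype=float),
                       vessel_class=c["vessel_class"], quadrant=c["quadrant"],
                       vessel_id=c["vessel_id"])
            for c in meta["centerlines"]
        ],
        landmarks=Landmarks(disc_center=tuple(lm["disc_center"]),
                            disc_radius_px=lm["disc_radius_px"],
                            fovea=tuple(lm["fovea"])),
        pixel_scale_um=meta["pixel_scale_um"],
    )


def save_choroid_volume(volume: ChoroidVolume, stack_path, sidecar_path) -> None:
    tifffile.imwrite(str(stack_path), np.asarray(volume.images, dtype=np.uint8))
    _write_json(Path(sidecar_path), {
        "inner_bounds": np.asarray(volume.inner_bounds).tolist(),
        "outer_bounds": np.asarray(volume.outer_bounds).tolist(),
        "col_pitch_mm": volume.col_pitch_mm,
        "bscan_y_mm": np.asarray(volume.bscan_y_mm).tolist(),
        "x0_mm": volume.x0_mm,
    })


def load_choroid_volume(stack_path, sidecar_path) -> ChoroidVolume:
    images = tifffile.imread(str(stack_path))
    meta = json.loads(Path(sidecar_path).read_text())
    return ChoroidVolume(
        images=images,
        inner_bounds=np.asarray(meta["inner_bounds"], dtype=float),
        outer_bounds=np.asarray(meta["outer_bounds"], dtype=float),
        col_pitch_mm=meta["col_pitch_mm"],
        bscan_y_mm=np.asarray(meta["bscan_y_mm"], dtype=float),
        x0_mm=meta["x0_mm"],
    )


def save_cvi_map_png(cvi_map: CVIMap, image_path, meta_path, nodata: int = 255) -> None:
    """Serialize the en-face CVI map: fraction scaled to 0-254, no-data = 255."""
    frac = cvi_map.cvi
    img = np.full(frac.shape, nodata, dtype=np.uint8)
    ok = np.isfinite(frac)
    img[ok] = np.clip(np.round(frac[ok] * 254), 0, 254).astype(np.uint8)
    Image.fromarray(img).save(str(image_path))
    _write_json(Path(meta_path), {
        "scale": "cvi = pixel_value / 254; 255 = no data",
        "x_mm": cvi_map.x_mm.tolist(),
        "y_mm": cvi_map.y_mm.tolist(),
    })
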