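"""Zoning and hierarchical phenotyping of peripheral microvascular lesions.

Graded lesions (microaneurysms: small round red dots; hemorrhages:
irregular red patches near vessels) are located in fovea-centred fundus
coordinates (mm) and assigned to the zones of a fovea-centred grading
grid -- central (posterior pole), mid-peripheral and far-peripheral --
split into temporal and nasal hemispheres by the vertical line through
the fovea.

Coordinate convention: +x runs along the disc-fovea axis toward the disc
(nasal) for a right eye (OD); left-eye (OS) annotations are mirrored so
that temporal keeps a consistent sign.  Boundary circles belong to the
inner zone; a lesion exactly on the vertical split (x = 0) is temporal.

Eyes are phenotyped hierarchically: any hemorrhage puts the eye in the
hemorrhage group, microaneurysms alone in the microaneurysm group, no
lesion means negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "LesionRecord",
    "MoorfieldsGrid",
    "EyePhenotype",
    "assign_zone",
    "phenotype_eye",
    "zone_counts",
]

LESION_TYPES = ("microaneurysm", "hemorrhage")
ZONES = ("central", "mid", "far")
HEMISPHERES = ("temporal", "nasal")


@dataclass(frozen=True)
class LesionRecord:
    type: str                   # "microaneurysm" | "hemorrhage"
    x_mm: float                 # fovea-centred; +x nasal for OD image coords
    y_mm: float

    def __post_init__(self) -> None:
        if self.type not in LESION_TYPES:
            raise ValueError(f"unknown lesion type {self.type!r}")


@dataclass(frozen=True)
class MoorfieldsGrid:
    """Fovea-centred zone radii in mm; boundaries belong to the inner zone."""

    central_r_mm: float = 10.0
    mid_r_mm: float = 15.0

    def __post_init__(self) -> None:
        if not 0 < self.central_r_mm < self.mid_r_mm:
            raise ValueError("grid radii must satisfy 0 < central_r < mid_r")


@dataclass(frozen=True)
class EyePhenotype:
    any_abnormality: bool
    group: str                  # "negative" | "microaneurysm" | "hemorrhage"


def assign_zone(
    lesion: LesionRecord,
    grid: MoorfieldsGrid = MoorfieldsGrid(),
    laterality: str = "OD",
) -> tuple[str, str]:
    """Map a lesion to (zone, hemisphere) on the fovea-centred grid.

    Zone by Euclidean distance from the fovea against the grid radii;
    hemisphere by the sign of the laterality-normalized horizontal
    coordinate (x <= 0 is temporal; the tie at the fovea goes temporal).
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    d = (lesion.x_mm ** 2 + lesion.y_mm ** 2) ** 0.5
    if d <= grid.central_r_mm:
        zone = "central"
    elif d <= grid.mid_r_mm:
        zone = "mid"
    else:
        zone = "far"
    x_norm = lesion.x_mm if laterality == "OD" else -lesion.x_mm
    hemisphere = "temporal" if x_norm <= 0 else "nasal"
    return zone, hemisphere


def phenotype_eye(lesions: list[LesionRecord]) -> EyePhenotype:
    """Hierarchical eye phenotype from its lesion list.

    Empty -> negative; only microaneurysms -> microaneurysm; any
    hemorrhage (alone or with microaneurysms) -> hemorrhage.
    """
    types = {l.type for l in lesions}
    unknown = types - set(LESION_TYPES)
    if unknown:
        raise ValueError(f"unknown lesion types: {sorted(unknown)}")
    if not types:
        return EyePhenotype(any_abnormality=False, group="negative")
    group = "hemorrhage" if "hemorrhage" in types else "microaneurysm"
    return EyePhenotype(any_abnormality=True, group=group)


def zone_counts(
    lesions: list[LesionRecord],
    grid: MoorfieldsGrid = MoorfieldsGrid(),
    laterality: str = "OD",
) -> pd.DataFrame:
    """Lesion counts per (zone, hemisphere, type), including zero cells."""
    idx = pd.MultiIndex.from_product(
        [ZONES, HEMISPHERES, LESION_TYPES], names=["zone", "hemisphere", "type"])
    counts = pd.Series(0, index=idx, name="count")
    for lesion in lesions:
        zone, hemi = assign_zone(lesion, grid, laterality)
        counts.loc[(zone, hemi, lesion.type)] += 1
    return counts.reset_index()
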