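"""Synthetic pelvic activity phantoms.

Patient ⁹⁹ᵐTc-PSMA SPECT volumes show a focal high-uptake prostate lesion
(ROI1), physiologic renal-cortex uptake (ROI2), tracer pooling in the
bladder, and low soft-tissue background.  This module builds digital
stand-ins for such volumes as sums of constant-activity ellipsoids on a
regular voxel grid, together with ground-truth region-of-interest masks.

Conventions
-----------
* World coordinates are in millimetres with the origin at the grid centre.
* Voxel membership is decided at the voxel centre.
* Organs are additive: a voxel inside several ellipsoids carries the sum
  of their activities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

ORGAN_LABELS = ("lesion", "renal_cortex_left", "renal_cortex_right", "bladder", "background")
RENAL_LABELS = ("renal_cortex_left", "renal_cortex_right")


@dataclass(frozen=True)
class GridSpec:
    """Isotropic voxel grid: ``nx × ny × nz`` voxels of edge ``voxel_size_mm``."""

    nx: int
    ny: int
    nz: int
    voxel_size_mm: float = 4.43

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical edge lengths (mm) of the grid box along x, y, z."""
        return np.array(self.shape, dtype=float) * self.voxel_size_mm

    def axis_centers_mm(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis, origin at the grid centre."""
        n = self.shape[axis]
        return (np.arange(n) + 0.5 - n / 2.0) * self.voxel_size_mm

    def center_grids_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(
            self.axis_centers_mm(0),
            self.axis_centers_mm(1),
            self.axis_centers_mm(2),
            indexing="ij",
        )


@dataclass(frozen=True)
class OrganSpec:
    """Constant-activity ellipsoid.

    ``activity`` is an emission rate per voxel in arbitrary counts-proportional
    units; absolute calibration happens later via the sinogram count budget.
    """

    label: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    activity: float

    def __post_init__(self) -> None:
        if self.label not in ORGAN_LABELS:
            raise ValueError(f"unknown organ label {self.label!r}; expected one of {ORGAN_LABELS}")
        if not all(a > 0 for a in self.semi_axes_mm):
            raise ValueError(f"organ {self.label!r}: semi-axes must all be > 0")
        if self.activity < 0:
            raise ValueError(f"organ {self.label!r}: activity must be >= 0")


@dataclass
class ActivityPhantom:
    """Ground-truth emission-rate volume (the unknown image OSEM estimates)."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("phantom values must be finite and non-negative")


@dataclass
class ROIMask:
    """Boolean region-of-interest mask: ROI1 = lesion, ROI2 = renal cortex."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.label not in ("ROI1", "ROI2"):
            raise ValueError("ROI label must be 'ROI1' or 'ROI2'")
        if not self.mask.any():
            raise ValueError(f"{self.label}: mask has no true voxel")


def _ellipsoid_mask(organ: OrganSpec, grid: GridSpec) -> np.ndarray:
    xs, ys, zs = grid.center_grids_mm()
    c = np.asarray(organ.center_mm, dtype=float)
    a = np.asarray(organ.semi_axes_mm, dtype=float)
    q = ((xs - c[0]) / a[0]) ** 2 + ((ys - c[1]) / a[1]) ** 2 + ((zs - c[2]) / a[2]) ** 2
    return q <= 1.0


def _check_inside_extent(organ: OrganSpec, grid: GridSpec) -> None:
    half = grid.extent_mm / 2.0
    c = np.abs(np.asarray(organ.center_mm, dtype=float))
    a = np.asarray(organ.semi_axes_mm, dtype=float)
    if np.any(c + a > half + 1e-9):
        raise ValueError(
            f"organ {organ.label!r} extends outside the grid extent "
            f"(|center| + semi-axes = {c + a}, half-extent = {half})"
        )


def generate_pelvic_phantom(organs: list[OrganSpec], grid: GridSpec) -> ActivityPhantom:
    """Sum constant-activity ellipsoids into a voxel grid.

    Each voxel's value is the sum of the activities of every ellipsoid whose
    surface encloses the voxel centre.  Deterministic; an empty organ list
    yields an all-zero phantom.
    """
    values = np.zeros(grid.shape, dtype=float)
    for organ in organs:
        _check_inside_extent(organ, grid)
        values[_ellipsoid_mask(organ, grid)] += organ.activity
    return ActivityPhantom(values=values, grid=grid)


def roi_masks(organs: list[OrganSpec], grid: GridSpec) -> list[ROIMask]:
    """Ground-truth ROI masks: ROI1 = lesion voxels, ROI2 = renal-cortex voxels.

    Masks come from the generating ellipsoids, not from reconstructed images,
    so the evaluation metrics are deterministic.
    """
    lesions = [o for o in organs if o.label == "lesion"]
    if not lesions:
        raise ValueError("organ list has no 'lesion' organ; ROI1 undefined")
    renals = [o for o in organs if o.label in RENAL_LABELS]
    if not renals:
        raise ValueError("organ list has no renal cortex organ; ROI2 undefined")
    roi1 = np.zeros(grid.shape, dtype=bool)
    for o in lesions:
        roi1 |= _ellipsoid_mask(o, grid)
    roi2 = np.zeros(grid.shape, dtype=bool)
    for o in renals:
        roi2 |= _ellipsoid_mask(o, grid)
    return [ROIMask("ROI1", roi1), ROIMask("ROI2", roi2)]


def default_pelvic_organs() -> list[OrganSpec]:
    """Clinical-like default anatomy for a pelvic field of view.

    Contrast ordering mirrors ⁹⁹ᵐTc-PSMA uptake: bladder (10) > lesion (8) >
    renal cortex (6) > background (1).  Sized to fit a 64×64×16 grid at
    4.43 mm voxels; all values configurable via YAML.
    """
    return [
        OrganSpec("background", (0.0, 0.0, 0.0), (120.0, 100.0, 34.0), 1.0),
        OrganSpec("lesion", (0.0, -40.0, 0.0), (12.0, 12.0, 10.0), 8.0),
        OrganSpec("renal_cortex_left", (60.0, 45.0, 8.0), (16.0, 12.0, 14.0), 6.0),
        OrganSpec("renal_cortex_right", (-60.0, 45.0, 8.0), (16.0, 12.0, 14.0), 6.0),
        OrganSpec("bladder", (0.0, -5.0, 0.0), (16.0, 14.0, 12.0), 10.0),
    ]


def default_grid() -> GridSpec:
    """Desk-scale default grid (clinical 128³ supported via config)."""
    return GridSpec(64, 64, 16, 4.43)


def organs_from_yaml(text: str) -> list[OrganSpec]:
    """Parse an ``organs:`` list (label / center_mm / semi_axes_mm / activity)."""
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "organs" not in doc:
        raise ValueError("YAML must contain an 'organs:' list")
    organs = []
    for entry in doc["organs"]:
        organs.append(
            OrganSpec(
                label=entry["label"],
                center_mm=tuple(float(v) for v in entry["center_mm"]),
                semi_axes_mm=tuple(float(v) for v in entry["semi_axes_mm"]),
                activity=float(entry["activity"]),
            )
        )
    return organs


def organs_to_yaml(organs: list[OrganSpec]) -> str:
    doc = {
        "organs": [
            {
                "label": o.label,
                "center_mm": list(o.center_mm),
                "semi_axes_mm": list(o.semi_axes_mm),
                "activity": o.activity,
            }
            for o in organs
        ]
    }
    return yaml.safe_dump(doc, sort_keys=False)
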