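"""Volume, sinogram and table serialisation.

Volumes (phantoms, masks, reconstructions) are NIfTI-1 with an affine whose
scale is the voxel size and whose origin sits at the grid centre, matching
the world-coordinate convention of the phantom module.  Sinograms are
NIfTI-1 arrays with a JSON sidecar carrying the projection geometry; the
round trip is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .metrics import METRICS_COLUMNS
from .phantom import GridSpec, ActivityPhantom, ROIMask
from .projection import ProjectionGeometry, Sinogram
from .reconstruction import ReconVolume


def _affine(voxel_size_mm: float, shape: tuple[int, ...]) -> np.ndarray:
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(shape, dtype=float) / 2.0 - 0.5) * voxel_size_mm
    return aff


def save_volume(path: str | Path, values: np.ndarray, grid: GridSpec, description: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine(grid.voxel_size_mm, values.shape))
    img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    voxel = round(float(img.header.get_zooms()[0]), 5)  # zooms are float32
    nx, ny, nz = values.shape
    return values, GridSpec(nx, ny, nz, voxel)


def save_phantom(path: str | Path, phantom: ActivityPhantom) -> None:
    save_volume(path, phantom.values, phantom.grid, "activity phantom")


def load_phantom(path: str | Path) -> ActivityPhantom:
    values, grid = load_volume(path)
    return ActivityPhantom(values, grid)


def save_mask(path: str | Path, mask: ROIMask, grid: GridSpec) -> None:
    save_volume(path, mask.mask.astype(np.int16), grid, f"ROI mask {mask.label}")


def save_recon(path: str | Path, recon: ReconVolume) -> None:
    tag = recon.meta.get("filter", "none")
    save_volume(path, recon.values, recon.grid, f"OSEM recon filter={tag}")


def load_recon(path: str | Path) -> ReconVolume:
    values, grid = load_volume(path)
    return ReconVolume(values, grid)


def save_sinogram(path: str | Path, sino: Sinogram, extra: dict | None = None) -> None:
    """Write counts as NIfTI plus a JSON geometry sidecar (bit-exact round trip)."""
    path = Path(path)
    img = nib.Nifti1Image(sino.counts.astype(np.float64), np.eye(4))
    nib.save(img, str(path))
    g = sino.geometry
    sidecar = {
        "n_views": g.n_views,
        "start_angle_deg": g.start_angle_deg,
        "step_deg": g.step_deg,
        "n_bins": g.n_bins,
        "bin_width_mm": g.bin_width_mm,
        "is_sampled": sino.is_sampled,
    }
    if extra:
        sidecar.update(extra)
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_sinogram(path: str | Path) -> Sinogram:
    path = Path(path)
    counts = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    geom = ProjectionGeometry(
        n_views=int(meta["n_views"]),
        start_angle_deg=float(meta["start_angle_deg"]),
        step_deg=float(meta["step_deg"]),
        n_bins=int(meta["n_bins"]),
        bin_width_mm=float(meta["bin_width_mm"]),
    )
    return Sinogram(counts, geom, is_sampled=bool(meta["is_sampled"]))


def save_metrics(path: str | Path, table: pd.DataFrame) -> None:
    table[METRICS_COLUMNS].to_csv(path, index=False)


def load_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics CSV missing columns {missing}")
    if df.empty:
        raise ValueError("metrics CSV contains no rows")
    return df


def save_likelihood_trace(path: str | Path, trace: list[tuple[int, int, float]]) -> None:
    pd.DataFrame(trace, columns=["iteration", "subset", "log_likelihood"]).to_csv(path, index=False)
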