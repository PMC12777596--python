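"""Shared fixtures and independent oracles.

The projector oracle builds a dense system matrix by clipping each ray
against every pixel's axis-aligned box (Liang–Barsky slab test) — a
different exact algorithm from the production traversal-based projector,
so agreement between the two is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
import scipy.sparse as sp

from sparsespect import (
    GridSpec,
    OrganSpec,
    ProjectionGeometry,
    SystemModel,
    build_geometry,
)


def clip_ray_to_box(c, n, x0, x1, y0, y1, length=1e6):
    """Exact intersection length of the infinite ray c + λn with a 2D box."""
    tmin, tmax = -length, length
    for axis, (lo, hi) in enumerate(((x0, x1), (y0, y1))):
        if n[axis] != 0.0:
            t0 = (lo - c[axis]) / n[axis]
            t1 = (hi - c[axis]) / n[axis]
            tmin = max(tmin, min(t0, t1))
            tmax = min(tmax, max(t0, t1))
        elif not (lo <= c[axis] <= hi):
            return 0.0
    return max(0.0, tmax - tmin)  # |n| = 1, so λ-extent is length in mm


def dense_oracle_matrix(geometry: ProjectionGeometry, grid: GridSpec) -> np.ndarray:
    """Dense system matrix from per-(ray, pixel) box clipping."""
    nx, ny, v = grid.nx, grid.ny, grid.voxel_size_mm
    xedges = (np.arange(nx + 1) - nx / 2.0) * v
    yedges = (np.arange(ny + 1) - ny / 2.0) * v
    A = np.zeros((geometry.n_views * geometry.n_bins, nx * ny))
    for vi, ang in enumerate(np.deg2rad(geometry.view_angles_deg)):
        t = np.array([np.cos(ang), np.sin(ang)])
        n = np.array([-np.sin(ang), np.cos(ang)])
        for b, s in enumerate(geometry.bin_centers_mm):
            c = s * t
            row = vi * geometry.n_bins + b
            for ix in range(nx):
                for iy in range(ny):
                    A[row, ix * ny + iy] = clip_ray_to_box(
                        c, n, xedges[ix], xedges[ix + 1], yedges[iy], yedges[iy + 1]
                    )
    return A


@dataclass
class DenseModel:
    """Stand-in system model wrapping an arbitrary matrix, for toy systems."""

    matrix: sp.csr_matrix
    geometry: ProjectionGeometry
    grid: GridSpec

    def view_rows(self, views):
        views = np.asarray(views, dtype=np.int64)
        nb = self.geometry.n_bins
        return (views[:, None] * nb + np.arange(nb)[None, :]).ravel()


def make_toy_model(A: np.ndarray, voxel_size_mm: float = 1.0) -> DenseModel:
    """Wrap an (n_bins_total × n_voxels) matrix: one bin per 'view'."""
    m, j = A.shape
    geometry = ProjectionGeometry(
        n_views=m, start_angle_deg=0.0, step_deg=360.0 / m, n_bins=1, bin_width_mm=1.0
    )
    grid = GridSpec(j, 1, 1, voxel_size_mm)
    return DenseModel(sp.csr_matrix(np.asarray(A, dtype=float)), geometry, grid)


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(8, 8, 1, 4.43)


@pytest.fixture(scope="session")
def small_geometry(small_grid) -> ProjectionGeometry:
    return build_geometry(4, n_bins=8, bin_width_mm=small_grid.voxel_size_mm)


@pytest.fixture(scope="session")
def small_model(small_geometry, small_grid) -> SystemModel:
    return SystemModel(small_geometry, small_grid)


@pytest.fixture(scope="session")
def small_oracle(small_geometry, small_grid) -> np.ndarray:
    return dense_oracle_matrix(small_geometry, small_grid)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def tiny_organs() -> list[OrganSpec]:
    """Organ set that fits a 16×16×4 grid at 4.43 mm voxels (70.9 mm extent)."""
    return [
        OrganSpec("background", (0.0, 0.0, 0.0), (30.0, 30.0, 8.0), 1.0),
        OrganSpec("lesion", (0.0, -14.0, 0.0), (7.0, 7.0, 5.0), 8.0),
        OrganSpec("renal_cortex_left", (15.0, 12.0, 0.0), (8.0, 7.0, 5.0), 6.0),
        OrganSpec("renal_cortex_right", (-15.0, 12.0, 0.0), (8.0, 7.0, 5.0), 6.0),
    ]


@pytest.fixture(scope="session")
def tiny_grid() -> GridSpec:
    return GridSpec(16, 16, 4, 4.43)
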