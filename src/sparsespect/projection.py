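"""Parallel-beam emission model, Poisson sampling and angular decimation.

The acquisition is modelled per transaxial slice as a 2D parallel-beam
projection: expected counts are p = A x where a_ij is the exact intersection
length (mm) of ray i with pixel j, computed by Siddon-style parametric grid
traversal.  The system matrix is materialised once per (geometry, grid) pair
as a scipy.sparse CSR matrix, so the back projection is the exact matrix
transpose — forward and adjoint satisfy ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ to machine
precision, which the ordered-subsets update relies on.

Geometry conventions (the physical acquisition protocol leaves these open):
rotation is counterclockwise with angle 0 along +x; the detector axis at
angle θ is t = (cos θ, sin θ) and rays travel along n = (−sin θ, cos θ);
detector bins default to the grid width at voxel pitch.  Attenuation,
scatter and collimator response are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .phantom import ActivityPhantom, GridSpec


@dataclass(frozen=True)
class ProjectionGeometry:
    n_views: int
    start_angle_deg: float
    step_deg: float
    n_bins: int
    bin_width_mm: float

    def __post_init__(self) -> None:
        if self.n_views < 1 or self.n_bins < 1:
            raise ValueError("n_views and n_bins must be >= 1")
        if not self.step_deg > 0 or not self.bin_width_mm > 0:
            raise ValueError("step_deg and bin_width_mm must be > 0")
        if self.n_views * self.step_deg > 360.0 + 1e-9:
            raise ValueError("n_views × step_deg must not exceed 360°")

    @property
    def view_angles_deg(self) -> np.ndarray:
        return self.start_angle_deg + self.step_deg * np.arange(self.n_views)

    @property
    def bin_centers_mm(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5 - self.n_bins / 2.0) * self.bin_width_mm


def build_geometry(
    n_views: int,
    start_angle_deg: float = 0.0,
    n_bins: int = 64,
    bin_width_mm: float = 4.43,
) -> ProjectionGeometry:
    """Full-ring geometry with step 360°/n_views (60 views → 6° steps)."""
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    return ProjectionGeometry(
        n_views=n_views,
        start_angle_deg=start_angle_deg,
        step_deg=360.0 / n_views,
        n_bins=n_bins,
        bin_width_mm=bin_width_mm,
    )


@dataclass
class Sinogram:
    """View × bin × slice count array.

    ``is_sampled`` distinguishes expected means p_i from Poisson draws y_i.
    """

    counts: np.ndarray
    geometry: ProjectionGeometry
    is_sampled: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim == 2:
            self.counts = self.counts[:, :, np.newaxis]
        if self.counts.ndim != 3:
            raise ValueError("counts must have shape (n_views, n_bins[, nz])")
        if self.counts.shape[:2] != (self.geometry.n_views, self.geometry.n_bins):
            raise ValueError(
                f"counts shape {self.counts.shape[:2]} does not match geometry "
                f"({self.geometry.n_views}, {self.geometry.n_bins})"
            )
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("sinogram counts must be finite and non-negative")
        if self.is_sampled and not np.allclose(self.counts, np.round(self.counts)):
            raise ValueError("sampled sinogram counts must be integers")

    @property
    def nz(self) -> int:
        return self.counts.shape[2]

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


def _siddon_ray(
    p0: np.ndarray, p1: np.ndarray, xedges: np.ndarray, yedges: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact intersection lengths of segment p0→p1 with a 2D pixel grid.

    Returns (flat pixel indices, lengths in mm); parametric Siddon traversal:
    collect the parameter values where the segment crosses grid lines, then
    read off the pixel containing each inter-crossing midpoint.
    """
    d = p1 - p0
    seg_len = float(np.hypot(d[0], d[1]))
    if seg_len == 0.0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    # entry/exit parameters through the grid bounding box (slab method)
    a_min, a_max = 0.0, 1.0
    for axis, edges in ((0, xedges), (1, yedges)):
        if d[axis] != 0.0:
            a0 = (edges[0] - p0[axis]) / d[axis]
            a1 = (edges[-1] - p0[axis]) / d[axis]
            a_min = max(a_min, min(a0, a1))
            a_max = min(a_max, max(a0, a1))
        elif not (edges[0] <= p0[axis] <= edges[-1]):
            return np.empty(0, dtype=np.int64), np.empty(0)
    if a_min >= a_max:
        return np.empty(0, dtype=np.int64), np.empty(0)

    alphas = [np.array([a_min, a_max])]
    for axis, edges in ((0, xedges), (1, yedges)):
        if d[axis] != 0.0:
            a = (edges - p0[axis]) / d[axis]
            alphas.append(a[(a > a_min) & (a < a_max)])
    alpha = np.unique(np.concatenate(alphas))
    if alpha.size < 2:
        return np.empty(0, dtype=np.int64), np.empty(0)

    mids = 0.5 * (alpha[:-1] + alpha[1:])
    pts = p0[np.newaxis, :] + mids[:, np.newaxis] * d[np.newaxis, :]
    dx = xedges[1] - xedges[0]
    dy = yedges[1] - yedges[0]
    ix = np.floor((pts[:, 0] - xedges[0]) / dx).astype(np.int64)
    iy = np.floor((pts[:, 1] - yedges[0]) / dy).astype(np.int64)
    lengths = np.diff(alpha) * seg_len
    ok = (ix >= 0) & (ix < xedges.size - 1) & (iy >= 0) & (iy < yedges.size - 1) & (lengths > 0)
    return (ix[ok] * (yedges.size - 1) + iy[ok]), lengths[ok]


class SystemModel:
    """Sparse system matrix A (rays × pixels) for one (geometry, grid) pair.

    Row ordering is view-major: ray index i = view · n_bins + bin.  Matrix
    elements are exposed only through forward/adjoint application and
    sensitivity computation; slices share the same 2D matrix.
    """

    def __init__(self, geometry: ProjectionGeometry, grid: GridSpec):
        self.geometry = geometry
        self.grid = grid
        self.matrix = self._build_matrix()

    def _build_matrix(self) -> sp.csr_matrix:
        g, grid = self.geometry, self.grid
        xedges = (np.arange(grid.nx + 1) - grid.nx / 2.0) * grid.voxel_size_mm
        yedges = (np.arange(grid.ny + 1) - grid.ny / 2.0) * grid.voxel_size_mm
        half_diag = 0.5 * float(np.hypot(xedges[-1] - xedges[0], yedges[-1] - yedges[0]))
        rows, cols, vals = [], [], []
        for v, ang in enumerate(np.deg2rad(self.geometry.view_angles_deg)):
            t = np.array([np.cos(ang), np.sin(ang)])  # detector axis
            n = np.array([-np.sin(ang), np.cos(ang)])  # ray direction
            for b, s in enumerate(g.bin_centers_mm):
                c = s * t
                idx, lengths = _siddon_ray(
                    c - 2.0 * half_diag * n, c + 2.0 * half_diag * n, xedges, yedges
                )
                if idx.size:
                    rows.append(np.full(idx.size, v * g.n_bins + b, dtype=np.int64))
                    cols.append(idx)
                    vals.append(lengths)
        shape = (g.n_views * g.n_bins, grid.nx * grid.ny)
        if not rows:
            return sp.csr_matrix(shape)
        return sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=shape
        )

    def view_rows(self, views: np.ndarray) -> np.ndarray:
        """Row indices of all bins belonging to the given views."""
        views = np.asarray(views, dtype=np.int64)
        nb = self.geometry.n_bins
        return (views[:, None] * nb + np.arange(nb)[None, :]).ravel()


def forward_project(phantom: ActivityPhantom, model: SystemModel) -> Sinogram:
    """Expected counts p = A x, applied slice by slice (linear, non-negative)."""
    if phantom.grid != model.grid:
        raise ValueError("phantom grid does not match system model grid")
    grid, g = model.grid, model.geometry
    x = phantom.values.reshape(grid.nx * grid.ny, grid.nz)
    p = model.matrix @ x  # (n_views*n_bins, nz)
    return Sinogram(p.reshape(g.n_views, g.n_bins, grid.nz), g, is_sampled=False)


def back_project(sino: Sinogram, model: SystemModel) -> np.ndarray:
    """Exact adjoint Aᵀ y, returned as a phantom-shaped array."""
    if sino.geometry != model.geometry:
        raise ValueError("sinogram geometry does not match system model geometry")
    grid, g = model.grid, model.geometry
    y = sino.counts.reshape(g.n_views * g.n_bins, sino.nz)
    x = model.matrix.T @ y
    return np.asarray(x).reshape(grid.nx, grid.ny, sino.nz)


def sensitivity(model: SystemModel, view_subset: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel sensitivity s_j = Σ_{i∈S} a_ij over the chosen views.

    Subset sensitivities over a partition of the views sum to the full-scan
    sensitivity.  Returned as a volume-shaped array (identical across slices
    in this slice-independent geometry).
    """
    g, grid = model.geometry, model.grid
    if view_subset is None:
        view_subset = np.arange(g.n_views)
    view_subset = np.asarray(sorted(set(int(v) for v in view_subset)), dtype=np.int64)
    if view_subset.size == 0:
        raise ValueError("view subset must be non-empty")
    if view_subset.min() < 0 or view_subset.max() >= g.n_views:
        raise ValueError("view subset indices out of range")
    rows = model.view_rows(view_subset)
    s2d = np.asarray(model.matrix[rows].sum(axis=0)).ravel().reshape(grid.nx, grid.ny)
    return np.repeat(s2d[:, :, np.newaxis], grid.nz, axis=2)


def sample_counts(expected: Sinogram, seed: int | np.random.Generator) -> Sinogram:
    """Independent Poisson draw per bin with the expected means (Eq. y~Pois(p))."""
    if expected.is_sampled:
        raise ValueError("sinogram is already a sampled realisation")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.poisson(expected.counts).astype(float)
    return Sinogram(counts, expected.geometry, is_sampled=True)


def scale_to_total(expected: Sinogram, total_counts: float) -> Sinogram:
    """Calibrate an expected sinogram so the full scan sums to a count budget.

    The clinical protocol fixes acquisition time per view but not counts;
    the budget (default 2×10⁶ for the 60-view scan in the pipeline) makes
    the Poisson noise level explicit and tunable.
    """
    if expected.is_sampled:
        raise ValueError("count calibration applies to expected sinograms only")
    current = expected.total_counts
    if current <= 0:
        raise ValueError("cannot calibrate an all-zero sinogram")
    return Sinogram(expected.counts * (total_counts / current), expected.geometry, False)


def decimate_views(sino: Sinogram, keep_every: int, offset: int = 0) -> Sinogram:
    """Uniform angular decimation: keep views offset, offset+keep_every, …

    Per-view counts are untouched, so effective total counts scale linearly
    with the number of retained views (60→30/15/10 views at 12°/24°/36° steps).
    """
    g = sino.geometry
    if keep_every < 1 or g.n_views % keep_every != 0:
        raise ValueError(f"keep_every={keep_every} must divide n_views={g.n_views}")
    if not 0 <= offset < keep_every:
        raise ValueError("offset must satisfy 0 <= offset < keep_every")
    kept = np.arange(offset, g.n_views, keep_every)
    new_geom = replace(
        g,
        n_views=kept.size,
        start_angle_deg=g.start_angle_deg + offset * g.step_deg,
        step_deg=g.step_deg * keep_every,
    )
    return Sinogram(sino.counts[kept], new_geom, is_sampled=sino.is_sampled)
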