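"""Synthetic 3D fibre-matrix stacks with embedded cells at known depths."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from ..errors import RenderError
from .specs import GroundTruth, LatticeSpec

__all__ = ["render_matrix_stack"]


def render_matrix_stack(
    surface_profile: np.ndarray,
    fibre_density: float,
    cells: Sequence[tuple[float, float, float, float]],
    voxel_size_um: tuple[float, float, float],
    shape: tuple[int, int, int],
    seed: int = 0,
    noise: bool = True,
    fibre_intensity: float = 150.0,
    cell_intensity: float = 200.0,
    background: float = 5.0,
    read_noise_sd: float = 2.0,
    shell_thickness_um: float = 0.6,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a two-channel (fibre, cell) 3D stack.

    Parameters
    ----------
    surface_profile:
        Matrix surface height in um over the lateral grid, shape ``(y, x)``.
        z increases bottom to top; matrix occupies z below the surface.
    fibre_density:
        Fibre segments per 1000 um^3 of matrix volume.
    cells:
        ``(x_um, y_um, depth_um, radius_um)`` per cell; ``depth_um`` is the
        distance of the cell centre below the local surface.
    voxel_size_um:
        ``(dz, dy, dx)``.
    shape:
        Stack shape ``(z, y, x)`` in voxels.

    Returns
    -------
    (2, z, y, x) array (channel 0 fibre, channel 1 cell) and GroundTruth with
    ``cell_depths_um`` recording the planted depths.
    """
    nz, ny, nx = shape
    dz, dy, dx = voxel_size_um
    surface = np.asarray(surface_profile, dtype=float)
    if surface.shape != (ny, nx):
        raise RenderError(f"surface profile shape {surface.shape} != lateral grid {(ny, nx)}")
    if np.any(surface < 0) or np.any(surface > nz * dz):
        raise RenderError("surface profile leaves the stack bounds")

    rng = np.random.default_rng(seed)
    zc = (np.arange(nz) + 0.5) * dz

    # --- fibre channel: random line segments below the surface -------------
    vol_um3 = nz * dz * ny * dy * nx * dx
    n_seg = int(round(fibre_density * vol_um3 / 1000.0))
    fib = np.zeros(shape, dtype=float)
    ext = np.array([nz * dz, ny * dy, nx * dx])
    for _ in range(n_seg):
        p0 = rng.uniform(0, ext)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(3.0, 12.0)
        n_pts = max(int(length / (0.5 * min(voxel_size_um))), 2)
        ts = np.linspace(0, length, n_pts)
        pts = p0[None, :] + ts[:, None] * direction[None, :]
        idx = np.round(pts / np.array([dz, dy, dx]) - 0.5).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        idx = idx[ok]
        fib[idx[:, 0], idx[:, 1], idx[:, 2]] += 1.0
    sig = 0.3 / np.array([dz, dy, dx])  # ~300 nm fibre cross-section
    fib = gaussian_filter(fib, sig)
    if fib.max() > 0:
        fib *= fibre_intensity / fib.max()
    # truncate above the surface
    above = zc[:, None, None] > surface[None, :, :]
    fib[above] = 0.0

    # --- cell channel: hollow membrane shells ------------------------------
    cellch = np.zeros(shape, dtype=float)
    depths = []
    centres = []
    for x_um, y_um, depth_um, radius_um in cells:
        if radius_um < 2 * max(voxel_size_um):
            raise RenderError(
                f"cell radius {radius_um} um is below 2 voxels; unsegmentable"
            )
        iy = int(round(y_um / dy - 0.5))
        ix = int(round(x_um / dx - 0.5))
        if not (0 <= iy < ny and 0 <= ix < nx):
            raise RenderError("cell centre outside the lateral stack extent")
        z_um = surface[iy, ix] - depth_um
        if not (radius_um <= z_um <= nz * dz - radius_um):
            raise RenderError("cell does not fit inside the stack in z")
        reach = radius_um + shell_thickness_um
        z0 = max(0, int((z_um - reach) / dz))
        z1 = min(nz, int((z_um + reach) / dz) + 2)
        y0 = max(0, int((y_um - reach) / dy))
        y1 = min(ny, int((y_um + reach) / dy) + 2)
        x0 = max(0, int((x_um - reach) / dx))
        x1 = min(nx, int((x_um + reach) / dx) + 2)
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1].astype(float)
        r = np.sqrt(
            ((zz + 0.5) * dz - z_um) ** 2
            + ((yy + 0.5) * dy - y_um) ** 2
            + ((xx + 0.5) * dx - x_um) ** 2
        )
        shell = np.abs(r - radius_um) <= shell_thickness_um / 2
        cellch[z0:z1, y0:y1, x0:x1][shell] = cell_intensity
        depths.append(depth_um)
        centres.append((x_um, y_um, z_um))

    stack = np.stack([fib + background, cellch + background])
    if noise:
        stack = rng.poisson(stack).astype(float)
        if read_noise_sd > 0:
            stack += rng.normal(0.0, read_noise_sd, size=stack.shape)
        stack = np.clip(stack, 0.0, None)

    gt = GroundTruth(
        lattice=LatticeSpec(),  # placeholder; no lattice in matrix stacks
        cell_depths_um=np.asarray(depths, dtype=float),
        node_xy=np.asarray([(c[0], c[1]) for c in centres], dtype=float)
        if centres
        else None,
        seed=seed,
    )
    return stack, gt
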