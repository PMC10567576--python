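"""Shared geometry helpers for periodic square lattices of nanostructures.

All public coordinates are ``(x, y)`` in pixel units; numpy arrays are
indexed ``[y, x]`` internally.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lattice_basis", "lattice_nodes"]


def lattice_basis(pitch_px: float, orientation_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Return the two lattice basis vectors ``(x, y)`` of a square lattice."""
    th = np.deg2rad(orientation_deg)
    e1 = np.array([np.cos(th), np.sin(th)])
    e2 = np.array([-np.sin(th), np.cos(th)])
    return pitch_px * e1, pitch_px * e2


def lattice_nodes(
    origin_xy: tuple[float, float],
    pitch_px: float,
    orientation_deg: float,
    shape: tuple[int, int],
    margin: float = 0.0,
    return_indices: bool = False,
):
    """Enumerate lattice node centres that fall inside an image.

    Parameters
    ----------
    origin_xy:
        Any one lattice node, ``(x, y)`` in pixels.
    pitch_px:
        Lattice period in pixels.
    orientation_deg:
        Angle of the first basis vector, degrees in ``[0, 180)``.
    shape:
        Image shape ``(height, width)``.
    margin:
        Nodes closer than ``margin`` pixels to any image edge are dropped.

    Returns
    -------
    ndarray, shape (n, 2)
        Node centres ``(x, y)``, sorted row-major along the lattice axes so
        that the ordering is deterministic and shared between the generator
        and the analysis side.
    """
    h, w = shape
    u1, u2 = lattice_basis(pitch_px, orientation_deg)
    origin = np.asarray(origin_xy, dtype=float)

    # Conservative integer ranges from projecting the image corners.
    corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float) - origin
    basis = np.stack([u1, u2], axis=1)  # columns
    coeffs = np.linalg.solve(basis, corners.T).T
    i_lo, j_lo = np.floor(coeffs.min(axis=0)).astype(int) - 1
    i_hi, j_hi = np.ceil(coeffs.max(axis=0)).astype(int) + 1

    nodes, idx = [], []
    for j in range(j_lo, j_hi + 1):
        for i in range(i_lo, i_hi + 1):
            p = origin + i * u1 + j * u2
            if (
                margin <= p[0] <= w - 1 - margin
                and margin <= p[1] <= h - 1 - margin
            ):
                nodes.append(p)
                idx.append((i, j))
    nodes = np.array(nodes, dtype=float) if nodes else np.empty((0, 2), dtype=float)
    idx = np.array(idx, dtype=int) if idx else np.empty((0, 2), dtype=int)
    if return_indices:
        return nodes, idx
    return nodes
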