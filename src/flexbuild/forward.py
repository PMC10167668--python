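"""Gaussian-atom forward density model.

Each atom contributes an isotropic 3-D Gaussian with amplitude proportional
to its electron count and occupancy, and width set by its isotropic B
factor through B = 8 pi^2 <u^2>:

    rho_atom(r) = occ * Z / (2 pi u^2)^(3/2) * exp(-r^2 / (2 u^2)),
    u^2 = B / (8 pi^2)

summed over atoms on a periodic unit-cell grid.  This deliberately omits
atomic form factors and Fourier-truncation ripple; it is the model used
both to generate synthetic maps and as the calculated density in real-space
correlation coefficients.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = ["ELECTRON_COUNTS", "AtomSpec", "gaussian_density", "mask_near_atoms"]

ELECTRON_COUNTS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15}

#: (element, position (3,), occupancy, b_iso)
AtomSpec = tuple


def _matrices(cell: gemmi.UnitCell):
    orth = np.array(cell.orth.mat.tolist())
    frac = np.array(cell.frac.mat.tolist())
    return orth, frac


def _index_box(fpos: np.ndarray, shape, cell: gemmi.UnitCell, radius: float):
    """Index ranges (per axis) covering a sphere around a fractional point."""
    spacings = np.array([cell.a, cell.b, cell.c]) / np.array(shape)
    # margin covers non-orthogonal skew
    half = np.ceil(radius / spacings).astype(int) + 2
    centre = np.round(fpos * shape).astype(int)
    return [np.arange(c - h, c + h + 1) for c, h in zip(centre, half)]


def gaussian_density(atoms: Iterable[AtomSpec],
                     cell: gemmi.UnitCell,
                     shape: Sequence[int],
                     cutoff_sigmas: float = 5.0) -> np.ndarray:
    """Render occupancy-weighted Gaussian atoms onto a periodic grid.

    ``grid[i, j, k]`` samples fractional coordinates (i/nx, j/ny, k/nz).
    Atoms outside the cell are wrapped periodically.
    """
    shape = tuple(int(s) for s in shape)
    grid = np.zeros(shape)
    orth, frac = _matrices(cell)
    for element, pos, occ, b in atoms:
        z = ELECTRON_COUNTS[element.upper()]
        u2 = b / (8.0 * math.pi ** 2)
        if u2 <= 0:
            raise ValueError(f"non-positive B factor {b}")
        amp = occ * z / (2.0 * math.pi * u2) ** 1.5
        radius = cutoff_sigmas * math.sqrt(u2)
        fpos = frac @ np.asarray(pos, dtype=float)
        ii, jj, kk = _index_box(fpos, shape, cell, radius)
        fi = ii[:, None, None] / shape[0] - fpos[0]
        fj = jj[None, :, None] / shape[1] - fpos[1]
        fk = kk[None, None, :] / shape[2] - fpos[2]
        disp = (fi[..., None] * orth[:, 0]
                + fj[..., None] * orth[:, 1]
                + fk[..., None] * orth[:, 2])
        r2 = np.sum(disp * disp, axis=-1)
        contrib = amp * np.exp(-r2 / (2.0 * u2))
        np.add.at(grid,
                  np.ix_(ii % shape[0], jj % shape[1], kk % shape[2]),
                  contrib)
    return grid


def mask_near_atoms(positions: Iterable[np.ndarray],
                    cell: gemmi.UnitCell,
                    shape: Sequence[int],
                    radius: float) -> np.ndarray:
    """Boolean grid marking nodes within `radius` (A) of any position,
    with periodic wrapping."""
    shape = tuple(int(s) for s in shape)
    mask = np.zeros(shape, dtype=bool)
    orth, frac = _matrices(cell)
    for pos in positions:
        fpos = frac @ np.asarray(pos, dtype=float)
        ii, jj, kk = _index_box(fpos, shape, cell, radius)
        fi = ii[:, None, None] / shape[0] - fpos[0]
        fj = jj[None, :, None] / shape[1] - fpos[1]
        fk = kk[None, None, :] / shape[2] - fpos[2]
        disp = (fi[..., None] * orth[:, 0]
                + fj[..., None] * orth[:, 1]
                + fk[..., None] * orth[:, 2])
        r2 = np.sum(disp * disp, axis=-1)
        sub = r2 <= radius * radius
        idx = np.ix_(ii % shape[0], jj % shape[1], kk % shape[2])
        mask[idx] |= sub
    return mask
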