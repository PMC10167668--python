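"""Real-space density maps and Ringer-style circular dihedral sampling.

A map is a 3-D grid of density values covering one full unit cell (P1,
periodic).  Values are expressed in sigma units after :func:`sigma_scale`:
(rho - mean)/sd over all grid points, so thresholds like "0.3 sigma" refer
to standard deviations above the map mean.

Ringer sampling rotates the probe atom of one chi dihedral (the single atom
directly bonded distal to the rotating bond, e.g. OG for serine chi1)
through a full turn on an absolute dihedral grid and interpolates the map at
each position, producing a circular density-versus-angle trace whose peaks
mark candidate side-chain conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import gemmi
import numpy as np

from .errors import FlatMapError, MapFormatError, ParameterError
from .geometry import rotate_about_axis, dihedral
from .rotamers import ChiDefinition

__all__ = ["DensityMap", "RingerTrace", "read_map", "write_map",
           "sigma_scale", "ringer_trace"]


@dataclass
class DensityMap:
    """A full-cell periodic density grid.

    ``grid[i, j, k]`` samples the point with fractional coordinates
    (i/nx, j/ny, k/nz) along the unit-cell axes a, b, c (canonical XYZ
    axis order; files with permuted axes are normalized on reading).
    """

    grid: np.ndarray
    cell: gemmi.UnitCell
    sigma_scaled: bool = False
    mean_raw: float | None = None
    sd_raw: float | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise MapFormatError(f"grid must be 3-D, got shape {self.grid.shape}")
        if min(self.cell.a, self.cell.b, self.cell.c) <= 0:
            raise MapFormatError("unit-cell lengths must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.grid.shape)

    def interpolate(self, position) -> float:
        """Trilinear interpolation at a Cartesian position (A), with
        periodic unit-cell wrapping.  Exact at grid nodes."""
        return float(self.interpolate_many(np.asarray(position, dtype=float)[None, :])[0])

    def interpolate_many(self, positions: np.ndarray) -> np.ndarray:
        """Vectorized trilinear interpolation for an (N, 3) array of
        Cartesian positions."""
        pos = np.asarray(positions, dtype=float)
        if not np.all(np.isfinite(pos)):
            raise ParameterError("non-finite position passed to interpolate")
        fmat = np.array(self.cell.frac.mat.tolist())
        frac = pos @ fmat.T
        shape = np.array(self.grid.shape)
        t = frac * shape
        i0 = np.floor(t).astype(int)
        d = t - i0
        out = np.zeros(len(pos))
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            idx = (i0 + off) % shape
            w = np.prod(np.where(off == 1, d, 1.0 - d), axis=1)
            out += w * self.grid[idx[:, 0], idx[:, 1], idx[:, 2]]
        return out


def read_map(path: str | Path) -> DensityMap:
    """Read a CCP4/MRC map, expand it to the full unit cell and normalize
    axis order to XYZ.  Returns an unscaled DensityMap."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read CCP4/MRC map {path}: {exc}") from exc
    cell = ccp4.grid.unit_cell
    if min(cell.a, cell.b, cell.c) <= 0:
        raise MapFormatError(
            f"map {path} has no unit-cell parameters; re-write the map with "
            "a complete cell description")
    # expand to the whole cell, reorder axes to XYZ
    ccp4.setup(float("nan"))
    arr = np.array(ccp4.grid, copy=True).astype(np.float64)
    if np.any(~np.isfinite(arr)):
        raise MapFormatError(
            f"map {path} does not cover the full unit cell; flexbuild "
            "requires whole-cell (P1-expandable) maps")
    return DensityMap(arr, ccp4.grid.unit_cell)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write a DensityMap as a CCP4 map (float32, P1)."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32),
                           dmap.cell, gemmi.SpaceGroup("P1"))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def sigma_scale(dmap: DensityMap) -> DensityMap:
    """Normalize a map to sigma units: (rho - mean)/sd over all grid points.

    Records the raw statistics; refuses to scale twice or to scale a flat
    (zero-variance) map.
    """
    if dmap.sigma_scaled:
        raise ParameterError("map is already sigma-scaled")
    mean = float(dmap.grid.mean())
    sd = float(dmap.grid.std())
    if sd == 0.0:
        raise FlatMapError("flat map: zero variance, cannot sigma-scale")
    return DensityMap((dmap.grid - mean) / sd, dmap.cell,
                      sigma_scaled=True, mean_raw=mean, sd_raw=sd)


@dataclass
class RingerTrace:
    """Circular density profile of one chi dihedral.

    ``angles`` are the absolute chi values sampled (0, step, ..., 360-step);
    ``values`` are map densities in sigma units at the probe-atom position
    for each angle.
    """

    residue_id: tuple  # (chain, resnum, icode, residue type)
    chi_index: int
    angles: np.ndarray
    values: np.ndarray
    probe_atom: str

    @property
    def step(self) -> float:
        return float(self.angles[1] - self.angles[0])

    def argmax_angle(self) -> float:
        return float(self.angles[int(np.argmax(self.values))])


def probe_positions(conformer: Mapping[str, np.ndarray],
                    definition: ChiDefinition,
                    angles: np.ndarray) -> np.ndarray:
    """Positions of the chi probe atom at each absolute dihedral angle.

    The probe atom is rotated rigidly about the chi bond axis, preserving
    its bond length and bond angle to the axis atoms.
    """
    a, b, c, d = (np.asarray(conformer[n], dtype=float)
                  for n in definition.atom_quadruple)
    current = dihedral(a, b, c, d)
    axis = c - b
    out = np.empty((len(angles), 3))
    for i, theta in enumerate(angles):
        out[i] = rotate_about_axis(d, b, axis, float(theta) - current)
    return out


def ringer_trace(dmap: DensityMap,
                 conformer: Mapping[str, np.ndarray],
                 residue_id: tuple,
                 definition: ChiDefinition,
                 step: float = 10.0) -> RingerTrace:
    """Sample the map around one chi dihedral on an absolute angle grid.

    The dihedral grid covers [0, 360) in increments of ``step`` (which must
    divide 360); at each angle the probe atom is rotated so the dihedral
    equals that absolute value and the sigma-scaled map is interpolated at
    the probe-atom center.
    """
    if not dmap.sigma_scaled:
        raise ParameterError("ringer_trace requires a sigma-scaled map")
    if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ParameterError(f"sampling step {step} must divide 360")
    from .errors import IncompleteSideChainError
    for name in definition.atom_quadruple:
        if name not in conformer:
            raise IncompleteSideChainError(residue_id, name)
    angles = np.arange(0.0, 360.0, step)
    pos = probe_positions(conformer, definition, angles)
    values = dmap.interpolate_many(pos)
    return RingerTrace(residue_id, definition.chi_index, angles, values,
                       definition.probe_atom)
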