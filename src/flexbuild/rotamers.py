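"""Ideal side-chain rotamer library and chi-dihedral definitions.

A rotamer is a statistically favored combination of side-chain dihedral
(chi) angles, identified by a short name such as ``p``, ``t`` or ``m``
(chi1 near +60, 180 and -60 degrees respectively), with longer names for
residues with several dihedrals (``mt``, ``ptp85`` ...).  The bundled table
(``data/rotamer_library.csv``) is a transcription of the published
penultimate rotamer library: for each residue type it lists the rotamer
names, modal chi angles and relative abundances in the PDB.  The schema is
documented in the README so users can substitute a newer library.

This module also owns the canonical chi atom quadruples (chi1 = N-CA-CB-CG
and so on) and, for each chi, the set of side-chain atoms distal to the
rotation axis -- the atoms that move when that dihedral changes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import IncompleteSideChainError, LibraryParseError, UnsupportedResidueError
from .geometry import dihedral, normalize_angle

logger = logging.getLogger(__name__)

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Residues excluded from sampling and building: no chi (GLY/ALA) or a
#: ring-constrained chi1 (PRO).
NON_ROTAMERIC = {"GLY", "ALA", "PRO"}

_CHI1 = ("N", "CA", "CB", "CG")

#: Canonical chi dihedral atom quadruples, in chi order.
CHI_ATOMS: dict[str, tuple[tuple[str, str, str, str], ...]] = {
    "ARG": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "NE"),
            ("CG", "CD", "NE", "CZ")),
    "ASN": (_CHI1, ("CA", "CB", "CG", "OD1")),
    "ASP": (_CHI1, ("CA", "CB", "CG", "OD1")),
    "CYS": (("N", "CA", "CB", "SG"),),
    "GLN": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")),
    "GLU": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")),
    "HIS": (_CHI1, ("CA", "CB", "CG", "ND1")),
    "ILE": (("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")),
    "LEU": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "LYS": (_CHI1, ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "CE"),
            ("CG", "CD", "CE", "NZ")),
    "MET": (_CHI1, ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")),
    "PHE": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "SER": (("N", "CA", "CB", "OG"),),
    "THR": (("N", "CA", "CB", "OG1"),),
    "TRP": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "TYR": (_CHI1, ("CA", "CB", "CG", "CD1")),
    "VAL": (("N", "CA", "CB", "CG1"),),
}

#: For each residue type, per chi, the atoms distal to the rotation axis.
ROTATING_SETS: dict[str, tuple[tuple[str, ...], ...]] = {
    "ARG": (("CG", "CD", "NE", "CZ", "NH1", "NH2"),
            ("CD", "NE", "CZ", "NH1", "NH2"),
            ("NE", "CZ", "NH1", "NH2"),
            ("CZ", "NH1", "NH2")),
    "ASN": (("CG", "OD1", "ND2"), ("OD1", "ND2")),
    "ASP": (("CG", "OD1", "OD2"), ("OD1", "OD2")),
    "CYS": (("SG",),),
    "GLN": (("CG", "CD", "OE1", "NE2"), ("CD", "OE1", "NE2"), ("OE1", "NE2")),
    "GLU": (("CG", "CD", "OE1", "OE2"), ("CD", "OE1", "OE2"), ("OE1", "OE2")),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"), ("ND1", "CD2", "CE1", "NE2")),
    "ILE": (("CG1", "CG2", "CD1"), ("CD1",)),
    "LEU": (("CG", "CD1", "CD2"), ("CD1", "CD2")),
    "LYS": (("CG", "CD", "CE", "NZ"), ("CD", "CE", "NZ"), ("CE", "NZ"), ("NZ",)),
    "MET": (("CG", "SD", "CE"), ("SD", "CE"), ("CE",)),
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
            ("CD1", "CD2", "CE1", "CE2", "CZ")),
    "SER": (("OG",),),
    "THR": (("OG1", "CG2"),),
    "TRP": (("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
            ("CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
            ("CD1", "CD2", "CE1", "CE2", "CZ", "OH")),
    "VAL": (("CG1", "CG2"),),
}

#: Terminal dihedrals whose two branches are chemically indistinguishable;
#: angle comparisons for these are 180-degree periodic.
SYMMETRIC_CHI: frozenset[tuple[str, int]] = frozenset({
    ("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2),
})


@dataclass(frozen=True)
class ChiDefinition:
    """One side-chain dihedral: its atom quadruple and the distal atoms
    that move when it rotates."""

    residue_type: str
    chi_index: int  # 1-based
    atom_quadruple: tuple[str, str, str, str]
    rotating_set: tuple[str, ...]

    @property
    def probe_atom(self) -> str:
        """The atom whose density is sampled when this chi is rotated: the
        single atom directly bonded distal to the rotating bond."""
        return self.atom_quadruple[3]

    @property
    def symmetric(self) -> bool:
        return (self.residue_type, self.chi_index) in SYMMETRIC_CHI


def chi_definitions(residue_type: str) -> tuple[ChiDefinition, ...]:
    """Canonical chi definitions for a standard residue type, in chi order.

    GLY and ALA have no side-chain dihedrals and return an empty tuple.
    PRO is treated the same way: its chi1 is ring-constrained and excluded
    from sampling and building.
    """
    residue_type = residue_type.upper()
    if residue_type not in STANDARD_AMINO_ACIDS:
        raise UnsupportedResidueError(
            f"unsupported residue type {residue_type!r}")
    if residue_type in NON_ROTAMERIC:
        return ()
    quads = CHI_ATOMS[residue_type]
    rots = ROTATING_SETS[residue_type]
    return tuple(
        ChiDefinition(residue_type, i + 1, quad, rot)
        for i, (quad, rot) in enumerate(zip(quads, rots))
    )


def measure_chi(conformer: Mapping[str, np.ndarray],
                definition: ChiDefinition) -> float:
    """Measure one chi dihedral (degrees, [-180, 180)) from an atom-name ->
    coordinate mapping.  Raises IncompleteSideChainError if any quadruple
    atom is absent or non-finite."""
    pts = []
    for name in definition.atom_quadruple:
        if name not in conformer:
            raise IncompleteSideChainError(definition.residue_type, name)
        p = np.asarray(conformer[name], dtype=float)
        if not np.all(np.isfinite(p)):
            raise IncompleteSideChainError(definition.residue_type, name)
        pts.append(p)
    return dihedral(*pts)


def measure_all_chis(conformer: Mapping[str, np.ndarray],
                     residue_type: str) -> tuple[float, ...]:
    """All chi angles of a conformer, in chi order."""
    return tuple(measure_chi(conformer, d) for d in chi_definitions(residue_type))


@dataclass(frozen=True)
class RotamerLibraryEntry:
    residue_type: str
    rotamer_name: str
    modal_chi_angles: tuple[float, ...]
    pdb_frequency: float


def chi_deviation(angle: float, modal: float, symmetric: bool = False) -> float:
    """Smallest circular deviation between two dihedrals in degrees;
    180-degree periodic when the terminal dihedral is symmetric."""
    period = 180.0 if symmetric else 360.0
    d = abs((angle - modal) % period)
    return min(d, period - d)


class RotamerLibrary:
    """An ideal rotamer library: named chi-angle combinations with PDB
    frequencies, grouped by residue type."""

    def __init__(self, entries: Sequence[RotamerLibraryEntry]):
        self._by_type: dict[str, list[RotamerLibraryEntry]] = {}
        for e in entries:
            self._by_type.setdefault(e.residue_type, []).append(e)
        for rtype, group in self._by_type.items():
            names = [e.rotamer_name for e in group]
            if len(names) != len(set(names)):
                raise LibraryParseError(
                    f"duplicate rotamer names for {rtype}: {sorted(names)}")
            total = sum(e.pdb_frequency for e in group)
            if total > 1.0 + 1e-9:
                raise LibraryParseError(
                    f"frequencies for {rtype} sum to {total:.3f} > 1")

    def residue_types(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_type))

    def entries(self, residue_type: str) -> tuple[RotamerLibraryEntry, ...]:
        """All entries for a residue type; empty for types without chi
        angles (e.g. GLY)."""
        return tuple(self._by_type.get(residue_type.upper(), ()))

    def entry(self, residue_type: str, rotamer_name: str) -> RotamerLibraryEntry:
        for e in self.entries(residue_type):
            if e.rotamer_name == rotamer_name:
                return e
        valid = sorted(e.rotamer_name for e in self.entries(residue_type))
        raise KeyError(
            f"no rotamer {rotamer_name!r} for {residue_type}; valid: {valid}")

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_type.values())


def load_library(source: str | Path | None = None) -> RotamerLibrary:
    """Load a rotamer-library CSV (columns: residue_type, rotamer_name,
    chi1..chi4 with blanks where undefined, frequency).

    With no argument, loads the bundled table.  Rows whose residue type is
    not a standard amino acid are skipped with a warning; malformed rows
    raise LibraryParseError naming the offending row.
    """
    if source is None:
        ref = resources.files("flexbuild").joinpath("data/rotamer_library.csv")
        text = ref.read_text()
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(source, newline="") as fh:
            rows = list(csv.DictReader(fh))

    entries = []
    for lineno, row in enumerate(rows, start=2):
        try:
            rtype = row["residue_type"].strip().upper()
            name = row["rotamer_name"].strip()
            freq = float(row["frequency"])
        except (KeyError, TypeError, ValueError) as exc:
            raise LibraryParseError(f"malformed library row {lineno}: {row!r}") from exc
        if rtype not in STANDARD_AMINO_ACIDS or rtype in NON_ROTAMERIC:
            logger.warning("rotamer library row %d: skipping residue type %r",
                           lineno, rtype)
            continue
        n_chi = len(CHI_ATOMS[rtype])
        try:
            angles = tuple(
                normalize_angle(float(row[f"chi{i}"])) for i in range(1, n_chi + 1)
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise LibraryParseError(
                f"malformed chi angles in library row {lineno}: {row!r}") from exc
        if not name or not (0.0 <= freq <= 1.0):
            raise LibraryParseError(f"malformed library row {lineno}: {row!r}")
        entries.append(RotamerLibraryEntry(rtype, name, angles, freq))
    return RotamerLibrary(entries)
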