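"""Internal-coordinate templates for building ideal residue geometry.

Each side-chain atom is placed by the natural-extension reference frame from
three previously placed atoms, using standard bond lengths (A) and bond
angles (deg).  Torsions are either fixed (ring/planar geometry, branch
offsets) or bound to a chi dihedral, so a conformer can be generated at any
combination of chi angles.

Backbone: CA at the origin, N along +x, C in the xy-plane; the N-C-CA-CB
improper is set to -122.6 deg, giving the L configuration.  The carbonyl O
torsion is arbitrary (an isolated residue has no psi).
"""

from __future__ import annotations

import numpy as np

from .errors import UnsupportedResidueError
from .geometry import place_atom
from .rotamers import NON_ROTAMERIC, STANDARD_AMINO_ACIDS

# torsion spec: ("fixed", deg) or ("chi", k, offset_deg)
_T = tuple


def _chi(k: int, offset: float = 0.0):
    return ("chi", k, offset)


def _fx(deg: float):
    return ("fixed", deg)


# name, (a, b, c) reference atoms, bond, angle, torsion spec
SIDE_CHAIN_TEMPLATES: dict[str, list] = {
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, _chi(1))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0))],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.521, 110.5, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.0)),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2))],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 122.0))],
    "ASP": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0))],
    "GLU": [("CG", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0))],
    "GLN": [("CG", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0))],
    "MET": [("CG", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3))],
    "LYS": [("CG", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, _chi(3)),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, _chi(4))],
    "ARG": [("CG", ("N", "CA", "CB"), 1.530, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("NE", ("CB", "CG", "CD"), 1.461, 112.0, _chi(3)),
            ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, _chi(4)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, _fx(0.0)),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, _fx(180.0))],
    "PHE": [("CG", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, _fx(180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, _fx(180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, _fx(0.0))],
    "TYR": [("CG", ("N", "CA", "CB"), 1.502, 113.8, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.384, 120.8, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.382, 120.8, _fx(180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.382, 120.8, _fx(180.0)),
            ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, _fx(0.0)),
            ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, _fx(180.0))],
    "TRP": [("CG", ("N", "CA", "CB"), 1.498, 113.6, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.433, 126.6, _chi(2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, _fx(180.0)),
            ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, _fx(180.0)),
            ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, _fx(0.0)),
            ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, _fx(180.0)),
            ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, _fx(180.0)),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.368, 117.5, _fx(0.0))],
    "HIS": [("CG", ("N", "CA", "CB"), 1.497, 113.8, _chi(1)),
            ("ND1", ("CA", "CB", "CG"), 1.371, 122.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.356, 131.1, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.319, 109.0, _fx(180.0)),
            ("NE2", ("CB", "CG", "CD2"), 1.374, 107.2, _fx(180.0))],
}


def build_backbone() -> dict[str, np.ndarray]:
    """N, CA, C, O, CB of an isolated L-residue (CA at the origin)."""
    import math
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])
    ang = math.radians(111.0)
    c = np.array([1.525 * math.cos(ang), 1.525 * math.sin(ang), 0.0])
    o = place_atom(n, ca, c, 1.231, 120.5, 135.0)
    cb = place_atom(n, c, ca, 1.530, 110.1, -122.6)
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


def build_conformer(residue_type: str, chi_angles) -> dict[str, np.ndarray]:
    """Ideal geometry for a residue at the given chi angles.

    Returns atom name -> coordinates (A).  GLY/ALA/PRO and non-standard
    types are rejected.
    """
    residue_type = residue_type.upper()
    if residue_type not in STANDARD_AMINO_ACIDS:
        raise UnsupportedResidueError(f"unsupported residue type {residue_type!r}")
    if residue_type in NON_ROTAMERIC:
        raise UnsupportedResidueError(
            f"{residue_type} has no rotameric side chain to build")
    chi_angles = tuple(float(a) for a in chi_angles)
    coords = build_backbone()
    for name, (a, b, c), bond, angle, tspec in SIDE_CHAIN_TEMPLATES[residue_type]:
        if tspec[0] == "chi":
            _, k, offset = tspec
            if k > len(chi_angles):
                raise ValueError(
                    f"{residue_type} needs chi{k} but only "
                    f"{len(chi_angles)} angles given")
            torsion = chi_angles[k - 1] + offset
        else:
            torsion = tspec[1]
        coords[name] = place_atom(coords[a], coords[b], coords[c],
                                  bond, angle, torsion)
    return coords


def element_of(atom_name: str) -> str:
    """Element symbol inferred from a (heavy-atom) PDB atom name."""
    head = atom_name.strip()[:1]
    if atom_name.startswith(("SD", "SG")):
        return "S"
    if head in ("N", "O", "S", "C"):
        return head
    raise ValueError(f"cannot infer element for atom {atom_name!r}")
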