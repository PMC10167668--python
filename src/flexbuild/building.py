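"""Multi-conformer model container, conformer building and validation.

A multi-conformer model is an ordinary PDB/mmCIF hierarchy in which
flexible residues carry several side-chain conformers distinguished by
altloc letters (A, B, ...) with occupancies that sum to 1.  Building turns
an ordered list of named candidate rotamers into explicit conformers:

* the input model's own conformation always becomes conformer A (observed
  structure is never deleted);
* each further rotamer gets the next letter, in descending peak-support
  order, its side chain generated by rigid chi rotations to the matched
  library entry's modal angles (bond lengths and angles untouched);
* in full-residue mode backbone atoms are duplicated per conformer
  (initially identical -- refinement separates them); in calpha-branch mode
  the backbone is shared, with blank altloc and unit occupancy.

Validation helpers implement normalized B factors (the z-score of an
atom's B over all protein atoms) and real-space correlation coefficients
against the Gaussian-atom forward model.
"""

from __future__ import annotations

import logging
import string
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

from .assembly import CandidateRotamer
from .density import DensityMap
from .errors import BuildError, ParameterError, UnsupportedResidueError
from .forward import gaussian_density, mask_near_atoms
from .geometry import set_dihedral
from .rotamers import chi_definitions

logger = logging.getLogger(__name__)

__all__ = ["BLANK_ALTLOC", "MultiConformerModel", "build_conformers",
           "assign_occupancies", "prune_low_occupancy", "b_norm", "rscc",
           "write_model", "clash_report"]

BLANK_ALTLOC = "\0"
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}


class MultiConformerModel:
    """Thin wrapper over a gemmi.Structure with altloc-aware helpers.

    Residues are addressed by id tuples (chain, residue number, insertion
    code, residue type).
    """

    def __init__(self, structure: gemmi.Structure):
        self.structure = structure

    # -- construction -----------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "MultiConformerModel":
        st = gemmi.read_structure(str(path))
        st.setup_entities()
        return cls(st)

    def copy(self) -> "MultiConformerModel":
        return MultiConformerModel(self.structure.clone())

    # -- residue access ---------------------------------------------------

    def residues(self):
        """Yield (residue_id, gemmi.Residue) over the first model."""
        model = self.structure[0]
        for chain in model:
            for res in chain:
                rid = (chain.name, res.seqid.num, res.seqid.icode, res.name)
                yield rid, res

    def find_residue(self, residue_id) -> gemmi.Residue:
        for rid, res in self.residues():
            if rid[:3] == tuple(residue_id)[:3]:
                return res
        raise KeyError(f"no residue {residue_id} in model")

    @staticmethod
    def altlocs(res: gemmi.Residue) -> list[str]:
        return sorted({a.altloc for a in res if a.altloc != BLANK_ALTLOC})

    @staticmethod
    def conformer_coords(res: gemmi.Residue, altloc: str | None = None) -> dict:
        """Atom name -> coordinates for one conformer (blank-altloc atoms
        plus the requested altloc; default: the highest-occupancy one)."""
        alts = MultiConformerModel.altlocs(res)
        if altloc is None:
            if alts:
                occ = {al: np.mean([a.occ for a in res if a.altloc == al])
                       for al in alts}
                altloc = max(alts, key=lambda al: (occ[al], al == "A"))
            else:
                altloc = BLANK_ALTLOC
        coords = {}
        for a in res:
            if a.altloc in (BLANK_ALTLOC, altloc) and a.name not in coords:
                coords[a.name] = np.array([a.pos.x, a.pos.y, a.pos.z])
        return coords

    def strip_alternate_conformers(self) -> int:
        """Reduce every residue to its highest-occupancy conformer with
        blank altloc and unit occupancy.  Returns the number of residues
        changed."""
        n_changed = 0
        for rid, res in self.residues():
            alts = self.altlocs(res)
            if not alts:
                continue
            occ = {al: np.mean([a.occ for a in res if a.altloc == al])
                   for al in alts}
            keep = max(alts, key=lambda al: (occ[al], al == "A"))
            drop = [i for i in range(len(res))
                    if res[i].altloc not in (BLANK_ALTLOC, keep)]
            for i in reversed(drop):
                del res[i]
            for a in res:
                a.altloc = BLANK_ALTLOC
                a.occ = 1.0
            n_changed += 1
        return n_changed

    # -- atom views -------------------------------------------------------

    def protein_atoms(self):
        """Yield (residue_id, gemmi.Atom) over amino-acid residues."""
        for rid, res in self.residues():
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and info.is_amino_acid():
                for a in res:
                    yield rid, a

    def atom_specs(self, heavy_only: bool = True):
        """(element, position, occupancy, b) tuples for the forward model."""
        out = []
        for rid, a in self.protein_atoms():
            el = a.element.name
            if heavy_only and el == "H":
                continue
            out.append((el, np.array([a.pos.x, a.pos.y, a.pos.z]),
                        a.occ, a.b_iso))
        return out


def build_conformers(model: MultiConformerModel,
                     residue_id,
                     rotamers: Sequence[CandidateRotamer],
                     mode: str = "full-residue",
                     at_peak_angles: bool = False) -> MultiConformerModel:
    """Add alternate conformers for one residue, in the given order.

    ``mode`` is ``"full-residue"`` (duplicate the whole residue including
    backbone) or ``"calpha"`` (branch at CA: backbone keeps blank altloc).
    By default each new conformer is set to its matched library entry's
    modal chi angles; ``at_peak_angles`` builds at the detected peak angles
    instead.  The model is modified in place and returned.
    """
    if mode not in ("full-residue", "calpha"):
        raise ParameterError(f"unknown build mode {mode!r}")
    if not rotamers:
        return model
    res = model.find_residue(residue_id)
    restype = res.name
    for r in rotamers:
        if r.residue_type != restype:
            raise BuildError(
                f"rotamer for {r.residue_type} cannot be built into {restype}")
    if model.altlocs(res):
        raise BuildError(
            f"residue {residue_id} already has alternate conformers; "
            "strip them before building")
    n_conformers = 1 + len(rotamers)
    if n_conformers > 25:
        raise BuildError(
            f"{n_conformers} conformers exceed the altloc alphabet")

    defs = chi_definitions(restype)
    if not defs:
        raise UnsupportedResidueError(f"{restype} is not buildable")
    orig = model.conformer_coords(res)

    shared = BACKBONE_ATOMS if mode == "calpha" else set()
    # snapshot before mutating: gemmi atom refs do not survive add_atom
    template_atoms = [(a.name, a.element.name, a.b_iso) for a in res
                      if a.element.name != "H" and a.name not in shared]

    # the observed conformation becomes conformer A
    for a in res:
        if a.name not in shared and a.element.name != "H":
            a.altloc = "A"

    letters = string.ascii_uppercase[1:1 + len(rotamers)]
    for letter, rot in zip(letters, rotamers):
        target = (rot.peak_angles if at_peak_angles
                  else rot.matched_entry.modal_chi_angles)
        coords = {k: v.copy() for k, v in orig.items()}
        for d, angle in zip(defs, target):
            set_dihedral(coords, d.atom_quadruple, d.rotating_set, angle)
        for name, element, b_iso in template_atoms:
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(element)
            a.altloc = letter
            a.b_iso = b_iso
            a.occ = 1.0
            a.pos = gemmi.Position(*coords[name])
            res.add_atom(a)
    return model


def _centi_allocate(weights: Sequence[float]) -> list[float]:
    """Occupancies on a 2-decimal grid summing to exactly 1.00; the
    rounding remainder goes to the first (conformer A)."""
    total = float(sum(weights))
    if total <= 0:
        raise ParameterError("occupancy weights must have positive sum")
    centi = [int(round(100.0 * w / total)) for w in weights]
    centi[0] += 100 - sum(centi)
    if centi[0] < 0:
        raise ParameterError(f"occupancy rounding failed for weights {weights}")
    return [c / 100.0 for c in centi]


def assign_occupancies(model: MultiConformerModel,
                       residue_id,
                       scheme: str = "area-weighted",
                       seed_areas: dict[str, float] | None = None,
                       ) -> dict[str, float]:
    """Set per-conformer occupancies for one residue.

    ``area-weighted`` uses ``seed_areas`` (altloc -> relative density-peak
    area) renormalized over the residue's conformers; with missing areas it
    falls back to uniform with a warning.  Occupancies are rounded to two
    decimals with the remainder added to conformer A so they sum to exactly
    1.00.  Returns altloc -> occupancy.
    """
    if scheme not in ("area-weighted", "uniform"):
        raise ParameterError(f"unknown occupancy scheme {scheme!r}")
    res = model.find_residue(residue_id)
    alts = model.altlocs(res)
    if not alts:
        return {}
    weights = None
    if scheme == "area-weighted":
        if seed_areas and all(al in seed_areas and seed_areas[al] is not None
                              and seed_areas[al] > 0 for al in alts):
            weights = [seed_areas[al] for al in alts]
        else:
            logger.warning("residue %s: missing peak areas, falling back to "
                           "uniform occupancies", residue_id)
    if weights is None:
        weights = [1.0] * len(alts)
    occs = _centi_allocate(weights)
    table = dict(zip(alts, occs))
    for a in res:
        if a.altloc != BLANK_ALTLOC:
            a.occ = table[a.altloc]
        else:
            a.occ = 1.0
    return table


def prune_low_occupancy(model: MultiConformerModel,
                        min_occupancy: float = 0.01) -> list[tuple]:
    """Remove conformers with occupancy below ``min_occupancy`` and
    renormalize the survivors per residue.

    A residue that would lose every conformer keeps its highest-occupancy
    one (with a warning).  A residue reduced to a single conformer loses
    its altloc labels.  Returns the ids of residues changed.
    """
    changed = []
    for rid, res in model.residues():
        alts = model.altlocs(res)
        if not alts:
            continue
        occ = {al: max(a.occ for a in res if a.altloc == al) for al in alts}
        keep = [al for al in alts if occ[al] >= min_occupancy]
        if not keep:
            best = max(alts, key=lambda al: (occ[al], al == "A"))
            logger.warning("residue %s: pruning would delete all conformers; "
                           "keeping %s", rid, best)
            keep = [best]
        if len(keep) == len(alts):
            continue
        drop = set(alts) - set(keep)
        idx = [i for i in range(len(res)) if res[i].altloc in drop]
        for i in reversed(idx):
            del res[i]
        if len(keep) == 1:
            for a in res:
                a.altloc = BLANK_ALTLOC
                a.occ = 1.0
        else:
            occs = _centi_allocate([occ[al] for al in keep])
            table = dict(zip(keep, occs))
            for a in res:
                if a.altloc != BLANK_ALTLOC:
                    a.occ = table[a.altloc]
        changed.append(rid)
    return changed


def b_norm(model: MultiConformerModel, sample_sd: bool = False) -> pd.DataFrame:
    """Normalized B factors: (B - mean)/sd over all protein atoms.

    Population standard deviation by default (``sample_sd`` switches to the
    n-1 denominator).  Raises on fewer than two atoms or zero spread.
    """
    rows = [(rid[0], rid[1], rid[2], rid[3], a.name, a.altloc, a.b_iso)
            for rid, a in model.protein_atoms()]
    if len(rows) < 2:
        raise ParameterError("b_norm needs at least two protein atoms")
    df = pd.DataFrame(rows, columns=["chain", "resi", "icode", "restype",
                                     "atom", "altloc", "b"])
    sd = df["b"].std(ddof=1 if sample_sd else 0)
    if sd == 0:
        raise ParameterError("all B factors identical: zero spread")
    df["b_norm"] = (df["b"] - df["b"].mean()) / sd
    df["altloc"] = df["altloc"].replace(BLANK_ALTLOC, "")
    return df


def rscc(dmap: DensityMap,
         model: MultiConformerModel,
         selection: Iterable[np.ndarray],
         radius: float = 2.0) -> float:
    """Real-space correlation coefficient for a selection of atom positions.

    Pearson correlation between observed (sigma-scaled) map values and the
    Gaussian-atom density calculated from the whole model, over grid nodes
    within ``radius`` A of any selected position.
    """
    if not dmap.sigma_scaled:
        raise ParameterError("rscc requires a sigma-scaled map")
    positions = [np.asarray(p, dtype=float) for p in selection]
    if not positions:
        raise ParameterError("empty selection")
    mask = mask_near_atoms(positions, dmap.cell, dmap.grid_shape, radius)
    if mask.sum() < 10:
        raise ParameterError(
            f"selection too small: only {int(mask.sum())} grid points in mask")
    calc = gaussian_density(model.atom_specs(), dmap.cell, dmap.grid_shape)
    obs_v = dmap.grid[mask]
    calc_v = calc[mask]
    return float(np.corrcoef(obs_v, calc_v)[0, 1])


def atom_positions(model: MultiConformerModel, residue_id,
                   altloc: str | None = None,
                   atom_names: Iterable[str] | None = None) -> list[np.ndarray]:
    """Convenience selection helper for :func:`rscc`."""
    res = model.find_residue(residue_id)
    names = set(atom_names) if atom_names is not None else None
    out = []
    for a in res:
        if altloc is not None and a.altloc not in (BLANK_ALTLOC, altloc):
            continue
        if names is not None and a.name not in names:
            continue
        out.append(np.array([a.pos.x, a.pos.y, a.pos.z]))
    return out


def write_model(model: MultiConformerModel, path: str | Path,
                format: str | None = None) -> None:
    """Write the model as PDB or mmCIF (inferred from the suffix).

    Altlocs, two-decimal occupancies and B factors are emitted; models that
    overflow the fixed PDB serial space get an error suggesting mmCIF.
    """
    path = Path(path)
    if format is None:
        format = "mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB"
    st = model.structure
    if format.upper() == "PDB":
        for rid, res in model.residues():
            if res.seqid.num > 9999:
                raise BuildError(
                    f"residue number {res.seqid.num} does not fit PDB "
                    "columns; write mmCIF instead")
        st.write_pdb(str(path))
    elif format.lower() in ("mmcif", "cif"):
        st.setup_entities()
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ParameterError(f"unknown format {format!r}")


def clash_report(model: MultiConformerModel,
                 overlap_tolerance: float = 0.4) -> pd.DataFrame:
    """Report (never block on) heavy-atom clashes between residues.

    Two atoms clash when they can coexist (same altloc, or either blank)
    and their distance is more than ``overlap_tolerance`` A below the sum
    of their van der Waals radii.  Waters are included: a new conformer
    that displaces a water is reported, not deleted.
    """
    from scipy.spatial import cKDTree

    atoms = []
    for rid, res in model.residues():
        for a in res:
            if a.element.name == "H":
                continue
            atoms.append((rid, a.name, a.altloc,
                          np.array([a.pos.x, a.pos.y, a.pos.z]),
                          _VDW.get(a.element.name, 1.7)))
    if not atoms:
        return pd.DataFrame(columns=["chain1", "resi1", "atom1", "altloc1",
                                     "chain2", "resi2", "atom2", "altloc2",
                                     "distance", "overlap"])
    pos = np.array([a[3] for a in atoms])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=2 * max(_VDW.values()), output_type="ndarray")
    rows = []
    for i, j in pairs:
        rid1, n1, al1, p1, r1 = atoms[i]
        rid2, n2, al2, p2, r2 = atoms[j]
        if rid1[:3] == rid2[:3]:
            continue
        if not (al1 == al2 or BLANK_ALTLOC in (al1, al2)):
            continue
        d = float(np.linalg.norm(p1 - p2))
        if d < r1 + r2 - overlap_tolerance:
            rows.append((rid1[0], rid1[1], n1, al1.strip("\0"),
                         rid2[0], rid2[1], n2, al2.strip("\0"),
                         round(d, 3), round(r1 + r2 - d, 3)))
    return pd.DataFrame(rows, columns=["chain1", "resi1", "atom1", "altloc1",
                                       "chain2", "resi2", "atom2", "altloc2",
                                       "distance", "overlap"])
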