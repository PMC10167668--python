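"""Synthetic ground-truth multi-conformer models and density maps.

Every stage of the pipeline is testable without downloads: this module
builds ideal residues at library rotamers, places occupancy-weighted
conformer mixtures in a periodic P1 box, renders a Gaussian-atom density
map (the forward model of :mod:`flexbuild.forward`) with optional i.i.d.
Gaussian noise, and packages named fixture cases with machine-readable
truth tables.

The forward model emulates the general shape of a 2mFo-DFc map but omits
form factors, Fourier-truncation ripple, solvent and symmetry mates.  One
consequence matters for thresholds: a synthetic cell containing a single
residue is almost empty, so the map standard deviation is far below the
typical atomic density -- the opposite of a real protein crystal, where
1 sigma is comparable to weakly occupied atomic density.  Each fixture
therefore carries a recommended sigma threshold defined as 0.3 x the minor
conformer's probe-atom density in sigma units, transplanting the "30% of
the weakest signal" role that the 0.3-sigma default plays on real maps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .building import BLANK_ALTLOC, MultiConformerModel, write_model
from .density import DensityMap, sigma_scale, write_map
from .errors import ParameterError, UnsupportedResidueError
from .forward import gaussian_density
from .rotamers import RotamerLibrary, chi_definitions, load_library
from .templates import build_conformer, element_of

__all__ = ["SyntheticSpec", "build_ideal_residue", "render_map",
           "make_fixture", "fixture_cases", "FixtureBundle"]


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic map: cell, sampling, atomic B factor
    and noise level.  The seed fixes all randomness."""

    cell_edge: float = 20.0       # cubic P1 cell edge (A)
    grid_spacing: float = 0.25    # target grid spacing (A)
    b_factor: float = 15.0        # isotropic B (A^2) -> Gaussian width
    noise_sd: float = 0.0         # i.i.d. Gaussian noise, pre-scaling units
    seed: int = 1

    def __post_init__(self):
        if self.grid_spacing >= self.cell_edge / 4:
            raise ParameterError("grid spacing must be < cell/4")

    @property
    def cell(self) -> gemmi.UnitCell:
        e = self.cell_edge
        return gemmi.UnitCell(e, e, e, 90.0, 90.0, 90.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        n = int(round(self.cell_edge / self.grid_spacing))
        return (n, n, n)


def build_ideal_residue(residue_type: str, rotamer_name: str,
                        library: RotamerLibrary | None = None) -> dict:
    """Ideal-geometry conformer (atom name -> coordinates) at the modal
    chi angles of a named library rotamer."""
    library = library or load_library()
    residue_type = residue_type.upper()
    entries = library.entries(residue_type)
    if not entries:
        raise UnsupportedResidueError(
            f"{residue_type} has no rotamers in the library")
    entry = library.entry(residue_type, rotamer_name)  # KeyError lists names
    return build_conformer(residue_type, entry.modal_chi_angles)


def _conformer_atom_specs(coords: dict, occupancy: float, b: float):
    return [(element_of(name), np.asarray(p, dtype=float), occupancy, b)
            for name, p in coords.items()]


def render_map(atom_specs, spec: SyntheticSpec,
               path: str | Path | None = None) -> DensityMap:
    """Render occupancy-weighted Gaussian atoms into a periodic map.

    ``atom_specs`` are (element, position, occupancy, b) tuples; atoms
    outside the cell are wrapped periodically.  Noise (if any) is seeded by
    ``spec.seed``.  Optionally writes a CCP4 file.
    """
    grid = gaussian_density(atom_specs, spec.cell, spec.shape)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        grid = grid + rng.normal(0.0, spec.noise_sd, size=grid.shape)
    dmap = DensityMap(grid, spec.cell)
    if path is not None:
        write_map(dmap, path)
    return dmap


# ---------------------------------------------------------------------------
# fixture registry

@dataclass(frozen=True)
class ResidueRecipe:
    residue_type: str
    rotamer_names: tuple[str, ...]
    occupancies: tuple[float, ...]
    position: tuple[float, float, float]  # CA placement in the cell

    def __post_init__(self):
        if len(self.rotamer_names) != len(self.occupancies):
            raise ParameterError("one occupancy per rotamer required")
        if abs(sum(self.occupancies) - 1.0) > 1e-9:
            raise ParameterError("occupancies must sum to 1")


_CENTRE = (10.0, 10.0, 10.0)

#: Named ground-truth cases.  The first rotamer of each recipe is the major
#: conformer and doubles as the single-conformer input model.
FIXTURE_RECIPES: dict[str, tuple[ResidueRecipe, ...]] = {
    "single_conformer": (
        ResidueRecipe("SER", ("p",), (1.0,), _CENTRE),
    ),
    "serine_70_30": (
        ResidueRecipe("SER", ("p", "m"), (0.7, 0.3), _CENTRE),
    ),
    "methionine_chi3_split": (
        ResidueRecipe("MET", ("mtp", "mtm"), (0.65, 0.35), _CENTRE),
    ),
    "tyrosine_minor": (
        ResidueRecipe("TYR", ("m-85", "t80"), (0.88, 0.12), _CENTRE),
    ),
    "lysine_chi3_split": (
        ResidueRecipe("LYS", ("mttt", "mtmt"), (0.74, 0.26), _CENTRE),
    ),
    "loop_multi": (
        ResidueRecipe("SER", ("p", "m"), (0.6, 0.4), (5.0, 5.0, 5.0)),
        ResidueRecipe("THR", ("p", "m"), (0.65, 0.35), (15.0, 5.0, 5.0)),
        ResidueRecipe("VAL", ("t", "m"), (0.7, 0.3), (5.0, 15.0, 5.0)),
        ResidueRecipe("LEU", ("mt", "tp"), (0.6, 0.4), (5.0, 5.0, 15.0)),
        ResidueRecipe("MET", ("mtp", "mtm"), (0.55, 0.45), (13.0, 13.0, 13.0)),
    ),
}


def fixture_cases() -> tuple[str, ...]:
    return tuple(FIXTURE_RECIPES)


@dataclass
class FixtureBundle:
    """One generated fixture: file paths plus in-memory truth."""

    case: str
    model_path: Path          # single-conformer input model
    truth_model_path: Path    # ground-truth multi-conformer model
    map_path: Path
    truth_path: Path          # truth table CSV
    meta_path: Path           # JSON: noise level, recommended threshold
    truth: list[dict]
    spec: SyntheticSpec
    sigma_threshold: float    # recommended detection threshold, sigma units
    noise_sd: float


def _residue_conformers(recipe: ResidueRecipe, library: RotamerLibrary):
    """Per-conformer coordinate dicts, translated so CA sits at the recipe
    position; all conformers share backbone atoms."""
    out = []
    for name in recipe.rotamer_names:
        coords = build_ideal_residue(recipe.residue_type, name, library)
        shift = np.asarray(recipe.position) - coords["CA"]
        out.append({k: v + shift for k, v in coords.items()})
    return out


def _make_structure(recipes, conformer_sets, occupancy_sets,
                    cell: gemmi.UnitCell, b: float,
                    multi: bool) -> MultiConformerModel:
    st = gemmi.Structure()
    st.cell = cell
    st.spacegroup_hm = "P 1"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (recipe, conformers, occs) in enumerate(
            zip(recipes, conformer_sets, occupancy_sets), start=1):
        res = gemmi.Residue()
        res.name = recipe.residue_type
        res.seqid = gemmi.SeqId(i, " ")
        res.het_flag = "A"  # ATOM records even for isolated residues
        if multi and len(conformers) > 1:
            for ci, (coords, occ) in enumerate(zip(conformers, occs)):
                letter = chr(ord("A") + ci)
                for aname, p in coords.items():
                    atom = gemmi.Atom()
                    atom.name = aname
                    atom.element = gemmi.Element(element_of(aname))
                    atom.pos = gemmi.Position(*p)
                    atom.altloc = letter
                    atom.occ = occ
                    atom.b_iso = b
                    res.add_atom(atom)
        else:
            for aname, p in conformers[0].items():
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(element_of(aname))
                atom.pos = gemmi.Position(*p)
                atom.altloc = BLANK_ALTLOC
                atom.occ = 1.0
                atom.b_iso = b
                res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return MultiConformerModel(st)


def make_fixture(case: str,
                 out_dir: str | Path,
                 seed: int = 1,
                 noise_frac: float = 0.10,
                 spec: SyntheticSpec | None = None,
                 library: RotamerLibrary | None = None) -> FixtureBundle:
    """Generate a named fixture: input model, truth model, map and truth
    table, all deterministic for a given seed.

    The noise standard deviation is ``noise_frac`` times the noiseless
    density at the minor conformer's probe atom (the weakest signal the
    pipeline must recover); the recommended detection threshold is 0.3 x
    that same signal, expressed in sigma units of the final noisy map.
    """
    if case not in FIXTURE_RECIPES:
        raise KeyError(f"unknown fixture case {case!r}; "
                       f"valid cases: {sorted(FIXTURE_RECIPES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    library = library or load_library()
    spec = spec or SyntheticSpec(seed=seed)
    spec.seed = seed
    recipes = FIXTURE_RECIPES[case]

    conformer_sets = [_residue_conformers(r, library) for r in recipes]
    occupancy_sets = [r.occupancies for r in recipes]

    atom_specs = []
    for conformers, occs in zip(conformer_sets, occupancy_sets):
        for coords, occ in zip(conformers, occs):
            atom_specs.extend(_conformer_atom_specs(coords, occ, spec.b_factor))

    noiseless = render_map(atom_specs,
                           SyntheticSpec(spec.cell_edge, spec.grid_spacing,
                                         spec.b_factor, 0.0, seed))

    # weakest signal: density at the distal probe atom of the least
    # occupied conformer (per residue), minimized over residues
    refs = []
    for recipe, conformers, occs in zip(recipes, conformer_sets, occupancy_sets):
        defs = chi_definitions(recipe.residue_type)
        probe = defs[-1].probe_atom
        idx = int(np.argmin(occs))
        refs.append(noiseless.interpolate(conformers[idx][probe]))
    ref_density = float(min(refs))

    noise_sd = noise_frac * ref_density
    spec = SyntheticSpec(spec.cell_edge, spec.grid_spacing, spec.b_factor,
                         noise_sd, seed)
    map_path = out_dir / f"{case}.ccp4"
    dmap = render_map(atom_specs, spec, path=map_path)
    sigma_threshold = 0.3 * ref_density / float(dmap.grid.std())

    truth_model = _make_structure(recipes, conformer_sets, occupancy_sets,
                                  spec.cell, spec.b_factor, multi=True)
    input_model = _make_structure(recipes, conformer_sets, occupancy_sets,
                                  spec.cell, spec.b_factor, multi=False)
    model_path = out_dir / f"{case}_input.pdb"
    truth_model_path = out_dir / f"{case}_truth.pdb"
    write_model(input_model, model_path)
    write_model(truth_model, truth_model_path)

    truth = []
    for i, recipe in enumerate(recipes, start=1):
        for name, occ in zip(recipe.rotamer_names, recipe.occupancies):
            truth.append({"chain": "A", "resi": i,
                          "restype": recipe.residue_type,
                          "rotamer_name": name, "occupancy": occ})
    truth_path = out_dir / f"{case}_truth.csv"
    with open(truth_path, "w") as fh:
        fh.write("chain,resi,restype,rotamer_name,occupancy\n")
        for row in truth:
            fh.write("{chain},{resi},{restype},{rotamer_name},"
                     "{occupancy}\n".format(**row))

    meta = {"case": case, "seed": seed, "noise_sd": noise_sd,
            "reference_density": ref_density,
            "sigma_threshold": sigma_threshold,
            "cell_edge": spec.cell_edge, "grid_spacing": spec.grid_spacing,
            "b_factor": spec.b_factor}
    meta_path = out_dir / f"{case}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))

    return FixtureBundle(case, model_path, truth_model_path, map_path,
                         truth_path, meta_path, truth, spec,
                         sigma_threshold, noise_sd)
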