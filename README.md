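# flexbuild

Automated multi-conformer protein model building from electron-density
dihedral sampling.

## The problem

X-ray crystallography averages over every copy of a protein in the lattice,
so electron-density maps routinely contain evidence for alternative
side-chain conformations that deposited single-conformer models ignore.
Systematic density sampling around side-chain dihedrals (the *Ringer*
approach) detects these weakly populated rotamers down to ~0.3σ, but turning
the detections into an explicit model — alternate conformers with altloc
labels and occupancies, ready for refinement — has traditionally been
manual.  `flexbuild` automates that step for crystallographers and anyone
mining deposited maps for hidden flexibility.

## The method

Given a real-space map (CCP4/MRC, e.g. a 2mFo−DFc map) and a
single-conformer model (PDB/mmCIF):

1. **Density sampling.**  The map is normalized to σ units
   (ρ → (ρ − μ)/σ over all grid points).  For every χ dihedral of every
   eligible residue, the probe atom (the atom directly bonded distal to the
   rotating bond, e.g. OG for serine χ1) is rotated rigidly through an
   absolute dihedral grid (default 10° steps) and the map is interpolated
   trilinearly (periodic P1 wrapping) at each position, giving a circular
   density trace per χ.
2. **Peak detection.**  Local maxima of the circularized trace with height
   ≥ σ-threshold (default 0.3σ; 0.35σ recommended for evaluating real
   maps), prominence ≥ 0.1σ and separation ≥ 30° are kept.  Each peak's
   area integrates the trace over its contiguous super-threshold run
   (trapezoid rule, σ·deg) and is normalized across peaks of the same χ —
   the relative area seeds the conformer occupancy.
3. **Rotamer assembly.**  Peak angles are combined across all χ of a
   residue into every possible combination (two peaks on each of two
   dihedrals → four candidates).  A combination matches an ideal-rotamer
   library entry when every χ is within a tolerance (default ≤30°,
   circular, 180°-periodic for the symmetric terminal dihedrals of
   Asp/Glu/Phe/Tyr) of the entry's modal angles; ties go to the rotamer
   most frequent in the PDB.  Matches sharing a name are collapsed.
4. **Model building.**  The input conformation always stays as conformer A;
   each surviving rotamer is built as the next altloc letter in descending
   peak-support order, its side chain generated by rigid χ rotations to the
   library's modal angles.  Building can branch at Cα or duplicate the
   whole residue (default), occupancies are seeded area-weighted (or
   uniform) and rounded to the 2-decimal PDB convention summing to exactly
   1.00, and near-zero-occupancy conformers can be pruned.  Refinement of
   the result is deliberately left to external programs.

Validation helpers provide per-selection real-space correlation
coefficients (RSCC, against a Gaussian-atom forward model; ≥0.8 confident,
≥0.7 minimal) and normalized B factors, B_norm = (B − B_μ)/B_σ over all
protein atoms.

A synthetic-data module generates ground-truth multi-conformer models and
Gaussian-atom maps (width from B = 8π²⟨u²⟩, amplitude ∝ electron count,
optional seeded i.i.d. noise) so the whole pipeline is testable without
downloads.

## Worked example

`examples/02_full_pipeline_methionine.py` builds a methionine whose two
conformers differ only in χ3 (rotamers `mtp`/`mtm` at 0.65/0.35), renders
a noisy map, and runs the pipeline from the single-conformer input:

```
rotamer report:
restype rotamer_name  support_sigma  seed_relative_area  is_original
    MET          mtp      13.122517            0.711291         True
    MET          mtm       7.091954            0.288709        False

build report:
chain  resi restype        disposition  n_conformers   occupancies
    A     1     MET built-1-alternates             2 A:0.71;B:0.29
```

Two χ3 peaks are detected; the original `mtp` conformation keeps altloc A
and the recovered minor rotamer `mtm` is built as altloc B with an
occupancy seeded from the relative χ3 peak areas (0.71/0.29 against a true
0.65/0.35 split).  The other examples cover trace/peak inspection,
parameter grid searching, and RSCC/B_norm validation.

## Command line

```sh
flexbuild run --map map.ccp4 --model model.pdb --sigma 0.3 --tolerance 30 \
              --step 10 --build-mode full-residue --occupancy area-weighted \
              --min-occ 0.01 --strip-altlocs --out outdir
flexbuild fixtures serine_70_30 --out fixtures --seed 1
flexbuild grid --map map.ccp4 --model model.pdb \
               --sigmas 0.3,0.35,0.5 --tolerances 20,30,40
```

`run` writes the multi-conformer model (PDB + mmCIF), per-angle trace CSV,
peak CSV, rotamer report, build report and clash report; every residue
appears in the build report with a disposition.  Exit code 0 even when no
alternates are found.

## Rotamer library schema

The bundled table (`src/flexbuild/data/rotamer_library.csv`) is a
transcription of the published penultimate rotamer library — columns
`residue_type, rotamer_name, chi1..chi4` (blank where undefined, degrees
in [−180, 180)) and `frequency` (relative PDB abundance).  Modal angles
and frequencies are approximate to a few degrees / few percent of the
published table; pass any CSV with the same schema to
`flexbuild.load_library` to substitute a newer library.

## Limitations

Gly/Ala have no χ and Pro's ring-constrained χ1 is excluded; sampling uses
one conformer per residue, so conformations whose *proximal* dihedrals
differ from the input conformer can shadow distal ones (common for
Lys/Arg); only periodic P1 wrapping is applied (no crystallographic
symmetry expansion); maps are consumed precomputed (no structure-factor
handling); waters are never moved, and clashes are reported rather than
resolved.  See `docs/methods.md` for the full account.
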