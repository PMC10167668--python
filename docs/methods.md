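# Methods

This note documents the models, numerical choices and limitations behind
`flexbuild`, in the order the pipeline applies them.

## Density model and σ units

A map is a 3-D grid covering one full unit cell, treated as periodic (P1).
Sigma scaling subtracts the grid mean and divides by the population
standard deviation over all grid points, so every threshold in the package
is in "standard deviations above the map mean".  Interpolation is
trilinear in fractional coordinates with periodic wrapping: it reproduces
grid values exactly at nodes, is monotone between them, and is adequate at
the 10° angular granularity of the dihedral sampling (documented so users
comparing against tricubic implementations know the difference is ours).
Crystallographic symmetry beyond periodic wrapping is not applied; users
must supply whole-cell maps or maps in P1.

## Dihedral sampling

For each χ the probe atom is the single atom directly bonded distal to the
rotating bond (OG for Ser χ1, SD for Met χ2, ...).  The probe is rotated
rigidly about the χ bond axis so the dihedral takes each value of an
**absolute** grid {0°, 10°, ..., 350°}; bond length and bond angle to the
axis atoms are preserved exactly (Rodrigues rotation).  Sampling on an
absolute grid (rather than offsets from the current conformation) makes
traces comparable across residues and runs; the 10° default matches the
granularity of the original dihedral-sampling literature and is
configurable.  Angles follow the signed IUPAC convention in [−180, 180);
the trace reports angles in [0, 360) for plotting convenience.

Only one conformer per residue is sampled (after optionally stripping
input altlocs to the highest-occupancy conformer).  Consequence: a
conformation that differs from the sampled conformer in a *proximal*
dihedral places its distal atoms on a different circle, so its distal
peaks are invisible.  This is inherent to single-pass dihedral sampling —
it is why a χ3-split lysine is recoverable but a χ1-split leucine's second
χ2 peak is not — and is the main reason flexible Lys/Arg side chains are
under-built.  Hydrogens are ignored throughout.

## Peak detection

Peaks are local maxima of the circularized trace (virtually extended one
period on each side, so maxima spanning 0°/360° are found once) with

* height ≥ threshold (default 0.3σ; 0.35σ exposed as the stricter
  evaluation preset for real maps),
* prominence ≥ 0.1σ,
* separation ≥ 30° (closer maxima merge, keeping the higher).

The prominence and separation defaults are this package's choices: at 10°
sampling they suppress double-counting of shoulders without hiding genuine
bimodality, and both are plain parameters for grid searching.  Peak area
integrates the **raw** σ values (not value-minus-threshold) over the
contiguous super-threshold run containing the maximum, by trapezoid rule
in degrees; raw integration keeps areas comparable across thresholds.  A
single-sample run falls back to a one-step rectangle so detected peaks
always have positive area.  If two maxima share one super-threshold run,
each integrates the full run; normalization still yields relative areas
summing to 1 per χ.

Relative areas for occupancy seeding are taken from the first χ (outward
from χ1) exhibiting more than one peak.  The area–occupancy relation is
genuinely strong only for unbranched single-χ side chains (serine is the
clean case); for branched or long side chains the attribution is
heuristic, which is why seeded occupancies are starting values for
refinement, never estimates.

## Rotamer assembly

All per-χ peak choices are enumerated (Cartesian product); each
combination matches a library entry iff **every** χ deviates by at most
the tolerance (default 30°) from the entry's modal angle.  The per-χ
maximum deviation (not an RMS aggregate) is used because a single
out-of-tolerance dihedral makes a rotamer assignment wrong regardless of
how well the others fit.  Circular differences are 180°-periodic for the
chemically symmetric terminal dihedrals (Asp χ2, Glu χ3, Phe/Tyr χ2),
which prevents the two indistinguishable branches from generating
duplicate conformers.  Among multiple matches the highest PDB frequency
wins (ties: lexicographic name, for determinism).  Candidates collapsing
onto one rotamer name keep the smallest maximum deviation.  Residues with
any χ lacking peaks are skipped — the conservative reading; an optional
fill-from-library mode for unresolved distal χ was considered and
rejected as more aggressive than the evidence supports.

The input model's own conformation is matched against the library **for
naming only**: it is retained even when non-rotameric, because observed
structure is never deleted.

## Building, altlocs, occupancies

Conformer A is always the input conformation, bit-identical.  Additional
rotamers become B, C, ... in descending peak-support order (support = the
minimum peak height among the contributing peaks), so lower letters
correspond to stronger density.  New side chains are generated by rigid χ
rotations of the input side chain to the matched entry's **modal** angles
(ideal-rotamer building; a flag builds at the detected peak angles
instead).  Bond lengths and angles are never altered.  In full-residue
mode (default) backbone atoms are duplicated per conformer with identical
coordinates — refinement separates them, which is how backbone
heterogeneity emerges; in Cα-branch mode the backbone keeps blank altloc
and occupancy 1.  B factors are copied unchanged from the source atoms:
the simplest defensible seed for refinement.  More than 25 alternates
would exhaust the altloc alphabet and raise an error.

Occupancies: area-weighted by default (each conformer maps to the
attribution-χ peak circularly nearest its χ value; weights renormalize
over the residue's conformers), uniform as fallback with a warning.
Values are rounded to two decimals with the remainder added to conformer
A, so the written sum is exactly 1.00.  Pruning removes conformers below
a minimum occupancy (default 0.01), renormalizes survivors, and demotes a
lone survivor to blank altloc; a residue never loses all conformers.

Waters are never moved or deleted even when a new conformer overlaps one;
clashes (heavy-atom distance more than 0.4 Å below the van der Waals sum,
between altloc-compatible atoms of different residues) are reported to a
CSV and never block building — the philosophy is build everything
defensible, let the crystallographer inspect.

## Validation formulas

* **B_norm** = (B − B_μ)/B_σ over all protein atoms; population standard
  deviation by default (a documented choice; sample sd available).
* **RSCC**: Pearson correlation between observed σ-scaled density and the
  Gaussian-atom forward density of the whole model, over grid nodes within
  2.0 Å (default) of the selected atoms.  Selections smaller than 10 grid
  points are rejected.  Because Pearson correlation is invariant to linear
  transforms, σ scaling of either side does not affect it.

## Synthetic ground truth

The forward model renders each atom as one isotropic Gaussian with
amplitude ∝ occupancy × electron count and variance u² = B/(8π²); maps are
linear in occupancy by construction.  Noise is i.i.d. Gaussian per voxel,
seeded with numpy's default PCG64 generator for cross-platform
determinism.  Defaults: 20 Å cubic P1 cell, 0.25 Å grid, B = 15 Ų.  What
this emulates: the local shape and occupancy-weighting of a 2mFo−DFc map
around a side chain.  What it does not: atomic form factors, Fourier
truncation ripple (which correlates noise between voxels), bulk solvent,
model-phase bias and symmetry mates.  Passing tests on these maps
demonstrate the detection/assembly/building logic, not performance on
real crystallographic noise.

**Threshold calibration for fixtures.**  In a real crystal the cell is
densely packed and 1σ of a 2mFo−DFc map is comparable to weakly occupied
atomic density, so a 0.3σ threshold asks for roughly 30% of a weak
conformer's signal.  A synthetic cell holding a single residue is almost
empty, so the global σ is strongly deflated and the same 0.3σ would sit
far below the noise floor relative to the peaks.  Each fixture therefore
carries a recommended threshold defined as 0.3 × (noiseless density at
the minor conformer's distal probe atom, in σ units of the final noisy
map) — the same "30% of the weakest expected signal" rule, expressed on
the fixture's σ scale.  Fixture noise is likewise anchored to that
reference signal (default sd = 10% of it).

Fixture registry: a single-conformer control; a 0.7/0.3 serine; a χ3-split
methionine; a tyrosine with a 0.12-occupancy minor conformer; a χ3-split
lysine; and a five-residue multi-conformer group.  In the multi-residue
case the residues are placed well separated in one cell (they are not a
covalently continuous loop; density overlap, not connectivity, is what
the sampling sees).  Branched β-carbon residues (Thr/Val/Ile) place their
second γ atom on the same χ1 circle as the probe atom, so a two-conformer
threonine legitimately produces a third χ1 peak from the other
conformer's CG2 — an inherent ambiguity of dihedral sampling that the
fixtures deliberately exhibit.

## Problem sizes

The test suite and the acceptance script run entirely on the synthetic
fixtures above: 80³ grids, one to five residues, 36-sample traces, and 20
noisy realizations for the serine occupancy-recovery statistic.  These
sizes exercise every code path while keeping a full run in seconds.

## Known limitations

* Single-pass sampling cannot see conformations that differ from the
  sampled conformer in a proximal dihedral (see above).
* No backbone sampling: backbone heterogeneity appears only through
  refinement of duplicated backbones.
* Occupancy seeds are peak-area heuristics; refinement owns the final
  values.
* Altloc letters are assigned per residue independently; no attempt is
  made to form a consistent altloc network across neighboring residues.
* Cys in disulfides is sampled and built like any other residue; inspect
  such sites manually.
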