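"""Assemble detected density peaks into named candidate rotamers.

Peak angles from each chi of a residue are combined into every possible
per-chi choice (Cartesian product).  Each combination is matched against
the ideal rotamer library: it matches an entry when every chi deviates from
the entry's modal angle by at most the tolerance (circular difference;
180-degree periodic for symmetric terminal dihedrals).  When several
entries match, the one most frequent in the PDB wins.  Candidates mapping
to the same rotamer name are collapsed to the best-geometry representative
and the survivors are ordered largest-peak-first for building.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .errors import UnsupportedResidueError
from .peaks import DensityPeak
from .rotamers import (RotamerLibrary, RotamerLibraryEntry, chi_definitions,
                       chi_deviation)

logger = logging.getLogger(__name__)

__all__ = ["CandidateRotamer", "enumerate_combinations", "match_to_library",
           "assemble_rotamers", "DEFAULT_TOLERANCE"]

#: Default angular tolerance (deg) for matching ideal rotamer geometry.
DEFAULT_TOLERANCE = 30.0


@dataclass(frozen=True)
class CandidateRotamer:
    """One peak-angle combination for a residue, possibly matched to a
    library entry."""

    residue_id: tuple
    residue_type: str
    peak_angles: tuple[float, ...]          # one per chi
    support: float                          # min peak height (sigma)
    seed_relative_area: float | None        # from the attribution chi's peak
    matched_entry: RotamerLibraryEntry | None = None
    max_deviation: float | None = None
    is_original: bool = False

    @property
    def rotamer_name(self) -> str | None:
        return self.matched_entry.rotamer_name if self.matched_entry else None


def attribution_chi(peaks_by_chi: Mapping[int, Sequence[DensityPeak]]) -> int | None:
    """The chi used for occupancy attribution: the first chi (outward from
    chi1) with more than one detected peak; None when every chi is
    unimodal."""
    for chi in sorted(peaks_by_chi):
        if len(peaks_by_chi[chi]) > 1:
            return chi
    return None


def enumerate_combinations(residue_id: tuple,
                           residue_type: str,
                           peaks_by_chi: Mapping[int, Sequence[DensityPeak]],
                           ) -> list[CandidateRotamer]:
    """All per-chi peak combinations for one residue (unmatched candidates).

    Every chi of the residue type must have at least one peak; the caller
    skips (and logs) residues that do not satisfy this.
    """
    n_chi = len(chi_definitions(residue_type))
    if n_chi == 0:
        raise UnsupportedResidueError(
            f"{residue_type} has no chi dihedrals to assemble")
    missing = [k for k in range(1, n_chi + 1) if not peaks_by_chi.get(k)]
    if missing:
        raise ValueError(
            f"residue {residue_id}: no peaks on chi {missing}; skip upstream")
    attr = attribution_chi(peaks_by_chi)
    per_chi = [list(peaks_by_chi[k]) for k in range(1, n_chi + 1)]
    out = []
    for combo in itertools.product(*per_chi):
        seed = combo[attr - 1].relative_area if attr is not None else 1.0
        out.append(CandidateRotamer(
            residue_id=residue_id,
            residue_type=residue_type,
            peak_angles=tuple(p.angle for p in combo),
            support=min(p.height for p in combo),
            seed_relative_area=seed,
        ))
    return out


def _deviation(entry: RotamerLibraryEntry, angles: Sequence[float]) -> float:
    devs = [
        chi_deviation(a, m, symmetric=d.symmetric)
        for a, m, d in zip(angles, entry.modal_chi_angles,
                           chi_definitions(entry.residue_type))
    ]
    return max(devs)


def match_to_library(candidate: CandidateRotamer,
                     library: RotamerLibrary,
                     tolerance: float = DEFAULT_TOLERANCE) -> CandidateRotamer:
    """Match a candidate against the library within an angular tolerance.

    All chi angles must individually deviate by <= tolerance from the
    entry's modal angles.  Ties between matching entries go to the entry
    with the highest PDB frequency (then lexicographic name, for
    determinism).  Rejected candidates come back with matched_entry None.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    entries = library.entries(candidate.residue_type)
    if not entries:
        raise UnsupportedResidueError(
            f"residue type {candidate.residue_type!r} absent from library")
    best = None
    for entry in entries:
        dev = _deviation(entry, candidate.peak_angles)
        if dev <= tolerance:
            key = (-entry.pdb_frequency, entry.rotamer_name)
            if best is None or key < best[0]:
                best = (key, entry, dev)
    if best is None:
        return replace(candidate, matched_entry=None, max_deviation=None)
    return replace(candidate, matched_entry=best[1], max_deviation=best[2])


def assemble_rotamers(residue_id: tuple,
                      residue_type: str,
                      peaks_by_chi: Mapping[int, Sequence[DensityPeak]],
                      library: RotamerLibrary,
                      tolerance: float = DEFAULT_TOLERANCE,
                      original_chi: Sequence[float] | None = None,
                      ) -> list[CandidateRotamer]:
    """Enumerate, match and deduplicate candidate rotamers for one residue.

    Candidates mapping to the same rotamer name are collapsed, keeping the
    smallest max_deviation.  Output is sorted by descending support
    (largest peaks built first), ties broken by rotamer name.  When
    ``original_chi`` (the input model's measured chi angles) is given, the
    candidate whose name matches the input conformation's library name is
    flagged ``is_original`` so building can retain it as conformer A.
    """
    candidates = enumerate_combinations(residue_id, residue_type, peaks_by_chi)
    matched = [match_to_library(c, library, tolerance) for c in candidates]
    matched = [c for c in matched if c.matched_entry is not None]

    by_name: dict[str, CandidateRotamer] = {}
    for c in matched:
        prev = by_name.get(c.rotamer_name)
        if prev is None or c.max_deviation < prev.max_deviation:
            by_name[c.rotamer_name] = c

    original_name = None
    if original_chi is not None:
        probe = CandidateRotamer(residue_id, residue_type,
                                 tuple(original_chi), support=0.0,
                                 seed_relative_area=None)
        # naming only: the observed conformation is kept regardless
        probe = match_to_library(probe, library, tolerance)
        original_name = probe.rotamer_name

    out = []
    for name, cand in by_name.items():
        out.append(replace(cand, is_original=(name == original_name)))
    out.sort(key=lambda c: (-c.support, c.rotamer_name))
    return out
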