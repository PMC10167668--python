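"""End-to-end orchestration: map + model in, multi-conformer model out.

The pipeline runs the three model-building stages (density sampling around
every chi of every eligible residue, circular peak detection, rotamer
assembly against the ideal library) and then builds occupancy-weighted
alternate conformers into the model.  Crystallographic refinement of the
result is deliberately left to external programs; the output files are
refinement-ready.

Per-residue failures (missing atoms, unsupported types) are logged and
skipped, never fatal; a run that builds zero alternates is still a
successful run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, building, peaks
from .assembly import assemble_rotamers, attribution_chi
from .building import (MultiConformerModel, assign_occupancies,
                       build_conformers, clash_report, prune_low_occupancy,
                       write_model)
from .density import DensityMap, read_map, ringer_trace, sigma_scale
from .errors import FlexbuildError, IncompleteSideChainError, ParameterError
from .peaks import find_peaks, normalize_peak_areas
from .rotamers import (NON_ROTAMERIC, STANDARD_AMINO_ACIDS, chi_definitions,
                       chi_deviation, load_library, measure_all_chis)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "grid_search"]


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips through a YAML config file."""

    map_path: str = ""
    model_path: str = ""
    out_dir: str = "flexbuild_out"
    sigma_threshold: float = peaks.DEFAULT_THRESHOLD   # 0.3 sigma
    tolerance_deg: float = assembly.DEFAULT_TOLERANCE  # 30 deg
    step_deg: float = 10.0
    min_prominence: float = 0.1
    min_separation_deg: float = 30.0
    build_mode: str = "full-residue"      # or "calpha"
    occupancy_scheme: str = "area-weighted"  # or "uniform"
    min_occupancy: float = 0.01
    strip_altlocs: bool = True
    build_at_peak_angles: bool = False
    write_plots: bool = False
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if self.sigma_threshold < 0 or self.step_deg <= 0:
            raise ParameterError("thresholds must be positive")
        if not (0 < self.tolerance_deg <= 60):
            raise ParameterError("tolerance must be in (0, 60] degrees")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParameterError(f"unparseable config file {path}")
        return cls(**data)


@dataclass
class ResidueReport:
    residue_id: tuple
    disposition: str          # built-N-alternates | no-peaks | no-alternates
    n_conformers: int         #                    | skipped-<reason> | not-eligible
    occupancies: dict


@dataclass
class PipelineResult:
    model: MultiConformerModel
    traces: pd.DataFrame
    peaks: pd.DataFrame
    rotamers: pd.DataFrame
    report: pd.DataFrame
    clashes: pd.DataFrame
    n_alternates_built: int
    out_dir: Path | None = None


def _nearest_peak_area(peak_list, angle: float) -> float | None:
    """relative_area of the peak whose angle is circularly closest."""
    if not peak_list:
        return None
    best = min(peak_list, key=lambda p: chi_deviation(p.angle, angle))
    return best.relative_area


def analyse_residue(dmap: DensityMap, model: MultiConformerModel,
                    rid: tuple, res, config: RunConfig, library):
    """Sampling + detection + assembly for one residue.

    Returns (traces, peaks_by_chi, rotamers, original_chi) or a disposition
    string when the residue cannot be processed.
    """
    restype = rid[3]
    defs = chi_definitions(restype)
    coords = model.conformer_coords(res)
    try:
        original_chi = measure_all_chis(coords, restype)
    except IncompleteSideChainError as exc:
        logger.info("residue %s skipped: %s", rid, exc)
        return "skipped-incomplete"
    traces = []
    peaks_by_chi = {}
    for d in defs:
        tr = ringer_trace(dmap, coords, rid, d, step=config.step_deg)
        traces.append(tr)
        pks = find_peaks(tr, threshold=config.sigma_threshold,
                         min_prominence=config.min_prominence,
                         min_separation=config.min_separation_deg)
        peaks_by_chi[d.chi_index] = pks
    if any(not v for v in peaks_by_chi.values()):
        empty = [k for k, v in peaks_by_chi.items() if not v]
        logger.info("residue %s: no peaks on chi %s", rid, empty)
        return traces, peaks_by_chi, [], original_chi, "no-peaks"
    flat = normalize_peak_areas([p for v in peaks_by_chi.values() for p in v])
    peaks_by_chi = {k: [p for p in flat if p.chi_index == k]
                    for k in peaks_by_chi}
    rots = assemble_rotamers(rid, restype, peaks_by_chi, library,
                             tolerance=config.tolerance_deg,
                             original_chi=original_chi)
    return traces, peaks_by_chi, rots, original_chi, "ok"


def run_pipeline(config: RunConfig,
                 dmap: DensityMap | None = None,
                 model: MultiConformerModel | None = None,
                 library=None,
                 write_outputs: bool = True) -> PipelineResult:
    """Execute the full workflow.

    Inputs may be given as paths in the config or as in-memory objects.
    Writes (when ``write_outputs``) the multi-conformer model plus trace,
    peak, rotamer and build-report CSVs into ``config.out_dir``.
    """
    library = library or load_library()
    if dmap is None:
        dmap = read_map(config.map_path)
    if not dmap.sigma_scaled:
        dmap = sigma_scale(dmap)
    if model is None:
        model = MultiConformerModel.from_file(config.model_path)
    model = model.copy()
    if config.strip_altlocs:
        n = model.strip_alternate_conformers()
        if n:
            logger.info("stripped alternate conformers from %d residues", n)

    trace_rows, peak_rows, rot_rows, report_rows = [], [], [], []
    plots = []
    n_built = 0

    for rid, res in list(model.residues()):
        chain, resi, icode, restype = rid
        if restype not in STANDARD_AMINO_ACIDS or res.het_flag == "H":
            continue  # HETATM/waters/non-standard: never modified
        if restype in NON_ROTAMERIC:
            report_rows.append((chain, resi, restype, "not-eligible", 1, ""))
            continue
        result = analyse_residue(dmap, model, rid, res, config, library)
        if isinstance(result, str):
            report_rows.append((chain, resi, restype, result, 1, ""))
            continue
        traces, peaks_by_chi, rots, original_chi, status = result

        for tr in traces:
            for ang, val in zip(tr.angles, tr.values):
                trace_rows.append((chain, resi, restype, tr.chi_index,
                                   float(ang), float(val)))
        for k in sorted(peaks_by_chi):
            for p in peaks_by_chi[k]:
                peak_rows.append((chain, resi, restype, k, p.angle, p.height,
                                  p.area, p.relative_area))
        if config.write_plots:
            plots.append((rid, traces, peaks_by_chi))

        if status == "no-peaks":
            report_rows.append((chain, resi, restype, "no-peaks", 1, ""))
            continue

        for r in rots:
            rot_rows.append((chain, resi, restype, r.rotamer_name,
                             ";".join(f"{a:.1f}" for a in r.peak_angles),
                             r.max_deviation, r.support,
                             r.seed_relative_area, r.is_original))

        alternates = [r for r in rots if not r.is_original]
        if not alternates:
            report_rows.append((chain, resi, restype, "no-alternates", 1, ""))
            continue

        build_conformers(model, rid, alternates, mode=config.build_mode,
                         at_peak_angles=config.build_at_peak_angles)
        # occupancy seeding: map each conformer to the attribution-chi peak
        # nearest its chi value on that dihedral
        attr = attribution_chi(peaks_by_chi)
        seed_areas = None
        if attr is not None:
            attr_peaks = peaks_by_chi[attr]
            seed_areas = {"A": _nearest_peak_area(attr_peaks,
                                                  original_chi[attr - 1])}
            for letter, r in zip("BCDEFGHIJKLMNOPQRSTUVWXYZ", alternates):
                seed_areas[letter] = _nearest_peak_area(
                    attr_peaks, r.peak_angles[attr - 1])
        occs = assign_occupancies(model, rid, scheme=config.occupancy_scheme,
                                  seed_areas=seed_areas)
        n_built += len(alternates)
        report_rows.append((chain, resi, restype,
                            f"built-{len(alternates)}-alternates",
                            1 + len(alternates),
                            ";".join(f"{al}:{occ:.2f}"
                                     for al, occ in sorted(occs.items()))))

    if config.min_occupancy > 0:
        pruned = prune_low_occupancy(model, config.min_occupancy)
        if pruned:
            logger.info("pruned low-occupancy conformers in %d residues",
                        len(pruned))

    clashes = clash_report(model)

    traces_df = pd.DataFrame(trace_rows, columns=[
        "chain", "resi", "restype", "chi", "angle", "sigma_density"])
    peaks_df = pd.DataFrame(peak_rows, columns=[
        "chain", "resi", "restype", "chi", "peak_angle", "height_sigma",
        "area", "relative_area"])
    rot_df = pd.DataFrame(rot_rows, columns=[
        "chain", "resi", "restype", "rotamer_name", "peak_angles",
        "max_deviation", "support_sigma", "seed_relative_area",
        "is_original"])
    report_df = pd.DataFrame(report_rows, columns=[
        "chain", "resi", "restype", "disposition", "n_conformers",
        "occupancies"])

    out_dir = None
    if write_outputs:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_model(model, out_dir / "multiconformer.pdb")
        write_model(model, out_dir / "multiconformer.cif")
        kw = dict(index=False, float_format="%.6f")
        traces_df.to_csv(out_dir / "traces.csv", **kw)
        peaks_df.to_csv(out_dir / "peaks.csv", **kw)
        rot_df.to_csv(out_dir / "rotamers.csv", **kw)
        report_df.to_csv(out_dir / "build_report.csv", **kw)
        clashes.to_csv(out_dir / "clashes.csv", **kw)
        if config.write_plots:
            _write_plots(plots, out_dir, config)

    return PipelineResult(model, traces_df, peaks_df, rot_df, report_df,
                          clashes, n_built, out_dir)


def _write_plots(plots, out_dir: Path, config: RunConfig) -> None:
    """Per-residue circular density plots with detected peaks starred."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir = out_dir / "plots"
    plot_dir.mkdir(exist_ok=True)
    for rid, traces, peaks_by_chi in plots:
        chain, resi, icode, restype = rid
        fig, axes = plt.subplots(len(traces), 1, squeeze=False,
                                 figsize=(6, 2.2 * len(traces)))
        for ax, tr in zip(axes[:, 0], traces):
            ax.plot(tr.angles, tr.values, lw=1)
            for p in peaks_by_chi.get(tr.chi_index, []):
                ax.plot(p.angle, p.height, "r*", ms=10)
            ax.axhline(config.sigma_threshold, ls="--", c="red", lw=0.8)
            ax.set_ylabel(f"chi{tr.chi_index} (sigma)")
            ax.set_xlim(0, 360)
        axes[-1, 0].set_xlabel("dihedral angle (deg)")
        fig.suptitle(f"{restype} {chain}{resi}")
        fig.tight_layout()
        fig.savefig(plot_dir / f"{chain}{resi}_{restype}.png", dpi=100)
        plt.close(fig)


def grid_search(config: RunConfig,
                sigma_thresholds,
                tolerances,
                dmap: DensityMap | None = None,
                model: MultiConformerModel | None = None,
                library=None) -> pd.DataFrame:
    """Run the pipeline over a sigma-threshold x tolerance grid.

    Tabulates alternates built, residues skipped and clash counts per
    parameter combination on the same inputs.
    """
    sigmas = list(sigma_thresholds)
    tols = list(tolerances)
    if not sigmas or not tols:
        raise ParameterError("empty parameter grid")
    library = library or load_library()
    if dmap is None:
        dmap = read_map(config.map_path)
    if not dmap.sigma_scaled:
        dmap = sigma_scale(dmap)
    if model is None:
        model = MultiConformerModel.from_file(config.model_path)
    rows = []
    for s in sigmas:
        for t in tols:
            cfg = dataclasses.replace(config, sigma_threshold=s,
                                      tolerance_deg=t)
            result = run_pipeline(cfg, dmap=dmap, model=model,
                                  library=library, write_outputs=False)
            skipped = int(result.report["disposition"]
                          .str.startswith(("skipped", "no-peaks")).sum())
            rows.append((s, t, result.n_alternates_built, skipped,
                         len(result.clashes)))
    return pd.DataFrame(rows, columns=["sigma_threshold", "tolerance_deg",
                                       "alternates_built",
                                       "residues_skipped", "clash_pairs"])
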