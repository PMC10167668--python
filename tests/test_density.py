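"""Density maps: I/O, sigma scaling, interpolation and Ringer traces."""

import gemmi
import numpy as np
import pytest

from flexbuild.density import (DensityMap, read_map, ringer_trace,
                               sigma_scale, write_map)
from flexbuild.errors import (FlatMapError, IncompleteSideChainError,
                              ParameterError)
from flexbuild.forward import gaussian_density
from flexbuild.geometry import dihedral
from flexbuild.rotamers import chi_definitions
from flexbuild.synthetic import SyntheticSpec, render_map
from flexbuild.templates import build_conformer, element_of


def _orth(cell, f):
    return np.array(cell.orthogonalize(gemmi.Fractional(*f)).tolist())


@pytest.fixture
def random_map():
    rng = np.random.default_rng(7)
    return DensityMap(rng.normal(size=(10, 12, 14)),
                      gemmi.UnitCell(10, 12, 14, 90, 90, 90))


class TestMapIO:
    def test_write_read_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(10, 10, 10)).astype(np.float32)
        m = DensityMap(grid.astype(np.float64),
                       gemmi.UnitCell(20, 20, 20, 90, 90, 90))
        path = tmp_path / "m.ccp4"
        write_map(m, path)
        r = read_map(path)
        assert np.array_equal(r.grid, grid.astype(np.float64))
        assert r.cell.a == pytest.approx(20.0)

    def test_truncated_file_rejected(self, tmp_path):
        from flexbuild.errors import MapFormatError
        bad = tmp_path / "bad.ccp4"
        bad.write_bytes(b"\x00" * 100)
        with pytest.raises(MapFormatError):
            read_map(bad)

    def test_non_orthogonal_cell_round_trip(self):
        cell = gemmi.UnitCell(10, 10, 15, 90, 90, 120)
        p = gemmi.Position(2.0, 3.0, 4.0)
        back = cell.orthogonalize(cell.fractionalize(p))
        assert np.allclose([back.x, back.y, back.z], [2, 3, 4], atol=1e-9)


class TestSigmaScale:
    def test_mean_zero_sd_one(self, random_map):
        s = sigma_scale(random_map)
        assert abs(s.grid.mean()) < 1e-12
        assert s.grid.std() == pytest.approx(1.0, rel=1e-12)
        assert s.sigma_scaled

    def test_agrees_with_naive_two_pass(self, random_map):
        s = sigma_scale(random_map)
        flat = random_map.grid.ravel()
        mean = sum(flat) / flat.size
        sd = (sum((x - mean) ** 2 for x in flat) / flat.size) ** 0.5
        expected = (random_map.grid - mean) / sd
        assert np.allclose(s.grid, expected, atol=1e-12)

    def test_double_scaling_rejected(self, random_map):
        s = sigma_scale(random_map)
        with pytest.raises(ParameterError):
            sigma_scale(s)

    def test_flat_map_rejected(self):
        m = DensityMap(np.ones((5, 5, 5)), gemmi.UnitCell(10, 10, 10, 90, 90, 90))
        with pytest.raises(FlatMapError, match="flat"):
            sigma_scale(m)


class TestInterpolation:
    def test_exact_at_grid_nodes(self, random_map):
        s = sigma_scale(random_map)
        p = _orth(s.cell, (3 / 10, 5 / 12, 7 / 14))
        assert s.interpolate(p) == pytest.approx(s.grid[3, 5, 7], abs=1e-12)

    def test_edge_midpoint_is_mean_of_flanking_nodes(self, random_map):
        s = sigma_scale(random_map)
        p = _orth(s.cell, (3.5 / 10, 5 / 12, 7 / 14))
        expected = 0.5 * (s.grid[3, 5, 7] + s.grid[4, 5, 7])
        assert s.interpolate(p) == pytest.approx(expected, abs=1e-12)

    def test_periodic_wrapping(self, random_map):
        s = sigma_scale(random_map)
        p = np.array([1.234, 2.345, 3.456])
        shift = _orth(s.cell, (2, -1, 3))
        assert s.interpolate(p + shift) == pytest.approx(s.interpolate(p),
                                                         abs=1e-9)

    def test_non_finite_position_rejected(self, random_map):
        with pytest.raises(ParameterError):
            sigma_scale(random_map).interpolate([np.nan, 0, 0])


def _centered(coords, offset=(10.0, 10.0, 10.0)):
    shift = np.asarray(offset) - coords["CA"]
    return {k: v + shift for k, v in coords.items()}


def _noise_free_map(conformers_with_occ, spec=None):
    spec = spec or SyntheticSpec()
    atoms = [(element_of(n), p, occ, spec.b_factor)
             for coords, occ in conformers_with_occ
             for n, p in coords.items()]
    return sigma_scale(render_map(atoms, spec))


class TestRingerTrace:
    def test_serine_trace_peaks_at_true_chi(self):
        coords = _centered(build_conformer("SER", [60.0]))
        dmap = _noise_free_map([(coords, 1.0)])
        defn = chi_definitions("SER")[0]
        tr = ringer_trace(dmap, coords, ("A", 1, " ", "SER"), defn, step=10.0)
        assert abs(tr.argmax_angle() - 60.0) <= 5.0
        assert np.all(np.isfinite(tr.values))
        assert tr.angles[0] == 0.0 and len(tr.angles) == 36

    def test_methionine_chi3_split_gives_two_maxima(self):
        a = _centered(build_conformer("MET", [-67, 180, 75]))
        b = _centered(build_conformer("MET", [-67, 180, -75]))
        dmap = _noise_free_map([(a, 0.6), (b, 0.4)])
        defn = chi_definitions("MET")[2]
        tr = ringer_trace(dmap, a, ("A", 1, " ", "MET"), defn, step=10.0)
        v = tr.values
        maxima = [i for i in range(len(v))
                  if v[i] > v[i - 1] and v[i] > v[(i + 1) % len(v)]
                  and v[i] > 1.0]
        assert len(maxima) == 2

    def test_probe_rotation_preserves_bond_geometry(self):
        from flexbuild.density import probe_positions
        coords = build_conformer("MET", [-67, 180, 75])
        defn = chi_definitions("MET")[2]
        b, c = coords["CG"], coords["SD"]
        d0 = coords["CE"]
        angles = np.arange(0.0, 360.0, 10.0)
        pos = probe_positions(coords, defn, angles)
        bond0 = np.linalg.norm(d0 - c)
        ax = (c - b) / np.linalg.norm(c - b)

        def bond_angle(d):
            v1 = b - c
            v2 = d - c
            cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            return np.degrees(np.arccos(np.clip(cosv, -1, 1)))

        ang0 = bond_angle(d0)
        for p in pos:
            assert np.linalg.norm(p - c) == pytest.approx(bond0, abs=1e-9)
            assert bond_angle(p) == pytest.approx(ang0, abs=1e-6)

    def test_sampled_grid_is_absolute(self):
        # the same dihedral grid is sampled regardless of the starting chi
        ser60 = _centered(build_conformer("SER", [60.0]))
        ser170 = {k: v.copy() for k, v in ser60.items()}
        from flexbuild.geometry import set_dihedral
        defn = chi_definitions("SER")[0]
        set_dihedral(ser170, defn.atom_quadruple, defn.rotating_set, 170.0)
        dmap = _noise_free_map([(ser60, 1.0)])
        t1 = ringer_trace(dmap, ser60, ("A", 1, " ", "SER"), defn)
        t2 = ringer_trace(dmap, ser170, ("A", 1, " ", "SER"), defn)
        assert np.allclose(t1.values, t2.values, atol=1e-9)

    def test_translation_by_whole_cells_is_invariant(self):
        coords = _centered(build_conformer("SER", [60.0]))
        dmap = _noise_free_map([(coords, 1.0)])
        defn = chi_definitions("SER")[0]
        t1 = ringer_trace(dmap, coords, ("A", 1, " ", "SER"), defn)
        moved = {k: v + np.array([20.0, -40.0, 20.0]) for k, v in coords.items()}
        t2 = ringer_trace(dmap, moved, ("A", 1, " ", "SER"), defn)
        assert np.allclose(t1.values, t2.values, atol=1e-9)

    def test_bad_step_rejected(self):
        coords = _centered(build_conformer("SER", [60.0]))
        dmap = _noise_free_map([(coords, 1.0)])
        defn = chi_definitions("SER")[0]
        with pytest.raises(ParameterError):
            ringer_trace(dmap, coords, ("A", 1, " ", "SER"), defn, step=7.0)

    def test_missing_probe_atom_reported(self):
        coords = _centered(build_conformer("SER", [60.0]))
        dmap = _noise_free_map([(coords, 1.0)])
        defn = chi_definitions("SER")[0]
        incomplete = {k: v for k, v in coords.items() if k != "OG"}
        with pytest.raises(IncompleteSideChainError):
            ringer_trace(dmap, incomplete, ("A", 1, " ", "SER"), defn)

    def test_unscaled_map_rejected(self):
        coords = _centered(build_conformer("SER", [60.0]))
        raw = render_map([(element_of(n), p, 1.0, 15.0)
                          for n, p in coords.items()], SyntheticSpec())
        with pytest.raises(ParameterError):
            ringer_trace(raw, coords, ("A", 1, " ", "SER"),
                         chi_definitions("SER")[0])
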