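"""Conformer building, occupancies, pruning, B_norm, RSCC, model I/O."""

import numpy as np
import pytest

from flexbuild.assembly import CandidateRotamer
from flexbuild.building import (BLANK_ALTLOC, MultiConformerModel,
                                assign_occupancies, atom_positions, b_norm,
                                build_conformers, clash_report,
                                prune_low_occupancy, rscc, write_model)
from flexbuild.density import sigma_scale
from flexbuild.errors import BuildError, ParameterError
from flexbuild.rotamers import chi_definitions, measure_chi
from flexbuild.synthetic import (FIXTURE_RECIPES, SyntheticSpec, make_fixture,
                                 render_map)

RID_MET = ("A", 1, " ")


def _candidate(library, rtype, name, rid, support=2.0, area=0.5):
    entry = library.entry(rtype, name)
    return CandidateRotamer(rid, rtype, entry.modal_chi_angles,
                            support=support, seed_relative_area=area,
                            matched_entry=entry, max_deviation=0.0)


@pytest.fixture
def met_model(met_fixture):
    return MultiConformerModel.from_file(met_fixture.model_path)


class TestBuildConformers:
    def test_two_rotamer_methionine_gets_altlocs_a_b(self, met_model, library):
        rid = ("A", 1, " ", "MET")
        model = met_model.copy()
        res = model.find_residue(rid)
        before = {(a.name): (a.pos.x, a.pos.y, a.pos.z) for a in res}
        build_conformers(model, rid,
                         [_candidate(library, "MET", "mtm", rid)])
        res = model.find_residue(rid)
        assert model.altlocs(res) == ["A", "B"]
        # conformer A is the untouched input conformation
        for a in res:
            if a.altloc == "A":
                assert (a.pos.x, a.pos.y, a.pos.z) == before[a.name]
        # conformer B sits at the library's modal chi angles
        coords_b = model.conformer_coords(res, "B")
        chi3 = measure_chi(coords_b, chi_definitions("MET")[2])
        assert chi3 == pytest.approx(-75.0, abs=1e-4)

    def test_all_built_chis_reproduce_modal_angles(self, met_model, library):
        rid = ("A", 1, " ", "MET")
        model = met_model.copy()
        build_conformers(model, rid, [
            _candidate(library, "MET", "mtm", rid),
            _candidate(library, "MET", "ttt", rid),
        ])
        res = model.find_residue(rid)
        for altloc, name in (("B", "mtm"), ("C", "ttt")):
            entry = library.entry("MET", name)
            coords = model.conformer_coords(res, altloc)
            for d, target in zip(chi_definitions("MET"),
                                 entry.modal_chi_angles):
                got = measure_chi(coords, d)
                assert abs((got - target + 180) % 360 - 180) < 1e-4

    def test_calpha_mode_keeps_backbone_shared(self, met_model, library):
        rid = ("A", 1, " ", "MET")
        model = met_model.copy()
        build_conformers(model, rid,
                         [_candidate(library, "MET", "mtm", rid)],
                         mode="calpha")
        res = model.find_residue(rid)
        backbone = [a for a in res if a.name in ("N", "CA", "C", "O")]
        assert all(a.altloc == BLANK_ALTLOC for a in backbone)
        assert len(backbone) == 4  # not duplicated

    def test_full_mode_duplicates_backbone_identically(self, met_model, library):
        rid = ("A", 1, " ", "MET")
        model = met_model.copy()
        build_conformers(model, rid,
                         [_candidate(library, "MET", "mtm", rid)],
                         mode="full-residue")
        res = model.find_residue(rid)
        pos = {}
        for a in res:
            pos.setdefault(a.name, {})[a.altloc] = (a.pos.x, a.pos.y, a.pos.z)
        for name in ("N", "CA", "C", "O"):
            assert pos[name]["A"] == pos[name]["B"]

    def test_empty_rotamer_list_is_noop(self, met_model):
        rid = ("A", 1, " ", "MET")
        model = met_model.copy()
        build_conformers(model, rid, [])
        res = model.find_residue(rid)
        assert model.altlocs(res) == []

    def test_wrong_residue_type_rejected(self, met_model, library):
        rid = ("A", 1, " ", "MET")
        with pytest.raises(BuildError):
            build_conformers(met_model.copy(), rid,
                             [_candidate(library, "SER", "p", rid)])

    def test_altloc_alphabet_exhaustion(self, met_model, library):
        rid = ("A", 1, " ", "MET")
        rots = [_candidate(library, "MET", e.rotamer_name, rid)
                for e in library.entries("MET")] * 2  # 26 > 25 limit
        with pytest.raises(BuildError, match="altloc"):
            build_conformers(met_model.copy(), rid, rots)


class TestOccupancies:
    def _built(self, met_model, library, n=1):
        rid = ("A", 1, " ", "MET")
        model = met_model.copy()
        names = ["mtm", "ttt", "mmm"][:n]
        build_conformers(model, rid,
                         [_candidate(library, "MET", nm, rid) for nm in names])
        return model, rid

    def test_uniform_two_conformers(self, met_model, library):
        model, rid = self._built(met_model, library)
        occs = assign_occupancies(model, rid, scheme="uniform")
        assert occs == {"A": 0.5, "B": 0.5}

    def test_area_weighted_74_26(self, met_model, library):
        model, rid = self._built(met_model, library)
        occs = assign_occupancies(model, rid,
                                  seed_areas={"A": 0.74, "B": 0.26})
        assert occs == {"A": 0.74, "B": 0.26}

    def test_rounding_remainder_goes_to_a(self, met_model, library):
        model, rid = self._built(met_model, library, n=2)
        occs = assign_occupancies(model, rid,
                                  seed_areas={"A": 1 / 3, "B": 1 / 3,
                                              "C": 1 / 3})
        # oracle: 2-decimal allocation with remainder on A
        assert occs == {"A": 0.34, "B": 0.33, "C": 0.33}
        assert round(sum(occs.values()), 10) == 1.0

    def test_three_conformer_sum_exact(self, met_model, library):
        model, rid = self._built(met_model, library, n=2)
        occs = assign_occupancies(model, rid,
                                  seed_areas={"A": 0.5, "B": 0.3, "C": 0.2})
        assert occs == {"A": 0.5, "B": 0.3, "C": 0.2}
        assert sum(int(round(100 * v)) for v in occs.values()) == 100

    def test_missing_areas_fall_back_to_uniform(self, met_model, library,
                                                caplog):
        model, rid = self._built(met_model, library)
        occs = assign_occupancies(model, rid, seed_areas=None)
        assert occs == {"A": 0.5, "B": 0.5}


class TestPrune:
    def _model_with_occs(self, met_model, library, occs):
        rid = ("A", 1, " ", "MET")
        model = met_model.copy()
        names = ["mtm", "ttt", "mmm"][:len(occs) - 1]
        build_conformers(model, rid,
                         [_candidate(library, "MET", nm, rid) for nm in names])
        res = model.find_residue(rid)
        table = dict(zip("ABC", occs))
        for a in res:
            a.occ = table[a.altloc]
        return model, rid

    def test_zero_occupancy_conformer_removed(self, met_model, library):
        model, rid = self._model_with_occs(met_model, library, [1.0, 0.0])
        changed = prune_low_occupancy(model, min_occupancy=0.01)
        assert rid[:3] in [c[:3] for c in changed]
        res = model.find_residue(rid)
        assert model.altlocs(res) == []  # single survivor loses altloc
        assert all(a.occ == 1.0 for a in res)

    def test_no_op_when_all_above_threshold(self, met_model, library):
        model, rid = self._model_with_occs(met_model, library, [0.6, 0.4])
        assert prune_low_occupancy(model, 0.01) == []

    def test_survivors_renormalized(self, met_model, library):
        model, rid = self._model_with_occs(met_model, library,
                                           [0.6, 0.3, 0.0])
        prune_low_occupancy(model, 0.01)
        res = model.find_residue(rid)
        occ = {al: max(a.occ for a in res if a.altloc == al)
               for al in model.altlocs(res)}
        assert occ["A"] == pytest.approx(0.67)
        assert occ["B"] == pytest.approx(0.33)

    def test_surviving_count_monotone_in_threshold(self, met_model, library):
        counts = []
        for thr in (0.0, 0.05, 0.15, 0.25, 0.45, 0.75):
            model, rid = self._model_with_occs(met_model, library,
                                               [0.5, 0.3, 0.2])
            prune_low_occupancy(model, thr)
            res = model.find_residue(rid)
            counts.append(max(1, len(model.altlocs(res))))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_never_deletes_every_conformer(self, met_model, library):
        model, rid = self._model_with_occs(met_model, library, [0.6, 0.4])
        prune_low_occupancy(model, min_occupancy=0.99)
        res = model.find_residue(rid)
        assert sum(1 for a in res if a.name == "CA") == 1


class TestBNorm:
    def _two_atom_model(self, met_model, bs):
        model = met_model.copy()
        res = model.find_residue(("A", 1, " "))
        for a, b in zip(res, bs):
            a.b_iso = b
        return model

    def test_two_value_hand_computation(self, met_model):
        # eight atoms: four at B=10, four at B=20 -> z = -1 / +1 (population)
        model = met_model.copy()
        res = model.find_residue(("A", 1, " "))
        for i, a in enumerate(res):
            a.b_iso = 10.0 if i % 2 == 0 else 20.0
        df = b_norm(model)
        assert set(np.round(df["b_norm"], 6)) == {-1.0, 1.0}

    def test_location_invariance(self, met_model):
        base = met_model.copy()
        for i, (rid, a) in enumerate(base.protein_atoms()):
            a.b_iso = 10.0 + 2.0 * i
        df1 = b_norm(base)
        shifted = base.copy()
        for rid, a in shifted.protein_atoms():
            a.b_iso += 7.5
        df2 = b_norm(shifted)
        assert np.allclose(df1["b_norm"], df2["b_norm"], atol=1e-6)

    def test_identical_bs_rejected(self, met_model):
        with pytest.raises(ParameterError):
            b_norm(met_model.copy())  # fixture atoms share one B value


class TestRscc:
    def _map_and_model(self, met_fixture, noise_free=True):
        from flexbuild.density import DensityMap, read_map
        from flexbuild.forward import gaussian_density
        model = MultiConformerModel.from_file(met_fixture.truth_model_path)
        if noise_free:
            grid = gaussian_density(model.atom_specs(),
                                    met_fixture.spec.cell,
                                    met_fixture.spec.shape)
            dmap = sigma_scale(DensityMap(grid, met_fixture.spec.cell))
        else:
            dmap = sigma_scale(read_map(met_fixture.map_path))
        return dmap, model

    def test_self_consistency(self, met_fixture):
        dmap, model = self._map_and_model(met_fixture)
        sel = atom_positions(model, ("A", 1, " "))
        assert rscc(dmap, model, sel) > 0.999

    def test_sign_flip_anticorrelates(self, met_fixture):
        from flexbuild.density import DensityMap
        dmap, model = self._map_and_model(met_fixture)
        flipped = DensityMap(-dmap.grid, dmap.cell, sigma_scaled=True)
        sel = atom_positions(model, ("A", 1, " "))
        assert rscc(flipped, model, sel) < -0.999

    def test_noisy_map_still_confidently_correlated(self, met_fixture):
        dmap, model = self._map_and_model(met_fixture, noise_free=False)
        sel = atom_positions(model, ("A", 1, " "))
        assert rscc(dmap, model, sel) > 0.8

    def test_omitting_minor_conformer_lowers_local_rscc(self, met_fixture):
        dmap, truth = self._map_and_model(met_fixture, noise_free=False)
        single = MultiConformerModel.from_file(met_fixture.model_path)
        sel = atom_positions(truth, ("A", 1, " "), altloc="B",
                             atom_names=["CE"])
        full = rscc(dmap, truth, sel, radius=1.5)
        partial = rscc(dmap, single, sel, radius=1.5)
        assert full > 0.8
        assert partial < full

    def test_tiny_selection_rejected(self, met_fixture):
        dmap, model = self._map_and_model(met_fixture)
        with pytest.raises(ParameterError, match="selection too small"):
            rscc(dmap, model, [np.array([1.0, 1.0, 1.0])], radius=0.05)


class TestModelIO:
    def test_pdb_round_trip_preserves_hierarchy(self, met_model, library,
                                                tmp_path):
        rid = ("A", 1, " ", "MET")
        model = met_model.copy()
        build_conformers(model, rid, [_candidate(library, "MET", "mtm", rid)])
        assign_occupancies(model, rid, seed_areas={"A": 0.6, "B": 0.4})
        path = tmp_path / "out.pdb"
        write_model(model, path)
        back = MultiConformerModel.from_file(path)
        res = back.find_residue(rid)
        assert back.altlocs(res) == ["A", "B"]
        occ = {al: max(a.occ for a in res if a.altloc == al)
               for al in ("A", "B")}
        assert occ["A"] == pytest.approx(0.60)
        assert occ["B"] == pytest.approx(0.40)
        orig = model.conformer_coords(model.find_residue(rid), "B")
        readback = back.conformer_coords(res, "B")
        for name, p in orig.items():
            assert np.allclose(readback[name], p, atol=1.5e-3)  # PDB precision

    def test_mmcif_write_and_read(self, met_model, library, tmp_path):
        rid = ("A", 1, " ", "MET")
        model = met_model.copy()
        build_conformers(model, rid, [_candidate(library, "MET", "mtm", rid)])
        path = tmp_path / "out.cif"
        write_model(model, path)
        back = MultiConformerModel.from_file(path)
        assert back.altlocs(back.find_residue(rid)) == ["A", "B"]

    def test_file_parses_in_independent_reader(self, met_model, library,
                                               tmp_path):
        Bio = pytest.importorskip("Bio.PDB")
        rid = ("A", 1, " ", "MET")
        model = met_model.copy()
        build_conformers(model, rid, [_candidate(library, "MET", "mtm", rid)])
        assign_occupancies(model, rid, seed_areas={"A": 0.7, "B": 0.3})
        path = tmp_path / "out.pdb"
        write_model(model, path)
        parser = Bio.PDBParser(QUIET=True)
        st = parser.get_structure("x", str(path))
        res = list(st.get_residues())[0]
        ce = res["CE"]
        assert ce.is_disordered()
        assert sorted(ce.disordered_get_id_list()) == ["A", "B"]

    def test_oversized_residue_numbers_need_mmcif(self, met_model):
        model = met_model.copy()
        import gemmi
        res = model.find_residue(("A", 1, " "))
        res.seqid = gemmi.SeqId(10000, " ")
        with pytest.raises(BuildError, match="mmCIF"):
            write_model(model, "/tmp/never_written.pdb")


def test_clash_report_flags_overlapping_residues(single_fixture, library):
    model = MultiConformerModel.from_file(single_fixture.model_path)
    # clone the residue on top of itself in a second chain
    import gemmi
    st = model.structure
    chain = gemmi.Chain("B")
    src = st[0]["A"][0]
    dup = gemmi.Residue()
    dup.name = src.name
    dup.seqid = gemmi.SeqId(99, " ")
    dup.het_flag = "A"
    for a in src:
        dup.add_atom(a)
    chain.add_residue(dup)
    st[0].add_chain(chain)
    report = clash_report(MultiConformerModel(st))
    assert len(report) > 0
    assert (report["overlap"] > 0).all()
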