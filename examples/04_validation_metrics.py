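"""Validate built conformers with RSCC and normalized B factors.

Real-space correlation (RSCC >= 0.8: confident modeling; >= 0.7: minimal
cutoff) measures local map-model agreement; B_norm is the z-score of an
atom's B factor over all protein atoms.  Here the truth model correlates
almost perfectly with its own map, while the single-conformer model loses
correlation around the missing minor conformer.
"""

import tempfile

from flexbuild import make_fixture, read_map, rscc, sigma_scale
from flexbuild.building import MultiConformerModel, atom_positions, b_norm

with tempfile.TemporaryDirectory() as tmp:
    fx = make_fixture("methionine_chi3_split", tmp, seed=1)
    dmap = sigma_scale(read_map(fx.map_path))
    truth = MultiConformerModel.from_file(fx.truth_model_path)
    single = MultiConformerModel.from_file(fx.model_path)

    whole = atom_positions(truth, ("A", 1, " "))
    minor_ce = atom_positions(truth, ("A", 1, " "), altloc="B",
                              atom_names=["CE"])

    print(f"RSCC, whole residue, truth model:  "
          f"{rscc(dmap, truth, whole):.3f}")
    print(f"RSCC at minor-conformer CE, truth model:   "
          f"{rscc(dmap, truth, minor_ce, radius=1.5):.3f}")
    print(f"RSCC at minor-conformer CE, single-conformer model: "
          f"{rscc(dmap, single, minor_ce, radius=1.5):.3f}")

    for i, (rid, a) in enumerate(truth.protein_atoms()):
        a.b_iso = 12.0 + 1.5 * i  # synthetic spread for the demo
    df = b_norm(truth)
    print("\nB_norm extremes (z-score of B over all protein atoms):")
    print(df.nlargest(2, "b_norm")[["atom", "altloc", "b", "b_norm"]]
          .to_string(index=False))
    print("\nDropping the minor conformer lowers the local RSCC, which is "
          "how map-model validation flags unmodeled flexibility.")
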