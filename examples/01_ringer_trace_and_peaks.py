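"""Sample density around a serine chi1 and detect conformation peaks.

Builds a synthetic 0.7/0.3 two-conformer serine, renders its density map,
rotates the OG probe atom through 360 degrees and finds the peaks in the
resulting circular trace.  Each peak marks a candidate chi1 conformation;
its relative integrated area is the seed for the conformer's occupancy.
"""

import tempfile

from flexbuild import make_fixture, read_map, ringer_trace, sigma_scale
from flexbuild.building import MultiConformerModel
from flexbuild.peaks import find_peaks, normalize_peak_areas
from flexbuild.rotamers import chi_definitions

with tempfile.TemporaryDirectory() as tmp:
    fx = make_fixture("serine_70_30", tmp, seed=1)
    dmap = sigma_scale(read_map(fx.map_path))
    model = MultiConformerModel.from_file(fx.model_path)

    rid, res = next(model.residues())
    coords = model.conformer_coords(res)
    chi1 = chi_definitions("SER")[0]
    trace = ringer_trace(dmap, coords, rid, chi1, step=10.0)

    print(f"residue {rid[3]} {rid[0]}{rid[1]}, probe atom {trace.probe_atom}")
    print(f"trace: {len(trace.angles)} samples, max {trace.values.max():.1f} "
          f"sigma at {trace.argmax_angle():.0f} deg")

    peaks = normalize_peak_areas(find_peaks(trace,
                                            threshold=fx.sigma_threshold))
    print(f"\npeaks above {fx.sigma_threshold:.2f} sigma:")
    for p in peaks:
        print(f"  chi1 = {p.angle:5.1f} deg   height {p.height:5.2f} sigma  "
              f"relative area {p.relative_area:.2f}")
    print("\nThe two peaks sit near the ideal 'p' (62) and 'm' (295) serine "
          "rotamers; their relative areas track the true 0.70/0.30 "
          "occupancy split.")
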