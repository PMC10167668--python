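"""Grid-search the detection threshold and matching tolerance.

The two key parameters -- the sigma threshold for peak detection and the
angular tolerance for matching ideal rotamers -- trade sensitivity against
false positives.  This sweeps both on the serine fixture and tabulates how
many alternates get built: raising the threshold can only reduce them.
"""

import tempfile

from flexbuild import RunConfig, grid_search, make_fixture

with tempfile.TemporaryDirectory() as tmp:
    fx = make_fixture("serine_70_30", tmp, seed=1)
    config = RunConfig(map_path=str(fx.map_path),
                       model_path=str(fx.model_path))
    base = fx.sigma_threshold
    table = grid_search(config,
                        sigma_thresholds=[0.5 * base, base, 4 * base,
                                          40 * base],
                        tolerances=[15.0, 30.0, 45.0])
    print(table.to_string(index=False))
    print("\nAlternates built are non-increasing in the sigma threshold; "
          "at thresholds far above the minor peak the pipeline stops "
          "detecting the second conformation altogether.")
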