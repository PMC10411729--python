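"""Detect and verify focal sources, and test their spatial randomness.

Focal beats appear as only-outgoing graph nodes; verification demands a
QS electrogram (no upstroke before the intrinsic deflection).  Verified
sources are binned per electrode and compared against the binomial
occupancy null of uniform placement.
"""

import numpy as np

import dgmap as dg
from dgmap.focal import binomial_null, heatmap, randomness_table

grid = dg.build_grid(1)
origin = grid.position(5)
events, truth = dg.gen_focal(grid, origin, cv=0.8,
                             beat_times=[100.0 + 400.0 * k for k in range(5)])
egm = dg.gen_electrograms(events, grid, truth)
res = dg.run_episode(events, grid, electrograms=egm)

confirmed = res.confirmed_sources
print(f"candidates: {len(res.focal_sources)}, confirmed: {len(confirmed)}")
for s in confirmed:
    d = np.linalg.norm(grid.position(s.electrode) - origin)
    print(f"  electrode {s.electrode} at {s.time:.0f} ms "
          f"({d:.1f} mm from the true origin)")

heat = heatmap(confirmed, grid)
null = binomial_null(len(confirmed), grid.n_usable)
table = randomness_table(heat, null)
print("\nobserved vs expected electrodes per source count:")
print(table.to_string(index=False,
                      formatters={"expected_electrodes": "{:.2f}".format,
                                  "observed_pct": "{:.2f}".format,
                                  "expected_pct": "{:.2f}".format}))
print("\nflag=True marks counts essentially impossible under uniform "
      "placement: all beats here share one electrode, a maximal hotspot.")
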