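"""Detect, classify and track macro-reentry around the LV cavity.

A rotating wave is generated along the wall electrodes encircling the
left-ventricular cavity; the pipeline must find directed cycles in the
merged activation graphs, condense them into distinct reentries and
classify the loop as holo-ventricular by its winding number.
"""

import numpy as np

import dgmap as dg

grid = dg.build_grid(1)
events, truth = dg.gen_macro_reentry(grid, cavity="LV",
                                     cycle_length=200.0, n_rotations=4)
egm = dg.gen_electrograms(events, grid, truth)
res = dg.run_episode(events, grid, electrograms=egm)

print(f"macro-reentry (cycle length {truth.cycle_length} ms) around LV")
print(f"distinct reentry tracks: {len(res.tracks)}")
for tr in res.tracks:
    print(f"  track {tr.track_id}: {tr.start:.0f}-{tr.end:.0f} ms, "
          f"class {tr.classification}, center {np.round(tr.mean_center, 1)}")
prof = res.summary.profile
print(f"mean simultaneous loops {prof.mean_loops:.2f}, max {prof.max_loops}")
print(f"holo/bi-ventricular time fraction: {prof.holo_fraction_pct:.1f}% "
      f"of reentry-present time")
print(f"confirmed focal sources: {len(res.confirmed_sources)} (reentry only)")
print("each recording layer hosts its own copy of the rotating loop; the "
      "12 mm layer spacing exceeds the 10 mm clustering radius, so the six "
      "copies stay distinct.")
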