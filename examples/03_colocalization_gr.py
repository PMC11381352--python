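"""Radial distribution function g(r) against replisome foci.

Computes g(r) for two scenarios in the same 200 synthetic cells: molecules
placed uniformly at random (no colocalization) and molecules seeded within
50 nm of a focus (strong colocalization).  g(r) is the experimental
distance histogram divided by that of matched uniform placements, which
removes the spurious short-distance enrichment that cell confinement alone
would produce.
"""

import numpy as np

from smtrack import colocalization as coloc
from smtrack import synthetic as syn

rng = np.random.default_rng(5)
cells = syn.make_cells(200, seed=5)
foci = {c.cell_id: syn.place_foci(c, seed=rng) for c in cells}
counts = {c.cell_id: 10 for c in cells}

uniform = coloc.random_distances(cells, foci, counts, seed=rng)
g_null = coloc.radial_distribution(uniform, cells, foci, counts,
                                   n_repeats=100, seed=6)
ok = g_null.valid
frac = np.mean(np.abs(g_null.g[ok] - 1) < 3 * g_null.repeat_sd[ok])
print(f"uniform molecules: g within 1 +/- 3 sigma in {frac:.0%} of "
      f"{ok.sum()} bins (max |g-1| = {np.nanmax(np.abs(g_null.g[ok]-1)):.2f})")

seeded = rng.uniform(0.0, 0.05, size=sum(counts.values()))
g_enr = coloc.radial_distribution(seeded, cells, foci, counts,
                                  n_repeats=100, seed=7)
first = int(np.flatnonzero(g_enr.n_defined >= 50)[0])
print(f"focus-seeded molecules: g({g_enr.r[first]*1e3:.0f} nm) = "
      f"{g_enr.g[first]:.1f}")
print("g = 1 everywhere for uniform placement (the confinement correction "
      "works); the seeded scenario shows the strong short-range enrichment "
      "a replisome-bound population produces.")
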