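"""Normalized cell coordinates and localization profiles.

Maps focus positions into the normalized (u, v) frame of each cell — u runs
pole-to-pole in 0..1, v across the width — and histograms the long-axis
positions, reproducing the characteristic quarter/three-quarter replisome
localization pattern.
"""

import numpy as np

from smtrack import cellcoords as cc
from smtrack import synthetic as syn

rng = np.random.default_rng(9)
cells = syn.make_cells(300, seed=9)
pts = []
for c in cells:
    foci = syn.place_foci(c, seed=rng)
    pts.extend(cc.normalize_coordinates(foci.centroids, c, source="focus"))

(uc, ud), (vc, vd) = cc.axis_histograms(pts, n_bins=20)
left = uc[uc < 0.5][np.argmax(ud[uc < 0.5])]
right = uc[uc >= 0.5][np.argmax(ud[uc >= 0.5])]
peaks = np.array([left, right])
print(f"{len(pts)} foci in {len(cells)} cells")
print(f"long-axis density peaks at u = {peaks[0]:.2f} and u = {peaks[1]:.2f} "
      "(expected: quarter and three-quarter positions)")
print(f"short-axis density peaks at v = {vc[np.argmax(vd)]:.2f} "
      "(expected: midline 0.5)")
print("Normalization makes cells of different sizes and orientations "
      "directly comparable, so population-level localization patterns "
      "emerge from single-cell scatter.")
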