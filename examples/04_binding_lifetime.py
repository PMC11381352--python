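"""Photobleaching-corrected binding lifetime.

Track durations in long-exposure imaging end either by dissociation or by
photobleaching; the rates add.  The apparent lifetime is fit from live-cell
durations, the bleaching lifetime from fixed cells (no dissociation), and
the true binding lifetime recovered as tau_app*tau_bleach/(tau_bleach-tau_app).
"""

import numpy as np

from smtrack import lifetimes as lt
from smtrack import synthetic as syn

FRAME = 0.25  # s
TAU_BOUND, TAU_BLEACH = 1.9, 1.10  # s, simulation ground truth

live = syn.simulate_binding_durations(2000, TAU_BOUND, TAU_BLEACH, FRAME,
                                      seed=1, min_frames=5)
fixed = syn.simulate_binding_durations(2000, np.inf, TAU_BLEACH, FRAME,
                                       seed=2, min_frames=5)

tau_app = lt.fit_exponential(live, FRAME, min_frames=5)
tau_bleach = lt.fit_exponential(fixed, FRAME, min_frames=5)
tau_bound = lt.bleach_correct(tau_app, tau_bleach)

print(f"apparent lifetime   tau_app    = {tau_app:.3f} s "
      f"(truth {lt.compose_rates(TAU_BOUND, TAU_BLEACH):.3f} s)")
print(f"bleaching lifetime  tau_bleach = {tau_bleach:.3f} s (truth {TAU_BLEACH} s)")
print(f"corrected lifetime  tau_bound  = {tau_bound:.2f} s (truth {TAU_BOUND} s)")
print("Without the correction the binding lifetime would be underestimated "
      "nearly two-fold, because most trajectories end by bleaching rather "
      "than by dissociation.")
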