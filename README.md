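# smtrack

Single-molecule tracking analysis for bacterial polymerase imaging:
simulation, detection, diffusion mixtures, colocalization, and binding
lifetimes.

## The problem

Translesion-synthesis (TLS) DNA polymerases in bacteria such as
*B. subtilis* are present in only a handful of labeled copies per cell.
Two-color single-molecule imaging — one sparse HaloTag-labeled polymerase
channel and one replisome-marker (clamp-loader fusion) channel — answers
four questions about such a protein:

1. **How does it move?**  Per-trajectory apparent diffusion coefficients
   `D* = MSD / (4 Δt)` are decomposed into a static, an intermediate and a
   fast species.  For trajectories truncated to exactly four steps, a
   single species with coefficient `D` gives a gamma density

   `f(x) = (4/D)^4 / 6 · x³ · e^(−4x/D)`,

   and the observed `D*` histogram is fit with a three-term mixture under
   `A₁ + A₂ + A₃ = 1`.  A complementary kinetic view fits jump-length CDFs
   at one to four frame lags with a two-state (bound/free) model whose
   per-state scale is `√(4(D·kΔt + σ_loc²))`, with an axial-retention
   factor for molecules diffusing out of the detection slab.
2. **Where is it?**  Positions are mapped to normalized cell coordinates
   (u along the pole-to-pole axis, v across the width, both 0..1) so
   localization patterns aggregate across cells.
3. **Is it at the replisome?**  The radial distribution function `g(r)`
   divides the molecule-to-focus distance histogram by that of uniformly
   placed points in the *same* cell outlines — removing the spurious
   colocalization that confinement in a 0.7 μm-wide rod produces.
   `g(r) ≈ 1` means chance proximity; `g(r) > 1` at short `r` means
   enrichment.
4. **How long does it stay bound?**  Long-exposure (250 ms) imaging blurs
   out mobile molecules; bound-molecule track durations mix dissociation
   with photobleaching (`1/τ_app = 1/τ_bound + 1/τ_bleach`), so the true
   binding lifetime is `τ_bound = τ_app·τ_bleach / (τ_bleach − τ_app)`
   with `τ_bleach` calibrated in fixed cells.

Every stage is verifiable: the `synthetic` module generates ground-truthed
cells, foci, trajectories and rendered EMCCD movies with the statistical
structure these analyses assume, so parameter recovery can be demonstrated
end to end without any raw microscopy data.

## Worked example

```python
import numpy as np
from smtrack import synthetic as syn, diffusion as diff

truth = ((0.28, 0.08), (0.25, 0.23), (0.47, 0.98))   # (fraction, D μm²/s)
tracks, _ = syn.simulate_mixture_tracks(5000, states=truth, n_steps=4,
                                        dt=0.0147, seed=11)
ests = diff.apparent_d_all(tracks, dt=0.0147)
fit = diff.fit_three_species([e.d_star for e in ests if e.n_steps == 4])
print(np.round(fit.a, 3), np.round(fit.d, 3))
```

prints

```
[0.282 0.258 0.459] [0.081 0.237 0.993]
```

— the fitted fractions (28.2%, 25.8%, 45.9%) and diffusion coefficients
(0.081, 0.237, 0.993 μm²/s) recover the simulated three-state mixture to
within a few percent on the fractions and ~10% on the coefficients.  The
`examples/` directory has one short script per capability (simulation,
mixture fit, g(r), lifetimes, detection/tracking, cell coordinates), each
printing the numbers it computes.  A thin CLI (`smtrack simulate|detect|
track|calibrate|diffusion|coords|nucleoid|gr|lifetime|run`) wraps the same
functions for shell pipelines.

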