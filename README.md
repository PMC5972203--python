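# chemotrack

High-speed single-molecule tracking analysis for fast-diffusing,
fluorescently labelled biomolecules — chemokine-scale proteins moving at
1–10 µm²/s through collagen matrices, tissue sections and viscous buffers,
imaged at sub-millisecond frame intervals.

At these speeds a molecule hops a few hundred nanometres between frames,
photobleaching limits tracks to a handful of localizations, and localization
error is comparable to the step size. `chemotrack` provides the full
analysis stack built for that regime, plus a ground-truth simulator to
validate every stage:

- **Simulation** of fluorescence image stacks: pixel-integrated Gaussian
  PSFs, Brownian motion, per-frame track truncation, intensity-dependent
  readout noise, bright static tissue structures — with complete
  ground-truth tracks.
- **Tracking**: matched-filter detection, sub-pixel Gaussian-masked
  centroiding with joint refitting of close spot groups,
  nearest-neighbour linking, localization-precision calibration from
  immobilized emitters.
- **Diffusion estimation**: per-track microscopic D from the MSD over the
  first four step intervals, MSD(kΔt) averaged over all overlapping
  windows; D is the through-origin weighted least-squares gradient
  (weights ∝ 1/lag²) divided by 4, with optional subtraction of the
  localization plateau 4σ².
- **Population decomposition**: the per-track D distribution is modelled as
  a mixture of gamma densities F(x; D, N) = (N/D)^N x^(N−1) e^(−Nx/D)/Γ(N),
  where D is the true coefficient and N the effective number of independent
  steps (≈2 for overlapping first-four-step windows). Constrained
  immobile+mobile fits, reduced-χ² model selection, simulation-in-the-loop
  constraint refinement, and subsampling-bootstrap errors.
- **Stoichiometry**: initial-intensity back-extrapolation, photobleaching
  step counting (Chung–Kennedy filter + change-point t tests), and a
  spatial-Poisson random-overlap null for apparent multimers.
- **Segmentation** of autofluorescent extracellular matrix (top-hat → Otsu →
  hole filling) and matrix/interstitial track classification.
- **Ensemble cross-checks**: FCS autocorrelation (triplet × translational
  diffusion) and FRAP single-exponential recovery fits with their D
  conversions, and hydrodynamic theory (Stokes–Einstein, globular radii,
  Faxén near-wall drag).

## Worked example

Simulate a sub-millisecond acquisition of emitters diffusing at
1.6 µm²/s, track it, and fit the diffusion-coefficient distribution:

```python
import numpy as np
from chemotrack import diffusion, gammafit, pipeline
from chemotrack.simulate import SimulationConfig, simulate_stack

config = SimulationConfig(
    frame_count=1200,
    components=[(1.6, 1.0)],   # one population, D = 1.6 µm²/s
    foci_per_frame=5,
    frame_interval_s=6.5e-4,
    seed=7,
)
stack, truth = simulate_stack(config)
tracks = pipeline.track_stack(stack)

ests = diffusion.estimate_tracks(tracks, config.frame_interval_s,
                                 config.pixel_size_nm)
vals = np.array([e.d_micro for e in ests])
hist = diffusion.build_histogram(vals, precision_nm=10.0,
                                 dt=config.frame_interval_s)
fit = gammafit.fit_single_gamma(hist, n_free=True, estimates=vals)
print(f"{vals.size} tracks: {fit.summary()}")
```

which prints

```
332 tracks: D = 1.63 µm²/s (N=2.08, w=1.00)
```

— the fitted mean sits just above the simulated 1.6 µm²/s (close encounters
between foci inflate a percent-level fraction of the estimates), and the
fitted shape N ≈ 2 reflects that only two of the four overlapping MSD steps
are independent. The same workflow from a shell:

```
chemotrack simulate --config sim.yaml --out run --seed 7
chemotrack track --in run.tif --pixel-size 120 --dt 0.00065 --out tracks.csv
chemotrack fitd --tracks tracks.csv --components 1 --precision-nm 30 --out fit.json
```

Other subcommands: `stoich` (stoichiometry + overlap null), `segment`
(matrix masks and track labels), `fcs`, `frap`, `theory`.

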