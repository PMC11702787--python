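# logprf

Log-warped bar stimuli and population receptive field (pRF) mapping.

## The problem

The pRF method models each fMRI voxel/vertex in visual cortex as an
isotropic 2-D Gaussian G(x, y; μx, μy, σ) over the visual field; its
predicted BOLD response to a binary stimulus aperture movie S(x, y, t) is

    R̂(t) = ⟨S(·,·,t), G⟩ ⊛ h(t),

the stimulus–pRF overlap convolved with a six-parameter double-gamma
hemodynamic response function h. Estimates maximize the Pearson
correlation between R̂ and the data; variance explained is its square.
With the traditional fixed-width drifting bar, cortical magnification
makes the bar sweep through tiny foveal pRFs far too quickly, so foveal
size estimates are inflated and unreliable. Warping each frame along the
eccentricity axis,

    r' = c·log(1 + k·r),   c = r_max / log(1 + k·r_max),   k = 5, r_max = 8°,

gives a *log-bar* stimulus — thin and slow near the fovea, wide and fast
peripherally — that approximates a constant-speed, constant-width wave on
cortex. This package generates both stimuli, implements the forward
model, a two-stage correlation-maximizing fitting procedure with
optional iterative HRF co-estimation, and a calibrated-noise simulation
framework that quantifies how much more accurately the log-bar stimulus
recovers pRF position and size, especially near the fovea.

It is aimed at visual-neuroscience researchers designing retinotopy
protocols or validating pRF analysis choices in simulation.

## Worked example

```python
import logprf
from logprf.simulate import RecoveryConfig, run_recovery_experiment

grid  = logprf.VisualFieldGrid(216)              # central 16° of visual field
warp  = logprf.WarpParams()                      # k = 5, r_max = 8°
fixed = logprf.generate_fixed_bar_movie(logprf.SweepSchedule(), grid, seed=1)
logm  = logprf.generate_log_bar_movie(fixed, warp)
fixed, logm = (logprf.preprocess_movie(m, 108, m.n_frames) for m in (fixed, logm))

cfg = RecoveryConfig(n_prfs=300, n_reps=1, sd=0.36, seed=7)
result = run_recovery_experiment(fixed, logm, config=cfg)
for stim in ("fixed", "log"):
    edge = result.overestimation_edge(stim, threshold=0.25)
    frac = result.retention_fraction(stim)
    print(f"{stim:>5}-bar: retention {100 * frac:.0f}%, "
          f"sigma overestimated (>25%) below {edge:.2f} deg eccentricity")
```

prints (this is `examples/04_recovery_experiment.py`, which also shows
the per-bin medians):

```
fixed-bar: retention 63%, sigma overestimated (>25%) below 1.08 deg eccentricity
  log-bar: retention 94%, sigma overestimated (>25%) below 0.00 deg eccentricity
```

i.e. under identical calibrated noise the fixed bar loses a third of the
units (mostly foveal) and inflates pRF size below ~1° eccentricity
(≈1.5° at full problem size), while the log bar keeps nearly all units
and tracks the true sizes across the whole eccentricity range. The
`examples/` directory holds one short script per capability: stimulus
generation and warping, forward prediction, fitting synthetic voxels,
the recovery experiment, and test–retest reliability (Spearman + circular
correlation + Fisher z).

A thin CLI wraps the same functions:

```bash
logprf make-stimulus --type log --pixels 540 --out log.nii.gz --seed 1
logprf fit --ts timeseries.tsv --movie log.nii.gz --out estimates.tsv
logprf demo --out demo_run --seed 0
```

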