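"""Predict the BOLD time course of a single pRF.

The forward model is the per-frame overlap of the binary aperture movie
with an isotropic Gaussian pRF, convolved with the double-gamma HRF and
resampled to the scanner TR grid (366 frames at 1 frame/s -> 305 volumes
at TR = 1.2 s).
"""

import numpy as np

import logprf

grid = logprf.VisualFieldGrid(108)
movie = logprf.generate_fixed_bar_movie(logprf.SweepSchedule(), grid, seed=1)
hrf = logprf.default_hrf()

prf = logprf.PRFParams(mu_x=2.0, mu_y=1.0, sigma=0.8)
ts = logprf.predict_timecourse(movie, prf, hrf, tr_s=1.2)
print(f"pRF at ({prf.mu_x}, {prf.mu_y}) deg, sigma {prf.sigma} deg")
print(f"  eccentricity {prf.eccentricity:.2f} deg, "
      f"polar angle {np.rad2deg(prf.polar_angle):.1f} deg")
print(f"  prediction: {ts.size} volumes, peak at volume {np.argmax(ts)} "
      f"(t = {1.2 * np.argmax(ts):.1f} s)")

# eight sweeps -> up to eight response events; count prominent peaks
above = ts > 0.5 * ts.max()
n_events = int(np.sum(np.diff(above.astype(int)) == 1))
print(f"  {n_events} response events above half maximum "
      f"(one per sweep crossing the pRF)")
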