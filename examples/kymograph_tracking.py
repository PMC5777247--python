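"""Round-trip a trajectory through a photon-limited kymograph.

Renders a diffusing particle as a kymograph (Gaussian spot + Poisson photon
noise), recovers per-frame positions by Gaussian fitting to the intensity
profiles, and compares with the known ground truth.
"""

import numpy as np

from tightrope import (TrajectorySimConfig, render_kymograph,
                       simulate_free_diffusion, track_kymograph)

config = TrajectorySimConfig(D_free=0.05, frame_interval_s=0.05, n_frames=400,
                             localization_sigma_um=0.0,
                             tightrope_length_um=4.0, start_position_um=2.0,
                             seed=3)
traj = simulate_free_diffusion(config)
kymo = render_kymograph(traj, psf_sigma_um=0.125, photons_per_frame=100,
                        background=2.0, pixel_size_um=0.05, seed=4)
tracked = track_kymograph(kymo)

ok = tracked.present
rmse_nm = 1000 * np.sqrt(np.mean(
    (tracked.positions_um[ok] - traj.true_positions_um[ok]) ** 2))
print(f"kymograph          : {kymo.n_pixels} px x {kymo.n_frames} frames")
print(f"frames localized   : {int(ok.sum())}/{tracked.n_frames}")
print(f"tracking RMSE      : {rmse_nm:.1f} nm")
print()
print("~100 detected photons/frame localize the emitter to ~16-20 nm, far")
print("below the ~300-nm optical resolution -- enough to resolve pausing at")
print("individual gap sites along the DNA.")
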