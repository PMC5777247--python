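"""Detect stable binding events amid diffusion with the sliding-window D_int.

Simulates a protein that alternates between a 1D-diffusing search mode and a
recognition mode stably bound at single-stranded gap sites, then scans the
trajectory with 40-frame (2-s) windows: windows whose interval diffusion
constant D_int falls below 1e-4 um^2/s are called static, and runs of static
windows become discrete binding events.
"""

import numpy as np

from tightrope import (TrajectorySimConfig, detect_static_events,
                       simulate_two_state, sliding_window_dint)

config = TrajectorySimConfig(
    D_free=0.1, frame_interval_s=0.05, n_frames=3000,
    localization_sigma_um=0.016, tightrope_length_um=10.0,
    pause_sites_um=(4.7, 5.3),    # gap sites 0.6 um apart
    k_pause_per_s=3.0, k_release_per_s=0.15, capture_radius_um=0.03,
    start_position_um=5.0, seed=8,
)
traj, states = simulate_two_state(config)
ws = sliding_window_dint(traj, window_frames=40, threshold=1e-4)
events = detect_static_events(ws, traj, min_run_windows=20)

print(f"true paused-frame fraction : {states.mean():.2f}")
print(f"static-window fraction     : {ws.fraction_static:.2f}")
print(f"detected binding events    : {len(events)}")
for ev in events:
    err_nm = 1000 * np.min(np.abs(ev.mean_position_um
                                  - np.array(config.pause_sites_um)))
    print(f"  {ev.start_s:7.1f}-{ev.end_s:6.1f} s at "
          f"{ev.mean_position_um:.3f} um  ({err_nm:.0f} nm from a true site)")
print()
print("Event positions land within a few tens of nm of the gap sites: the")
print("window detector converts pauses in the random walk into site calls.")
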