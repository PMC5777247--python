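# tightrope

Single-molecule analysis of DNA-binding proteins that search duplex DNA by
1D diffusion and stop at structural targets — single-stranded gaps, DNA
ends, flaps and forks.  The package covers the three measurement platforms
such studies combine, together with seeded generators that emulate each one,
so every estimator can be validated against known ground truth:

* **DNA tightropes** — trajectories of a quantum-dot-labeled protein moving
  along DNA stretched between beads: sub-pixel Gaussian localization in
  kymographs, time-averaged mean square displacement, diffusion-constant and
  anomalous-exponent fitting, and sliding-window detection of transient
  static binding.
* **AFM depositions** — position distributions of protein–DNA complexes on
  defined linear substrates: binding-specificity estimation from fractional
  occupancies, and protein copy-number estimation from AFM volumes.
* **Fluorescence anisotropy** — equilibrium titrations fitted with the law
  of mass action to extract dissociation constants and compare substrates.

## The statistics at the core

For a trajectory x_i sampled every Δt over N frames, the time-averaged MSD
at lag nΔt is

    MSD(nΔt) = 1/(N−n) · Σ_{i=1..N−n} (x_{i+n} − x_i)²

and diffusion is characterized by fitting

    MSD = 2 D t^α

(α = 1: unbiased random walk; α < 1: pausing / subdiffusion).  A molecule is
*mobile* when D > 5×10⁻⁴ µm² s⁻¹ and the fit's R² > 0.8.  Transient
recognition events are found with an interval diffusion constant D_int from
a sliding 40-frame (2 s) window; windows with D_int < 1×10⁻⁴ µm² s⁻¹ are
static, and runs of static windows become discrete binding events.

On a linear substrate with N binding sites (one per bp), specificity for a
marked site is estimated from the position histogram's occupancies as

    S = K_SP / K_NSP = N · A_SP / A_NSP + 1,

with the nonspecific baseline occupancy of the specific region subtracted by
default (see `docs/methods.md`).  AFM volumes V (nm³) convert to molecular
weight via the calibration V = 1.45·M_r − 21.59, giving copy numbers.
Anisotropy titrations follow

    P = (P_bound − P_free)·[protein] / (K_d + [protein]) + P_free.

## Worked example

`examples/` contains one short script per capability.  For instance,
detecting recognition events amid diffusion
(`python examples/gap_binding_two_state.py`):

```
true paused-frame fraction : 0.26
static-window fraction     : 0.21
detected binding events    : 5
      5.3-   9.5 s at 5.299 um  (1 nm from a true site)
      9.1-  16.5 s at 5.301 um  (1 nm from a true site)
     17.4-  35.1 s at 5.299 um  (1 nm from a true site)
     34.3-  42.1 s at 5.300 um  (0 nm from a true site)
     44.4-  48.5 s at 4.698 um  (2 nm from a true site)
```

A protein that alternates between a diffusive search mode (D = 0.1 µm² s⁻¹)
and stable binding at gap sites 0.6 µm apart spends 26% of frames bound;
the window detector calls 21% of windows static and places every recovered
event within a few nanometres of a true site — far below the optical
resolution, thanks to Gaussian-fit localization.

The same pattern runs from the shell:

```sh
tightrope simulate --config scenario.yaml --out traj.csv --seed 1
tightrope msd  --in traj.csv --out fits.csv
tightrope dint --in traj.csv --out windows.csv --window 40 --threshold 1e-4
tightrope pipeline --config pipeline.yaml --out results/
```

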