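"""Seeded forward models for every input the analysis pipeline consumes.

This module emulates the three experimental platforms the package analyzes:

* **DNA tightropes** -- a linear DNA molecule stretched between surface-anchored
  beads, along which a quantum-dot-labeled protein moves in one dimension.
  :func:`simulate_free_diffusion` produces unbiased 1D Brownian trajectories
  (reflecting bead anchors, Gaussian localization noise);
  :func:`simulate_two_state` adds reversible capture at defined pause sites,
  modelling a protein that alternates between a fast *search* mode on duplex
  DNA and a *recognition* mode stably bound at single-stranded gaps.
  :func:`render_kymograph` turns a trajectory into a photon-limited
  space x time image so that the localization code can be exercised against
  known ground truth.
* **AFM depositions** -- :func:`simulate_afm_positions` places protein-DNA
  complexes on a linear substrate with a tunable specificity ``S`` for marked
  sites (ends, gaps, flaps, forks), reporting positions folded to the nearest
  DNA end (0-50%) exactly as AFM position-distribution analyses do.
* **Anisotropy titrations** -- :func:`simulate_titration` draws polarization
  readings from the law-of-mass-action binding isotherm plus Gaussian noise.

Every generator is a pure function of its configuration, including the seed:
the same inputs always reproduce the same arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "SITE_KINDS",
    "SubstrateGeometry",
    "TrajectorySimConfig",
    "Trajectory",
    "Kymograph",
    "simulate_free_diffusion",
    "simulate_two_state",
    "render_kymograph",
    "simulate_afm_positions",
    "simulate_titration",
]

#: Recognized specific-site kinds on a linear substrate.
SITE_KINDS = frozenset(
    {"end", "gap", "nick", "flap", "fork", "replication_fork"}
)


@dataclass(frozen=True)
class SubstrateGeometry:
    """Geometry of a linear DNA substrate.

    Parameters
    ----------
    length_bp:
        Substrate length in base pairs. Must be positive.
    specific_sites:
        ``(kind, position_bp)`` pairs marking structure-specific binding
        sites; ``kind`` is one of :data:`SITE_KINDS` and ``position_bp`` lies
        in ``[0, length_bp]``.
    repeat_unit_bp:
        Length of the tandem-ligated repeat unit for concatemer tightropes
        (``None`` for a single fragment).
    rise_nm_per_bp:
        Helical rise, nm per base pair.  B-form DNA is 0.32-0.34 nm/bp.
    elongation_fraction:
        Fraction of the contour length at which tightropes are stretched
        between beads (flow-stretched tightropes sit near 0.9).
    """

    length_bp: int
    specific_sites: tuple = ()
    repeat_unit_bp: Optional[int] = None
    rise_nm_per_bp: float = 0.34
    elongation_fraction: float = 0.9

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be > 0, got {self.length_bp}")
        if not 0 < self.elongation_fraction <= 1:
            raise ValueError(
                f"elongation_fraction must be in (0, 1], got {self.elongation_fraction}"
            )
        if self.rise_nm_per_bp <= 0:
            raise ValueError(f"rise_nm_per_bp must be > 0, got {self.rise_nm_per_bp}")
        sites = tuple((str(k), int(p)) for k, p in self.specific_sites)
        for kind, pos in sites:
            if kind not in SITE_KINDS:
                raise ValueError(f"unknown site kind {kind!r}; expected one of {sorted(SITE_KINDS)}")
            if not 0 <= pos <= self.length_bp:
                raise ValueError(
                    f"site position {pos} bp outside [0, {self.length_bp}]"
                )
        object.__setattr__(self, "specific_sites", sites)

    @property
    def contour_length_nm(self) -> float:
        return self.length_bp * self.rise_nm_per_bp

    @property
    def tightrope_length_um(self) -> float:
        """Bead-to-bead extension in micrometres at the set elongation."""
        return self.contour_length_nm * self.elongation_fraction / 1000.0


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Configuration of a 1D tightrope trajectory simulation.

    Defaults are the study conditions this package targets: D ~ 0.1 um^2/s,
    20 frames per second (0.05 s per frame), 16 nm localization precision.

    Parameters
    ----------
    D_free:
        Free 1D diffusion constant, um^2 s^-1.
    frame_interval_s:
        Time between frames, s.
    n_frames:
        Number of recorded frames.
    localization_sigma_um:
        Standard deviation of the Gaussian localization error added to the
        reported (not the true) positions, um.
    tightrope_length_um:
        Bead-to-bead length of the tightrope; reflecting boundaries.
    pause_sites_um:
        Coordinates of specific sites at which the particle can be captured.
    k_pause_per_s:
        Capture rate while within ``capture_radius_um`` of a site, s^-1.
    k_release_per_s:
        Release rate from the captured (recognition) state, s^-1.
    capture_radius_um:
        Distance within which capture can fire.  A point site is never hit by
        a discrete-step walk, so capture needs a finite radius; the default
        20 nm is comparable to the localization precision.
    detach_rate_per_s:
        Optional per-second detachment rate from the tightrope; frames after
        detachment are marked absent.
    start_position_um:
        Initial position; drawn uniformly on the tightrope when ``None``.
    start_paused:
        Start in the captured state at the nearest pause site.
    seed:
        Seed for the single named random generator driving the run.
    """

    D_free: float = 0.1
    frame_interval_s: float = 0.05
    n_frames: int = 1200
    localization_sigma_um: float = 0.016
    tightrope_length_um: float = 5.0
    pause_sites_um: tuple = ()
    k_pause_per_s: float = 0.5
    k_release_per_s: float = 0.1
    capture_radius_um: float = 0.020
    detach_rate_per_s: float = 0.0
    start_position_um: Optional[float] = None
    start_paused: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "pause_sites_um", tuple(float(p) for p in self.pause_sites_um))
        if self.frame_interval_s <= 0:
            raise ValueError(f"frame_interval_s must be > 0, got {self.frame_interval_s}")
        if self.D_free < 0:
            raise ValueError(f"D_free must be >= 0, got {self.D_free}")
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.tightrope_length_um <= 0:
            raise ValueError(
                f"tightrope_length_um must be > 0, got {self.tightrope_length_um}"
            )
        for name in ("k_pause_per_s", "k_release_per_s", "detach_rate_per_s",
                     "localization_sigma_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for p in self.pause_sites_um:
            if not 0 <= p <= self.tightrope_length_um:
                raise ValueError(
                    f"pause site {p} um outside [0, {self.tightrope_length_um}]"
                )
        if self.k_pause_per_s > 0 and self.pause_sites_um and self.capture_radius_um <= 0:
            raise ValueError(
                f"capture_radius_um must be > 0 when k_pause_per_s > 0, "
                f"got {self.capture_radius_um}"
            )


@dataclass
class Trajectory:
    """Time-stamped 1D positions of a single particle on a tightrope."""

    particle_id: str
    times_s: np.ndarray
    positions_um: np.ndarray
    present: np.ndarray
    #: Noise-free positions, kept by the simulators for ground-truth tests.
    true_positions_um: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if not (len(self.times_s) == len(self.positions_um) == len(self.present)):
            raise ValueError("times_s, positions_um and present must have equal length")
        if len(self.times_s) > 1:
            dts = np.diff(self.times_s)
            if np.any(dts <= 0):
                raise ValueError("times_s must be strictly increasing")
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
                raise ValueError("times_s must be evenly spaced")
        if not np.all(np.isfinite(self.positions_um[self.present])):
            raise ValueError("positions must be finite where the particle is present")

    @property
    def n_frames(self) -> int:
        return len(self.times_s)

    @property
    def frame_interval_s(self) -> float:
        if len(self.times_s) < 2:
            raise ValueError("frame interval undefined for a single-frame trajectory")
        return float(self.times_s[1] - self.times_s[0])


@dataclass
class Kymograph:
    """Space x time intensity image of a particle on a tightrope."""

    intensity: np.ndarray  # (space_pixels, frames), counts >= 0
    pixel_size_um: float
    frame_interval_s: float
    psf_sigma_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D (space x time) array")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]


def _reflect(x: np.ndarray, length: float) -> np.ndarray:
    """Fold unconstrained coordinates into [0, length] by mirror reflection."""
    y = np.mod(x, 2.0 * length)
    return np.where(y > length, 2.0 * length - y, y)


def _finish_trajectory(config, true, rng, particle_id, extra_meta=None):
    n = config.n_frames
    present = np.ones(n, dtype=bool)
    if config.detach_rate_per_s > 0 and n > 1:
        # survival of each inter-frame interval; present from frame 0 onward
        p_stay = math.exp(-config.detach_rate_per_s * config.frame_interval_s)
        survived = rng.random(n - 1) < p_stay
        present[1:] = np.cumprod(survived).astype(bool)
    if config.localization_sigma_um > 0:
        noise = rng.normal(0.0, config.localization_sigma_um, size=n)
    else:
        noise = np.zeros(n)
    reported = np.clip(true + noise, 0.0, config.tightrope_length_um)
    reported = np.where(present, reported, np.nan)
    times = np.arange(n) * config.frame_interval_s
    meta = {
        "seed": config.seed,
        "D_free": config.D_free,
        "tightrope_length_um": config.tightrope_length_um,
        "localization_sigma_um": config.localization_sigma_um,
    }
    if extra_meta:
        meta.update(extra_meta)
    return Trajectory(
        particle_id=particle_id,
        times_s=times,
        positions_um=reported,
        present=present,
        true_positions_um=true,
        meta=meta,
    )


def simulate_free_diffusion(config: TrajectorySimConfig,
                            particle_id: str = "p0") -> Trajectory:
    """Simulate unbiased 1D diffusion on a tightrope.

    The true path is a Gaussian random walk with per-frame step variance
    ``2 * D_free * frame_interval_s``, reflected at the bead anchors
    ``[0, tightrope_length_um]``.  Reported positions add independent
    Gaussian localization noise and are clipped to the tightrope.

    Notes
    -----
    Reflection is applied to the cumulative path; for Brownian motion the
    reflection map applied to the free path is exact in law for the
    reflected process.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    L = config.tightrope_length_um
    if config.start_position_um is None:
        x0 = rng.uniform(0.0, L)
    else:
        x0 = float(config.start_position_um)
    step_sd = math.sqrt(2.0 * config.D_free * config.frame_interval_s)
    steps = rng.normal(0.0, step_sd, size=n - 1) if n > 1 and step_sd > 0 else np.zeros(max(n - 1, 0))
    raw = x0 + np.concatenate([[0.0], np.cumsum(steps)])
    true = _reflect(raw, L)
    return _finish_trajectory(config, true, rng, particle_id)


def simulate_two_state(config: TrajectorySimConfig,
                       particle_id: str = "p0"):
    """Simulate diffusion with reversible capture at pause sites.

    While diffusing, a particle that lands within ``capture_radius_um`` of a
    pause site is captured with per-frame probability
    ``1 - exp(-k_pause_per_s * dt)``; a captured particle sits exactly at the
    site coordinate and is released with per-frame probability
    ``1 - exp(-k_release_per_s * dt)``, resuming diffusion from the site on
    the next frame.

    Returns
    -------
    (trajectory, states)
        ``states`` is an int array per frame, 0 = diffusing (search mode),
        1 = captured (recognition mode), for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    L = config.tightrope_length_um
    dt = config.frame_interval_s
    sites = np.asarray(config.pause_sites_um, dtype=float)
    p_capture = 1.0 - math.exp(-config.k_pause_per_s * dt)
    p_release = 1.0 - math.exp(-config.k_release_per_s * dt)
    step_sd = math.sqrt(2.0 * config.D_free * dt)

    if config.start_position_um is None:
        pos = rng.uniform(0.0, L)
    else:
        pos = float(config.start_position_um)
    paused = bool(config.start_paused and sites.size)
    if paused:
        pos = float(sites[np.argmin(np.abs(sites - pos))])

    true = np.empty(n)
    states = np.empty(n, dtype=np.int8)
    true[0], states[0] = pos, int(paused)
    for i in range(1, n):
        if paused:
            if rng.random() < p_release:
                paused = False
        else:
            y = pos + rng.normal(0.0, step_sd) if step_sd > 0 else pos
            y = math.fmod(y, 2.0 * L)
            if y < 0:
                y += 2.0 * L
            pos = 2.0 * L - y if y > L else y
            if sites.size and p_capture > 0:
                j = int(np.argmin(np.abs(sites - pos)))
                if abs(sites[j] - pos) <= config.capture_radius_um and rng.random() < p_capture:
                    paused = True
                    pos = float(sites[j])
        true[i], states[i] = pos, int(paused)

    traj = _finish_trajectory(
        config, true, rng, particle_id,
        extra_meta={"pause_sites_um": list(sites),
                    "k_pause_per_s": config.k_pause_per_s,
                    "k_release_per_s": config.k_release_per_s},
    )
    return traj, states


def render_kymograph(traj: Trajectory,
                     psf_sigma_um: float = 0.125,
                     photons_per_frame: float = 300.0,
                     background: float = 2.0,
                     pixel_size_um: float = 0.05,
                     seed: int = 0,
                     n_pixels: Optional[int] = None) -> Kymograph:
    """Render a trajectory as a photon-limited kymograph.

    Each frame column is an integrated Gaussian spot (total intensity
    Poisson-distributed around ``photons_per_frame``) centered at the true
    position, over a uniform Poisson background of ``background`` counts per
    pixel.  Frames where the particle is absent contain background only.
    """
    if psf_sigma_um <= 0:
        raise ValueError(f"psf_sigma_um must be > 0, got {psf_sigma_um}")
    if photons_per_frame < 0 or background < 0:
        raise ValueError("photons_per_frame and background must be >= 0")
    x = traj.true_positions_um if traj.true_positions_um is not None else traj.positions_um
    x = np.asarray(x, dtype=float)
    length = float(traj.meta.get("tightrope_length_um", np.nanmax(x) if np.isfinite(x).any() else 0.0))
    if n_pixels is None:
        n_pixels = int(math.ceil(length / pixel_size_um)) + 1
    if n_pixels * pixel_size_um < length:
        raise ValueError(
            f"pixel grid ({n_pixels} px x {pixel_size_um} um) shorter than the "
            f"tightrope ({length} um)"
        )
    edges = np.arange(n_pixels + 1) * pixel_size_um
    # per-pixel integral of the PSF: Phi((hi-x)/s) - Phi((lo-x)/s)
    centered = np.where(traj.present & np.isfinite(x), x, np.nan)
    z = (edges[:, None] - centered[None, :]) / psf_sigma_um
    cdf = ndtr(np.nan_to_num(z, nan=-np.inf))
    frac = np.diff(cdf, axis=0)
    frac[:, ~(traj.present & np.isfinite(x))] = 0.0
    expected = photons_per_frame * frac + background
    rng = np.random.default_rng(seed)
    intensity = rng.poisson(expected).astype(np.float64)
    return Kymograph(
        intensity=intensity,
        pixel_size_um=pixel_size_um,
        frame_interval_s=traj.frame_interval_s if traj.n_frames > 1 else 0.05,
        psf_sigma_um=psf_sigma_um,
        meta={"seed": seed, "photons_per_frame": photons_per_frame,
              "background": background, "source_particle": traj.particle_id},
    )


def simulate_afm_positions(geometry: SubstrateGeometry,
                           S: float,
                           n_complexes: int,
                           seed: int = 0,
                           substrate_id: str = "substrate",
                           volume_median_nm3: float = 1000.0,
                           volume_sigma_log: float = 0.25,
                           height_mean_nm: float = 1.41,
                           height_sd_nm: float = 0.30) -> pd.DataFrame:
    """Deposit protein-DNA complexes on a linear substrate.

    One binding site per base pair.  Each site marked in
    ``geometry.specific_sites`` carries probability weight ``S`` relative to
    1 for a nonspecific site, so ``S = 1`` is exactly uniform and the
    occupancy ratio between a specific and a nonspecific site is ``S``.
    Reported positions are the percentage of the substrate length measured
    from the *closest* DNA end (folded to 0-50%).  Volumes are log-normal
    (median ``volume_median_nm3``), heights Gaussian.

    Returns a DataFrame with columns
    ``substrate_id, position_pct, height_nm, volume_nm3``.
    """
    if S < 1:
        raise ValueError(
            f"S must be >= 1 (preferential binding cannot give S < 1), got {S}"
        )
    if n_complexes <= 0:
        raise ValueError(f"n_complexes must be > 0, got {n_complexes}")
    rng = np.random.default_rng(seed)
    N = geometry.length_bp
    weights = np.ones(N)
    for _, pos_bp in geometry.specific_sites:
        idx = min(max(int(round(pos_bp)), 1), N) - 1
        weights[idx] = S
    p = weights / weights.sum()
    sites = rng.choice(N, size=n_complexes, p=p)  # 0-based bp index
    pct = 100.0 * (sites + 0.5) / N
    folded = np.minimum(pct, 100.0 - pct)
    volumes = rng.lognormal(mean=math.log(volume_median_nm3),
                            sigma=volume_sigma_log, size=n_complexes)
    heights = np.clip(rng.normal(height_mean_nm, height_sd_nm, size=n_complexes),
                      0.05, None)
    return pd.DataFrame({
        "substrate_id": substrate_id,
        "position_pct": folded,
        "height_nm": heights,
        "volume_nm3": volumes,
    })


def simulate_titration(Kd_nM: float,
                       P_free_mP: float,
                       P_bound_mP: float,
                       concentrations_nM: Sequence[float],
                       noise_sd_mP: float = 0.0,
                       seed: int = 0,
                       substrate_id: str = "substrate") -> pd.DataFrame:
    """Draw an anisotropy titration from the law-of-mass-action isotherm.

    ``P([c]) = (P_bound - P_free) * [c] / (Kd + [c]) + P_free`` plus Gaussian
    noise of sd ``noise_sd_mP``.  Returns a DataFrame with columns
    ``substrate_id, conc_nM, polarization_mP``.
    """
    from .anisotropy import binding_polarization

    if Kd_nM <= 0:
        raise ValueError(f"Kd_nM must be > 0, got {Kd_nM}")
    if P_bound_mP == P_free_mP:
        raise ValueError("P_bound_mP must differ from P_free_mP "
                         "(zero amplitude is unidentifiable)")
    conc = np.asarray(concentrations_nM, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations_nM must be >= 0")
    rng = np.random.default_rng(seed)
    pol = binding_polarization(conc, Kd_nM, P_free_mP, P_bound_mP)
    if noise_sd_mP > 0:
        pol = pol + rng.normal(0.0, noise_sd_mP, size=conc.size)
    return pd.DataFrame({
        "substrate_id": substrate_id,
        "conc_nM": conc,
        "polarization_mP": pol,
    })
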