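"""Independent reference implementations used only to cross-check the package.

These are deliberately naive (double loops, dense transition matrices, grid
search) so that they share no code path with the implementations they test.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr


def msd_bruteforce(positions, present, dt, max_lag):
    """Double-loop time-averaged MSD; returns (lags_s, msd, n_pairs).

    Averages (x_{i+n} - x_i)^2 over every i with both endpoints present.
    """
    x = np.asarray(positions, dtype=float)
    N = len(x)
    lags, msds, npairs = [], [], []
    for n in range(1, max_lag + 1):
        acc = 0.0
        m = 0
        for i in range(N - n):
            if present[i] and present[i + n]:
                d = x[i + n] - x[i]
                acc += d * d
                m += 1
        if m:
            lags.append(n * dt)
            msds.append(acc / m)
            npairs.append(m)
    return np.array(lags), np.array(msds), np.array(npairs)


def markov_stationary_paused_fraction(cfg, n_bins=200):
    """Stationary paused-frame fraction of the two-state walk.

    Discretizes position into ``n_bins`` bins plus one paused state per
    site, builds the exact one-frame transition matrix of the simulator's
    update rule (Gaussian step with reflecting images, capture within the
    capture radius, release back to the site bin), and power-iterates to the
    stationary distribution.
    """
    L = cfg.tightrope_length_um
    h = L / n_bins
    centers = (np.arange(n_bins) + 0.5) * h
    edges = np.arange(n_bins + 1) * h
    sd = np.sqrt(2.0 * cfg.D_free * cfg.frame_interval_s)
    p_c = 1.0 - np.exp(-cfg.k_pause_per_s * cfg.frame_interval_s)
    p_r = 1.0 - np.exp(-cfg.k_release_per_s * cfg.frame_interval_s)
    sites = np.asarray(cfg.pause_sites_um, dtype=float)
    nearest = np.argmin(np.abs(centers[:, None] - sites[None, :]), axis=1)
    in_zone = np.abs(centers - sites[nearest]) <= cfg.capture_radius_um
    site_bin = [int(np.clip(s // h, 0, n_bins - 1)) for s in sites]

    # free-motion kernel: Gaussian step reflected at 0 and L (image method)
    K = np.zeros((n_bins, n_bins))
    for i, c in enumerate(centers):
        prob = np.zeros(n_bins)
        for k in (-2, -1, 0, 1, 2):
            for img in (c + 2 * k * L, -c + 2 * k * L):
                prob += ndtr((edges[1:] - img) / sd) - ndtr((edges[:-1] - img) / sd)
        K[i] = prob / prob.sum()

    n_sites = len(sites)
    N = n_bins + n_sites
    T = np.zeros((N, N))
    for i in range(n_bins):
        for j in range(n_bins):
            if in_zone[j]:
                T[i, n_bins + nearest[j]] += K[i, j] * p_c
                T[i, j] += K[i, j] * (1.0 - p_c)
            else:
                T[i, j] += K[i, j]
    for s in range(n_sites):
        T[n_bins + s, n_bins + s] = 1.0 - p_r
        T[n_bins + s, site_bin[s]] += p_r

    v = np.ones(N) / N
    for _ in range(200000):
        v2 = v @ T
        if np.max(np.abs(v2 - v)) < 1e-14:
            v = v2
            break
        v = v2
    return float(v[n_bins:].sum())


def kd_gridsearch(conc, pol, kd_grid):
    """Best least-squares Kd over a grid, profiling out P_free and P_bound.

    For fixed Kd the isotherm is linear in (P_free, P_bound), so each grid
    point solves a 2-parameter linear least squares exactly.
    """
    conc = np.asarray(conc, dtype=float)
    pol = np.asarray(pol, dtype=float)
    best = (np.inf, np.nan)
    for kd in kd_grid:
        frac = conc / (kd + conc)
        A = np.column_stack([1.0 - frac, frac])
        coef, residues, *_ = np.linalg.lstsq(A, pol, rcond=None)
        resid = pol - A @ coef
        sse = float(resid @ resid)
        if sse < best[0]:
            best = (sse, float(kd))
    return best[1]
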