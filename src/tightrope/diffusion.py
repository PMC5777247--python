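"""Diffusion analysis of single-particle tightrope trajectories.

The quantities computed here are the standard single-particle-tracking
statistics for 1D motion along DNA:

* the time-averaged mean square displacement

  ``MSD(n*dt) = 1/(N-n) * sum_i (x_{i+n} - x_i)^2``

  over all ordered frame pairs at each lag;
* the anomalous-diffusion fit ``MSD = 2 D t^alpha`` (ordinary least squares
  on log MSD vs log t; ``alpha`` = 1 is an unbiased random walk, < 1
  indicates pausing), plus a second D estimate with ``alpha`` fixed at 1;
* a mobile/static classification of whole trajectories
  (mobile iff D > 5e-4 um^2/s and R^2 > 0.8);
* a sliding-window, interval-based diffusion constant ``D_int`` (40-frame /
  2-s windows by default) thresholded at 1.0e-4 um^2/s to flag transient
  static binding events amid free diffusion;
* extraction of maximal static runs as discrete binding events, and the
  survival fraction of particles remaining attached over time.

Within a window, ``D_int`` is half the slope of a straight-line (slope +
intercept) fit of the window MSD against lag time over lags
``1..window/4``.  Fitting an intercept absorbs the constant ``2*sigma^2``
localization-noise floor, so a paused particle yields a slope near zero
rather than the noise floor itself; negative slopes are clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .simulate import Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "WindowSeries",
    "StaticEvent",
    "compute_msd",
    "fit_diffusion",
    "classify_mobility",
    "sliding_window_dint",
    "detect_static_events",
    "survival_fraction",
    "MOBILE_D_THRESHOLD",
    "MOBILE_R2_THRESHOLD",
    "STATIC_DINT_THRESHOLD",
]

#: Mobile-classification thresholds for whole trajectories.
MOBILE_D_THRESHOLD = 5e-4  # um^2 s^-1
MOBILE_R2_THRESHOLD = 0.8
#: D_int below this flags a window as a static binding event (um^2 s^-1).
STATIC_DINT_THRESHOLD = 1e-4


@dataclass
class MSDCurve:
    """Lag-dependent displacement statistics of one trajectory."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self):
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(self.lags_s <= 0):
            raise ValueError("lag 0 is excluded; lags must be > 0")
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD values must be >= 0")


@dataclass
class DiffusionFit:
    """Result of fitting MSD = 2 D t^alpha to an MSD curve."""

    D_um2_per_s: float
    alpha: float
    r_squared: float
    fit_lag_range: Tuple[float, float]
    #: D from a linear fit through the origin with alpha fixed at 1.
    D_alpha1_um2_per_s: float = np.nan
    n_lags: int = 0

    def __post_init__(self):
        if self.D_um2_per_s < 0:
            raise ValueError("D must be >= 0")
        if not 0 <= self.alpha <= 2.5:
            raise ValueError(f"alpha {self.alpha} outside the physical range [0, 2.5]")


@dataclass
class WindowSeries:
    """Sliding-window D_int series over one trajectory."""

    window_start_frames: np.ndarray
    D_int_um2_per_s: np.ndarray
    static_flags: np.ndarray
    valid: np.ndarray            # False where the window was skipped (absent frames)
    window_frames: int
    threshold: float
    frame_interval_s: float

    @property
    def fraction_static(self) -> float:
        """Fraction of valid windows flagged static."""
        n_valid = int(self.valid.sum())
        if n_valid == 0:
            return float("nan")
        return float(self.static_flags[self.valid].sum() / n_valid)


@dataclass
class StaticEvent:
    """One stable binding event recovered from a window series."""

    start_s: float
    end_s: float
    mean_position_um: float
    n_windows: int = 0

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("event must have end_s > start_s")


def compute_msd(traj: Trajectory, max_lag_fraction: float = 0.25) -> MSDCurve:
    """Time-averaged MSD of a trajectory.

    Averages ``(x_{i+n} - x_i)^2`` over every ordered frame pair at each lag
    ``n``, for lags up to ``max_lag_fraction`` of the trajectory length.
    Pairs with an absent endpoint are excluded; lags left with no pairs are
    dropped from the curve.

    Raises
    ------
    ValueError
        If fewer than 10 frames are present.
    """
    x = np.asarray(traj.positions_um, dtype=float)
    present = np.asarray(traj.present, dtype=bool) & np.isfinite(x)
    if present.sum() == 0:
        raise ValueError("trajectory has no present frames")
    if present.sum() < 10:
        raise ValueError(
            f"need >= 10 present frames for an MSD, got {int(present.sum())}"
        )
    N = len(x)
    dt = traj.frame_interval_s
    max_lag = max(int(np.floor(max_lag_fraction * N)), 1)
    lags, msds, npairs = [], [], []
    for n in range(1, max_lag + 1):
        ok = present[n:] & present[:-n]
        m = int(ok.sum())
        if m == 0:
            continue
        d = x[n:][ok] - x[:-n][ok]
        lags.append(n * dt)
        msds.append(float(np.mean(d * d)))
        npairs.append(m)
    if not lags:
        raise ValueError("no valid frame pairs at any lag")
    return MSDCurve(np.array(lags), np.array(msds), np.array(npairs))


def fit_diffusion(msd: MSDCurve,
                  min_pairs: int = 5,
                  fit_lag_range: Optional[Tuple[float, float]] = None) -> DiffusionFit:
    """Fit ``MSD = 2 D t^alpha`` by OLS on ``log MSD`` vs ``log t``.

    ``alpha`` is the slope and ``D = exp(intercept) / 2``; R^2 is reported on
    the same log-log regression.  A second estimate with ``alpha`` fixed at 1
    (straight line through the origin over the same lags) is returned as
    ``D_alpha1_um2_per_s``.  Lags with nonpositive MSD or fewer than
    ``min_pairs`` averaging pairs are dropped; at least 4 usable lags are
    required.
    """
    sel = (msd.n_pairs >= min_pairs) & (msd.msd_um2 > 0)
    if fit_lag_range is not None:
        lo, hi = fit_lag_range
        sel &= (msd.lags_s >= lo) & (msd.lags_s <= hi)
    t = msd.lags_s[sel]
    y = msd.msd_um2[sel]
    if t.size < 4:
        raise ValueError(
            f"need >= 4 usable lags to fit MSD = 2Dt^alpha, got {t.size}"
        )
    logt, logy = np.log(t), np.log(y)
    alpha, logb = np.polyfit(logt, logy, 1)
    pred = alpha * logt + logb
    ss_res = float(np.sum((logy - pred) ** 2))
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    D = float(np.exp(logb) / 2.0)
    # alpha fixed at 1: least squares through the origin, MSD = 2 D t
    D_alpha1 = float(np.sum(y * t) / (2.0 * np.sum(t * t)))
    return DiffusionFit(
        D_um2_per_s=D,
        alpha=float(np.clip(alpha, 0.0, 2.5)),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        fit_lag_range=(float(t.min()), float(t.max())),
        D_alpha1_um2_per_s=D_alpha1,
        n_lags=int(t.size),
    )


def classify_mobility(fit: DiffusionFit,
                      d_threshold: float = MOBILE_D_THRESHOLD,
                      r2_threshold: float = MOBILE_R2_THRESHOLD) -> str:
    """Classify a trajectory fit as ``"mobile"`` or ``"static"``.

    Mobile requires both D above ``d_threshold`` (default 5e-4 um^2/s) and
    R^2 above ``r2_threshold`` (default 0.8); anything else is static.
    """
    if fit.D_um2_per_s > d_threshold and fit.r_squared > r2_threshold:
        return "mobile"
    return "static"


def sliding_window_dint(traj: Trajectory,
                        window_frames: int = 40,
                        step_frames: int = 1,
                        threshold: float = STATIC_DINT_THRESHOLD) -> WindowSeries:
    """Interval-based diffusion constant over a sliding window.

    For each window of ``window_frames`` frames (stepped by ``step_frames``),
    the within-window MSD is computed over lags ``1..window_frames//4`` and a
    straight line (slope + intercept) is fitted against lag time;
    ``D_int = max(slope / 2, 0)``.  Windows containing absent frames are
    skipped (marked invalid).  A window is flagged static when
    ``D_int < threshold``.
    """
    if window_frames < 10:
        raise ValueError(f"window_frames must be >= 10, got {window_frames}")
    N = traj.n_frames
    if N < window_frames:
        raise ValueError(
            f"trajectory ({N} frames) shorter than the window ({window_frames})"
        )
    x = np.asarray(traj.positions_um, dtype=float)
    present = np.asarray(traj.present, dtype=bool) & np.isfinite(x)
    dt = traj.frame_interval_s
    W = window_frames
    L = max(W // 4, 2)
    starts = np.arange(0, N - W + 1, step_frames)
    n_win = starts.size

    # windows free of absent frames
    pres_csum = np.concatenate([[0], np.cumsum(present)])
    valid = (pres_csum[starts + W] - pres_csum[starts]) == W

    xs = np.where(present, x, 0.0)
    # M[w, n-1] = within-window MSD at lag n for window starting at starts[w]
    M = np.empty((n_win, L))
    for n in range(1, L + 1):
        sq = (xs[n:] - xs[:-n]) ** 2
        csum = np.concatenate([[0.0], np.cumsum(sq)])
        cnt = W - n
        M[:, n - 1] = (csum[starts + cnt] - csum[starts]) / cnt

    tlags = np.arange(1, L + 1) * dt
    tc = tlags - tlags.mean()
    denom = float(np.sum(tc * tc))
    slope = (M - M.mean(axis=1, keepdims=True)) @ tc / denom
    D_int = np.maximum(slope / 2.0, 0.0)
    D_int[~valid] = np.nan
    flags = np.zeros(n_win, dtype=bool)
    flags[valid] = D_int[valid] < threshold
    return WindowSeries(
        window_start_frames=starts,
        D_int_um2_per_s=D_int,
        static_flags=flags,
        valid=valid,
        window_frames=W,
        threshold=threshold,
        frame_interval_s=dt,
    )


def detect_static_events(ws: WindowSeries,
                         traj: Trajectory,
                         min_run_windows: int = 20) -> List[StaticEvent]:
    """Turn runs of static windows into discrete binding events.

    Maximal runs of at least ``min_run_windows`` consecutive static windows
    become events; runs separated by fewer than ``window_frames // 2`` window
    steps are merged first.  The event position is the mean reported position
    over the frames the run covers, and its times span from the first frame
    of the first window to the last frame of the last.
    """
    flags = ws.static_flags & ws.valid
    starts = ws.window_start_frames
    W = ws.window_frames
    dt = ws.frame_interval_s
    x = np.asarray(traj.positions_um, dtype=float)
    present = np.asarray(traj.present, dtype=bool) & np.isfinite(x)
    times = np.asarray(traj.times_s, dtype=float)

    # maximal runs of consecutive static windows (indices into the series)
    runs = []
    i = 0
    n = flags.size
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    # merge runs separated by less than half a window
    merged = []
    for run in runs:
        if merged and (run[0] - merged[-1][1]) < W // 2:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    events = []
    for i0, i1 in merged:
        if (i1 - i0 + 1) < min_run_windows:
            continue
        f0 = int(starts[i0])
        f1 = int(starts[i1]) + W - 1
        seg = slice(f0, f1 + 1)
        ok = present[seg]
        if not ok.any():
            continue
        mean_pos = float(np.mean(x[seg][ok]))
        events.append(StaticEvent(
            start_s=float(times[f0]),
            end_s=float(times[f1]) if times[f1] > times[f0] else float(times[f0]) + dt,
            mean_position_um=mean_pos,
            n_windows=i1 - i0 + 1,
        ))
    return events


def survival_fraction(trajs: Sequence[Trajectory], t_s: float) -> float:
    """Fraction of particles still attached at time ``t_s``.

    Counts, among particles present at time 0, those still present at the
    first recorded frame at or after ``t_s``.
    """
    if len(trajs) == 0:
        raise ValueError("survival_fraction needs at least one trajectory")
    alive0 = 0
    alive_t = 0
    for traj in trajs:
        if not traj.present[0]:
            continue
        if traj.times_s[-1] < t_s:
            raise ValueError(
                f"trajectory {traj.particle_id!r} ends at {traj.times_s[-1]} s, "
                f"before t = {t_s} s"
            )
        alive0 += 1
        idx = int(np.searchsorted(traj.times_s, t_s))
        if traj.present[idx]:
            alive_t += 1
    if alive0 == 0:
        raise ValueError("no particles present at t = 0")
    return alive_t / alive0
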