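"""Equilibrium binding affinity from fluorescence anisotropy titrations.

A fluorescently labeled DNA probe tumbles more slowly when protein is bound,
raising the measured polarization P.  Titration of protein at a trace probe
concentration follows the law of mass action,

    ``P = (P_bound - P_free) * [protein] / (Kd + [protein]) + P_free``,

where ``P_free`` is the polarization of the free probe, ``P_bound`` the
plateau at saturation, and ``Kd`` the equilibrium dissociation constant.
This treats the total protein concentration as free protein, valid when
``[probe] << Kd`` (the usual ~1 nM probe regime).  An optional
depletion-corrected variant solves the exact quadratic mass balance for the
bound fraction instead; it goes beyond the plain isotherm and is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["AffinityFit", "binding_polarization", "fit_binding", "compare_affinities"]


def binding_polarization(conc_nM, Kd_nM, P_free_mP, P_bound_mP):
    """Law-of-mass-action polarization at given protein concentrations."""
    conc = np.asarray(conc_nM, dtype=float)
    return (P_bound_mP - P_free_mP) * conc / (Kd_nM + conc) + P_free_mP


def _depletion_polarization(conc_nM, Kd_nM, P_free_mP, P_bound_mP, probe_nM):
    """Quadratic mass-balance variant accounting for probe depletion."""
    c = np.asarray(conc_nM, dtype=float)
    b = Kd_nM + c + probe_nM
    bound = (b - np.sqrt(b * b - 4.0 * c * probe_nM)) / (2.0 * probe_nM)
    return (P_bound_mP - P_free_mP) * bound + P_free_mP


@dataclass
class AffinityFit:
    """Fitted binding isotherm for one substrate."""

    substrate_id: str
    Kd_nM: float
    P_free_mP: float
    P_bound_mP: float
    se_Kd_nM: float
    converged: bool
    no_detectable_binding: bool = False
    residual_sd_mP: float = float("nan")
    n_points: int = 0
    message: str = ""


def fit_binding(titration: pd.DataFrame,
                probe_nM: Optional[float] = None,
                amplitude_snr: float = 3.0) -> AffinityFit:
    """Fit the binding isotherm to one titration.

    ``titration`` needs columns ``conc_nM`` and ``polarization_mP`` (and
    optionally ``substrate_id``).  Starting values: ``P_free`` from the
    lowest concentration, ``P_bound`` from the highest, ``Kd`` from the
    concentration nearest half-amplitude; ``Kd`` is bounded in
    ``(0, 10 * max concentration]``.  ``se_Kd`` comes from the covariance of
    the least-squares fit.

    A fitted amplitude smaller than ``amplitude_snr`` times the residual sd
    is flagged ``no_detectable_binding`` (the titration never leaves the
    noise floor).  Non-convergence returns ``converged=False`` with a
    diagnostic message instead of raising.

    When ``probe_nM`` is given, the exact probe-depletion quadratic is used
    in place of the plain isotherm.
    """
    for col in ("conc_nM", "polarization_mP"):
        if col not in titration.columns:
            raise ValueError(f"titration is missing required column {col!r}")
    sid = str(titration["substrate_id"].iloc[0]) if "substrate_id" in titration else ""
    conc = titration["conc_nM"].to_numpy(dtype=float)
    pol = titration["polarization_mP"].to_numpy(dtype=float)
    if conc.size < 6:
        raise ValueError(f"need >= 6 titration points, got {conc.size}")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    order = np.argsort(conc)
    conc, pol = conc[order], pol[order]

    p_free0 = float(pol[0])
    p_bound0 = float(pol[-1])
    half = p_free0 + 0.5 * (p_bound0 - p_free0)
    kd0 = float(conc[np.argmin(np.abs(pol - half))])
    cmax = float(conc.max())
    kd0 = min(max(kd0, 1e-3), 10.0 * cmax)

    if probe_nM is None:
        model = binding_polarization
        p0 = (kd0, p_free0, p_bound0)
    else:
        def model(c, kd, pf, pb):
            return _depletion_polarization(c, kd, pf, pb, probe_nM)
        p0 = (kd0, p_free0, p_bound0)

    try:
        popt, pcov = curve_fit(
            model, conc, pol, p0=p0,
            bounds=([1e-9, -np.inf, -np.inf], [10.0 * cmax, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return AffinityFit(substrate_id=sid, Kd_nM=float("nan"),
                           P_free_mP=float("nan"), P_bound_mP=float("nan"),
                           se_Kd_nM=float("nan"), converged=False,
                           n_points=conc.size, message=f"fit failed: {exc}")
    kd, pf, pb = (float(v) for v in popt)
    resid = pol - model(conc, *popt)
    dof = max(conc.size - 3, 1)
    resid_sd = float(np.sqrt(np.sum(resid ** 2) / dof))
    se_kd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    # realized response span over the measured range; a huge fitted amplitude
    # paired with a huge Kd still means the curve never left the noise floor
    span = abs(float(model(np.array([cmax]), *popt)[0])
               - float(model(np.array([conc.min()]), *popt)[0]))
    no_binding = span < amplitude_snr * resid_sd
    return AffinityFit(
        substrate_id=sid, Kd_nM=kd, P_free_mP=pf, P_bound_mP=pb,
        se_Kd_nM=se_kd, converged=True,
        no_detectable_binding=bool(no_binding),
        residual_sd_mP=resid_sd, n_points=int(conc.size),
    )


def compare_affinities(fits: Sequence[AffinityFit]):
    """Rank converged fits by affinity and tabulate pairwise Kd ratios.

    Returns ``(table, ratios)``: ``table`` lists the converged fits sorted by
    ascending Kd (strongest binder first); ``ratios`` holds every unordered
    pair's ``Kd_a / Kd_b`` with the standard error propagated from the two
    fit SEs.  Unconverged fits are excluded and listed in
    ``table.attrs["excluded"]``.
    """
    good = [f for f in fits if f.converged]
    excluded = [f.substrate_id for f in fits if not f.converged]
    if len(good) < 2:
        raise ValueError("need at least 2 converged fits to compare")
    good = sorted(good, key=lambda f: f.Kd_nM)
    table = pd.DataFrame({
        "substrate_id": [f.substrate_id for f in good],
        "Kd_nM": [f.Kd_nM for f in good],
        "se_Kd_nM": [f.se_Kd_nM for f in good],
        "no_detectable_binding": [f.no_detectable_binding for f in good],
    })
    table.attrs["excluded"] = excluded

    rows: List[dict] = []
    for a, b in combinations(good, 2):
        ratio = a.Kd_nM / b.Kd_nM
        rel = 0.0
        for f in (a, b):
            if np.isfinite(f.se_Kd_nM) and f.Kd_nM > 0:
                rel += (f.se_Kd_nM / f.Kd_nM) ** 2
        rows.append({
            "substrate_a": a.substrate_id,
            "substrate_b": b.substrate_id,
            "Kd_ratio": ratio,
            "se_ratio": ratio * np.sqrt(rel),
        })
    return table, pd.DataFrame(rows)
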