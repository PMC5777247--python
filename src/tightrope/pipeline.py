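"""End-to-end orchestration: simulate -> analyze -> report.

A pipeline run is driven by a single configuration mapping with up to three
stage sections plus a global seed:

``trajectories``
    list of scenarios, each ``{name, kind: free|two_state, n_trajectories,
    config: {TrajectorySimConfig overrides}}``; every trajectory is
    simulated, written to CSV, fitted (MSD -> D, alpha), classified
    mobile/static, and scanned with the sliding-window D_int detector.
``afm``
    ``{substrate: {length_bp, specific_sites: [{kind, position_bp}], ...},
    S, n_complexes, bin_width_pct, end_region_bp, site_halfwidth_bp}``;
    simulates a deposition and estimates the binding specificity.
``titration``
    ``{Kd_nM, P_free_mP, P_bound_mP, concentrations_nM, noise_sd_mP}``;
    simulates a titration and refits the isotherm.

Per-stage seeds are spawned deterministically from the global seed, so an
identical configuration reproduces an identical summary, byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import __version__
from .afm import (build_position_histogram, estimate_specificity,
                  specific_regions_from_geometry)
from .anisotropy import fit_binding
from .diffusion import (classify_mobility, compute_msd, fit_diffusion,
                        sliding_window_dint)
from .io import write_afm_records, write_titrations, write_trajectories
from .simulate import (SubstrateGeometry, TrajectorySimConfig,
                       simulate_afm_positions, simulate_free_diffusion,
                       simulate_titration, simulate_two_state)

__all__ = ["PipelineError", "run_pipeline", "PIPELINE_KEYS"]

PIPELINE_KEYS = ("seed", "trajectories", "afm", "titration")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``.stage``."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _config_hash(config: Dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def _seed_for(master_seed: int, label: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _trajectory_stage(scenarios: List[dict], seed: int, out_dir: Optional[Path]):
    summary = {}
    for scenario in scenarios:
        name = scenario["name"]
        kind = scenario.get("kind", "free")
        n_traj = int(scenario.get("n_trajectories", 10))
        overrides = dict(scenario.get("config", {}))
        trajs = []
        rows = []
        for i in range(n_traj):
            cfg = TrajectorySimConfig(
                **{**overrides, "seed": _seed_for(seed, f"{name}:{i}")}
            )
            if kind == "two_state":
                traj, _states = simulate_two_state(cfg, particle_id=f"{name}_{i}")
            elif kind == "free":
                traj = simulate_free_diffusion(cfg, particle_id=f"{name}_{i}")
            else:
                raise ValueError(f"unknown scenario kind {kind!r}")
            trajs.append(traj)
            fit = fit_diffusion(compute_msd(traj))
            ws = sliding_window_dint(traj)
            rows.append({
                "D": fit.D_um2_per_s,
                "alpha": fit.alpha,
                "r2": fit.r_squared,
                "mobility": classify_mobility(fit),
                "fraction_static": ws.fraction_static,
            })
        if out_dir is not None:
            write_trajectories(trajs, out_dir / f"trajectories_{name}.csv")
        frac = [r["fraction_static"] for r in rows if np.isfinite(r["fraction_static"])]
        summary[name] = {
            "n_trajectories": n_traj,
            "mean_D_um2_per_s": round(float(np.mean([r["D"] for r in rows])), 6),
            "mean_alpha": round(float(np.mean([r["alpha"] for r in rows])), 4),
            "fraction_mobile": round(
                sum(r["mobility"] == "mobile" for r in rows) / n_traj, 4),
            "fraction_static_windows": round(float(np.mean(frac)), 4) if frac else None,
        }
    return summary


def _afm_stage(cfg: dict, seed: int, out_dir: Optional[Path]):
    sub = cfg["substrate"]
    geometry = SubstrateGeometry(
        length_bp=int(sub["length_bp"]),
        specific_sites=tuple((s["kind"], s["position_bp"])
                             for s in sub.get("specific_sites", [])),
        rise_nm_per_bp=float(sub.get("rise_nm_per_bp", 0.34)),
    )
    records = simulate_afm_positions(
        geometry, S=float(cfg["S"]), n_complexes=int(cfg.get("n_complexes", 2000)),
        seed=_seed_for(seed, "afm"), substrate_id=sub.get("id", "substrate"),
    )
    if out_dir is not None:
        write_afm_records(records, out_dir / "afm_records.csv")
    regions = specific_regions_from_geometry(
        geometry,
        end_region_bp=float(cfg.get("end_region_bp", 0.0)),
        site_halfwidth_bp=float(cfg.get("site_halfwidth_bp",
                                        geometry.length_bp * 0.0125)),
    )
    hist = build_position_histogram(
        records, bin_width_pct=float(cfg.get("bin_width_pct", 2.5)),
        specific_regions=regions,
    )
    result = estimate_specificity(hist, N_sites=geometry.length_bp,
                                  seed=_seed_for(seed, "afm-boot"))
    return {
        "S": round(result.S, 2),
        "se_S": round(result.se_S, 2),
        "A_SP": result.A_SP,
        "A_NSP": result.A_NSP,
        "N_sites": result.N_sites,
    }


def _titration_stage(cfg: dict, seed: int, out_dir: Optional[Path]):
    titr = simulate_titration(
        Kd_nM=float(cfg["Kd_nM"]),
        P_free_mP=float(cfg.get("P_free_mP", 100.0)),
        P_bound_mP=float(cfg.get("P_bound_mP", 300.0)),
        concentrations_nM=cfg.get("concentrations_nM",
                                  [0, 5, 10, 25, 50, 100, 200, 400, 700, 1000]),
        noise_sd_mP=float(cfg.get("noise_sd_mP", 0.0)),
        seed=_seed_for(seed, "titration"),
        substrate_id=cfg.get("id", "substrate"),
    )
    if out_dir is not None:
        write_titrations(titr, out_dir / "titration.csv")
    fit = fit_binding(titr)
    return {
        "Kd_nM": round(fit.Kd_nM, 3),
        "se_Kd_nM": round(fit.se_Kd_nM, 3) if np.isfinite(fit.se_Kd_nM) else None,
        "converged": fit.converged,
        "no_detectable_binding": fit.no_detectable_binding,
    }


def run_pipeline(config: Dict, out_dir=None) -> Dict:
    """Run the configured stages and return (and optionally write) a summary.

    Unknown configuration keys are rejected.  Stage failures raise
    :class:`PipelineError` naming the stage; outputs written by earlier
    stages are retained.
    """
    unknown = set(config) - set(PIPELINE_KEYS)
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    summary: Dict = {
        "provenance": {
            "config_sha256": _config_hash(config),
            "seed": seed,
            "tightrope_version": __version__,
        }
    }
    stages = (
        ("trajectories", _trajectory_stage),
        ("afm", _afm_stage),
        ("titration", _titration_stage),
    )
    for stage_name, runner in stages:
        if stage_name not in config:
            continue
        try:
            summary[stage_name] = runner(config[stage_name], seed, out_path)
        except Exception as exc:  # noqa: BLE001 - report the failing stage
            if out_path is not None:
                (out_path / "summary_partial.json").write_text(
                    json.dumps(summary, indent=2, sort_keys=True))
            raise PipelineError(stage_name, exc) from exc

    if out_path is not None:
        (out_path / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
    return summary
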