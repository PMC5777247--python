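"""Readers and writers for the pipeline's file formats.

Conventions (stated in every header): tightrope positions in um from the
left bead anchor; AFM positions as % of substrate length folded to [0, 50];
bp coordinates 1-based inclusive.  Trajectories round-trip positions to
1e-6 um.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .simulate import Kymograph, SubstrateGeometry, Trajectory

__all__ = [
    "TRAJECTORY_COLUMNS", "AFM_COLUMNS", "TITRATION_COLUMNS",
    "write_trajectories", "read_trajectories",
    "write_kymograph", "read_kymograph",
    "write_afm_records", "read_afm_records",
    "write_titrations", "read_titrations",
    "load_substrate_yaml", "load_yaml_config",
]

TRAJECTORY_COLUMNS = ["particle_id", "frame", "time_s", "position_um", "present"]
AFM_COLUMNS = ["substrate_id", "position_pct", "height_nm", "volume_nm3"]
TITRATION_COLUMNS = ["substrate_id", "conc_nM", "polarization_mP"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def write_trajectories(trajs: Sequence[Trajectory], path) -> None:
    frames = []
    for traj in trajs:
        frames.append(pd.DataFrame({
            "particle_id": traj.particle_id,
            "frame": np.arange(traj.n_frames),
            "time_s": traj.times_s,
            "position_um": np.round(traj.positions_um, 6),
            "present": traj.present.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> List[Trajectory]:
    df = pd.read_csv(path)
    _require_columns(df, TRAJECTORY_COLUMNS, path)
    for col in ("frame", "time_s", "position_um", "present"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = coerced
    trajs = []
    for pid, sub in df.groupby("particle_id", sort=False):
        sub = sub.sort_values("frame")
        trajs.append(Trajectory(
            particle_id=str(pid),
            times_s=sub["time_s"].to_numpy(),
            positions_um=sub["position_um"].to_numpy(),
            present=sub["present"].to_numpy().astype(bool),
        ))
    return trajs


def write_kymograph(kymo: Kymograph, path) -> None:
    """Single-channel TIFF plus a JSON sidecar with the physical metadata."""
    path = Path(path)
    tifffile.imwrite(path, kymo.intensity.astype(np.float32))
    sidecar = {
        "pixel_size_um": kymo.pixel_size_um,
        "frame_interval_s": kymo.frame_interval_s,
        "psf_sigma_um": kymo.psf_sigma_um,
        "meta": {k: v for k, v in kymo.meta.items()
                 if isinstance(v, (int, float, str, bool))},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_kymograph(path) -> Kymograph:
    path = Path(path)
    intensity = tifffile.imread(path).astype(np.float64)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"kymograph sidecar {sidecar_path} not found")
    sidecar = json.loads(sidecar_path.read_text())
    return Kymograph(
        intensity=intensity,
        pixel_size_um=float(sidecar["pixel_size_um"]),
        frame_interval_s=float(sidecar["frame_interval_s"]),
        psf_sigma_um=float(sidecar.get("psf_sigma_um", 0.125)),
        meta=sidecar.get("meta", {}),
    )


def write_afm_records(records: pd.DataFrame, path) -> None:
    _require_columns(records, AFM_COLUMNS, "records")
    records.to_csv(path, index=False, columns=AFM_COLUMNS)


def read_afm_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, AFM_COLUMNS, path)
    return df


def write_titrations(titrations: pd.DataFrame, path) -> None:
    _require_columns(titrations, TITRATION_COLUMNS, "titrations")
    titrations.to_csv(path, index=False, columns=TITRATION_COLUMNS)


def read_titrations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TITRATION_COLUMNS, path)
    return df


def load_substrate_yaml(path) -> dict:
    """Load a substrate definition (geometry + analysis regions) from YAML.

    Recognized keys: ``length_bp`` (required), ``specific_sites`` (list of
    ``{kind, position_bp}``), ``rise_nm_per_bp``, ``elongation_fraction``,
    ``repeat_unit_bp``, ``end_region_bp``, ``site_halfwidth_bp``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    allowed = {"length_bp", "specific_sites", "rise_nm_per_bp",
               "elongation_fraction", "repeat_unit_bp",
               "end_region_bp", "site_halfwidth_bp"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown substrate keys {sorted(unknown)}")
    sites = tuple(
        (s["kind"], s["position_bp"]) for s in raw.get("specific_sites", [])
    )
    geometry = SubstrateGeometry(
        length_bp=int(raw["length_bp"]),
        specific_sites=sites,
        repeat_unit_bp=raw.get("repeat_unit_bp"),
        rise_nm_per_bp=float(raw.get("rise_nm_per_bp", 0.34)),
        elongation_fraction=float(raw.get("elongation_fraction", 0.9)),
    )
    return {
        "geometry": geometry,
        "end_region_bp": float(raw.get("end_region_bp", 0.0)),
        "site_halfwidth_bp": float(raw.get("site_halfwidth_bp", 0.5)),
    }


def load_yaml_config(path, allowed_keys: Sequence[str]) -> Dict:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - set(allowed_keys)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return raw
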