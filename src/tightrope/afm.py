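"""AFM position-distribution analysis of protein-DNA complexes.

From an AFM field of deposited complexes on a defined linear substrate, the
binding specificity of a protein for a structural feature (DNA end, ssDNA
gap, flap, fork, ...) is estimated from fractional occupancies: with
``A_SP`` complexes counted in the specific region, ``A_NSP`` in the
nonspecific remainder, and ``N`` binding sites on the substrate (one per
base pair),

    ``S = K_SP / K_NSP = N * A_SP / A_NSP + 1``.

Positions are measured as a percentage of the substrate length from the
*closest* DNA end, folding the distribution to 0-50% (so a substrate has two
end sites in the first bin and one site per internal feature).

Because the specific region of the histogram also collects the baseline
nonspecific occupancy of the sites it covers, the default estimator
subtracts that baseline before applying the ratio:

    ``S = 1 + (N / n_sp) * ((1 - f) * A_SP - f * A_NSP) / A_NSP``

where ``f`` is the fraction of binding sites falling in the specific bins
and ``n_sp`` the number of specific sites.  This reduces to the plain ratio
formula in the narrow-region, single-site limit (``f -> 0``, ``n_sp = 1``)
and is unbiased for all ``S >= 1``, including the no-specificity case
``S = 1``.  The uncorrected value is kept on the result as ``eq1_value``.

The module also carries the AFM volume-to-molecular-weight calibration
``V = 1.45 * M_r - 21.59`` (V in nm^3, M_r in kDa) used to count protein
copies in a complex, and the substrate geometry arithmetic (bp <-> nm,
fractional positions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .simulate import SubstrateGeometry

__all__ = [
    "AFMComplexRecord",
    "PositionHistogram",
    "SpecificityResult",
    "VolumeCalibration",
    "build_position_histogram",
    "estimate_specificity",
    "specificity_from_counts",
    "volume_to_mw",
    "mw_to_volume",
    "estimate_copy_number",
    "substrate_fraction",
    "fold_position_pct",
    "nm_bp_convert",
    "specific_regions_from_geometry",
]


@dataclass(frozen=True)
class AFMComplexRecord:
    """One protein-DNA complex measured in an AFM image."""

    substrate_id: str
    position_pct: float  # % of length from the closest end, in [0, 50]
    height_nm: float
    volume_nm3: float

    def __post_init__(self):
        if not 0 <= self.position_pct <= 50:
            raise ValueError(
                f"position_pct must lie in [0, 50], got {self.position_pct}"
            )
        if self.volume_nm3 < 0:
            raise ValueError(f"volume_nm3 must be >= 0, got {self.volume_nm3}")


@dataclass(frozen=True)
class VolumeCalibration:
    """Linear AFM volume vs molecular weight calibration, V = slope*M_r + intercept."""

    slope_nm3_per_kDa: float = 1.45
    intercept_nm3: float = -21.59

    def __post_init__(self):
        if self.slope_nm3_per_kDa <= 0:
            raise ValueError("calibration slope must be > 0")


@dataclass
class PositionHistogram:
    """Folded (0-50%) position distribution of complexes on one substrate."""

    bin_edges_pct: np.ndarray
    counts: np.ndarray
    n_total: int
    specific_bins: Tuple[int, ...]
    n_specific_sites: int
    positions_pct: np.ndarray  # the underlying folded positions

    @property
    def bin_width_pct(self) -> float:
        return float(self.bin_edges_pct[1] - self.bin_edges_pct[0])

    @property
    def specific_site_fraction(self) -> float:
        """Fraction of binding sites covered by the specific bins."""
        return len(self.specific_bins) * self.bin_width_pct / 50.0


@dataclass
class SpecificityResult:
    """Binding specificity S with its occupancy inputs."""

    S: float
    se_S: float
    A_SP: int
    A_NSP: int
    N_sites: int
    n_specific_sites: int
    specific_site_fraction: float
    background_corrected: bool
    infinite: bool = False

    @property
    def eq1_value(self) -> float:
        """Plain ratio-formula value N * A_SP / A_NSP + 1 on the raw counts."""
        if self.A_NSP == 0:
            return float("inf")
        return self.N_sites * self.A_SP / self.A_NSP + 1.0


def fold_position_pct(pct: np.ndarray | float) -> np.ndarray | float:
    """Fold a position in % of full length onto the nearest end (0-50%)."""
    pct = np.asarray(pct, dtype=float)
    folded = np.minimum(pct, 100.0 - pct)
    return float(folded) if folded.ndim == 0 else folded


class SubstratePosition(NamedTuple):
    pct: float
    folded_pct: float


def substrate_fraction(position_bp: float, length_bp: float) -> SubstratePosition:
    """Express a bp coordinate as percent of the substrate length.

    Returns both the raw percentage from the reference end and the variant
    folded to the closest end (0-50%).
    """
    if length_bp <= 0:
        raise ValueError(f"length_bp must be > 0, got {length_bp}")
    if not 0 <= position_bp <= length_bp:
        raise ValueError(
            f"position_bp {position_bp} outside [0, {length_bp}]"
        )
    pct = 100.0 * position_bp / length_bp
    return SubstratePosition(pct=pct, folded_pct=float(min(pct, 100.0 - pct)))


def nm_bp_convert(value: float, rise_nm_per_bp: float = 0.32,
                  direction: str = "bp_to_nm") -> float:
    """Convert between base pairs and nanometres at a given helical rise."""
    if rise_nm_per_bp <= 0:
        raise ValueError(f"rise_nm_per_bp must be > 0, got {rise_nm_per_bp}")
    if direction == "bp_to_nm":
        return value * rise_nm_per_bp
    if direction == "nm_to_bp":
        return value / rise_nm_per_bp
    raise ValueError(f"direction must be 'bp_to_nm' or 'nm_to_bp', got {direction!r}")


def specific_regions_from_geometry(geometry: SubstrateGeometry,
                                   end_region_bp: float = 0.0,
                                   site_halfwidth_bp: float = 0.5
                                   ) -> List[Tuple[float, float, int]]:
    """Folded ``(lo_pct, hi_pct, n_sites)`` regions for a substrate's features.

    Internal sites become one region each (one site); if the substrate's
    specific sites include ends, or ``end_region_bp`` is positive, the end
    region covers both physical ends (two sites).
    """
    N = geometry.length_bp
    regions: List[Tuple[float, float, int]] = []
    has_end = any(k == "end" for k, _ in geometry.specific_sites)
    if has_end or end_region_bp > 0:
        width = max(end_region_bp, site_halfwidth_bp)
        regions.append((0.0, 100.0 * width / N, 2))
    for kind, pos_bp in geometry.specific_sites:
        if kind == "end":
            continue
        folded = substrate_fraction(pos_bp, N).folded_pct
        h = 100.0 * site_halfwidth_bp / N
        regions.append((max(folded - h, 0.0), min(folded + h, 50.0), 1))
    return regions


def build_position_histogram(records: pd.DataFrame,
                             bin_width_pct: float = 2.5,
                             specific_regions: Optional[Sequence] = None
                             ) -> PositionHistogram:
    """Histogram folded positions and mark the specific bins.

    ``records`` needs a ``position_pct`` column with folded (0-50%)
    positions; ``bin_width_pct`` must divide 50 evenly.  ``specific_regions``
    is a sequence of ``(lo_pct, hi_pct)`` or ``(lo_pct, hi_pct, n_sites)``
    intervals in folded coordinates; every bin overlapping a region is
    marked specific.
    """
    if "position_pct" not in records.columns:
        raise ValueError("records must have a 'position_pct' column")
    pos = records["position_pct"].to_numpy(dtype=float)
    bad = (pos < 0) | (pos > 50) | ~np.isfinite(pos)
    if bad.any():
        ids = records.index[bad].tolist()[:5]
        raise ValueError(
            f"positions outside [0, 50] for record(s) {ids} "
            f"(values {pos[bad][:5].tolist()})"
        )
    n_bins_f = 50.0 / bin_width_pct
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(
            f"bin_width_pct {bin_width_pct} does not divide 50 evenly"
        )
    edges = np.linspace(0.0, 50.0, n_bins + 1)
    counts, _ = np.histogram(pos, bins=edges)

    specific_bins: List[int] = []
    n_sites = 0
    if specific_regions:
        for region in specific_regions:
            if len(region) == 3:
                lo, hi, k = region
            else:
                (lo, hi), k = region, 1
            if not (0 <= lo < hi <= 50):
                raise ValueError(f"specific region ({lo}, {hi}) outside [0, 50]")
            n_sites += int(k)
            for b in range(n_bins):
                if edges[b] < hi and edges[b + 1] > lo:
                    specific_bins.append(b)
    specific_bins = sorted(set(specific_bins))
    return PositionHistogram(
        bin_edges_pct=edges,
        counts=counts.astype(int),
        n_total=int(counts.sum()),
        specific_bins=tuple(specific_bins),
        n_specific_sites=n_sites,
        positions_pct=pos,
    )


def specificity_from_counts(A_SP: float, A_NSP: float, N_sites: int) -> float:
    """Plain fractional-occupancy specificity, ``S = N * A_SP / A_NSP + 1``."""
    if A_NSP <= 0:
        return float("inf")
    return N_sites * A_SP / A_NSP + 1.0


def _point_specificity(A_SP, A_NSP, N, n_sp, f, corrected):
    if A_NSP <= 0:
        return float("inf")
    if not corrected:
        return N * A_SP / A_NSP + 1.0
    # S < 1 is outside the preferential-binding model; floor at 1
    excess = (1.0 - f) * A_SP - f * A_NSP
    return max(1.0 + (N / n_sp) * excess / A_NSP, 1.0)


def estimate_specificity(hist: PositionHistogram,
                         N_sites: int,
                         background_correction: bool = True,
                         n_boot: int = 1000,
                         seed: int = 0) -> SpecificityResult:
    """Estimate the binding specificity S from a position histogram.

    ``N_sites`` defaults in practice to the substrate length in base pairs
    (one binding site per bp).  With ``background_correction`` (default) the
    nonspecific occupancy expected inside the specific bins is subtracted
    before the ratio formula is applied; without it the plain
    ``N * A_SP / A_NSP + 1`` is returned.  The standard error is a seeded
    bootstrap (multinomial resampling of the histogram counts).

    A histogram with no counts outside the specific region yields an
    infinite S with ``infinite=True`` rather than an exception.
    """
    if N_sites <= 0:
        raise ValueError(f"N_sites must be > 0, got {N_sites}")
    if not hist.specific_bins:
        raise ValueError("histogram has no specific bins marked")
    mask = np.zeros(len(hist.counts), dtype=bool)
    mask[list(hist.specific_bins)] = True
    A_SP = int(hist.counts[mask].sum())
    A_NSP = int(hist.n_total - A_SP)
    f = hist.specific_site_fraction
    n_sp = max(hist.n_specific_sites, 1)

    if A_NSP == 0:
        return SpecificityResult(
            S=float("inf"), se_S=float("nan"), A_SP=A_SP, A_NSP=0,
            N_sites=N_sites, n_specific_sites=n_sp,
            specific_site_fraction=f,
            background_corrected=background_correction, infinite=True,
        )

    S = _point_specificity(A_SP, A_NSP, N_sites, n_sp, f, background_correction)

    se = float("nan")
    if n_boot > 0 and hist.n_total > 0:
        rng = np.random.default_rng(seed)
        p = hist.counts / hist.n_total
        res = rng.multinomial(hist.n_total, p, size=n_boot)
        a_sp = res[:, mask].sum(axis=1).astype(float)
        a_nsp = hist.n_total - a_sp
        ok = a_nsp > 0
        if ok.sum() >= 2:
            if background_correction:
                excess = (1.0 - f) * a_sp[ok] - f * a_nsp[ok]
                s_boot = np.maximum(1.0 + (N_sites / n_sp) * excess / a_nsp[ok], 1.0)
            else:
                s_boot = N_sites * a_sp[ok] / a_nsp[ok] + 1.0
            se = float(np.std(s_boot, ddof=1))
    return SpecificityResult(
        S=S, se_S=se, A_SP=A_SP, A_NSP=A_NSP, N_sites=N_sites,
        n_specific_sites=n_sp, specific_site_fraction=f,
        background_corrected=background_correction,
    )


def volume_to_mw(volume_nm3: float,
                 cal: VolumeCalibration = VolumeCalibration()) -> float:
    """Molecular weight (kDa) implied by an AFM volume, M_r = (V - b) / a."""
    mw = (volume_nm3 - cal.intercept_nm3) / cal.slope_nm3_per_kDa
    if mw <= 0:
        raise ValueError(
            f"volume {volume_nm3} nm^3 implies a nonpositive molecular weight"
        )
    return mw


def mw_to_volume(mw_kDa: float,
                 cal: VolumeCalibration = VolumeCalibration()) -> float:
    """AFM volume (nm^3) predicted for a molecular weight, V = a*M_r + b."""
    return cal.slope_nm3_per_kDa * mw_kDa + cal.intercept_nm3


class CopyNumber(NamedTuple):
    copies: int
    ratio: float


def estimate_copy_number(volume_nm3: float,
                         monomer_kDa: float,
                         cal: VolumeCalibration = VolumeCalibration()) -> CopyNumber:
    """Number of protein copies in a complex from its AFM volume.

    Converts the volume to a molecular weight via the calibration and
    divides by the monomer weight; returns the rounded copy count together
    with the unrounded ratio.
    """
    if monomer_kDa <= 0:
        raise ValueError(f"monomer_kDa must be > 0, got {monomer_kDa}")
    ratio = volume_to_mw(volume_nm3, cal) / monomer_kDa
    return CopyNumber(copies=int(round(ratio)), ratio=ratio)
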