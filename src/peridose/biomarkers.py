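"""Tissue-composition labeling, EQD2 conversion, dose binning, and the
three pericardial imaging biomarkers.

Tissue scheme (integer HU intervals, pairwise disjoint, covering
[-1000, 1000]):

======================= ==============
label                   HU range
======================= ==============
Calcification           [130, 1000]
Fibrous                 [65, 129]
Heme                    [13, 64]
Fluid                   [-5, 12]
Fat                     [-1000, -6]
======================= ==============

Biomarkers (per patient P, over pericardial-shell voxels v with volume
V_v; dHU = HU_baseline - HU_followup):

1. dHUV — percent pericardial volume at each integer HU change:
   dHUV[P, dHU] = 100 * sum_{v: dHU_v = dHU} V_v / sum_v V_v,
   averaged unweighted across patients within mean-pericardium-dose bins.
2. VMC — voxel-based percent mass change per tissue range and voxel-dose
   bin, with mass proxied by (HU + 1000) * volume:
   VMC[P, T, D] = 100 * sum_{v in D, T} dHU_v * V_v
                      / sum_v (HU_baseline_v + 1000) * V_v.
   Positive VMC = mass decrease from baseline to follow-up.
3. dV — percent pericardial volume change per tissue range:
   dV[P, T] = 100 * (V_baseline-labeled-T - V_followup-labeled-T) / sum_v V_v.
   Positive dV = volume loss in that HU range; the per-patient values sum
   to zero over tissues because labels partition the shell.

Physical dose is converted voxelwise to the equivalent dose in 2 Gy
fractions (EQD2) under the linear-quadratic model before any binning;
mean-dose bin edges default to [0, 0.2, 2, 5, 12.5, 20, inf) Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from peridose.cohort import (
    HU_MAX,
    HU_MIN,
    BinaryMask,
    DoseGrid,
    ImageVolume,
    ValidationError,
)
from peridose.geometry import _check_congruent, _round_half_away

#: Default alpha/beta ratio in Gy for EQD2 (late cardiac-effect convention).
DEFAULT_ALPHA_BETA_GY = 3.0

#: Mean-dose bin edges in Gy (EQD2), left-closed right-open, last bin open.
DEFAULT_DOSE_BIN_EDGES = (0.0, 0.2, 2.0, 5.0, 12.5, 20.0, np.inf)


@dataclass(frozen=True)
class TissueScheme:
    """Ordered partition of integer HU into tissue-composition labels."""

    labels: tuple[str, ...] = ("Calcification", "Fibrous", "Heme", "Fluid", "Fat")
    # (lo, hi) inclusive integer HU bounds, same order as labels
    ranges: tuple[tuple[int, int], ...] = (
        (130, HU_MAX),
        (65, 129),
        (13, 64),
        (-5, 12),
        (HU_MIN, -6),
    )

    def __post_init__(self) -> None:
        covered = np.zeros(HU_MAX - HU_MIN + 1, dtype=int)
        for lo, hi in self.ranges:
            covered[lo - HU_MIN : hi - HU_MIN + 1] += 1
        if not np.all(covered == 1):
            raise ValidationError("tissue ranges must partition [-1000, 1000]")

    def label_of(self, hu: float) -> str:
        hu = int(_round_half_away(np.asarray(float(hu))))
        if not HU_MIN <= hu <= HU_MAX:
            raise ValidationError(f"HU {hu} outside [{HU_MIN}, {HU_MAX}]")
        for label, (lo, hi) in zip(self.labels, self.ranges):
            if lo <= hu <= hi:
                return label
        raise AssertionError("unreachable: scheme partitions the range")

    def label_array(self, hu: np.ndarray) -> np.ndarray:
        """Vectorized integer label codes (index into ``labels``)."""
        hu_i = _round_half_away(np.clip(hu, HU_MIN, HU_MAX)).astype(np.int64)
        codes = np.empty(hu_i.shape, dtype=np.int64)
        for code, (lo, hi) in enumerate(self.ranges):
            codes[(hu_i >= lo) & (hu_i <= hi)] = code
        return codes


TISSUE_SCHEME = TissueScheme()


def label_tissue(hu: float, scheme: TissueScheme = TISSUE_SCHEME) -> str:
    """Tissue-composition label for a single HU value in [-1000, 1000]."""
    return scheme.label_of(hu)


@dataclass(frozen=True)
class DoseBinning:
    """Left-closed right-open EQD2 dose bins; last edge may be inf."""

    edges: tuple[float, ...] = DEFAULT_DOSE_BIN_EDGES

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValidationError("dose bin edges must be strictly increasing")
        if e[0] > 0:
            raise ValidationError("dose bins must cover dose >= 0")

    @property
    def labels(self) -> list[str]:
        out = []
        e = self.edges
        for lo, hi in zip(e[:-1], e[1:]):
            out.append(f">={lo:g}Gy" if np.isinf(hi) else f"[{lo:g},{hi:g})Gy")
        return out

    def bin_index(self, dose: np.ndarray) -> np.ndarray:
        """Bin index per dose value (dose >= 0 always falls in a bin)."""
        d = np.asarray(dose, dtype=float)
        if np.any(d < 0):
            raise ValidationError("negative dose")
        return np.minimum(
            np.searchsorted(self.edges, d, side="right") - 1, len(self.edges) - 2
        )


def eqd2(
    total_dose_gy: np.ndarray | float,
    dose_per_fraction_gy: np.ndarray | float,
    alpha_beta_gy: float = DEFAULT_ALPHA_BETA_GY,
) -> np.ndarray | float:
    """Equivalent dose in 2 Gy fractions under the linear-quadratic model.

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta), with D the total dose
    and d the dose per fraction. At d = 2 Gy the conversion is the
    identity; hypofractionated schedules (large d) are up-weighted for
    late-responding tissue (small alpha/beta).
    """
    D = np.asarray(total_dose_gy, dtype=float)
    d = np.asarray(dose_per_fraction_gy, dtype=float)
    if np.any(D < 0) or np.any(d < 0) or alpha_beta_gy <= 0:
        raise ValidationError("doses must be >= 0 and alpha/beta > 0")
    out = D * (d + alpha_beta_gy) / (2.0 + alpha_beta_gy)
    return float(out) if out.ndim == 0 else out


def eqd2_grid(dose: DoseGrid, alpha_beta_gy: float = DEFAULT_ALPHA_BETA_GY) -> np.ndarray:
    """Voxelwise EQD2 array for a dose grid (uses its per-fraction map)."""
    return eqd2(dose.physical_dose, dose.dose_per_fraction_map, alpha_beta_gy)


def mean_region_dose(dose_eqd2: np.ndarray, region: BinaryMask) -> float:
    """Volume-weighted mean EQD2 over the region's voxels (Gy)."""
    region.require_nonempty("dose region")
    if dose_eqd2.shape != region.voxels.shape:
        raise ValidationError("dose grid and region shape mismatch")
    return float(dose_eqd2[region.voxels].mean())


# ---------------------------------------------------------------------------
# Biomarker 1: volume associated with an HU change
# ---------------------------------------------------------------------------

DELTA_HU_MIN = -2000
DELTA_HU_MAX = 2000
N_DELTA_BINS = DELTA_HU_MAX - DELTA_HU_MIN + 1


@dataclass
class DeltaHUVCurve:
    """Percent pericardial volume per integer HU change (baseline - follow-up).

    ``values[i]`` is the percent volume at dHU = ``i - 2000``; the values
    are non-negative and sum to 100.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_DELTA_BINS,):
            raise ValidationError(f"curve must have {N_DELTA_BINS} bins")

    @property
    def delta_hu(self) -> np.ndarray:
        return np.arange(DELTA_HU_MIN, DELTA_HU_MAX + 1)

    def at(self, dhu: int) -> float:
        return float(self.values[int(dhu) - DELTA_HU_MIN])

    def mean_shift(self) -> float:
        """Volume-weighted mean HU change (the dose-response scalar)."""
        return float(self.delta_hu @ self.values / 100.0)

    def smoothed(self, window: int = 11) -> "DeltaHUVCurve":
        return DeltaHUVCurve(smooth_curve(self.values, window))

    def to_series(self, drop_zero: bool = True) -> pd.Series:
        s = pd.Series(self.values, index=self.delta_hu, name="pct_volume")
        s.index.name = "delta_hu"
        return s[s > 0] if drop_zero else s


def _shell_delta_hu(baseline: ImageVolume, followup: ImageVolume, shell: BinaryMask
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Integer (HU_baseline, dHU) arrays over shell voxels."""
    _check_congruent(baseline, followup, "biomarkers")
    _check_congruent(baseline, shell, "biomarkers")
    shell.require_nonempty("pericardial shell")
    hu_b = _round_half_away(np.clip(baseline.voxels[shell.voxels], HU_MIN, HU_MAX))
    hu_f = _round_half_away(np.clip(followup.voxels[shell.voxels], HU_MIN, HU_MAX))
    return hu_b.astype(np.int64), (hu_b - hu_f).astype(np.int64)


def delta_huv(baseline: ImageVolume, followup: ImageVolume, shell: BinaryMask) -> DeltaHUVCurve:
    """Biomarker 1: percent shell volume at each integer HU change.

    dHU = HU_baseline - HU_followup per voxel; the returned curve sums to
    100 (volumes are normalized by the patient's total shell volume, so
    equal-size voxels contribute equally).
    """
    _, dhu = _shell_delta_hu(baseline, followup, shell)
    counts = np.bincount(dhu - DELTA_HU_MIN, minlength=N_DELTA_BINS).astype(np.float64)
    return DeltaHUVCurve(100.0 * counts / counts.sum())


def aggregate_delta_huv(
    curves: Sequence[DeltaHUVCurve],
    mean_doses: Sequence[float],
    binning: DoseBinning = DoseBinning(),
) -> dict[str, DeltaHUVCurve]:
    """Unweighted mean curve per mean-pericardium-dose bin.

    Patients are grouped by their mean pericardial EQD2; empty bins are
    absent from the result rather than reported as zero curves.
    """
    if len(curves) != len(mean_doses):
        raise ValidationError("one mean dose per curve required")
    idx = binning.bin_index(np.asarray(mean_doses, dtype=float))
    out: dict[str, DeltaHUVCurve] = {}
    for b, label in enumerate(binning.labels):
        members = [c.values for c, i in zip(curves, idx) if i == b]
        if members:
            out[label] = DeltaHUVCurve(np.mean(members, axis=0))
    return out


# ---------------------------------------------------------------------------
# Biomarker 2: voxel-based tissue mass change
# ---------------------------------------------------------------------------


def vmc(
    baseline: ImageVolume,
    followup: ImageVolume,
    shell: BinaryMask,
    dose_eqd2: np.ndarray,
    scheme: TissueScheme = TISSUE_SCHEME,
    binning: DoseBinning = DoseBinning(),
    label_timepoint: str = "followup",
) -> pd.DataFrame:
    """Biomarker 2: percent mass change per (tissue range x voxel-dose bin).

    Mass is proxied by (HU + 1000) * voxel volume. Each cell sums
    dHU_v * V_v over shell voxels whose EQD2 falls in the bin and whose HU
    at ``label_timepoint`` lies in the tissue range, divided by the
    patient's total baseline shell mass proxy, times 100. Positive values
    mean mass decreased from baseline to follow-up.

    Returns a DataFrame indexed by tissue label with one column per dose
    bin.
    """
    if label_timepoint not in ("followup", "baseline"):
        raise ValidationError(f"label_timepoint must be followup|baseline, got {label_timepoint!r}")
    hu_b, dhu = _shell_delta_hu(baseline, followup, shell)
    if dose_eqd2.shape != shell.voxels.shape:
        raise ValidationError("dose grid and shell shape mismatch")
    vol = shell.voxel_volume_mm3
    denom = float(((hu_b + 1000.0) * vol).sum())
    if denom <= 0:
        raise ValidationError("degenerate input: zero total baseline mass proxy")
    label_hu = hu_b if label_timepoint == "baseline" else hu_b - dhu
    codes = scheme.label_array(label_hu)
    bins = binning.bin_index(dose_eqd2[shell.voxels])
    n_t, n_b = len(scheme.labels), len(binning.labels)
    num = np.zeros((n_t, n_b))
    np.add.at(num, (codes, bins), dhu * vol)
    table = pd.DataFrame(100.0 * num / denom, index=list(scheme.labels),
                         columns=binning.labels)
    table.index.name = "tissue"
    return table


# ---------------------------------------------------------------------------
# Biomarker 3: tissue volume change
# ---------------------------------------------------------------------------


def delta_v(
    baseline: ImageVolume,
    followup: ImageVolume,
    shell: BinaryMask,
    scheme: TissueScheme = TISSUE_SCHEME,
) -> pd.Series:
    """Biomarker 3: percent shell-volume change per tissue range.

    100 * (baseline-labeled volume - follow-up-labeled volume) / total
    shell volume per tissue; positive = volume loss in that range. The
    values sum to zero because labels partition the shell at both
    timepoints.
    """
    hu_b, dhu = _shell_delta_hu(baseline, followup, shell)
    hu_f = hu_b - dhu
    n_t = len(scheme.labels)
    counts_b = np.bincount(scheme.label_array(hu_b), minlength=n_t).astype(float)
    counts_f = np.bincount(scheme.label_array(hu_f), minlength=n_t).astype(float)
    total = float(hu_b.size)
    out = pd.Series(100.0 * (counts_b - counts_f) / total, index=list(scheme.labels),
                    name="pct_volume_change")
    out.index.name = "tissue"
    return out


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth_curve(values: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    ``window`` must be odd; each output element averages the input over a
    window of ``window`` centered on it, truncated to the available
    neighbors near the edges, so output length equals input length.
    """
    values = np.asarray(values, dtype=np.float64)
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be odd and >= 1, got {window}")
    if window > values.size:
        raise ValidationError("window exceeds series length")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = values.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)
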