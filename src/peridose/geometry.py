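"""Pericardial-shell and reference-ring construction, follow-up selection,
and mask-overlap metrics.

The pericardial sac is modeled as the outermost layer of the heart mask:
voxels inside the mask within ``shell_thickness_mm`` (default 4 mm) of the
mask boundary, measured as a Euclidean distance transform in physical mm
with anisotropic spacing respected. The out-of-field reference ring —
used to pick the follow-up scan whose HU distribution best matches
baseline — is the set of voxels outside the heart, within
``ring_width_mm`` (default 50 mm) of the heart surface, that received at
most ``ring_dose_max_gy`` (default 1 Gy) physical dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from peridose.cohort import (
    HU_MAX,
    HU_MIN,
    BinaryMask,
    DoseGrid,
    ImageVolume,
    ValidationError,
)

N_HU_BINS = HU_MAX - HU_MIN + 1  # 2001 integer-centered bins


@dataclass(frozen=True)
class RegionSpec:
    """Geometric parameters of the shell and reference-ring regions (mm, Gy)."""

    shell_thickness_mm: float = 4.0
    ring_width_mm: float = 50.0
    ring_dose_max_gy: float = 1.0

    def __post_init__(self) -> None:
        if min(self.shell_thickness_mm, self.ring_width_mm, self.ring_dose_max_gy) <= 0:
            raise ValidationError("RegionSpec parameters must be strictly positive")


def _check_congruent(a, b, what: str) -> None:
    sa = a.voxels.shape
    sb = b.voxels.shape
    if sa != sb or not np.allclose(a.spacing, b.spacing):
        raise ValidationError(f"incongruent grids for {what}: {sa}/{a.spacing} vs {sb}/{b.spacing}")


def pericardial_shell(heart: BinaryMask, thickness_mm: float = 4.0) -> BinaryMask:
    """Outermost ``thickness_mm`` layer of the heart mask (the pericardial sac).

    Returns voxels inside the mask whose Euclidean distance to the mask's
    outer boundary is at most ``thickness_mm``. Distances are computed on
    voxel centers against the complement, so a zero thickness yields an
    empty shell and the shell is always a subset of the heart mask.
    """
    heart.require_nonempty("heart mask")
    if thickness_mm < 0:
        raise ValidationError("thickness must be non-negative")
    depth = ndimage.distance_transform_edt(heart.voxels, sampling=heart.spacing)
    return BinaryMask(
        voxels=heart.voxels & (depth <= thickness_mm),
        spacing=heart.spacing,
        origin=heart.origin,
    )


def reference_ring(heart: BinaryMask, dose: DoseGrid, spec: RegionSpec = RegionSpec()) -> BinaryMask:
    """Low-dose ring around the heart used for follow-up matching.

    Voxels outside the heart, within ``spec.ring_width_mm`` of the heart
    surface, with physical dose at most ``spec.ring_dose_max_gy``. Always
    disjoint from the heart mask.
    """
    heart.require_nonempty("heart mask")
    _check_congruent(heart, dose, "reference_ring")
    dist_out = ndimage.distance_transform_edt(~heart.voxels, sampling=heart.spacing)
    ring = (~heart.voxels) & (dist_out <= spec.ring_width_mm)
    ring &= dose.physical_dose <= spec.ring_dose_max_gy
    return BinaryMask(voxels=ring, spacing=heart.spacing, origin=heart.origin)


def hu_histogram(volume: ImageVolume, region: BinaryMask, normalize: bool = True) -> np.ndarray:
    """Volume-weighted HU histogram over a region, 2001 one-HU bins.

    Bin ``i`` covers integer HU ``i - 1000`` (values are rounded
    half-away-from-zero and clamped into [-1000, 1000] before binning).
    Counts are weighted by voxel volume; with ``normalize=True`` the bins
    sum to one.
    """
    _check_congruent(volume, region, "hu_histogram")
    region.require_nonempty("histogram region")
    hu = volume.voxels[region.voxels]
    idx = _round_half_away(np.clip(hu, HU_MIN, HU_MAX)).astype(np.int64) - HU_MIN
    hist = np.bincount(idx, minlength=N_HU_BINS).astype(np.float64)
    hist *= volume.voxel_volume_mm3
    if normalize:
        hist /= hist.sum()
    return hist


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (.5 -> 1, -.5 -> -1)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def histogram_distance(h1: np.ndarray, h2: np.ndarray, metric: str = "l1") -> float:
    """Distance between two normalized HU histograms.

    ``l1`` (default) sums absolute bin differences; ``l2`` is Euclidean;
    ``mean_hu`` is the absolute difference of the histogram means.
    """
    if metric == "l1":
        return float(np.abs(h1 - h2).sum())
    if metric == "l2":
        return float(np.sqrt(((h1 - h2) ** 2).sum()))
    if metric == "mean_hu":
        centers = np.arange(HU_MIN, HU_MAX + 1, dtype=np.float64)
        return float(abs(centers @ h1 - centers @ h2))
    raise ValidationError(f"unknown histogram metric: {metric!r}")


def select_followup(
    baseline: ImageVolume,
    candidates: list[ImageVolume],
    ring: BinaryMask,
    metric: str = "l1",
) -> int:
    """Index of the follow-up whose ring-region HU distribution best matches baseline.

    Minimizes the histogram distance (default L1 on normalized 1-HU-bin
    histograms) inside the low-dose reference ring; ties break to the
    lowest index.
    """
    if not candidates:
        raise ValidationError("empty candidate list")
    base_h = hu_histogram(baseline, ring, normalize=True)
    dists = [
        histogram_distance(base_h, hu_histogram(c, ring, normalize=True), metric)
        for c in candidates
    ]
    return int(np.argmin(dists))


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); both-empty input is an error."""
    _check_congruent(a, b, "dice")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        raise ValidationError("Dice undefined: both masks empty")
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


def com_align(
    moving: ImageVolume, moving_heart: BinaryMask, fixed_heart: BinaryMask
) -> ImageVolume:
    """Translate ``moving`` so the heart-mask centers of mass coincide.

    The shift is rounded to whole voxels (registration initialization
    only), so the aligned centers of mass agree within half a voxel per
    axis. Voxels shifted in from outside the field of view are padded
    with -1000 HU (air).
    """
    moving_heart.require_nonempty("moving heart mask")
    fixed_heart.require_nonempty("fixed heart mask")
    com_mov = np.array(ndimage.center_of_mass(moving_heart.voxels))
    com_fix = np.array(ndimage.center_of_mass(fixed_heart.voxels))
    shift = np.round(com_fix - com_mov).astype(int)
    out = np.full_like(moving.voxels, float(HU_MIN))
    src = [slice(max(0, -s), min(n, n - s)) for s, n in zip(shift, moving.voxels.shape)]
    dst = [slice(max(0, s), min(n, n + s)) for s, n in zip(shift, moving.voxels.shape)]
    out[tuple(dst)] = moving.voxels[tuple(src)]
    return ImageVolume(
        voxels=out,
        spacing=moving.spacing,
        origin=moving.origin,
        contrast_enhanced=moving.contrast_enhanced,
        scanner_tag=moving.scanner_tag,
    )
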