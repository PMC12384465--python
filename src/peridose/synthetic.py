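"""Synthetic CT-like phantom cohorts with the statistical structure the
analysis assumes.

Each synthetic patient is a small axis-aligned grid holding an ellipsoidal
"heart" in lung-density background. The pericardial shell (outermost
layer of the heart mask) is populated with tissue classes drawn from a
composition prior; a point-source dose field with exponential falloff and
a per-patient fractionation schedule produces the spread of mean
pericardial EQD2 seen across real lung-RT cohorts (conventional 2 Gy/fx
through SBRT). At follow-up each shell voxel shifts one class up the
Fluid -> Heme -> Fibrous -> Calcification ladder with probability
``min(1, beta * EQD2 / 100)``, emulating dose-dependent densification;
fat voxels carry noise but never shift (weight-change confounding makes
fat uninformative for the planted effect). Contrast enhancement adds an
additive (optionally multiplicative) HU batch effect; each follow-up
candidate carries its own reconstruction-kernel noise, exactly one with
the smallest sigma (the matched-kernel candidate). Outcome times are
exponential with a log-hazard offset for the planted high-dose biomarker
group, plus an ICD-10 CVD event process whose rate is higher for
high-dose patients.

Every draw flows from a single master seed through spawned per-patient
substreams, so the same seed yields a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from peridose.biomarkers import TISSUE_SCHEME, TissueScheme, eqd2
from peridose.cohort import (
    BinaryMask,
    ClinicalRecord,
    DoseGrid,
    ImageVolume,
    PatientStudy,
    ValidationError,
)
from peridose.geometry import pericardial_shell

#: fractionation schedules (n_fractions, dose_per_fraction_gy): conventional
#: 33x2 Gy, SBRT 3x22.3 / 5x10 / ultracentral 8x7, and SCLC 30x1.5 Gy.
FRACTION_SCHEDULES = ((33, 2.0), (3, 22.3), (5, 10.0), (8, 7.0), (30, 1.5))

#: one-step "densification ladder"; Fat and Calcification are absorbing.
SHIFT_LADDER = {"Fluid": "Heme", "Heme": "Fibrous", "Fibrous": "Calcification"}


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the study conditions for all tests."""

    n_patients: int = 20
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    heart_semiaxes_mm: tuple[float, float, float] = (26.0, 24.0, 22.0)
    shell_thickness_mm: float = 4.0
    falloff_mm: float = 12.0
    tumor_distance_range_mm: tuple[float, float] = (5.0, 75.0)
    composition: dict[str, float] = field(
        default_factory=lambda: {
            "Fat": 0.35, "Fluid": 0.20, "Heme": 0.25, "Fibrous": 0.18,
            "Calcification": 0.02,
        }
    )
    beta: float = 0.5            # shift probability per voxel = min(1, beta*EQD2/100)
    texture_sigma_hu: float = 3.0
    kernel_sigmas_hu: tuple[float, ...] = (5.0, 20.0, 40.0)
    contrast_offset_hu: float = 25.0
    contrast_scale: float = 1.0
    p_contrast: float = 0.7
    alpha_beta_gy: float = 3.0
    # outcomes
    baseline_hazard_per_day: float = 1.0 / 900.0
    log_hr_biomarker: float = 0.7  # ~ HR 2 for the planted high-dose group
    cvd_rate_per_day: float = 1.0 / 2000.0
    cvd_rate_multiplier: float = 3.0  # extra CVD rate factor for high-dose group
    followup_window_days: int = 1500
    p_nsclc: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"composition fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.composition.values()):
            raise ValidationError("composition fractions must be non-negative")
        if self.beta < 0 or self.texture_sigma_hu < 0:
            raise ValidationError("beta and noise levels must be >= 0")


def _hu_interval(scheme: TissueScheme, label: str) -> tuple[int, int]:
    return scheme.ranges[scheme.labels.index(label)]


def _sample_class_hu(rng: np.random.Generator, labels: np.ndarray,
                     scheme: TissueScheme, texture_sigma: float) -> np.ndarray:
    """HU uniform within each voxel's class interval plus Gaussian texture."""
    hu = np.empty(labels.shape, dtype=float)
    for code, lab in enumerate(scheme.labels):
        sel = labels == code
        if sel.any():
            lo, hi = scheme.ranges[code]
            hu[sel] = rng.uniform(lo, hi, size=int(sel.sum()))
    return hu + rng.normal(0.0, texture_sigma, size=labels.shape)


def _ellipsoid_mask(shape, spacing, semiaxes) -> np.ndarray:
    center = [(n - 1) / 2.0 * s for n, s in zip(shape, spacing)]
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[PatientStudy], list[ClinicalRecord], pd.DataFrame]:
    """Generate studies, clinical records, and the ground-truth table.

    The truth table records, per patient, the true mean pericardial EQD2,
    planted per-class upward-shift counts, the contrast batch of the
    (baseline, matched follow-up) pair, the planted outcome group, and the
    index of the matched-kernel follow-up candidate.
    """
    scheme = TISSUE_SCHEME
    master = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in master.spawn(config.n_patients + 1)]
    cohort_rng = streams[-1]

    shape, spacing = tuple(config.shape), tuple(config.spacing_mm)
    heart = _ellipsoid_mask(shape, spacing, config.heart_semiaxes_mm)
    heart_mask = BinaryMask(heart, spacing)
    shell_mask = pericardial_shell(heart_mask, config.shell_thickness_mm)
    shell = shell_mask.voxels
    n_shell = int(shell.sum())
    center = np.array([(n - 1) / 2.0 * s for n, s in zip(shape, spacing)])
    grids = np.stack(
        np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    )

    class_codes = {lab: i for i, lab in enumerate(scheme.labels)}
    prior_labels = list(config.composition)
    prior_p = np.array([config.composition[k] for k in prior_labels])

    studies: list[PatientStudy] = []
    records: list[ClinicalRecord] = []
    truth_rows: list[dict] = []

    for p in range(config.n_patients):
        rng = streams[p]
        pid = f"SYN{p:04d}"

        # --- dose field: point source outside the heart, exponential falloff
        n_fx, d_fx = FRACTION_SCHEDULES[rng.integers(len(FRACTION_SCHEDULES))]
        peak = n_fx * d_fx
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        surf_dist = rng.uniform(*config.tumor_distance_range_mm)
        # place the source surf_dist beyond the heart surface along `direction`
        semi = np.array(config.heart_semiaxes_mm)
        r_surface = 1.0 / np.sqrt(np.sum((direction / semi) ** 2))
        source = center + direction * (r_surface + surf_dist)
        dist = np.sqrt(np.sum((grids - source[:, None, None, None]) ** 2, axis=0))
        phys = peak * np.exp(-dist / config.falloff_mm)
        dose = DoseGrid(phys, n_fx, spacing)
        shell_eqd2 = eqd2(phys[shell], phys[shell] / n_fx, config.alpha_beta_gy)
        mean_shell_eqd2 = float(shell_eqd2.mean())

        # --- baseline composition and HU
        base_codes = np.full(shape, -1, dtype=np.int64)
        drawn = rng.choice([class_codes[k] for k in prior_labels], size=n_shell, p=prior_p)
        base_codes[shell] = drawn
        baseline_hu = np.full(shape, -800.0)  # lung background
        baseline_hu[heart & ~shell] = 45.0    # blood-pool interior
        baseline_hu[shell] = _sample_class_hu(rng, drawn, scheme, config.texture_sigma_hu)
        baseline_hu[heart & ~shell] += rng.normal(0, config.texture_sigma_hu,
                                                  size=int((heart & ~shell).sum()))
        bg = ~heart
        baseline_hu[bg] += rng.normal(0, config.texture_sigma_hu, size=int(bg.sum()))

        # --- planted follow-up shifts (one class up the ladder)
        p_shift = np.minimum(1.0, config.beta * shell_eqd2 / 100.0)
        shiftable = np.array(
            [scheme.labels[c] in SHIFT_LADDER for c in drawn]
        )
        do_shift = shiftable & (rng.random(n_shell) < p_shift)
        fu_codes = drawn.copy()
        for lab, nxt in SHIFT_LADDER.items():
            sel = do_shift & (drawn == class_codes[lab])
            fu_codes[sel] = class_codes[nxt]
        followup_hu = baseline_hu.copy()
        fu_shell = followup_hu[shell]
        fu_shell[do_shift] = _sample_class_hu(
            rng, fu_codes[do_shift], scheme, config.texture_sigma_hu
        )
        followup_hu[shell] = fu_shell

        shift_counts = {
            lab: int(np.sum(do_shift & (drawn == class_codes[lab])))
            for lab in SHIFT_LADDER
        }

        # --- contrast batch effects: iodinated contrast raises HU in perfused
        # tissue (blood pool and pericardium), not in out-of-field lung, so the
        # offset is applied inside the heart mask only and the low-dose ring
        # stays usable for kernel matching
        base_ce = bool(rng.random() < config.p_contrast)
        fu_ce = bool(rng.random() < config.p_contrast)
        base_img = baseline_hu.copy()
        if base_ce:
            base_img[heart] = base_img[heart] * config.contrast_scale + config.contrast_offset_hu
        fu_img = followup_hu.copy()
        if fu_ce:
            fu_img[heart] = fu_img[heart] * config.contrast_scale + config.contrast_offset_hu

        # --- follow-up candidates with per-kernel noise, shuffled order
        order = rng.permutation(len(config.kernel_sigmas_hu))
        candidates = []
        matched_idx = int(np.where(order == int(np.argmin(config.kernel_sigmas_hu)))[0][0])
        for slot, k in enumerate(order):
            sigma = config.kernel_sigmas_hu[k]
            noisy = fu_img + rng.normal(0.0, sigma, size=shape)
            candidates.append(
                ImageVolume(np.clip(noisy, -1000, 1000), spacing,
                            contrast_enhanced=fu_ce, scanner_tag=f"kernel_s{sigma:g}")
            )

        baseline_vol = ImageVolume(np.clip(base_img, -1000, 1000), spacing,
                                   contrast_enhanced=base_ce, scanner_tag="plan")
        diagnosis = "NSCLC" if rng.random() < config.p_nsclc else "SCLC"
        study = PatientStudy(
            patient_id=pid, baseline=baseline_vol, followup_candidates=candidates,
            heart_mask=heart_mask, dose=dose,
            sex="F" if rng.random() < 0.5 else "M",
            age=float(np.round(rng.normal(68, 8), 1)), diagnosis=diagnosis,
        )
        studies.append(study)
        truth_rows.append(
            dict(patient_id=pid, mean_shell_eqd2=mean_shell_eqd2,
                 n_fractions=n_fx, dose_per_fraction=d_fx,
                 matched_candidate=matched_idx,
                 baseline_ce=base_ce, followup_ce=fu_ce,
                 n_shifted_total=int(do_shift.sum()),
                 **{f"n_shifted_{k}": v for k, v in shift_counts.items()})
        )

    truth = pd.DataFrame(truth_rows)
    # planted outcome group: above-median mean pericardial EQD2
    median_dose = float(truth["mean_shell_eqd2"].median())
    truth["outcome_group"] = (truth["mean_shell_eqd2"] > median_dose).astype(int)

    for p, study in enumerate(studies):
        rng = streams[p]
        group = int(truth.loc[p, "outcome_group"])
        rate = config.baseline_hazard_per_day * np.exp(config.log_hr_biomarker * group)
        t_death = rng.exponential(1.0 / rate)
        death = t_death <= config.followup_window_days
        last_day = int(np.ceil(min(t_death, config.followup_window_days)))
        last_day = max(last_day, 1)
        cvd_rate = config.cvd_rate_per_day * (
            1.0 + (config.cvd_rate_multiplier - 1.0) * group
        )
        events: list[tuple[int, str]] = []
        t = 0.0
        codes = ["I20", "I21.0", "I25", "I50.9"]
        while True:
            t += rng.exponential(1.0 / cvd_rate)
            if t >= last_day:
                break
            events.append((int(np.ceil(t)), codes[rng.integers(len(codes))]))
        if rng.random() < 0.2:  # occasional non-cardiac diagnosis in the stream
            events.append((int(rng.integers(1, max(2, last_day))), "J18.9"))
        events.sort()
        records.append(
            ClinicalRecord(patient_id=study.patient_id, rt_end_day=0,
                           last_day=last_day, death=bool(death), events=events)
        )
    return studies, records, truth


def generate_toy_patient(
    hu_pairs: Sequence[tuple[float, float]],
    doses: Optional[Sequence[float]] = None,
    n_fractions: int = 1,
) -> PatientStudy:
    """Minimal study wrapping explicit per-voxel (HU_base, HU_followup, dose).

    The voxels form a flat line with unit voxel volume; the heart mask
    covers all of them and doubles as the pericardial shell, which makes
    this the canonical fixture for closed-form biomarker checks. The dose
    grid is built with a 2 Gy per-fraction map so its EQD2 equals the
    given physical dose.
    """
    hu_pairs = list(hu_pairs)
    n = len(hu_pairs)
    if n == 0:
        raise ValidationError("need at least one voxel")
    doses = [0.0] * n if doses is None else list(doses)
    if len(doses) != n:
        raise ValidationError("one dose per voxel required")
    shape = (n, 1, 1)
    base = np.array([b for b, _ in hu_pairs], dtype=float).reshape(shape)
    fu = np.array([f for _, f in hu_pairs], dtype=float).reshape(shape)
    dose_arr = np.array(doses, dtype=float).reshape(shape)
    return PatientStudy(
        patient_id="TOY",
        baseline=ImageVolume(base),
        followup_candidates=[ImageVolume(fu)],
        heart_mask=BinaryMask(np.ones(shape, dtype=bool)),
        dose=DoseGrid(dose_arr, n_fractions,
                      dose_per_fraction_map=np.full(shape, 2.0)),
    )


def random_toy_patient(
    n_voxels: int, seed: int, max_dose_gy: float = 30.0
) -> PatientStudy:
    """Seeded random toy patient for oracle-equivalence tests."""
    rng = np.random.default_rng(seed)
    base = rng.integers(-1000, 1001, size=n_voxels)
    fu = np.clip(base + rng.integers(-150, 151, size=n_voxels), -1000, 1000)
    doses = rng.uniform(0.0, max_dose_gy, size=n_voxels)
    return generate_toy_patient(list(zip(base.tolist(), fu.tolist())), doses.tolist())
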