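"""Data model, volume/table I/O, and clinical cardiovascular-event rules.

The core containers are :class:`ImageVolume` (a 3-D Hounsfield-unit grid
with physical spacing), :class:`BinaryMask`, :class:`DoseGrid`,
:class:`PatientStudy` (one patient's paired scans, mask and dose) and
:class:`ClinicalRecord` (RT dates, vital status, ICD-10 event stream).

Cardiovascular disease (CVD) events are ICD-10 categories I20-I25 and I50
(ischaemic heart disease and heart failure). Events separated by at most
28 days are collapsed onto the first diagnosis entry; survival endpoints
count days from the end of radiotherapy to the first deduplicated CVD
event strictly after RT end.

Volumes are read and written as NIfTI (via nibabel) or NRRD (via
SimpleITK). HU values are clipped to [-1000, 1000] at ingest, matching
the 1-HU histogram binning range used throughout the analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

HU_MIN = -1000
HU_MAX = 1000

#: ICD-10 three-character categories counted as cardiovascular disease.
CVD_CATEGORIES = frozenset(
    {"I20", "I21", "I22", "I23", "I24", "I25", "I50"}
)

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(?:\.?\w{1,4})?$")


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """File exists but does not contain usable 3-D scalar data."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageVolume:
    """A 3-D grid of Hounsfield units with physical geometry.

    Parameters
    ----------
    voxels : ndarray
        3-D array of HU values.
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    origin : tuple of float
        Physical position of voxel (0, 0, 0) in mm.
    contrast_enhanced : bool
        Whether the scan used iodinated contrast (drives batch assignment).
    scanner_tag : str
        Free-text scanner / reconstruction-kernel identifier.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    contrast_enhanced: bool = False
    scanner_tag: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise FormatError(f"volume must be 3-D, got {self.voxels.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("volume contains non-finite HU values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def clipped(self) -> "ImageVolume":
        """Return a copy with HU clamped to [-1000, 1000] (idempotent)."""
        return replace(self, voxels=np.clip(self.voxels, HU_MIN, HU_MAX))

    def same_grid(self, other: "ImageVolume | BinaryMask | DoseGrid") -> bool:
        o_shape = other.voxels.shape if hasattr(other, "voxels") else other.physical_dose.shape
        o_spacing = other.spacing
        return self.voxels.shape == o_shape and np.allclose(self.spacing, o_spacing)


@dataclass
class BinaryMask:
    """Boolean voxel set on the same grid as an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise FormatError(f"mask must be 3-D, got {self.voxels.ndim}-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("mask spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def require_nonempty(self, what: str = "mask") -> None:
        if not self.voxels.any():
            raise ValidationError(f"{what} is empty")


@dataclass
class DoseGrid:
    """Physical dose distribution with fractionation metadata.

    ``dose_per_fraction_map`` defaults to ``physical_dose / n_fractions``,
    i.e. every voxel's dose is assumed delivered over the full schedule.
    """

    physical_dose: np.ndarray
    n_fractions: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dose_per_fraction_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.physical_dose = np.asarray(self.physical_dose, dtype=np.float64)
        if self.physical_dose.ndim != 3:
            raise FormatError("dose grid must be 3-D")
        if np.any(self.physical_dose < 0):
            raise ValidationError("dose must be non-negative everywhere")
        if int(self.n_fractions) < 1:
            raise ValidationError(f"n_fractions must be positive, got {self.n_fractions}")
        self.n_fractions = int(self.n_fractions)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.dose_per_fraction_map is None:
            self.dose_per_fraction_map = self.physical_dose / self.n_fractions
        else:
            self.dose_per_fraction_map = np.asarray(self.dose_per_fraction_map, dtype=np.float64)
            if self.dose_per_fraction_map.shape != self.physical_dose.shape:
                raise ValidationError("dose_per_fraction_map shape mismatch")

    @property
    def voxels(self) -> np.ndarray:  # grid-congruence helper
        return self.physical_dose


@dataclass
class PatientStudy:
    """One patient's baseline scan, follow-up candidates, mask, dose, metadata."""

    patient_id: str
    baseline: ImageVolume
    followup_candidates: list[ImageVolume]
    heart_mask: BinaryMask
    dose: DoseGrid
    sex: str = "F"
    age: float = 65.0
    diagnosis: str = "NSCLC"

    def __post_init__(self) -> None:
        if not self.followup_candidates:
            raise ValidationError(f"{self.patient_id}: needs at least one follow-up candidate")
        for i, fu in enumerate(self.followup_candidates):
            if not self.baseline.same_grid(fu):
                raise ValidationError(f"{self.patient_id}: follow-up {i} not on baseline grid")
        if not self.baseline.same_grid(self.heart_mask):
            raise ValidationError(f"{self.patient_id}: heart mask not on baseline grid")
        if self.baseline.voxels.shape != self.dose.physical_dose.shape:
            raise ValidationError(f"{self.patient_id}: dose grid not on baseline grid")

    def validate(self) -> None:
        """Full input validation used by the pipeline; raises on any defect."""
        self.heart_mask.require_nonempty(f"{self.patient_id}: heart mask")


@dataclass
class ClinicalRecord:
    """RT end, censoring, vital status and the dated ICD-10 event stream.

    Dates are integer day offsets from RT end (day 0 = last RT fraction);
    calendar parsing happens only at the CSV boundary.
    """

    patient_id: str
    rt_end_day: int = 0
    last_day: int = 0  # last follow-up or death, days after RT end
    death: bool = False
    events: list[tuple[int, str]] = field(default_factory=list)  # (day offset, ICD-10)

    def __post_init__(self) -> None:
        if self.last_day < self.rt_end_day:
            raise ValidationError(
                f"{self.patient_id}: censor/death day precedes RT end"
            )
        for _, code in self.events:
            validate_icd10(code)


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------


def read_volume(path: str | Path, clip: bool = True, *, contrast_enhanced: bool = False,
                scanner_tag: str = "") -> ImageVolume:
    """Read a 3-D scalar NIfTI (.nii/.nii.gz) or NRRD volume.

    Spacing and origin come from the header. Oblique affines (NIfTI rotation
    matrices that are not axis-aligned) are rejected: this pipeline does all
    voxel math on axis-aligned grids. With ``clip=True`` HU values are
    clamped to [-1000, 1000].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        data, spacing, origin = _read_nifti(path)
    elif suffixes.endswith(".nrrd"):
        data, spacing, origin = _read_nrrd(path)
    else:
        raise FormatError(f"unsupported volume format: {path.name} (need .nii/.nii.gz/.nrrd)")
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected 3-D data, got shape {data.shape}")
    if clip:
        data = np.clip(data, HU_MIN, HU_MAX)
    return ImageVolume(voxels=data, spacing=spacing, origin=origin,
                       contrast_enhanced=contrast_enhanced, scanner_tag=scanner_tag)


def write_volume(path: str | Path, volume: ImageVolume | BinaryMask | DoseGrid) -> None:
    """Write a volume, mask or dose grid as NIfTI or NRRD (by extension)."""
    path = Path(path)
    if isinstance(volume, DoseGrid):
        data, spacing, origin = volume.physical_dose, volume.spacing, volume.origin
    elif isinstance(volume, BinaryMask):
        data, spacing, origin = volume.voxels.astype(np.uint8), volume.spacing, volume.origin
    else:
        data, spacing, origin = volume.voxels, volume.spacing, volume.origin
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(spacing) + [1.0])
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
    elif suffixes.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.asarray(data).transpose(2, 1, 0))
        img.SetSpacing(tuple(spacing))
        img.SetOrigin(tuple(origin))
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        raise FormatError(f"unsupported volume format: {path.name}")


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    # axis-aligned check: exactly one nonzero entry per column
    if np.any(np.sum(np.abs(rot) > 1e-6, axis=0) != 1):
        raise FormatError(f"{path.name}: oblique affine not supported")
    data = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in affine[:3, 3])
    return data, spacing, origin


def _read_nrrd(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    import SimpleITK as sitk

    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - corrupt file path
        raise IOError(f"cannot read {path}: {exc}") from exc
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    return data, tuple(img.GetSpacing()), tuple(img.GetOrigin())


# ---------------------------------------------------------------------------
# clinical-event rules
# ---------------------------------------------------------------------------


def validate_icd10(code: str) -> str:
    """Return the upper-cased code if syntactically valid, else raise."""
    code = str(code).strip().upper()
    if not _ICD10_RE.match(code):
        raise ValidationError(f"malformed ICD-10 code: {code!r}")
    return code


def is_cvd_code(icd10: str) -> bool:
    """True iff the 3-character ICD-10 category is I20-I25 or I50.

    Subcodes match by category prefix: ``I50.9`` and ``I509`` are both
    heart-failure (I50) events.
    """
    code = validate_icd10(icd10)
    return code[:3] in CVD_CATEGORIES


def dedup_events(events: Sequence[tuple[int, str]], window_days: int = 28) -> list[tuple[int, str]]:
    """Collapse event clusters: drop events within ``window_days`` of the last KEPT one.

    A greedy left-to-right scan over date-sorted ``(day, code)`` pairs; an
    event is dropped when its day is at most ``window_days`` after the most
    recently kept event, so only the first diagnosis entry of each cluster
    survives. Input must be sorted ascending by day.
    """
    events = list(events)
    days = [d for d, _ in events]
    if days != sorted(days):
        raise ValidationError("events must be sorted ascending by date")
    kept: list[tuple[int, str]] = []
    for ev in events:
        if not kept or ev[0] - kept[-1][0] > window_days:
            kept.append(ev)
    return kept


def first_post_rt_cvd(record: ClinicalRecord, window_days: int = 28) -> tuple[float, bool]:
    """Time (days from RT end) to first deduplicated post-RT CVD event.

    Returns ``(time_days, event_observed)``; censored at the last follow-up
    or death day when no qualifying event exists. Only events strictly after
    RT end count; deduplication runs on the full CVD stream first so a
    cluster starting before RT end does not spawn a spurious post-RT event.
    """
    cvd = sorted((d, c) for d, c in record.events if is_cvd_code(c))
    kept = dedup_events(cvd, window_days=window_days)
    post = [d for d, _ in kept if d > record.rt_end_day]
    if post:
        return float(post[0] - record.rt_end_day), True
    return float(record.last_day - record.rt_end_day), False


# ---------------------------------------------------------------------------
# clinical CSV boundary
# ---------------------------------------------------------------------------


def _parse_day(value, rt_end: Optional[date] = None) -> int:
    """ISO-8601 date -> day offset from rt_end; integers pass through."""
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, str) and re.match(r"^-?\d+$", value.strip()):
        return int(value)
    d = datetime.strptime(str(value).strip(), "%Y-%m-%d").date()
    if rt_end is None:
        raise ValidationError("calendar dates need an rt_end_date reference")
    return (d - rt_end).days


def write_cohort_dir(
    studies: Sequence[PatientStudy],
    records: Sequence[ClinicalRecord],
    out_dir: str | Path,
    fmt: str = "nrrd",
    truth: Optional[pd.DataFrame] = None,
) -> Path:
    """Write a cohort to the on-disk layout the pipeline consumes.

    Layout: ``patients.csv`` + ``events.csv`` (clinical tables),
    ``images.csv`` (per-image role/contrast/scanner manifest) and a
    ``volumes/`` directory of NRRD or NIfTI files (baseline, follow-up
    candidates, heart mask, dose per patient). ``truth.csv`` is written
    when a generator truth table is supplied.
    """
    out_dir = Path(out_dir)
    vol_dir = out_dir / "volumes"
    vol_dir.mkdir(parents=True, exist_ok=True)
    ext = {"nrrd": ".nrrd", "nifti": ".nii.gz"}.get(fmt)
    if ext is None:
        raise ValidationError(f"unknown cohort format {fmt!r}")
    pat_rows, img_rows, ev_rows = [], [], []
    by_id = {r.patient_id: r for r in records}
    for study in studies:
        rec = by_id[study.patient_id]
        pid = study.patient_id
        pat_rows.append(
            dict(patient_id=pid, sex=study.sex, age=study.age, diagnosis=study.diagnosis,
                 n_fractions=study.dose.n_fractions, rt_end_date=rec.rt_end_day,
                 last_date=rec.last_day, death=int(rec.death))
        )
        for day, code in rec.events:
            ev_rows.append(dict(patient_id=pid, date=day, icd10=code))
        items = [("baseline", study.baseline)] + [
            (f"followup{i}", fu) for i, fu in enumerate(study.followup_candidates)
        ]
        for role, vol in items:
            fname = f"{pid}_{role}{ext}"
            write_volume(vol_dir / fname, vol)
            img_rows.append(dict(patient_id=pid, role=role, filename=fname,
                                 contrast_enhanced=int(vol.contrast_enhanced),
                                 scanner_tag=vol.scanner_tag))
        write_volume(vol_dir / f"{pid}_mask{ext}", study.heart_mask)
        write_volume(vol_dir / f"{pid}_dose{ext}", study.dose)
    pd.DataFrame(pat_rows).to_csv(out_dir / "patients.csv", index=False)
    pd.DataFrame(ev_rows, columns=["patient_id", "date", "icd10"]).to_csv(
        out_dir / "events.csv", index=False)
    pd.DataFrame(img_rows).to_csv(out_dir / "images.csv", index=False)
    if truth is not None:
        truth.to_csv(out_dir / "truth.csv", index=False)
    return out_dir


def read_cohort_dir(cohort_dir: str | Path) -> tuple[list[PatientStudy], list[ClinicalRecord]]:
    """Load a cohort directory written by :func:`write_cohort_dir`."""
    cohort_dir = Path(cohort_dir)
    patients = pd.read_csv(cohort_dir / "patients.csv", dtype={"patient_id": str})
    images = pd.read_csv(cohort_dir / "images.csv", dtype={"patient_id": str})
    records = read_clinical_csv(cohort_dir / "patients.csv", cohort_dir / "events.csv")
    studies = []
    for _, row in patients.iterrows():
        pid = str(row["patient_id"])
        sub = images[images["patient_id"] == pid]

        def load(role: str) -> ImageVolume:
            r = sub[sub["role"] == role].iloc[0]
            return read_volume(cohort_dir / "volumes" / r["filename"], clip=True,
                               contrast_enhanced=bool(int(r["contrast_enhanced"])),
                               scanner_tag=str(r["scanner_tag"]))

        baseline = load("baseline")
        fu_roles = sorted(
            (r for r in sub["role"] if r.startswith("followup")),
            key=lambda r: int(r.removeprefix("followup")),
        )
        followups = [load(r) for r in fu_roles]
        ext = "".join(Path(sub.iloc[0]["filename"]).suffixes)
        mask_vol = read_volume(cohort_dir / "volumes" / f"{pid}_mask{ext}", clip=False)
        dose_vol = read_volume(cohort_dir / "volumes" / f"{pid}_dose{ext}", clip=False)
        studies.append(
            PatientStudy(
                patient_id=pid,
                baseline=baseline,
                followup_candidates=followups,
                heart_mask=BinaryMask(mask_vol.voxels > 0.5, mask_vol.spacing, mask_vol.origin),
                dose=DoseGrid(dose_vol.voxels, int(row["n_fractions"]),
                              dose_vol.spacing, dose_vol.origin),
                sex=str(row["sex"]), age=float(row["age"]), diagnosis=str(row["diagnosis"]),
            )
        )
    return studies, records


def read_clinical_csv(patients_csv: str | Path, events_csv: Optional[str | Path] = None
                      ) -> list[ClinicalRecord]:
    """Load clinical records from the two-table CSV layout.

    ``patients_csv`` columns: patient_id, sex, age, diagnosis, n_fractions,
    rt_end_date, last_date, death (0/1). ``events_csv`` columns:
    patient_id, date, icd10. Dates are ISO-8601 calendar dates or plain
    integer day offsets from RT end.
    """
    patients = pd.read_csv(patients_csv, dtype={"patient_id": str})
    events = pd.read_csv(events_csv, dtype={"patient_id": str}) if events_csv else None
    records = []
    for _, row in patients.iterrows():
        rt_end_cal: Optional[date] = None
        raw = str(row["rt_end_date"]).strip()
        if not re.match(r"^-?\d+$", raw):
            rt_end_cal = datetime.strptime(raw, "%Y-%m-%d").date()
        rt_end_day = 0 if rt_end_cal else int(raw)
        last_day = _parse_day(row["last_date"], rt_end_cal)
        evs: list[tuple[int, str]] = []
        if events is not None:
            sub = events[events["patient_id"] == row["patient_id"]]
            evs = sorted(
                (_parse_day(r["date"], rt_end_cal), validate_icd10(r["icd10"]))
                for _, r in sub.iterrows()
            )
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                rt_end_day=rt_end_day,
                last_day=last_day,
                death=bool(int(row["death"])),
                events=evs,
            )
        )
    return records
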