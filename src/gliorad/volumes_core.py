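"""Label-volume data model, NIfTI/CSV I/O, and tumor subregion conversions.

A glioma label map follows the BraTS convention on a 3D voxel grid:

* 0 — background,
* 1 — non-enhancing tumor core (NEC),
* 2 — peritumoral edema (PTE),
* 4 — enhancing core (ENC).

The three *non-overlapping* subregions combine into the *overlapping*
hierarchy used by segmentation metrics and the whole-tumor radiomics
model: whole tumor WT = PTE ∪ NEC ∪ ENC, tumor core TC = NEC ∪ ENC,
and enhancing/active tumor EC = ENC, so that EC ⊆ TC ⊆ WT.

Only voxel spacing is honoured from NIfTI affines: all synthetic and
BraTS-style data is axis-aligned and isotropically resampled, so
orientation handling would add nothing but risk.  Coordinates are
0-based voxel indices, converted to millimetres by multiplying with the
spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("gliorad")

# BraTS label codes
LBL_BG = 0
LBL_NEC = 1
LBL_PTE = 2
LBL_ENC = 4
TUMOR_LABELS = frozenset({LBL_BG, LBL_NEC, LBL_PTE, LBL_ENC})


class GlioradError(Exception):
    """Base class for all package errors."""


class FormatError(GlioradError):
    """File exists but is not a usable volume/table."""


class GeometryError(GlioradError):
    """Grids (shape/spacing) of two volumes do not match."""


class LabelError(GlioradError):
    """Unexpected label value in a label map."""


class DataError(GlioradError):
    """Tabular/clinical data inconsistent or incomplete."""


class SchemaError(GlioradError):
    """Feature-table columns do not match the expected schema."""


class SpecError(GlioradError):
    """A configuration/spec value is out of its valid range."""


class DomainError(GlioradError):
    """A numeric argument is outside the domain of the operation."""


# ---------------------------------------------------------------------------
# volumes


@dataclass
class LabelVolume:
    """3D integer label grid with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"label volume must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded, atol=1e-6):
                raise FormatError("label volume holds non-integer values")
            self.data = rounded.astype(np.int16)
        if self.data.min() < 0:
            raise LabelError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise SpecError(f"spacing must be three positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def labels(self) -> set[int]:
        return set(np.unique(self.data).tolist())

    def same_grid(self, other: "LabelVolume | RegionMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class RegionMask:
    """3D boolean mask living on the same grid as its parent volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise FormatError(f"region mask must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise SpecError(f"spacing must be three positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "LabelVolume | RegionMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def _require_same_grid(a, b) -> None:
    if tuple(a.shape) != tuple(b.shape) or not np.allclose(a.spacing, b.spacing):
        raise GeometryError(
            f"grid mismatch: {a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )


# ---------------------------------------------------------------------------
# clinical records


class ResectionStatus(str, Enum):
    GTR = "GTR"
    OTHER = "other"
    UNKNOWN = "unknown"


class OSClass(str, Enum):
    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"
    UNKNOWN = "unknown"


#: fixed class order used everywhere (probability columns, tie-breaks)
CLASS_ORDER: tuple[OSClass, OSClass, OSClass] = (OSClass.SHORT, OSClass.MEDIUM, OSClass.LONG)

DAYS_PER_MONTH = 365.25 / 12.0
SHORT_MAX_DAYS = 10 * DAYS_PER_MONTH   # exclusive upper bound of "short"
LONG_MIN_DAYS = 15 * DAYS_PER_MONTH    # exclusive lower bound of "long"


def class_from_days(days: float) -> OSClass:
    """Overall-survival class from survival days.

    Short-term < 10 months, medium-term 10-15 months, long-term > 15
    months, with one month = 365.25/12 days.
    """
    if days < 0:
        raise DomainError(f"survival days must be >= 0, got {days}")
    if days < SHORT_MAX_DAYS:
        return OSClass.SHORT
    if days > LONG_MIN_DAYS:
        return OSClass.LONG
    return OSClass.MEDIUM


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    survival_days: float | None = None
    resection_status: ResectionStatus = ResectionStatus.UNKNOWN
    os_class: OSClass = OSClass.UNKNOWN

    def __post_init__(self) -> None:
        if self.survival_days is not None:
            if self.survival_days < 0:
                raise DataError(f"{self.subject_id}: negative survival_days")
            derived = class_from_days(self.survival_days)
            if self.os_class == OSClass.UNKNOWN:
                self.os_class = derived
            elif self.os_class != derived:
                raise DataError(
                    f"{self.subject_id}: os_class {self.os_class.value} inconsistent "
                    f"with survival_days {self.survival_days}"
                )


class CohortRole(str, Enum):
    TRAINING = "training"
    TESTING_A = "testingA"
    TESTING_B = "testingB"


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    role: CohortRole = CohortRole.TRAINING

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate subject ids in cohort")
        if self.role == CohortRole.TRAINING:
            missing = [s.subject_id for s in self.subjects if s.os_class == OSClass.UNKNOWN]
            if missing:
                raise DataError(f"training cohort has unknown os_class for {missing}")

    def __len__(self) -> int:
        return len(self.subjects)

    def ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def class_counts(self) -> dict[OSClass, int]:
        counts = {c: 0 for c in CLASS_ORDER}
        for s in self.subjects:
            if s.os_class in counts:
                counts[s.os_class] += 1
        return counts


# ---------------------------------------------------------------------------
# I/O


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a 3D single-channel NIfTI as an integer label volume.

    Spacing is taken from the header zooms; the affine's orientation is
    intentionally ignored (logged at debug level).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types for bad files
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    logger.debug("read %s shape=%s spacing=%s (affine orientation ignored)", path, data.shape, spacing)
    return LabelVolume(data=data, spacing=spacing)


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a label volume as NIfTI with a diagonal spacing affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.int16), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


CLINICAL_COLUMNS = ["subject_id", "age_years", "survival_days", "extent_of_resection"]


def read_clinical_csv(path: str | Path, role: CohortRole = CohortRole.TRAINING) -> Cohort:
    """Read a clinical table (`subject_id,age_years,survival_days,extent_of_resection`)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical CSV missing columns {missing}")
    subjects = []
    for _, row in df.iterrows():
        days = row["survival_days"]
        days = None if pd.isna(days) else float(days)
        res = str(row["extent_of_resection"])
        try:
            status = ResectionStatus(res)
        except ValueError:
            status = ResectionStatus.OTHER if res and res != "nan" else ResectionStatus.UNKNOWN
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                age=float(row["age_years"]),
                survival_days=days,
                resection_status=status,
            )
        )
    return Cohort(subjects=subjects, role=role)


def write_clinical_csv(cohort: Cohort, path: str | Path) -> None:
    rows = []
    for s in cohort.subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "age_years": s.age,
                "survival_days": s.survival_days if s.survival_days is not None else "",
                "extent_of_resection": s.resection_status.value,
            }
        )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# subregion conversions


def nonoverlapping_to_overlapping(tumor: LabelVolume) -> tuple[RegionMask, RegionMask, RegionMask]:
    """Convert a BraTS label map to the (WT, TC, EC) overlapping hierarchy.

    WT = labels {1,2,4}, TC = {1,4}, EC = {4}; EC ⊆ TC ⊆ WT by
    construction.
    """
    unexpected = tumor.labels() - TUMOR_LABELS
    if unexpected:
        raise LabelError(f"unexpected tumor labels {sorted(unexpected)}")
    d = tumor.data
    wt = RegionMask((d == LBL_NEC) | (d == LBL_PTE) | (d == LBL_ENC), tumor.spacing)
    tc = RegionMask((d == LBL_NEC) | (d == LBL_ENC), tumor.spacing)
    ec = RegionMask(d == LBL_ENC, tumor.spacing)
    return wt, tc, ec


def overlapping_to_nonoverlapping(wt: RegionMask, tc: RegionMask, ec: RegionMask) -> LabelVolume:
    """Convert (WT, TC, EC) masks back to a BraTS label map via set subtraction.

    Hierarchy violations (EC ⊄ TC or TC ⊄ WT) are repaired by
    intersecting down the chain, with a warning — this mirrors the
    hierarchy-imposing post-processing used by cascaded segmentation
    networks.
    """
    _require_same_grid(wt, tc)
    _require_same_grid(wt, ec)
    tc_d, ec_d = tc.data, ec.data
    if np.any(tc_d & ~wt.data) or np.any(ec_d & ~tc_d):
        logger.warning("hierarchy violation in overlapping masks; imposing EC ⊆ TC ⊆ WT")
        tc_d = tc_d & wt.data
        ec_d = ec_d & tc_d
    out = np.zeros(wt.shape, dtype=np.int16)
    out[wt.data] = LBL_PTE              # WT \ TC
    out[tc_d] = LBL_NEC                 # TC \ EC
    out[ec_d] = LBL_ENC
    return LabelVolume(out, wt.spacing)


def tumor_region_masks(tumor: LabelVolume) -> dict[str, RegionMask]:
    """Convenience: all named masks of a tumor map (non-overlapping + hierarchy)."""
    wt, tc, ec = nonoverlapping_to_overlapping(tumor)
    d = tumor.data
    return {
        "PTE": RegionMask(d == LBL_PTE, tumor.spacing),
        "NEC": RegionMask(d == LBL_NEC, tumor.spacing),
        "ENC": RegionMask(d == LBL_ENC, tumor.spacing),
        "WT": wt,
        "TC": tc,
        "EC": ec,
    }
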