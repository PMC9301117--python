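"""Shape, spatial, and demographic feature extraction.

Each radiomic model turns one subject into a fixed-length vector:

* per region (model-dependent region list): volume in mm^3 and surface
  area in mm^2,
* spatial: offset (dx, dy, dz) in mm of the whole-tumor centroid from
  the brain-mask centroid, plus its Euclidean norm,
* demographic: age in years.

That gives 2·R + 5 features: 7 for the whole-tumor model (R = 1), 11
for the physiologic 3-subregions model, 17 for the anatomical
6-subregions model, and 47 for the 21-subregions model.

Surface area uses exposed-face counting — every mask-voxel face
adjacent to background (or to the volume border) contributes its face
area from the spacing.  The estimator is bit-exact and translation
invariant; it over-estimates smooth surfaces relative to mesh-based
estimators (a cube-side bias common to voxel counting), which is
irrelevant for the relative comparisons the models make.  Empty regions
contribute zeros, never missing values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .anatomy_partition import RadiomicModel, SubregionModelSpec, build_model_masks
from .volumes_core import (
    DataError,
    DomainError,
    GeometryError,
    LabelVolume,
    RegionMask,
    SubjectRecord,
    OSClass,
)

logger = logging.getLogger("gliorad")

SPATIAL_COLUMNS = ("dx_mm", "dy_mm", "dz_mm", "distance_mm")
MODEL_N_FEATURES = {
    RadiomicModel.WT: 7,
    RadiomicModel.SUB3: 11,
    RadiomicModel.SUB6: 17,
    RadiomicModel.SUB21: 47,
}


def region_volume(mask: RegionMask) -> float:
    """Region volume in mm^3 (voxel count × voxel volume)."""
    return mask.count * mask.voxel_volume


def region_surface_area(mask: RegionMask) -> float:
    """Region surface area in mm^2 by exposed-face counting."""
    m = mask.data
    if not m.any():
        return 0.0
    sx, sy, sz = mask.spacing
    face_areas = (sy * sz, sx * sz, sx * sy)
    total = 0.0
    for axis, fa in enumerate(face_areas):
        inner_exposed = 0
        # faces between consecutive voxels along `axis`
        a = np.swapaxes(m, 0, axis)
        inner_exposed += int((a[1:] != a[:-1]).sum())
        # faces on the volume border
        border = int(a[0].sum()) + int(a[-1].sum())
        total += fa * (inner_exposed + border)
    return float(total)


def _centroid_mm(mask: RegionMask) -> np.ndarray:
    return np.argwhere(mask.data).mean(axis=0) * np.asarray(mask.spacing)


def spatial_features(wt: RegionMask, brain: RegionMask) -> tuple[float, float, float, float]:
    """Whole-tumor centroid offset from the brain centroid, in mm.

    Returns (dx, dy, dz, distance) with distance = ||(dx, dy, dz)||.
    Centroids are unweighted means of voxel centers times spacing.
    """
    if wt.shape != brain.shape or not np.allclose(wt.spacing, brain.spacing):
        raise GeometryError("spatial_features: masks on different grids")
    if wt.count == 0 or brain.count == 0:
        raise DomainError("spatial_features: empty WT or brain mask")
    offset = _centroid_mm(wt) - _centroid_mm(brain)
    return (
        float(offset[0]),
        float(offset[1]),
        float(offset[2]),
        float(np.linalg.norm(offset)),
    )


def feature_columns(spec: SubregionModelSpec) -> list[str]:
    """Deterministic column order: per region volume then surface, then
    dx, dy, dz, distance, age."""
    if spec.model == RadiomicModel.WT:
        names = ["WT"]
    elif spec.model == RadiomicModel.SUB3:
        names = ["PTE", "NEC", "ENC"]
    else:
        names = [f"region{rid:02d}" for rid in spec.region_ids]
    cols = []
    for n in names:
        cols += [f"{n}_volume_mm3", f"{n}_surface_mm2"]
    cols += list(SPATIAL_COLUMNS) + ["age_years"]
    return cols


def assemble_features(
    spec: SubregionModelSpec,
    tumor: LabelVolume,
    brain: RegionMask,
    record: SubjectRecord,
    atlas: LabelVolume | None = None,
) -> pd.Series:
    """One subject's feature vector for one radiomic model.

    Exactly 7 / 11 / 17 / 47 values depending on the model.
    """
    if record.age is None or (isinstance(record.age, float) and np.isnan(record.age)):
        raise DataError(f"{record.subject_id}: age required for feature extraction")
    masks = build_model_masks(spec, tumor, atlas)
    from .volumes_core import nonoverlapping_to_overlapping

    wt, _, _ = nonoverlapping_to_overlapping(tumor)
    values: dict[str, float] = {}
    for name, mask in masks:
        values[f"{name}_volume_mm3"] = region_volume(mask)
        values[f"{name}_surface_mm2"] = region_surface_area(mask)
    dx, dy, dz, dist = spatial_features(wt, brain)
    values.update(
        {"dx_mm": dx, "dy_mm": dy, "dz_mm": dz, "distance_mm": dist, "age_years": float(record.age)}
    )
    cols = feature_columns(spec)
    vec = pd.Series({c: values[c] for c in cols}, name=record.subject_id)[cols]
    expected = MODEL_N_FEATURES[spec.model]
    assert len(vec) == expected, f"{spec.model}: {len(vec)} features, expected {expected}"
    return vec


def feature_table(
    spec: SubregionModelSpec,
    subjects: list[tuple[SubjectRecord, LabelVolume, RegionMask, LabelVolume | None]],
) -> pd.DataFrame:
    """Feature table for one model over a cohort.

    ``subjects`` holds (record, tumor, brain, atlas) tuples.  The result
    is indexed by subject id, with an ``os_class`` column when known.
    """
    rows, classes = [], []
    for record, tumor, brain, atlas in subjects:
        rows.append(assemble_features(spec, tumor, brain, record, atlas=atlas))
        classes.append(record.os_class.value if record.os_class != OSClass.UNKNOWN else "")
    df = pd.DataFrame(rows)
    df.index.name = "subject_id"
    if any(classes):
        df["os_class"] = classes
    return df
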