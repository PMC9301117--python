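"""Anatomy-guided tumor partitioning.

The anatomy-based segmentation models overlay the whole-tumor mask on a
subject-space anatomical parcellation (a Harvard-Oxford-style 21-region
subcortical atlas, or the synthetic Voronoi stand-in), measure the
tumor-affected volume of every anatomical region, rank regions by that
volume, and retain the smallest top-K prefix whose cumulative coverage
of the whole tumor strictly exceeds 85%.  On BraTS-like cohorts this
selection yields K = 6 (bilateral cerebral cortex, cerebral white
matter, and lateral ventricles), giving the 6-subregions model; using
all atlas regions gives the 21-subregions model.

Because a per-subject K would make feature-vector length vary, the
6-subregions *feature* model uses a fixed cohort-level region set:
regions ranked by mean tumor-affected volume across the cohort, with
the coverage rule applied to the mean coverage.  Features are computed
on WT ∩ region — the tumor-affected portion of the structure, not the
whole structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .volumes_core import (
    DomainError,
    GeometryError,
    LabelVolume,
    RegionMask,
    SpecError,
    nonoverlapping_to_overlapping,
)

logger = logging.getLogger("gliorad")

DEFAULT_COVERAGE_THRESHOLD = 0.85

#: Harvard-Oxford subcortical region names, for real-atlas runs.
HARVARD_OXFORD_SUBCORTICAL_NAMES = {
    1: "Left Cerebral White Matter",
    2: "Left Cerebral Cortex",
    3: "Left Lateral Ventricle",
    4: "Left Thalamus",
    5: "Left Caudate",
    6: "Left Putamen",
    7: "Left Pallidum",
    8: "Brain-Stem",
    9: "Left Hippocampus",
    10: "Left Amygdala",
    11: "Left Accumbens",
    12: "Right Cerebral White Matter",
    13: "Right Cerebral Cortex",
    14: "Right Lateral Ventricle",
    15: "Right Thalamus",
    16: "Right Caudate",
    17: "Right Putamen",
    18: "Right Pallidum",
    19: "Right Hippocampus",
    20: "Right Amygdala",
    21: "Right Accumbens",
}


class RadiomicModel(str, Enum):
    WT = "wt"
    SUB3 = "sub3"
    SUB6 = "sub6"
    SUB21 = "sub21"


@dataclass
class SubregionModelSpec:
    """Which region masks a radiomic model extracts features from."""

    model: RadiomicModel
    region_ids: tuple[int, ...] = ()

    def __post_init__(self):
        if self.model == RadiomicModel.SUB6 and len(self.region_ids) != 6:
            raise SpecError(f"sub6 needs exactly 6 region ids, got {len(self.region_ids)}")
        if self.model == RadiomicModel.SUB21 and len(self.region_ids) != 21:
            raise SpecError(f"sub21 needs exactly 21 region ids, got {len(self.region_ids)}")


def overlay_tumor_on_atlas(wt: RegionMask, atlas: LabelVolume) -> pd.DataFrame:
    """Tumor-affected volume of every atlas region.

    Returns a DataFrame with one row per atlas region (zero-overlap
    regions included), sorted by volume descending with ties broken by
    lower region id, columns: ``region_id``, ``volume_mm3``,
    ``coverage``, ``cumulative_coverage`` (fractions of |WT|).
    """
    if wt.shape != atlas.shape or not np.allclose(wt.spacing, atlas.spacing):
        raise GeometryError("overlay: WT mask and atlas on different grids")
    region_ids = sorted(atlas.labels() - {0})
    voxvol = atlas.voxel_volume
    max_lbl = max(region_ids) if region_ids else 0
    counts = np.bincount(atlas.data[wt.data].ravel(), minlength=max_lbl + 1)
    wt_vox = wt.count
    rows = []
    for rid in region_ids:
        vox = int(counts[rid]) if rid <= max_lbl else 0
        rows.append(
            {
                "region_id": rid,
                "volume_mm3": vox * voxvol,
                "coverage": vox / wt_vox if wt_vox else 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=["region_id", "volume_mm3", "coverage"])
    df = df.sort_values(
        ["volume_mm3", "region_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["cumulative_coverage"] = df["coverage"].cumsum()
    return df


def select_top_k(
    table: pd.DataFrame, coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD
) -> tuple[list[int], int]:
    """Top-K regions by tumor-affected volume under the coverage rule.

    K is the smallest prefix (in descending-volume order, ties by lower
    region id) whose cumulative coverage of |WT| strictly exceeds
    ``coverage_threshold``.  If even all tumor-affected regions fail to
    reach the threshold (tumor partly outside the atlas), all nonzero
    regions are returned with a logged flag.
    """
    if table["volume_mm3"].sum() <= 0:
        raise DomainError("select_top_k: no tumor-affected volume")
    nonzero = table[table["volume_mm3"] > 0]
    cum = nonzero["cumulative_coverage"].to_numpy()
    above = np.nonzero(cum > coverage_threshold)[0]
    if len(above) == 0:
        logger.warning(
            "atlas covers only %.1f%% of WT (< %.0f%%); returning all %d affected regions",
            100 * cum[-1], 100 * coverage_threshold, len(nonzero),
        )
        k = len(nonzero)
    else:
        k = int(above[0]) + 1
    ids = nonzero["region_id"].head(k).tolist()
    return [int(r) for r in ids], k


def cohort_region_table(per_subject_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Cohort-level region ranking: mean volume and mean coverage per region.

    Regions absent from a subject's atlas contribute zero for that
    subject.  Output has the same columns/ordering convention as
    :func:`overlay_tumor_on_atlas` so :func:`select_top_k` applies
    directly to mean coverage.
    """
    if not per_subject_tables:
        raise DomainError("cohort_region_table: empty input")
    all_ids = sorted({int(r) for t in per_subject_tables for r in t["region_id"]})
    vol = pd.DataFrame(0.0, index=all_ids, columns=range(len(per_subject_tables)))
    cov = vol.copy()
    for j, t in enumerate(per_subject_tables):
        vol.loc[t["region_id"].to_numpy(), j] = t["volume_mm3"].to_numpy()
        cov.loc[t["region_id"].to_numpy(), j] = t["coverage"].to_numpy()
    df = pd.DataFrame(
        {
            "region_id": all_ids,
            "volume_mm3": vol.mean(axis=1).to_numpy(),
            "coverage": cov.mean(axis=1).to_numpy(),
        }
    )
    df = df.sort_values(
        ["volume_mm3", "region_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["cumulative_coverage"] = df["coverage"].cumsum()
    return df


def select_cohort_regions(
    per_subject_tables: list[pd.DataFrame],
    k: int | None = None,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> list[int]:
    """Fixed cohort-level region list for the anatomical feature models.

    With ``k`` given, simply the top-k regions by mean tumor-affected
    volume (the 6-subregions feature model needs exactly six); otherwise
    the coverage rule applied to mean coverage.
    """
    table = cohort_region_table(per_subject_tables)
    if k is not None:
        if len(table) < k:
            raise SpecError(f"cohort atlas has only {len(table)} regions, need {k}")
        return [int(r) for r in table["region_id"].head(k)]
    ids, _ = select_top_k(table, coverage_threshold)
    return ids


def build_model_masks(
    spec: SubregionModelSpec, tumor: LabelVolume, atlas: LabelVolume | None = None
) -> list[tuple[str, RegionMask]]:
    """Ordered, named region masks for one radiomic model.

    WT -> [WT]; sub3 -> [PTE, NEC, ENC]; sub6/sub21 -> [WT ∩ region] for
    the spec's region ids (order fixed by the spec; empty masks kept so
    feature vectors stay fixed-length).
    """
    wt, tc, ec = nonoverlapping_to_overlapping(tumor)
    if spec.model == RadiomicModel.WT:
        return [("WT", wt)]
    if spec.model == RadiomicModel.SUB3:
        d = tumor.data
        return [
            ("PTE", RegionMask(d == 2, tumor.spacing)),
            ("NEC", RegionMask(d == 1, tumor.spacing)),
            ("ENC", RegionMask(d == 4, tumor.spacing)),
        ]
    if atlas is None:
        raise SpecError(f"model {spec.model.value} needs an atlas")
    if tumor.shape != atlas.shape or not np.allclose(tumor.spacing, atlas.spacing):
        raise GeometryError("tumor and atlas on different grids")
    atlas_labels = atlas.labels() - {0}
    missing = set(spec.region_ids) - atlas_labels
    if missing:
        raise SpecError(f"region ids {sorted(missing)} absent from atlas")
    out = []
    for rid in spec.region_ids:
        out.append(
            (f"region{rid:02d}", RegionMask(wt.data & (atlas.data == rid), tumor.spacing))
        )
    return out
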