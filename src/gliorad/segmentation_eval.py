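"""Segmentation-quality metrics and scheme ranking.

Implements the evaluation battery used to compare automatic
segmentation schemes against ground truth:

* Dice similarity coefficient (DSC) per overlapping subregion,
* 95th-percentile symmetric Hausdorff surface distance (HD-95) in mm,
* per-scheme cohort summaries and mean-HD differences,
* the Final Ranking Score (FRS): competition ranks per subject and
  metric, averaged, lower = better,
* paired sign-flip permutation tests for the significance of rank
  differences between schemes.

HD-95 convention (the BraTS-community one): surfaces are mask voxels
with at least one 6-connected background neighbour (volume boundaries
count as background); the directed distance set from A to B holds, for
each surface voxel of A, the Euclidean distance in mm to the nearest
surface voxel of B; HD-95 = max of the two directed 95th percentiles
(linear-interpolation percentile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .volumes_core import (
    DataError,
    DomainError,
    GeometryError,
    LabelVolume,
    RegionMask,
    nonoverlapping_to_overlapping,
)

logger = logging.getLogger("gliorad")

REGIONS = ("wt", "tc", "ec")
METRIC_COLUMNS = ("dsc_wt", "dsc_tc", "dsc_ec", "hd_wt", "hd_tc", "hd_ec")


class UndefinedDistanceError(GeometryError):
    """Hausdorff distance undefined: exactly one of the two masks is empty."""


@dataclass
class SegQuality:
    """DSC and HD-95 of one (subject, scheme) pair for WT/TC/EC."""

    subject_id: str
    scheme: str
    dsc_wt: float
    dsc_tc: float
    dsc_ec: float
    hd_wt: float
    hd_tc: float
    hd_ec: float

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "scheme": self.scheme,
            "dsc_wt": self.dsc_wt,
            "dsc_tc": self.dsc_tc,
            "dsc_ec": self.dsc_ec,
            "hd_wt": self.hd_wt,
            "hd_tc": self.hd_tc,
            "hd_ec": self.hd_ec,
        }


@dataclass
class RankingResult:
    """FRS per scheme plus pairwise permutation p-values.

    ``frs`` maps scheme -> mean rank normalized by the number of
    schemes (lower = better); ``ordinal`` maps scheme -> 1-based
    position in the FRS ordering; ``pairwise_p`` is a DataFrame of
    two-sided permutation p-values.
    """

    frs: dict[str, float]
    ordinal: dict[str, int]
    per_subject_mean_rank: pd.DataFrame  # subjects x schemes
    pairwise_p: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# voxel-overlap metrics


def dice(a: RegionMask, b: RegionMask) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|); both empty -> 1."""
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing):
        raise GeometryError("dice: masks on different grids")
    na, nb = a.count, b.count
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a 6-connected background neighbour (borders count)."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return mask & ~eroded


def _directed_distances(surf_a: np.ndarray, surf_b: np.ndarray, spacing) -> np.ndarray:
    """Distances (mm) from each surface voxel of A to the nearest of B."""
    pa = np.argwhere(surf_a) * np.asarray(spacing)
    pb = np.argwhere(surf_b) * np.asarray(spacing)
    d, _ = cKDTree(pb).query(pa, k=1)
    return d


def hd95(a: RegionMask, b: RegionMask, percentile: float = 95.0) -> float:
    """Symmetric 95th-percentile Hausdorff surface distance in mm.

    Raises :class:`UndefinedDistanceError` when exactly one mask is
    empty; both empty -> 0 (perfect agreement).
    """
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing):
        raise GeometryError("hd95: masks on different grids")
    na, nb = a.count, b.count
    if na == 0 and nb == 0:
        return 0.0
    if na == 0 or nb == 0:
        raise UndefinedDistanceError("hd95 undefined: exactly one mask is empty")
    sa = _surface_voxels(a.data)
    sb = _surface_voxels(b.data)
    d_ab = _directed_distances(sa, sb, a.spacing)
    d_ba = _directed_distances(sb, sa, a.spacing)
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def grid_diagonal_mm(shape, spacing) -> float:
    """Length of the grid diagonal in mm — the empty-prediction HD penalty."""
    return float(np.linalg.norm(np.asarray(shape) * np.asarray(spacing)))


def evaluate_scheme(truth: LabelVolume, pred: LabelVolume, subject_id: str = "", scheme: str = "") -> SegQuality:
    """All six metrics of one predicted tumor map against ground truth.

    An empty predicted (or empty truth) region makes HD-95 undefined;
    following the deterministic bounded-penalty convention the pipeline
    substitutes the grid diagonal in mm (logged).
    """
    if truth.shape != pred.shape or not np.allclose(truth.spacing, pred.spacing):
        raise GeometryError("evaluate_scheme: volumes on different grids")
    masks_t = nonoverlapping_to_overlapping(truth)
    masks_p = nonoverlapping_to_overlapping(pred)
    vals = {}
    for region, mt, mp in zip(REGIONS, masks_t, masks_p):
        vals[f"dsc_{region}"] = dice(mt, mp)
        try:
            vals[f"hd_{region}"] = hd95(mt, mp)
        except UndefinedDistanceError:
            penalty = grid_diagonal_mm(truth.shape, truth.spacing)
            logger.warning(
                "%s/%s: HD-95(%s) undefined (one empty mask); substituting grid diagonal %.1f mm",
                subject_id, scheme, region.upper(), penalty,
            )
            vals[f"hd_{region}"] = penalty
    return SegQuality(subject_id=subject_id, scheme=scheme, **vals)


def quality_table(qualities: list[SegQuality]) -> pd.DataFrame:
    """Long-format DataFrame of per-(subject, scheme) metrics."""
    return pd.DataFrame([q.as_dict() for q in qualities])


# ---------------------------------------------------------------------------
# cohort summaries


def mean_hd(q: SegQuality) -> float:
    """Mean of the three HD-95 values of one quality record."""
    return float(np.mean([q.hd_wt, q.hd_tc, q.hd_ec]))


def mean_hd_row(hd_wt: float, hd_tc: float, hd_ec: float) -> float:
    """Mean HD-95 of a cohort-summary row (three region means)."""
    return float(np.mean([hd_wt, hd_tc, hd_ec]))


def delta_mean_hd(row_a, row_b) -> float:
    """Difference of mean HD-95 between two cohort rows (A minus B).

    Each row is a (hd_wt, hd_tc, hd_ec) triple of cohort means, e.g. the
    Hausdorff cells of one scheme's summary line.
    """
    return mean_hd_row(*row_a) - mean_hd_row(*row_b)


def scheme_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-scheme mean ± sd of all six metrics (rows indexed by scheme)."""
    g = table.groupby("scheme")[list(METRIC_COLUMNS)]
    summary = g.mean().join(g.std(ddof=1), rsuffix="_sd")
    return summary


# ---------------------------------------------------------------------------
# Final Ranking Score


def _subject_scheme_ranks(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean rank of each scheme over the six metrics.

    For every subject and metric, schemes are ranked (DSC descending,
    HD ascending; ties get the fractional mean rank); ranks are averaged
    over the six metrics.
    """
    if table[list(METRIC_COLUMNS)].isna().any().any():
        raise DataError("FRS: missing metric cells")
    schemes = sorted(table["scheme"].unique())
    if len(schemes) < 2:
        raise DataError("FRS requires >= 2 schemes")
    wide = table.set_index(["subject_id", "scheme"])
    subjects = sorted(table["subject_id"].unique())
    rows = {}
    for sid in subjects:
        sub = wide.loc[sid].reindex(schemes)
        if sub[list(METRIC_COLUMNS)].isna().any().any():
            raise DataError(f"FRS: subject {sid} missing a scheme row")
        ranks = np.zeros(len(schemes))
        for m in METRIC_COLUMNS:
            vals = sub[m].to_numpy(dtype=float)
            if m.startswith("dsc"):
                ranks += rankdata(-vals, method="average")
            else:
                ranks += rankdata(vals, method="average")
        rows[sid] = ranks / len(METRIC_COLUMNS)
    return pd.DataFrame.from_dict(rows, orient="index", columns=schemes)


def frs_rank(table: pd.DataFrame, n_perm: int = 0, seed: int = 0) -> RankingResult:
    """Final Ranking Score per scheme from a per-(subject, scheme) metric table.

    FRS = mean over subjects of the per-subject mean rank, normalized by
    the number of schemes so scores are comparable across experiments;
    lower is better.  ``ordinal`` gives the 1-based position in the FRS
    ordering (the form the field usually prints).  With ``n_perm`` > 0,
    pairwise sign-flip permutation tests against every other scheme are
    included.
    """
    per_subject = _subject_scheme_ranks(table)
    schemes = list(per_subject.columns)
    frs = (per_subject.mean(axis=0) / len(schemes)).to_dict()
    order = sorted(schemes, key=lambda s: (frs[s], s))
    ordinal = {s: i + 1 for i, s in enumerate(order)}
    pairwise = None
    if n_perm:
        rng = np.random.default_rng(seed)
        pairwise = pd.DataFrame(np.ones((len(schemes), len(schemes))), index=schemes, columns=schemes)
        for i, a in enumerate(schemes):
            for b in schemes[i + 1 :]:
                p = permutation_test(
                    per_subject[a].to_numpy(), per_subject[b].to_numpy(), n_perm=n_perm,
                    seed=int(rng.integers(2**31)),
                )
                pairwise.loc[a, b] = pairwise.loc[b, a] = p
    return RankingResult(frs=frs, ordinal=ordinal, per_subject_mean_rank=per_subject, pairwise_p=pairwise)


def permutation_test(
    scores_a: np.ndarray, scores_b: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> float:
    """Paired sign-flip permutation test on per-subject scores.

    Two-sided: p = (1 + #{permutations with |mean difference| >=
    observed}) / (1 + n_perm), where each permutation swaps the A/B pair
    of each subject independently with probability 1/2.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("permutation test needs paired 1D score vectors")
    n = len(a)
    if n < 2:
        raise DataError("permutation test needs >= 2 subjects")
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    d = a - b
    observed = abs(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    stats = np.abs((signs * d).mean(axis=1))
    exceed = int((stats >= observed - 1e-12).sum())
    return (1 + exceed) / (1 + n_perm)
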