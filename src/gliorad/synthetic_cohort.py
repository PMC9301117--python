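"""Synthetic phantom cohorts for the glioma survival-radiomics pipeline.

Real studies of this kind run on BraTS-style data: skull-stripped MRI
with expert tumor labels, an anatomical parcellation registered into
subject space, and automatic segmentations from several CNNs.  None of
that can ship with a package, so this module generates the full bundle
as label maps:

* a *brain* mask (discrete ellipsoid) with a Voronoi parcellation into
  ``n_atlas_regions`` anatomical regions (default 21, emulating the
  Harvard-Oxford subcortical atlas),
* a nested three-compartment tumor (non-enhancing core inside enhancing
  core inside peritumoral edema) with a jittered surface,
* an overall-survival outcome drawn from an ordinal logistic model on
  log tumor volume, centroid distance, and age,
* several "segmentation schemes": controlled random corruptions of the
  ground-truth labels standing in for the predictions of different
  segmentation networks, with tunable Dice / HD-95 quality.

No MRI intensities are simulated — the pipeline uses shape and spatial
features only, so label maps are sufficient.

Everything is a pure function of its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes_core import (
    CLASS_ORDER,
    LBL_ENC,
    LBL_NEC,
    LBL_PTE,
    Cohort,
    CohortRole,
    DomainError,
    GeometryError,
    LabelVolume,
    OSClass,
    RegionMask,
    SpecError,
    SubjectRecord,
    ResectionStatus,
    class_from_days,
    nonoverlapping_to_overlapping,
    overlapping_to_nonoverlapping,
    write_clinical_csv,
    write_label_volume,
)

logger = logging.getLogger("gliorad")

DAYS_PER_MONTH = 365.25 / 12.0


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one phantom head.

    The parcellation emulates a registered anatomical atlas: region
    identities are meant to be shared across a cohort (one spec — hence
    one seed — per cohort), and a handful of regions dominate in volume
    the way cerebral cortex, white matter, and ventricles dominate a
    subcortical atlas.  ``n_major_regions`` of the ``n_atlas_regions``
    parcels receive ``major_region_weight``-times the reach of the rest
    in the weighted-Voronoi assignment.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_atlas_regions: int = 21
    n_major_regions: int = 6
    major_region_weight: float = 2.5
    seed: int = 0

    def __post_init__(self):
        if self.n_atlas_regions < 1:
            raise SpecError("n_atlas_regions must be >= 1")
        if not 0 <= self.n_major_regions <= self.n_atlas_regions:
            raise SpecError("n_major_regions must be in [0, n_atlas_regions]")
        if self.major_region_weight < 1:
            raise SpecError("major_region_weight must be >= 1")


@dataclass(frozen=True)
class TumorSpec:
    """Nested spherical tumor: NEC ball inside ENC shell inside PTE shell.

    Radii are in voxels; ``jitter`` is the amplitude (in voxels) of a
    smooth random radial perturbation of all three surfaces.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]  # (r_NEC, r_ENC, r_PTE)
    jitter: float = 0.0

    def __post_init__(self):
        r1, r2, r3 = self.radii
        if not (0 < r1 < r2 < r3):
            raise SpecError(f"radii must satisfy 0 < r_NEC < r_ENC < r_PTE, got {self.radii}")
        if self.jitter < 0:
            raise SpecError("jitter must be >= 0")


@dataclass(frozen=True)
class SchemeProfile:
    """Corruption profile standing in for one automatic segmentation scheme.

    boundary_sigma — scale (mm) of a smooth random in/out displacement of
    each subregion surface; flip_rate — probability that a boundary voxel
    of the label map swaps to a neighbouring label; dropout_rate —
    probability that a small connected enhancing-core component is missed
    (relabelled as non-enhancing core).
    """

    name: str
    boundary_sigma: float = 0.5
    flip_rate: float = 0.0
    dropout_rate: float = 0.0
    dropout_max_voxels: int = 150

    def __post_init__(self):
        if self.boundary_sigma < 0:
            raise SpecError("boundary_sigma must be >= 0")
        for p in (self.flip_rate, self.dropout_rate):
            if not 0.0 <= p <= 1.0:
                raise SpecError("rates must be in [0, 1]")


#: Six profiles bracketing the DSC/HD-95 operating range reported for
#: state-of-the-art BraTS segmentation networks (cohort mean DSC(WT)
#: roughly 0.88-0.93).  Names are generic stand-ins, not reimplementations.
DEFAULT_SCHEME_PROFILES: tuple[SchemeProfile, ...] = (
    SchemeProfile("cnn2d_a", boundary_sigma=1.55, flip_rate=0.06, dropout_rate=0.30),
    SchemeProfile("cnn25d_b", boundary_sigma=1.48, flip_rate=0.05, dropout_rate=0.20),
    SchemeProfile("cnn3d_c", boundary_sigma=1.25, flip_rate=0.02, dropout_rate=0.05),
    SchemeProfile("cnn3d_d", boundary_sigma=1.32, flip_rate=0.03, dropout_rate=0.10),
    SchemeProfile("cnn3d_e", boundary_sigma=1.40, flip_rate=0.04, dropout_rate=0.15),
    SchemeProfile("consensus_f", boundary_sigma=1.25, flip_rate=0.01, dropout_rate=0.02),
)


@dataclass(frozen=True)
class SurvivalModelParams:
    """Ordinal (cumulative-logit) outcome model on standardized features.

    The linear predictor is
    ``eta = b_v * z(log V) + b_d * z(distance) + b_a * z(age)``;
    positive ``eta`` pushes toward the *long*-survival class.  Class
    probabilities are ``P(short) = s(c1 - eta)``,
    ``P(short or medium) = s(c2 - eta)`` with logistic ``s`` and
    cutpoints ``c1 < c2``; the default cutpoints give a uniform class
    marginal when all betas are zero.  Survival days are drawn uniformly
    from the emitted class's day range, so days always classify back to
    the emitted class.
    """

    beta_volume: float = -2.0
    beta_distance: float = -0.5
    beta_age: float = -1.0
    # (log-volume mm^3, centroid distance mm, age years) standardization
    feature_means: tuple[float, float, float] = (8.3, 9.0, 62.0)
    feature_stds: tuple[float, float, float] = (0.6, 4.0, 12.0)
    cutpoints: tuple[float, float] = (
        float(np.log((1 / 3) / (2 / 3))),  # logit(1/3)
        float(np.log((2 / 3) / (1 / 3))),  # logit(2/3)
    )
    class_day_ranges: dict = field(
        default_factory=lambda: {
            OSClass.SHORT: (12.0, 304.0),
            OSClass.MEDIUM: (305.0, 456.0),
            OSClass.LONG: (457.0, 1767.0),
        }
    )

    def __post_init__(self):
        for cls, (lo, hi) in self.class_day_ranges.items():
            if not (0 <= lo < hi):
                raise SpecError(f"bad day range for {cls}: {(lo, hi)}")
            if class_from_days(lo) != cls or class_from_days(hi) != cls:
                raise SpecError(f"day range {(lo, hi)} not contained in class {cls.value}")


def default_survival_params(spec: "PhantomSpec") -> SurvivalModelParams:
    """Survival-model parameters with standardization constants matched to
    the tumor-sampling design of ``spec``'s grid.

    Tumor radii scale with the grid, so the population mean/sd of
    log-volume and centroid distance depend on the phantom geometry;
    standardizing with the matched constants keeps the ordinal model's
    class marginal balanced on any grid size.
    """
    m = min(spec.grid_shape) * float(np.mean(spec.spacing))
    a, b = 0.11 * m, 0.22 * m  # r_PTE sampling range, mm
    mean_log_r = (b * np.log(b) - b - a * np.log(a) + a) / (b - a)
    sd_log_r = np.sqrt(
        (b * (np.log(b) ** 2 - 2 * np.log(b) + 2) - a * (np.log(a) ** 2 - 2 * np.log(a) + 2))
        / (b - a)
        - mean_log_r**2
    )
    mean_log_v = float(np.log(4 / 3 * np.pi) + 3 * mean_log_r)
    sd_log_v = float(3 * sd_log_r)
    return SurvivalModelParams(
        feature_means=(mean_log_v, 0.14 * m, 62.0),
        feature_stds=(sd_log_v, 0.06 * m, 12.0),
    )


def null_survival_params(spec: "PhantomSpec | None" = None) -> SurvivalModelParams:
    """Parameters with all effects switched off (uniform classes)."""
    base = default_survival_params(spec) if spec is not None else SurvivalModelParams()
    return replace(base, beta_volume=0.0, beta_distance=0.0, beta_age=0.0)


# ---------------------------------------------------------------------------
# phantom geometry


def generate_phantom(spec: PhantomSpec) -> tuple[RegionMask, LabelVolume]:
    """Ellipsoidal brain mask plus a Voronoi parcellation of it.

    The atlas labels ``1..n_atlas_regions`` exactly partition the brain
    mask: each brain voxel is assigned to the seed point minimizing
    distance / weight (weighted Voronoi), where the first
    ``n_major_regions`` seeds carry ``major_region_weight`` and the rest
    weight 1, giving the size-heterogeneous parcel spectrum of a real
    subcortical atlas.  Deterministic for a fixed seed.
    """
    shape = tuple(spec.grid_shape)
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * np.array([0.42, 0.39, 0.36])
    if np.any(semi < 1):
        raise SpecError(f"grid {shape} too small to hold a brain ellipsoid")
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    brain = RegionMask(r2 <= 1.0, spec.spacing)

    coords = np.argwhere(brain.data)
    if spec.n_atlas_regions > len(coords):
        raise SpecError(
            f"n_atlas_regions={spec.n_atlas_regions} exceeds brain voxel count {len(coords)}"
        )
    rng = np.random.default_rng(spec.seed)
    seeds = coords[rng.choice(len(coords), size=spec.n_atlas_regions, replace=False)]
    weights = np.ones(spec.n_atlas_regions)
    weights[: spec.n_major_regions] = spec.major_region_weight
    diff = coords[:, None, :].astype(float) - seeds[None, :, :].astype(float)
    dist = np.sqrt((diff**2).sum(axis=2)) / weights[None, :]
    nearest = dist.argmin(axis=1)
    atlas_data = np.zeros(shape, dtype=np.int16)
    atlas_data[tuple(coords.T)] = nearest.astype(np.int16) + 1
    return brain, LabelVolume(atlas_data, spec.spacing)


def _smooth_unit_field(shape, rng, smooth_vox: float = 2.0) -> np.ndarray:
    """Smooth Gaussian random field normalized to unit standard deviation."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=smooth_vox)
    sd = f.std()
    return f / sd if sd > 0 else f


def implant_tumor(brain: RegionMask, tumor_spec: TumorSpec, seed: int = 0) -> LabelVolume:
    """Implant a nested spherical tumor into the brain mask.

    NEC = ball(r_NEC), ENC = shell(r_NEC..r_ENC), PTE = shell
    (r_ENC..r_PTE), all intersected with the brain.  ``jitter`` adds a
    smooth random radial perturbation shared by the three surfaces.
    """
    cz = np.asarray(tumor_spec.center, dtype=float)
    ci = tuple(int(round(c)) for c in cz)
    if not all(0 <= ci[a] < brain.shape[a] for a in range(3)) or not brain.data[ci]:
        raise GeometryError(f"tumor center {tumor_spec.center} outside brain mask")
    idx = np.indices(brain.shape, dtype=float)
    dist = np.sqrt(sum((idx[a] - cz[a]) ** 2 for a in range(3)))
    if tumor_spec.jitter > 0:
        rng = np.random.default_rng(seed)
        dist = dist + tumor_spec.jitter * _smooth_unit_field(brain.shape, rng)
    r_nec, r_enc, r_pte = tumor_spec.radii
    out = np.zeros(brain.shape, dtype=np.int16)
    out[dist <= r_pte] = LBL_PTE
    out[dist <= r_enc] = LBL_ENC
    out[dist <= r_nec] = LBL_NEC
    out[~brain.data] = 0
    if not out.any():
        raise GeometryError("tumor lies entirely outside the brain mask")
    return LabelVolume(out, brain.spacing)


# ---------------------------------------------------------------------------
# survival simulation


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def survival_class_probabilities(
    volume_mm3: float, distance_mm: float, age_years: float, params: SurvivalModelParams
) -> np.ndarray:
    """Class probabilities (short, medium, long) of the ordinal model."""
    x = np.array([np.log(max(volume_mm3, 1e-9)), distance_mm, age_years])
    z = (x - np.asarray(params.feature_means)) / np.asarray(params.feature_stds)
    eta = (
        params.beta_volume * z[0]
        + params.beta_distance * z[1]
        + params.beta_age * z[2]
    )
    c1, c2 = params.cutpoints
    p_le1 = _sigmoid(c1 - eta)
    p_le2 = _sigmoid(c2 - eta)
    return np.array([p_le1, p_le2 - p_le1, 1.0 - p_le2])


def simulate_survival(
    volume_mm3: float,
    distance_mm: float,
    age_years: float,
    params: SurvivalModelParams,
    seed: int | np.random.Generator = 0,
) -> tuple[OSClass, float]:
    """Draw (os_class, survival_days) for one subject."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = survival_class_probabilities(volume_mm3, distance_mm, age_years, params)
    k = int(rng.choice(3, p=probs))
    os_class = CLASS_ORDER[k]
    lo, hi = params.class_day_ranges[os_class]
    days = float(rng.uniform(lo, hi))
    assert class_from_days(days) == os_class
    return os_class, days


# ---------------------------------------------------------------------------
# segmentation perturbation


def _bbox_slices(mask: np.ndarray, margin: int, shape) -> tuple[slice, slice, slice]:
    coords = np.argwhere(mask)
    lo = np.maximum(coords.min(axis=0) - margin, 0)
    hi = np.minimum(coords.max(axis=0) + margin + 1, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def perturb_segmentation(
    truth: LabelVolume, profile: SchemeProfile, seed: int = 0
) -> LabelVolume:
    """Corrupt a ground-truth tumor map according to a scheme profile.

    Three independent corruptions, in order: (1) each of the WT/TC/EC
    surfaces is displaced by an independent smooth random field of scale
    ``boundary_sigma`` mm (hierarchy re-imposed afterwards); (2) boundary
    voxels of the label map swap to a random 6-neighbour label with
    probability ``flip_rate``; (3) small connected enhancing-core
    components are missed with probability ``dropout_rate``.  The output
    is a valid tumor map, deterministic per (seed, profile).
    """
    rng = np.random.default_rng(seed)
    if not truth.data.any():
        return LabelVolume(truth.data.copy(), truth.spacing)

    # work on a crop around the tumor for speed; outside stays background
    margin = int(np.ceil(4 * max(profile.boundary_sigma, 1.0))) + 4
    sl = _bbox_slices(truth.data > 0, margin, truth.shape)
    crop = truth.data[sl]
    spacing = truth.spacing

    wt, tc, ec = nonoverlapping_to_overlapping(LabelVolume(crop, spacing))

    if profile.boundary_sigma > 0:
        new_masks = []
        for m in (wt, tc, ec):
            if not m.data.any():
                new_masks.append(m)
                continue
            inside = ndimage.distance_transform_edt(m.data, sampling=spacing)
            outside = ndimage.distance_transform_edt(~m.data, sampling=spacing)
            signed = inside - outside  # >0 inside, mm
            fldnoise = _smooth_unit_field(m.data.shape, rng)
            new_masks.append(
                RegionMask(signed + profile.boundary_sigma * fldnoise > 0, spacing)
            )
        wt, tc, ec = new_masks
        # independent surface noise breaks nesting; re-impose it here so the
        # conversion below sees a valid hierarchy
        tc = RegionMask(tc.data & wt.data, spacing)
        ec = RegionMask(ec.data & tc.data, spacing)
    pert = overlapping_to_nonoverlapping(wt, tc, ec)
    lab = pert.data.copy()

    if profile.flip_rate > 0 and lab.any():
        # boundary voxels: any voxel whose 6-neighbourhood holds a different label
        boundary = np.zeros(lab.shape, dtype=bool)
        shifts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        neigh = []
        for sh in shifts:
            rolled = np.roll(lab, sh, axis=(0, 1, 2))
            boundary |= rolled != lab
            neigh.append(rolled)
        boundary &= lab > 0  # only tumor voxels flip
        flip = boundary & (rng.random(lab.shape) < profile.flip_rate)
        if flip.any():
            pick = rng.integers(0, 6, size=int(flip.sum()))
            stacked = np.stack([n[flip] for n in neigh])  # (6, n_flip)
            lab[flip] = stacked[pick, np.arange(len(pick))]

    if profile.dropout_rate > 0:
        enc = lab == LBL_ENC
        comp, n_comp = ndimage.label(enc, structure=_FACE_STRUCT)
        if n_comp:
            sizes = ndimage.sum_labels(enc, comp, index=np.arange(1, n_comp + 1))
            for i, size in enumerate(sizes, start=1):
                if size <= profile.dropout_max_voxels and rng.random() < profile.dropout_rate:
                    lab[comp == i] = LBL_NEC  # missed enhancement read as core

    out = np.zeros(truth.shape, dtype=np.int16)
    out[sl] = lab
    return LabelVolume(out, truth.spacing)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SubjectBundle:
    """Everything generated for one subject."""

    record: SubjectRecord
    truth: LabelVolume
    brain: RegionMask
    atlas: LabelVolume
    predictions: dict[str, LabelVolume] = field(default_factory=dict)


@dataclass
class CohortBundle:
    cohort: Cohort
    subjects: dict[str, SubjectBundle] = field(default_factory=dict)

    def __iter__(self):
        for rec in self.cohort.subjects:
            yield self.subjects[rec.subject_id]


def _sample_subject_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Random tumor spec inside the brain of `spec`'s geometry."""
    shape = np.asarray(spec.grid_shape)
    center_vox = (shape - 1) / 2.0
    semi = shape * np.array([0.42, 0.39, 0.36])
    r_pte = rng.uniform(0.11, 0.22) * shape.min()
    r_enc = r_pte * rng.uniform(0.60, 0.72)
    r_nec = r_pte * rng.uniform(0.28, 0.42)
    # tumor center inside a shrunken ellipsoid so the bulk stays in-brain
    while True:
        u = rng.uniform(-0.55, 0.55, size=3)
        if (u ** 2).sum() <= 0.55 ** 2:
            break
    center = center_vox + u * semi
    return TumorSpec(center=tuple(center), radii=(r_nec, r_enc, r_pte), jitter=0.75)


def generate_subject(
    subject_id: str,
    spec: PhantomSpec,
    params: SurvivalModelParams,
    seed: int,
    scheme_profiles: tuple[SchemeProfile, ...] = (),
    with_survival: bool = True,
    phantom: tuple[RegionMask, LabelVolume] | None = None,
) -> SubjectBundle:
    """Generate one subject: phantom, tumor, outcome, and scheme predictions.

    The parcellation plays the role of a registered atlas, so it is a
    function of the cohort's :class:`PhantomSpec` (one layout shared by
    all subjects); ``phantom`` lets callers pass the precomputed
    (brain, atlas) pair instead of regenerating it.
    """
    ss = np.random.SeedSequence(seed)
    _s_phantom, s_tumor, s_surv, s_age, *s_schemes = ss.spawn(4 + len(scheme_profiles))
    brain, atlas = phantom if phantom is not None else generate_phantom(spec)
    rng_t = np.random.default_rng(s_tumor)
    tumor_spec = _sample_subject_geometry(spec, rng_t)
    truth = implant_tumor(brain, tumor_spec, seed=int(s_tumor.generate_state(2)[1] % 2**31))

    wt, _, _ = nonoverlapping_to_overlapping(truth)
    volume = wt.count * truth.voxel_volume
    bc = np.argwhere(brain.data).mean(axis=0) * np.asarray(brain.spacing)
    tc_ = np.argwhere(wt.data).mean(axis=0) * np.asarray(brain.spacing)
    distance = float(np.linalg.norm(tc_ - bc))
    age = float(np.clip(np.random.default_rng(s_age).normal(62.0, 12.0), 18.0, 90.0))

    if with_survival:
        os_class, days = simulate_survival(
            volume, distance, age, params, seed=np.random.default_rng(s_surv)
        )
        record = SubjectRecord(
            subject_id=subject_id,
            age=age,
            survival_days=days,
            resection_status=ResectionStatus.GTR,
            os_class=os_class,
        )
    else:
        record = SubjectRecord(
            subject_id=subject_id, age=age, resection_status=ResectionStatus.GTR
        )

    preds = {
        p.name: perturb_segmentation(
            truth, p, seed=int(s.generate_state(1)[0] % 2**31)
        )
        for p, s in zip(scheme_profiles, s_schemes)
    }
    return SubjectBundle(record=record, truth=truth, brain=brain, atlas=atlas, predictions=preds)


def generate_cohort(
    n_subjects: int,
    role: CohortRole = CohortRole.TRAINING,
    master_seed: int = 0,
    scheme_profiles: tuple[SchemeProfile, ...] = (),
    spec: PhantomSpec | None = None,
    params: SurvivalModelParams | None = None,
    class_counts: dict[OSClass, int] | None = None,
    id_prefix: str | None = None,
) -> CohortBundle:
    """Generate a full cohort bundle.

    ``class_counts`` (e.g. ``{short: 16, medium: 3, long: 12}``) is
    honoured exactly by rejection sampling on the outcome; a training
    cohort without explicit counts is guaranteed to contain all three
    classes.  Deterministic for a fixed ``master_seed``.
    """
    if n_subjects < 1:
        raise SpecError("n_subjects must be >= 1")
    spec = spec or PhantomSpec()
    params = params or default_survival_params(spec)
    id_prefix = id_prefix or f"{role.value}"
    if class_counts is not None and sum(class_counts.values()) != n_subjects:
        raise SpecError("class_counts must sum to n_subjects")

    phantom = generate_phantom(spec)
    remaining = dict(class_counts) if class_counts else None
    need_all_classes = role == CohortRole.TRAINING and class_counts is None

    subjects: list[SubjectBundle] = []
    attempt = 0
    max_attempts = 400 * n_subjects
    while len(subjects) < n_subjects:
        if attempt >= max_attempts:
            raise SpecError("could not satisfy requested class composition")
        slot = len(subjects)
        seed = int(np.random.SeedSequence([master_seed, slot, attempt]).generate_state(1)[0] % 2**31)
        attempt += 1
        sid = f"{id_prefix}_{slot:03d}"
        bundle = generate_subject(
            sid, spec, params, seed, scheme_profiles=scheme_profiles,
            with_survival=True, phantom=phantom,
        )
        cls = bundle.record.os_class
        if remaining is not None:
            if remaining.get(cls, 0) <= 0:
                continue
            remaining[cls] -= 1
        if need_all_classes:
            # once the remaining slots are only just enough to cover the
            # classes still missing, accept missing classes only
            missing = set(CLASS_ORDER) - {b.record.os_class for b in subjects}
            slots_left = n_subjects - len(subjects)
            if slots_left <= len(missing) and cls not in missing:
                continue
        subjects.append(bundle)

    cohort = Cohort([b.record for b in subjects], role=role)
    return CohortBundle(cohort=cohort, subjects={b.record.subject_id: b for b in subjects})


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write the directory layout: per-subject NIfTIs plus clinical.csv."""
    outdir = Path(outdir)
    for sb in bundle:
        d = outdir / sb.record.subject_id
        write_label_volume(sb.truth, d / "truth.nii.gz")
        write_label_volume(
            LabelVolume(sb.brain.data.astype(np.int16), sb.brain.spacing), d / "brain.nii.gz"
        )
        write_label_volume(sb.atlas, d / "atlas.nii.gz")
        for name, pred in sb.predictions.items():
            write_label_volume(pred, d / f"pred_{name}.nii.gz")
    write_clinical_csv(bundle.cohort, outdir / "clinical.csv")


# ---------------------------------------------------------------------------
# class balance


def class_entropy(counts) -> float:
    """Shannon entropy of class counts, normalized to [0, 1].

    Base = number of classes, so equal counts give 1.0 and a single
    occupied class gives 0.0.
    """
    c = np.asarray(list(counts), dtype=float)
    if c.sum() <= 0:
        raise DomainError("at least one count must be nonzero")
    if np.any(c < 0):
        raise DomainError("counts must be non-negative")
    p = c / c.sum()
    nz = p[p > 0]
    h = -(nz * np.log(nz)).sum()
    return float(h / np.log(len(c))) if len(c) > 1 else 0.0
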