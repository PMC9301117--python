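"""End-to-end pipeline driver and failure analysis.

``run_pipeline`` orchestrates the whole experiment on synthetic
phantoms: cohort simulation, per-scheme segmentation evaluation, STAPLE
fusion as an extra scheme, anatomical partitioning, feature extraction
for the four radiomic models, ensemble training/evaluation per model ×
scheme, a stability report (RSD of AUC across schemes), and the failure
analysis.

Failure analysis mirrors the standard post-hoc audit of multi-scheme
radiomics: for each radiomic model, count for every subject how many
segmentation schemes misclassify it; a subject counts as
*majority-misclassified* for a model when at least 4 of the 6 schemes
get it wrong.  The per-model majority sets are intersected (Venn
counts), and subjects are stratified by mean HD-95(WT) across schemes
into majority-correct vs majority-misclassified groups — the
expectation being that misclassified subjects carry larger segmentation
errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import __version__
from .anatomy_partition import (
    RadiomicModel,
    SubregionModelSpec,
    overlay_tumor_on_atlas,
    select_cohort_regions,
)
from .radiomic_features import feature_table
from .segmentation_eval import evaluate_scheme, frs_rank, quality_table, scheme_summary
from .staple_fusion import RaterSet, staple_fuse
from .survival_model import (
    StabilityReport,
    evaluate_classification,
    soft_vote_predict,
    train_ensemble,
    zscore_apply,
    zscore_fit,
)
from .synthetic_cohort import (
    DEFAULT_SCHEME_PROFILES,
    CohortBundle,
    PhantomSpec,
    SchemeProfile,
    SurvivalModelParams,
    default_survival_params,
    generate_cohort,
)
from .volumes_core import (
    CohortRole,
    DataError,
    OSClass,
    nonoverlapping_to_overlapping,
)

logger = logging.getLogger("gliorad")

STAPLE_SCHEME_NAME = "staple"


# ---------------------------------------------------------------------------
# failure analysis


@dataclass
class FailureReport:
    """Misclassification-by-scheme tallies and HD-stratified summaries."""

    #: per model: subjects × schemes table of 0/1 misclassification flags
    misclassified: dict[str, pd.DataFrame]
    #: per model per subject: number of schemes misclassifying it
    counts: dict[str, pd.Series]
    #: per model: subjects wrong under all / >= n-1 / >= majority schemes
    bins: dict[str, dict[str, int]]
    #: per model: majority-misclassified subject set
    majority_sets: dict[str, set[str]]
    #: intersection counts for every pair/triple/... of models
    intersections: dict[tuple[str, ...], int]
    majority_threshold: int
    n_schemes: int
    #: mean ± sd HD-95(WT) for majority-correct vs majority-misclassified
    hd_summary: dict[str, dict[str, float | int | None]] | None = None

    def union_majority_set(self) -> set[str]:
        out: set[str] = set()
        for s in self.majority_sets.values():
            out |= s
        return out

    def as_dict(self) -> dict:
        return {
            "majority_threshold": self.majority_threshold,
            "n_schemes": self.n_schemes,
            "bins": self.bins,
            "majority_sets": {m: sorted(s) for m, s in self.majority_sets.items()},
            "intersections": {" & ".join(k): v for k, v in self.intersections.items()},
            "hd_summary": self.hd_summary,
        }


def misclassification_distribution(
    predictions: dict[str, pd.DataFrame],
    truth: pd.Series,
    majority_threshold: int | None = None,
) -> FailureReport:
    """Tally misclassifications per subject, model, and scheme.

    ``predictions`` maps radiomic-model name to a subjects × schemes
    DataFrame of hard class labels; ``truth`` is indexed by subject.
    ``majority_threshold`` defaults to a strict majority of the schemes
    (4 of 6).
    """
    models = list(predictions)
    if not models:
        raise DataError("no prediction tables given")
    ref_index = predictions[models[0]].index
    n_schemes = predictions[models[0]].shape[1]
    for m, tbl in predictions.items():
        if not tbl.index.equals(ref_index):
            raise DataError(f"model {m}: subject index misaligned")
        if tbl.shape[1] != n_schemes:
            raise DataError(f"model {m}: scheme count differs")
    truth = truth.reindex(ref_index)
    if truth.isna().any():
        raise DataError("truth labels missing for some subjects")
    if majority_threshold is None:
        majority_threshold = n_schemes // 2 + 1

    mis, counts, bins, majority_sets = {}, {}, {}, {}
    for m, tbl in predictions.items():
        wrong = tbl.ne(truth, axis=0).astype(int)
        cnt = wrong.sum(axis=1)
        mis[m] = wrong
        counts[m] = cnt
        bins[m] = {
            "all_schemes": int((cnt == n_schemes).sum()),
            "ge_n_minus_1": int((cnt >= n_schemes - 1).sum()),
            "ge_majority": int((cnt >= majority_threshold).sum()),
        }
        majority_sets[m] = set(cnt.index[cnt >= majority_threshold])

    intersections: dict[tuple[str, ...], int] = {}
    for r in range(2, len(models) + 1):
        for combo in combinations(models, r):
            inter = set.intersection(*(majority_sets[m] for m in combo))
            intersections[combo] = len(inter)

    return FailureReport(
        misclassified=mis,
        counts=counts,
        bins=bins,
        majority_sets=majority_sets,
        intersections=intersections,
        majority_threshold=majority_threshold,
        n_schemes=n_schemes,
    )


def hd_stratified_summary(
    report: FailureReport, seg_table: pd.DataFrame
) -> dict[str, dict[str, float | int | None]]:
    """Mean ± sd of per-subject mean HD-95(WT) by classification group.

    Per subject, HD-95(WT) is averaged over schemes; subjects in the
    union of the per-model majority-misclassified sets form the
    "misclassified" group, the rest the "correct" group.  An empty group
    is flagged with undefined statistics.
    """
    per_subject_hd = seg_table.groupby("subject_id")["hd_wt"].mean()
    missing = set(report.counts[next(iter(report.counts))].index) - set(per_subject_hd.index)
    if missing:
        raise DataError(f"HD values missing for subjects {sorted(missing)}")
    mis_set = report.union_majority_set()
    groups = {
        "misclassified": [s for s in per_subject_hd.index if s in mis_set],
        "correct": [s for s in per_subject_hd.index if s not in mis_set],
    }
    out: dict[str, dict[str, float | int | None]] = {}
    for name, ids in groups.items():
        if not ids:
            logger.warning("HD-stratified summary: group %r is empty", name)
            out[name] = {"n": 0, "mean_hd_wt": None, "sd_hd_wt": None}
            continue
        vals = per_subject_hd.loc[ids]
        out[name] = {
            "n": len(ids),
            "mean_hd_wt": float(vals.mean()),
            "sd_hd_wt": float(vals.std(ddof=1)) if len(ids) > 1 else 0.0,
        }
    report.hd_summary = out
    return out


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Configuration of one end-to-end synthetic experiment."""

    n_train: int = 118
    n_test: int = 31
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    master_seed: int = 0
    scheme_profiles: tuple[SchemeProfile, ...] = DEFAULT_SCHEME_PROFILES[:5]
    with_staple: bool = True
    models: tuple[RadiomicModel, ...] = (
        RadiomicModel.WT,
        RadiomicModel.SUB3,
        RadiomicModel.SUB6,
        RadiomicModel.SUB21,
    )
    survival_params: SurvivalModelParams | None = None  # None -> grid-matched defaults
    test_class_counts: dict[OSClass, int] | None = None
    n_members: int = 25
    rf_params: dict = field(default_factory=lambda: {"n_estimators": 100})
    n_perm: int = 2000
    outdir: str | None = None

    @property
    def phantom_spec(self) -> PhantomSpec:
        return PhantomSpec(grid_shape=tuple(self.grid_shape))


@dataclass
class PipelineResult:
    train_bundle: CohortBundle
    test_bundle: CohortBundle
    seg_table: pd.DataFrame
    seg_summary: pd.DataFrame
    ranking: object
    evaluations: dict[str, dict[str, object]]  # model -> scheme -> EvalReport
    stability: StabilityReport
    failure: FailureReport
    sub6_regions: list[int]
    sub21_regions: list[int]


def _fuse_predictions(bundle: CohortBundle) -> None:
    for sb in bundle:
        raters = RaterSet(maps=list(sb.predictions.values()))
        sb.predictions[STAPLE_SCHEME_NAME] = staple_fuse(raters).fused


def _model_specs(config: RunConfig, train_bundle: CohortBundle) -> dict[RadiomicModel, SubregionModelSpec]:
    """Fixed region lists for the anatomical models from the training cohort."""
    overlay_tables = []
    for sb in train_bundle:
        wt, _, _ = nonoverlapping_to_overlapping(sb.truth)
        overlay_tables.append(overlay_tumor_on_atlas(wt, sb.atlas))
    sub6 = select_cohort_regions(overlay_tables, k=6)
    n_atlas = len(train_bundle.subjects[next(iter(train_bundle.subjects))].atlas.labels() - {0})
    sub21 = select_cohort_regions(overlay_tables, k=n_atlas)
    specs = {}
    for m in config.models:
        if m == RadiomicModel.SUB6:
            specs[m] = SubregionModelSpec(m, tuple(sub6))
        elif m == RadiomicModel.SUB21:
            specs[m] = SubregionModelSpec(m, tuple(sub21))
        else:
            specs[m] = SubregionModelSpec(m)
    return specs


def _features_for(bundle: CohortBundle, spec: SubregionModelSpec, scheme: str | None) -> pd.DataFrame:
    rows = []
    for sb in bundle:
        tumor = sb.truth if scheme is None else sb.predictions[scheme]
        rows.append((sb.record, tumor, sb.brain, sb.atlas))
    return feature_table(spec, rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full synthetic experiment; see module docstring."""
    logger.info("pipeline: simulating cohorts (train=%d, test=%d, grid=%s)",
                config.n_train, config.n_test, config.grid_shape)
    spec = config.phantom_spec
    params = config.survival_params or default_survival_params(spec)
    train_bundle = generate_cohort(
        config.n_train, CohortRole.TRAINING, master_seed=config.master_seed,
        spec=spec, params=params, id_prefix="train",
    )
    test_bundle = generate_cohort(
        config.n_test, CohortRole.TESTING_A, master_seed=config.master_seed + 1,
        scheme_profiles=config.scheme_profiles, spec=spec,
        params=params, class_counts=config.test_class_counts,
        id_prefix="test",
    )
    if config.with_staple:
        logger.info("pipeline: STAPLE fusion of %d schemes", len(config.scheme_profiles))
        _fuse_predictions(test_bundle)
    schemes = list(next(iter(test_bundle)).predictions.keys())

    logger.info("pipeline: segmentation evaluation (%d schemes)", len(schemes))
    qualities = []
    for sb in test_bundle:
        for scheme in schemes:
            qualities.append(
                evaluate_scheme(sb.truth, sb.predictions[scheme],
                                subject_id=sb.record.subject_id, scheme=scheme)
            )
    seg_table = quality_table(qualities)
    seg_sum = scheme_summary(seg_table)
    ranking = frs_rank(seg_table, n_perm=config.n_perm, seed=config.master_seed + 7)

    logger.info("pipeline: anatomical partitioning and feature extraction")
    specs = _model_specs(config, train_bundle)
    truth_labels = pd.Series(
        {sb.record.subject_id: sb.record.os_class.value for sb in test_bundle}
    )

    evaluations: dict[str, dict[str, object]] = {}
    stability = StabilityReport()
    hard_predictions: dict[str, pd.DataFrame] = {}
    for model_enum, mspec in specs.items():
        mname = model_enum.value
        train_feats = _features_for(train_bundle, mspec, scheme=None)
        stats = zscore_fit(train_feats)
        ensemble = train_ensemble(
            zscore_apply(train_feats, stats),
            n_members=config.n_members,
            rf_params=config.rf_params,
            master_seed=config.master_seed + 101,
            stats=stats,
        )
        evaluations[mname] = {}
        stability.per_scheme_auc[mname] = {}
        hard_tbl = {}
        for scheme in schemes:
            test_feats = _features_for(test_bundle, mspec, scheme=scheme)
            probs, hard = soft_vote_predict(ensemble, zscore_apply(test_feats, stats))
            report = evaluate_classification(probs, truth_labels)
            evaluations[mname][scheme] = report
            stability.per_scheme_auc[mname][scheme] = report.weighted_auc
            hard_tbl[scheme] = hard
        hard_predictions[mname] = pd.DataFrame(hard_tbl)

    logger.info("pipeline: failure analysis")
    failure = misclassification_distribution(hard_predictions, truth_labels)
    hd_stratified_summary(failure, seg_table)

    result = PipelineResult(
        train_bundle=train_bundle,
        test_bundle=test_bundle,
        seg_table=seg_table,
        seg_summary=seg_sum,
        ranking=ranking,
        evaluations=evaluations,
        stability=stability,
        failure=failure,
        sub6_regions=list(specs.get(RadiomicModel.SUB6, SubregionModelSpec(RadiomicModel.WT)).region_ids),
        sub21_regions=list(specs.get(RadiomicModel.SUB21, SubregionModelSpec(RadiomicModel.WT)).region_ids),
    )
    if config.outdir:
        write_report_bundle(result, config)
    return result


# ---------------------------------------------------------------------------
# report output


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def report_json(result: PipelineResult, config: RunConfig) -> dict:
    return {
        "config": {
            "n_train": config.n_train,
            "n_test": config.n_test,
            "grid_shape": list(config.grid_shape),
            "master_seed": config.master_seed,
            "schemes": [p.name for p in config.scheme_profiles]
            + ([STAPLE_SCHEME_NAME] if config.with_staple else []),
            "n_members": config.n_members,
            "rf_params": config.rf_params,
        },
        "segmentation_summary": json.loads(result.seg_summary.to_json(orient="index")),
        "frs": result.ranking.frs,
        "frs_ordinal": result.ranking.ordinal,
        "pairwise_p": None
        if result.ranking.pairwise_p is None
        else json.loads(result.ranking.pairwise_p.to_json(orient="index")),
        "evaluations": {
            m: {s: r.as_dict() for s, r in d.items()} for m, d in result.evaluations.items()
        },
        "stability": result.stability.as_dict(),
        "failure": result.failure.as_dict(),
        "sub6_regions": result.sub6_regions,
    }


def markdown_summary(result: PipelineResult) -> str:
    lines = ["# Pipeline summary", "", "## Segmentation quality (cohort mean ± sd)", ""]
    hdr = "| scheme | DSC WT | DSC TC | DSC EC | HD WT | HD TC | HD EC | FRS |"
    lines += [hdr, "|" + "---|" * 8]
    for scheme, row in result.seg_summary.iterrows():
        lines.append(
            f"| {scheme} "
            f"| {row['dsc_wt']:.3f} ± {row['dsc_wt_sd']:.3f} "
            f"| {row['dsc_tc']:.3f} ± {row['dsc_tc_sd']:.3f} "
            f"| {row['dsc_ec']:.3f} ± {row['dsc_ec_sd']:.3f} "
            f"| {row['hd_wt']:.2f} ± {row['hd_wt_sd']:.2f} "
            f"| {row['hd_tc']:.2f} ± {row['hd_tc_sd']:.2f} "
            f"| {row['hd_ec']:.2f} ± {row['hd_ec_sd']:.2f} "
            f"| {result.ranking.ordinal.get(scheme, '-')} |"
        )
    lines += ["", "## Classification (weighted AUC per model × scheme)", ""]
    models = list(result.evaluations)
    schemes = list(next(iter(result.evaluations.values())))
    lines.append("| scheme | " + " | ".join(models) + " |")
    lines.append("|" + "---|" * (len(models) + 1))
    for s in schemes:
        cells = [f"{result.evaluations[m][s].weighted_auc:.3f}" for m in models]
        lines.append(f"| {s} | " + " | ".join(cells) + " |")
    lines += ["", "## Stability", ""]
    for m in models:
        lines.append(
            f"- {m}: mean AUC {result.stability.mean_auc(m):.3f}, "
            f"RSD {result.stability.rsd(m):.2f}%"
        )
    if result.failure.hd_summary:
        lines += ["", "## Failure analysis (HD-95 WT by group)", ""]
        for g, stats in result.failure.hd_summary.items():
            if stats["n"]:
                lines.append(
                    f"- {g}: n={stats['n']}, mean HD-95(WT) = "
                    f"{stats['mean_hd_wt']:.2f} ± {stats['sd_hd_wt']:.2f} mm"
                )
            else:
                lines.append(f"- {g}: empty group")
    return "\n".join(lines) + "\n"


def write_report_bundle(result: PipelineResult, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    seg_csv = outdir / "segmentation_metrics.csv"
    result.seg_table.to_csv(seg_csv, index=False)
    outputs.append(seg_csv)
    rep = outdir / "report.json"
    rep.write_text(json.dumps(report_json(result, config), indent=2))
    outputs.append(rep)
    md = outdir / "summary.md"
    md.write_text(markdown_summary(result))
    outputs.append(md)
    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "files": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline: wrote report bundle to %s", outdir)
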