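"""Overall-survival classification with a soft-voting random-forest ensemble.

Pipeline: features are z-scored with training-cohort statistics, N
random forests (default N = 100; 200 trees, sqrt feature subsampling,
balanced class weights, Gini criterion) are trained on the same data
with different RNG streams, and inference averages the members' class
probability vectors with uniform weights before taking the argmax
(ties to the earlier class in short < medium < long order).

Evaluation reports one-vs-rest AUC per survival class, a
support-weighted headline AUC and AUPRC, and accuracy; robustness of a
radiomic model across segmentation schemes is the relative standard
deviation (RSD), 100·sd/mean of the per-scheme AUCs (population sd).
Overfitting is monitored by repeated stratified 70/30 splitting of the
training cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit

from .volumes_core import CLASS_ORDER, DataError, DomainError, SchemaError

logger = logging.getLogger("gliorad")

CLASS_LABELS = tuple(c.value for c in CLASS_ORDER)  # ("short", "medium", "long")

#: BraTS-style continuous survival-day proxies per predicted class
CLASS_DAY_PROXY = {"short": 150.0, "medium": 376.0, "long": 796.0}

DEFAULT_RF_PARAMS = {
    "n_estimators": 200,
    "max_features": "sqrt",  # classification meaning of the historical "auto"
    "class_weight": "balanced",
    "criterion": "gini",
}


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizationStats:
    """Per-feature training-cohort mean and standard deviation."""

    means: pd.Series
    stds: pd.Series

    def __post_init__(self):
        if not self.means.index.equals(self.stds.index):
            raise SchemaError("normalization means/stds keyed by different features")
        if (self.stds < 0).any():
            raise SchemaError("negative standard deviation")


def _split_features(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series | None]:
    if "os_class" in table.columns:
        return table.drop(columns=["os_class"]), table["os_class"]
    return table, None


def zscore_fit(train: pd.DataFrame) -> NormalizationStats:
    """Fit per-feature mean/sd on a training feature table."""
    X, _ = _split_features(train)
    if len(X) == 0:
        raise DataError("cannot fit normalization on an empty table")
    return NormalizationStats(means=X.mean(axis=0), stds=X.std(axis=0, ddof=0))


def zscore_apply(table: pd.DataFrame, stats: NormalizationStats) -> pd.DataFrame:
    """Apply training z-score stats; constant features map to 0."""
    X, y = _split_features(table)
    if list(X.columns) != list(stats.means.index):
        raise SchemaError(
            f"feature columns {list(X.columns)} do not match normalization stats"
        )
    stds = stats.stds.replace(0.0, np.nan)
    Z = (X - stats.means) / stds
    Z = Z.fillna(0.0)
    if y is not None:
        Z["os_class"] = y
    return Z


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleModel:
    members: list[RandomForestClassifier]
    feature_names: list[str]
    stats: NormalizationStats | None = None
    class_order: tuple[str, ...] = CLASS_LABELS

    @property
    def n_members(self) -> int:
        return len(self.members)


def train_ensemble(
    train: pd.DataFrame,
    n_members: int = 100,
    rf_params: dict | None = None,
    master_seed: int = 0,
    stats: NormalizationStats | None = None,
) -> EnsembleModel:
    """Train N forests on identical (normalized) data, differing only in
    the RNG stream (member i is seeded ``master_seed + i``)."""
    if n_members < 1:
        raise DomainError("n_members must be >= 1")
    X, y = _split_features(train)
    if y is None:
        raise DataError("training table must carry an os_class column")
    present = set(y.unique())
    if len(present) < 2:
        raise DataError(f"training data holds a single class {present}")
    params = dict(DEFAULT_RF_PARAMS)
    if rf_params:
        params.update(rf_params)
    members = []
    for i in range(n_members):
        clf = RandomForestClassifier(random_state=(master_seed + i) % 2**31, **params)
        clf.fit(X.to_numpy(), y.to_numpy())
        members.append(clf)
    return EnsembleModel(members=members, feature_names=list(X.columns), stats=stats)


def soft_vote_predict(model: EnsembleModel, table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Uniform-weight soft voting over ensemble members.

    Returns (probabilities DataFrame with short/medium/long columns,
    hard labels).  Argmax ties go to the earlier class in
    (short, medium, long) order.
    """
    X, _ = _split_features(table)
    if list(X.columns) != model.feature_names:
        raise SchemaError("prediction table columns do not match the trained schema")
    acc = np.zeros((len(X), len(model.class_order)))
    Xv = X.to_numpy()
    for clf in model.members:
        proba = clf.predict_proba(Xv)
        # align member class columns to the fixed class order; a class a
        # member never saw contributes probability 0
        col = {c: k for k, c in enumerate(clf.classes_)}
        for k, c in enumerate(model.class_order):
            if c in col:
                acc[:, k] += proba[:, col[c]]
    acc /= model.n_members
    probs = pd.DataFrame(acc, index=X.index, columns=list(model.class_order))
    hard = probs.idxmax(axis=1)  # first max wins -> class-order tie-break
    return probs, hard


# ---------------------------------------------------------------------------
# metrics


@dataclass
class EvalReport:
    per_class_auc: dict[str, float | None]
    weighted_auc: float
    per_class_auprc: dict[str, float | None]
    weighted_auprc: float
    accuracy_pct: float
    n_subjects: int = 0

    def as_dict(self) -> dict:
        return {
            "per_class_auc": self.per_class_auc,
            "weighted_auc": self.weighted_auc,
            "per_class_auprc": self.per_class_auprc,
            "weighted_auprc": self.weighted_auprc,
            "accuracy_pct": self.accuracy_pct,
            "n_subjects": self.n_subjects,
        }


def evaluate_classification(probs: pd.DataFrame, truth: pd.Series) -> EvalReport:
    """One-vs-rest AUC/AUPRC per class plus support-weighted summaries.

    A class absent from the truth has undefined AUC: it is flagged
    (None), excluded from the weighting, and logged.
    """
    truth = truth.reindex(probs.index)
    if truth.isna().any():
        raise DataError("truth labels missing for some subjects")
    aucs: dict[str, float | None] = {}
    auprcs: dict[str, float | None] = {}
    weights: dict[str, int] = {}
    for c in probs.columns:
        pos = (truth == c).to_numpy().astype(int)
        n_pos = int(pos.sum())
        weights[c] = n_pos
        if n_pos == 0 or n_pos == len(pos):
            logger.warning("class %r has no positives/negatives in truth; AUC undefined", c)
            aucs[c] = None
            auprcs[c] = None
            continue
        aucs[c] = float(roc_auc_score(pos, probs[c].to_numpy()))
        auprcs[c] = float(average_precision_score(pos, probs[c].to_numpy()))

    def _weighted(d: dict[str, float | None]) -> float:
        num = sum(d[c] * weights[c] for c in d if d[c] is not None)
        den = sum(weights[c] for c in d if d[c] is not None)
        return num / den if den else float("nan")

    hard = probs.idxmax(axis=1)
    accuracy = 100.0 * float((hard == truth).mean())
    return EvalReport(
        per_class_auc=aucs,
        weighted_auc=_weighted(aucs),
        per_class_auprc=auprcs,
        weighted_auprc=_weighted(auprcs),
        accuracy_pct=accuracy,
        n_subjects=len(truth),
    )


# ---------------------------------------------------------------------------
# repeated-split evaluation


@dataclass
class RepeatedSplitReport:
    mean_weighted_auc: float
    sd_weighted_auc: float
    mean_weighted_auprc: float
    sd_weighted_auprc: float
    mean_accuracy_pct: float
    sd_accuracy_pct: float
    n_repeats: int


def repeated_split_eval(
    train: pd.DataFrame,
    n_repeats: int = 200,
    test_fraction: float = 0.30,
    n_members: int = 100,
    rf_params: dict | None = None,
    master_seed: int = 0,
) -> RepeatedSplitReport:
    """Repeated stratified 70/30 splitting of the training cohort.

    Every repeat runs the full pipeline on the split: z-score stats
    fitted on the 70% part, ensemble trained there, evaluated on the
    held-out 30%.
    """
    X, y = _split_features(train)
    if y is None:
        raise DataError("repeated_split_eval needs an os_class column")
    counts = y.value_counts()
    if (counts < 2).any():
        raise DataError(f"stratification impossible: class counts {counts.to_dict()}")
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_fraction, random_state=master_seed % 2**31
    )
    aucs, auprcs, accs = [], [], []
    for rep, (tr_idx, te_idx) in enumerate(splitter.split(X, y)):
        tr = train.iloc[tr_idx]
        te = train.iloc[te_idx]
        stats = zscore_fit(tr)
        model = train_ensemble(
            zscore_apply(tr, stats),
            n_members=n_members,
            rf_params=rf_params,
            master_seed=master_seed + 1000 * (rep + 1),
            stats=stats,
        )
        probs, _ = soft_vote_predict(model, zscore_apply(te, stats))
        report = evaluate_classification(probs, _split_features(te)[1])
        aucs.append(report.weighted_auc)
        auprcs.append(report.weighted_auprc)
        accs.append(report.accuracy_pct)
    return RepeatedSplitReport(
        mean_weighted_auc=float(np.nanmean(aucs)),
        sd_weighted_auc=float(np.nanstd(aucs, ddof=1)) if n_repeats > 1 else 0.0,
        mean_weighted_auprc=float(np.nanmean(auprcs)),
        sd_weighted_auprc=float(np.nanstd(auprcs, ddof=1)) if n_repeats > 1 else 0.0,
        mean_accuracy_pct=float(np.mean(accs)),
        sd_accuracy_pct=float(np.std(accs, ddof=1)) if n_repeats > 1 else 0.0,
        n_repeats=n_repeats,
    )


# ---------------------------------------------------------------------------
# stability


def rsd(aucs) -> float:
    """Relative standard deviation: 100 × population sd / mean, in percent."""
    x = np.asarray(list(aucs), dtype=float)
    if len(x) < 2:
        raise DomainError("RSD needs at least two values")
    mean = x.mean()
    if mean <= 0:
        raise DomainError("RSD undefined for non-positive mean")
    return float(100.0 * x.std(ddof=0) / mean)


@dataclass
class StabilityReport:
    """Per radiomic model: per-scheme AUCs, their mean, and RSD (%)."""

    per_scheme_auc: dict[str, dict[str, float]] = field(default_factory=dict)

    def mean_auc(self, model: str) -> float:
        return float(np.mean(list(self.per_scheme_auc[model].values())))

    def rsd(self, model: str) -> float:
        return rsd(self.per_scheme_auc[model].values())

    def as_dict(self) -> dict:
        return {
            m: {
                "auc_per_scheme": dict(v),
                "mean_auc": self.mean_auc(m),
                "rsd_pct": self.rsd(m),
            }
            for m, v in self.per_scheme_auc.items()
        }


def prediction_csv(hard_labels: pd.Series, path=None) -> pd.DataFrame:
    """BraTS-style prediction table with survival-day proxies per class."""
    df = pd.DataFrame(
        {
            "subject_id": hard_labels.index,
            "predicted_class": hard_labels.to_numpy(),
            "survival_days_proxy": [CLASS_DAY_PROXY[c] for c in hard_labels],
        }
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
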