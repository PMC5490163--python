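"""Supervised classification of collapsed variants.

Builds the ten-feature matrix, constructs balanced training sets, trains
and selects classifiers by tenfold cross-validation, and computes the
six performance measures (recall, precision, F1, false positive rate,
accuracy, AUC) with somatic as the positive class.

The naive Bayes classifier is implemented in-repo to control the
missing-value semantics exactly: categorical likelihoods are Laplace
smoothed over the fixed schema levels, continuous likelihoods are
Gaussian, and a missing continuous value is omitted from the likelihood
product rather than imputed. Tree ensembles and the linear baselines
delegate to scikit-learn behind the same interface, with missing values
encoded as a dedicated category (categoricals) or a sentinel plus
indicator column (continuous).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from isown.annotate import MA_LEVELS, PP2_LEVELS
from isown.features import SUBSTITUTION_PATTERNS

logger = logging.getLogger(__name__)

POSITIVE = "somatic"
NEGATIVE = "germline"

TRINUCLEOTIDES = tuple(
    "".join(t) for t in itertools.product("ACGT", "ACGT", "ACGT")
)

#: fixed feature schema: the ten classifier features, in column order
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "in_exac": ("false", "true"),
    "in_dbsnp_rare": ("false", "true"),
    "ma_category": MA_LEVELS,
    "pp2_category": PP2_LEVELS,
    "context": TRINUCLEOTIDES + ("missing",),
    "pattern": SUBSTITUTION_PATTERNS,
}
CONTINUOUS_FEATURES = ("cnt", "sample_frequency", "mean_vaf", "flank_weight")
FEATURE_ORDER = (
    "cnt", "in_exac", "in_dbsnp_rare", "ma_category", "pp2_category",
    "context", "pattern", "sample_frequency", "mean_vaf", "flank_weight",
)

CLASSIFIER_KINDS = ("naive_bayes", "tree_ensemble", "boosted_tree", "logistic", "svm")


class ClassifierError(Exception):
    pass


class SchemaError(ClassifierError):
    """Feature matrix does not match the model's training schema."""


@dataclass(frozen=True)
class FeatureSchema:
    columns: tuple[str, ...] = FEATURE_ORDER
    categorical_levels: tuple[tuple[str, tuple[str, ...]], ...] = tuple(
        sorted(CATEGORICAL_LEVELS.items())
    )

    def levels(self) -> dict[str, tuple[str, ...]]:
        return dict(self.categorical_levels)

    def validate(self, matrix: pd.DataFrame) -> None:
        if tuple(matrix.columns) != self.columns:
            raise SchemaError(
                f"feature columns {tuple(matrix.columns)} != schema {self.columns}"
            )


def build_matrix(variants: Sequence) -> tuple[pd.DataFrame, Optional[pd.Series]]:
    """Feature matrix (+ label vector if any variant is labeled).

    Missing values are explicit: NaN for continuous features, the
    'missing' level for categoricals. Unlabeled/excluded variants yield a
    label of NaN in the label vector.
    """
    rows = []
    labels = []
    for v in variants:
        rows.append(
            {
                "cnt": float(v.ann.cnt),
                "in_exac": "true" if v.ann.in_exac else "false",
                "in_dbsnp_rare": "true" if v.ann.in_dbsnp_rare else "false",
                "ma_category": v.ann.ma_category,
                "pp2_category": v.ann.pp2_category,
                "context": v.context if v.context is not None else "missing",
                "pattern": v.pattern,
                "sample_frequency": v.sample_frequency,
                "mean_vaf": v.mean_vaf,
                "flank_weight": np.nan if v.flank_weight is None else v.flank_weight,
            }
        )
        labels.append(v.label if v.label in (POSITIVE, NEGATIVE) else np.nan)
    matrix = pd.DataFrame(rows, columns=list(FEATURE_ORDER))
    if matrix.empty:
        matrix = pd.DataFrame({c: pd.Series(dtype=object) for c in FEATURE_ORDER})
    label_series = pd.Series(labels, dtype=object)
    has_labels = label_series.notna().any() if len(label_series) else False
    return matrix, (label_series if has_labels else None)


def sanitize_levels(matrix: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    """Map unknown categorical levels to 'missing' with a logged warning."""
    matrix = matrix.copy()
    for col, levels in schema.levels().items():
        known = set(levels)
        bad = ~matrix[col].isin(known)
        if bad.any():
            if "missing" not in known:
                raise SchemaError(f"unknown level(s) in {col} with no missing level")
            logger.warning("%d unknown level(s) in %s mapped to missing", bad.sum(), col)
            matrix.loc[bad, col] = "missing"
    return matrix


# ---------------------------------------------------------------------------
# naive Bayes with mixed categorical/Gaussian likelihoods


class NaiveBayes:
    """Mixed-feature naive Bayes.

    Categorical features: Laplace-smoothed frequencies over the schema's
    fixed levels, P(level|class) = (count + 1) / (n_class + n_levels).
    Continuous features: Gaussian with per-class mean and (population)
    variance, floored at ``var_floor``. A NaN continuous value is omitted
    from the likelihood product. Posterior scores sum to 1 over classes.
    """

    def __init__(self, schema: FeatureSchema, var_floor: float = 1e-9):
        self.schema = schema
        self.var_floor = var_floor
        self.classes_ = (NEGATIVE, POSITIVE)
        self.log_prior_: dict[str, float] = {}
        self.cat_loglik_: dict[tuple[str, str], dict[str, float]] = {}
        self.gauss_: dict[tuple[str, str], tuple[float, float]] = {}

    def fit(self, matrix: pd.DataFrame, y: Sequence[str]) -> "NaiveBayes":
        y = np.asarray(y, dtype=object)
        n = len(y)
        levels = self.schema.levels()
        for cls in self.classes_:
            mask = y == cls
            n_cls = int(mask.sum())
            if n_cls == 0:
                raise ClassifierError(f"training set lacks class {cls}")
            self.log_prior_[cls] = math.log(n_cls / n)
            sub = matrix.loc[mask]
            for col, lvls in levels.items():
                counts = sub[col].value_counts()
                denom = n_cls + len(lvls)
                self.cat_loglik_[(cls, col)] = {
                    lvl: math.log((counts.get(lvl, 0) + 1) / denom) for lvl in lvls
                }
            for col in CONTINUOUS_FEATURES:
                vals = sub[col].to_numpy(dtype=float)
                vals = vals[~np.isnan(vals)]
                if vals.size == 0:
                    self.gauss_[(cls, col)] = (0.0, None)  # feature never observed
                else:
                    self.gauss_[(cls, col)] = (
                        float(vals.mean()),
                        max(float(vals.var()), self.var_floor),
                    )
        return self

    def predict_scores(self, matrix: pd.DataFrame) -> np.ndarray:
        """P(somatic | x) for each row."""
        n = len(matrix)
        log_post = np.zeros((n, 2))
        for k, cls in enumerate(self.classes_):
            log_post[:, k] = self.log_prior_[cls]
            for col in self.schema.levels():
                table = self.cat_loglik_[(cls, col)]
                log_post[:, k] += matrix[col].map(table).to_numpy(dtype=float)
            for col in CONTINUOUS_FEATURES:
                mu, var = self.gauss_[(cls, col)]
                if var is None:
                    continue
                x = matrix[col].to_numpy(dtype=float)
                ll = -0.5 * (np.log(2 * math.pi * var) + (x - mu) ** 2 / var)
                log_post[:, k] += np.where(np.isnan(x), 0.0, ll)
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=1, keepdims=True)
        return post[:, self.classes_.index(POSITIVE)]


# ---------------------------------------------------------------------------
# scikit-learn backed kinds share a numeric encoding


def encode_numeric(matrix: pd.DataFrame, schema: FeatureSchema) -> np.ndarray:
    """One-hot categoricals over fixed levels; continuous NaN -> sentinel+flag."""
    blocks = []
    levels = schema.levels()
    for col in schema.columns:
        if col in levels:
            vals = matrix[col].to_numpy(dtype=object)
            for lvl in levels[col]:
                blocks.append((vals == lvl).astype(float))
        else:
            x = matrix[col].to_numpy(dtype=float)
            missing = np.isnan(x)
            blocks.append(np.where(missing, -1.0, x))
            blocks.append(missing.astype(float))
    if not blocks:
        return np.zeros((len(matrix), 0))
    return np.column_stack(blocks)


def _make_sklearn(kind: str, seed: Optional[int]):
    if kind == "tree_ensemble":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    if kind == "boosted_tree":
        from sklearn.ensemble import HistGradientBoostingClassifier

        return HistGradientBoostingClassifier(random_state=seed)
    if kind == "logistic":
        from sklearn.linear_model import LogisticRegression
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    if kind == "svm":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        return make_pipeline(StandardScaler(), SVC(probability=True, random_state=seed))
    raise ClassifierError(f"unknown classifier kind: {kind}")


@dataclass
class TrainedModel:
    kind: str
    schema: FeatureSchema
    fitted: object
    provenance: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise ClassifierError(f"{path} is not a trained model file")
        return model


def train(
    kind: str,
    matrix: pd.DataFrame,
    y: Sequence[str],
    seed: Optional[int] = None,
    schema: FeatureSchema = FeatureSchema(),
    provenance: Optional[dict] = None,
) -> TrainedModel:
    """Fit a classifier of the given kind on a labeled feature matrix."""
    schema.validate(matrix)
    y = np.asarray(y, dtype=object)
    if len(y) != len(matrix) or len(matrix) == 0:
        raise ClassifierError("empty or misaligned training set")
    present = set(y)
    if present != {POSITIVE, NEGATIVE}:
        raise ClassifierError(f"training set must contain both classes, got {present}")
    matrix = sanitize_levels(matrix, schema)
    if kind == "naive_bayes":
        fitted = NaiveBayes(schema).fit(matrix, y)
    else:
        est = _make_sklearn(kind, seed)
        est.fit(encode_numeric(matrix, schema), (y == POSITIVE).astype(int))
        fitted = est
    prov = {"seed": seed, "n_train": len(y), **(provenance or {})}
    return TrainedModel(kind=kind, schema=schema, fitted=fitted, provenance=prov)


def predict(
    model: TrainedModel, matrix: pd.DataFrame, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, somatic scores) for each row; label = score >= threshold."""
    model.schema.validate(matrix)
    if len(matrix) == 0:
        return np.array([], dtype=object), np.array([], dtype=float)
    matrix = sanitize_levels(matrix, model.schema)
    if model.kind == "naive_bayes":
        scores = model.fitted.predict_scores(matrix)
    else:
        scores = model.fitted.predict_proba(encode_numeric(matrix, model.schema))[:, 1]
    labels = np.where(scores >= threshold, POSITIVE, NEGATIVE).astype(object)
    return labels, scores


# ---------------------------------------------------------------------------
# training-set construction


def balanced_sets(
    matrix: pd.DataFrame,
    y: Sequence[str],
    n_sets: int = 1000,
    per_class: int = 700,
    seed: Optional[int] = None,
) -> list[tuple[pd.DataFrame, np.ndarray]]:
    """Balanced training sets: per_class of each label, without replacement
    within a set. When a class is smaller than per_class, per_class is
    reduced to the minority size with a warning.
    """
    y = np.asarray(y, dtype=object)
    idx_pos = np.flatnonzero(y == POSITIVE)
    idx_neg = np.flatnonzero(y == NEGATIVE)
    if idx_pos.size == 0 or idx_neg.size == 0:
        raise ClassifierError("both classes required to build balanced sets")
    cap = min(idx_pos.size, idx_neg.size)
    if per_class > cap:
        logger.warning("per_class reduced from %d to minority size %d", per_class, cap)
        per_class = cap
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        take = np.concatenate(
            [
                rng.choice(idx_pos, size=per_class, replace=False),
                rng.choice(idx_neg, size=per_class, replace=False),
            ]
        )
        sets.append((matrix.iloc[take].reset_index(drop=True), y[take]))
    return sets


def train_from_samples(
    variants: Sequence,
    sample_ids: Sequence[str],
    seed: Optional[int] = None,
) -> list:
    """Training set drawn from the given samples: every somatic unique
    variant called in them plus an equal number of randomly selected
    germline variants called in them.
    """
    chosen = set(sample_ids)
    pool = [v for v in variants if v.sample_ids & chosen]
    somatic = [v for v in pool if v.label == POSITIVE]
    germline = [v for v in pool if v.label == NEGATIVE]
    if not somatic:
        raise ClassifierError("no somatic variants in the chosen training samples")
    if not germline:
        raise ClassifierError("no germline variants in the chosen training samples")
    rng = np.random.default_rng(seed)
    k = len(somatic)
    if k > len(germline):
        logger.warning(
            "only %d germline variants available for %d somatic; using all", len(germline), k
        )
        k_g = len(germline)
    else:
        k_g = k
    picked = rng.choice(len(germline), size=k_g, replace=False)
    return somatic + [germline[i] for i in picked]


# ---------------------------------------------------------------------------
# performance measures


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    recall: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    fpr: Optional[float]
    accuracy: Optional[float]
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "fpr": self.fpr,
            "accuracy": self.accuracy,
            "auc": self.auc,
        }


def metrics(c: ConfusionCounts) -> MetricsReport:
    """The five confusion-based measures; undefined ratios are None.

    recall = TP/(TP+FN); precision = TP/(TP+FP);
    F1 = 2*precision*recall/(precision+recall); FPR = FP/(FP+TN);
    accuracy = (TP+TN)/total.
    """
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    if recall is not None and precision is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) > 0 else None
    accuracy = (c.tp + c.tn) / c.total if c.total > 0 else None
    return MetricsReport(recall=recall, precision=precision, f1=f1, fpr=fpr, accuracy=accuracy)


def confusion_from_labels(y_true: Sequence[str], y_pred: Sequence[str]) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    return ConfusionCounts(
        tp=int(((y_true == POSITIVE) & (y_pred == POSITIVE)).sum()),
        fp=int(((y_true == NEGATIVE) & (y_pred == POSITIVE)).sum()),
        tn=int(((y_true == NEGATIVE) & (y_pred == NEGATIVE)).sum()),
        fn=int(((y_true == POSITIVE) & (y_pred == NEGATIVE)).sum()),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Probability that a somatic variant outscores a germline one, ties
    counted half (the rank-sum normalization of the Mann-Whitney U).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    pos = labels == POSITIVE
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ClassifierError("AUC undefined with a single class")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluate_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], scores: Optional[Sequence[float]] = None
) -> MetricsReport:
    rep = metrics(confusion_from_labels(y_true, y_pred))
    auc = None
    if scores is not None:
        labels = np.asarray(y_true, dtype=object)
        if (labels == POSITIVE).any() and (labels == NEGATIVE).any():
            auc = roc_auc(scores, labels)
    return MetricsReport(
        recall=rep.recall, precision=rep.precision, f1=rep.f1,
        fpr=rep.fpr, accuracy=rep.accuracy, auc=auc,
    )


# ---------------------------------------------------------------------------
# cross-validation and model selection


def cross_validate(
    kind: str,
    sets: Sequence[tuple[pd.DataFrame, np.ndarray]],
    folds: int = 10,
    seed: Optional[int] = None,
) -> tuple[list[MetricsReport], dict]:
    """Stratified k-fold CV per balanced set, metrics on pooled
    out-of-fold predictions; aggregate reports the mean over sets with a
    normal-approximation 95% CI.
    """
    from sklearn.model_selection import StratifiedKFold

    rng = np.random.default_rng(seed)
    reports: list[MetricsReport] = []
    for matrix, y in sets:
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        y = np.asarray(y, dtype=object)
        pred = np.empty(len(y), dtype=object)
        scores = np.empty(len(y), dtype=float)
        strat = (y == POSITIVE).astype(int)
        for train_idx, test_idx in skf.split(matrix, strat):
            model = train(kind, matrix.iloc[train_idx].reset_index(drop=True),
                          y[train_idx], seed=int(rng.integers(2**31 - 1)))
            p, s = predict(model, matrix.iloc[test_idx].reset_index(drop=True))
            pred[test_idx] = p
            scores[test_idx] = s
        reports.append(evaluate_predictions(y, pred, scores))
    aggregate = {}
    for name in ("recall", "precision", "f1", "fpr", "accuracy", "auc"):
        vals = np.array([getattr(r, name) for r in reports if getattr(r, name) is not None])
        if vals.size:
            mean = float(vals.mean())
            half = float(1.96 * vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
            aggregate[name] = {"mean": mean, "ci95": (mean - half, mean + half)}
    return reports, aggregate


def select_best(aggregates: dict[str, dict]) -> str:
    """Best kind by mean AUC, ties by mean F1, then lexicographic name."""
    if not aggregates:
        raise ClassifierError("no classifier reports to select from")

    def sort_key(item):
        kind, agg = item
        return (-agg["auc"]["mean"], -agg["f1"]["mean"], kind)

    return sorted(aggregates.items(), key=sort_key)[0][0]


# ---------------------------------------------------------------------------
# feature relevance


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def info_gain(
    column: Sequence, labels: Sequence[str], n_bins: int = 10
) -> float:
    """Information gain H(label) - H(label | feature), in bits.

    Continuous columns are discretized into ``n_bins`` equal-frequency
    bins; missing values (NaN or None) form their own category.
    """
    labels = np.asarray(labels, dtype=object)
    col = pd.Series(list(column))
    if pd.api.types.is_numeric_dtype(col):
        vals = col.to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        cats = np.full(len(vals), "missing", dtype=object)
        if ok.sum() > 0:
            finite = vals[ok]
            edges = np.unique(np.quantile(finite, np.linspace(0, 1, n_bins + 1)[1:-1]))
            cats[ok] = np.digitize(finite, edges).astype(str)
    else:
        cats = col.fillna("missing").to_numpy(dtype=object)
    y = (labels == POSITIVE).astype(int)
    h_label = _entropy(np.bincount(y, minlength=2))
    h_cond = 0.0
    n = len(y)
    for cat in pd.unique(cats):
        mask = cats == cat
        h_cond += mask.sum() / n * _entropy(np.bincount(y[mask], minlength=2))
    return max(h_label - h_cond, 0.0)
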