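"""Questionnaire scoring, group labeling, SVM training and evaluation.

The screening instrument is a 36-item self-rating scale with 4-point
responses, so totals range from 36 to 144.  Respondents are split into a
high-risk and a non-high-risk group at the sample mean plus one sample
standard deviation of the totals; membership in the high group requires a
total strictly above the cutoff.

A linear support-vector machine is trained on per-user category-ratio
feature vectors to separate the two groups, and performance is reported
as precision, recall and F-measure for the high class, by default as
stratified 5-fold cross-validated means.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .risk_profile import FeatureVector

N_ITEMS = 36
ITEM_MIN, ITEM_MAX = 1, 4

SPS_COLUMNS = ("user_id",) + tuple(f"item_{i:02d}" for i in range(1, N_ITEMS + 1))


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class SPSRecord:
    """One respondent's 36 item responses and their total."""

    user_id: str
    items: tuple[int, ...]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "total", sps_total(self.items))


@dataclass(frozen=True)
class GroupLabel:
    """high / non_high group assignment at a stated threshold."""

    user_id: str
    group: str
    threshold_used: float


@dataclass(frozen=True)
class EvaluationReport:
    """Precision, recall and F-measure for the positive (high) class."""

    precision: float
    recall: float
    f_measure: float
    n: int
    pearson_r: float | None = None


def sps_total(items: Sequence[int]) -> int:
    """Sum of the 36 item responses; validates count and the 1–4 range."""
    if len(items) != N_ITEMS:
        raise ScreeningError(f"expected {N_ITEMS} items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if not isinstance(v, (int, np.integer)) or not ITEM_MIN <= v <= ITEM_MAX:
            raise ScreeningError(f"item {i} out of range 1..4: {v!r}")
    return int(sum(items))


def sps_threshold(scores: Sequence[float]) -> float:
    """High-risk cutoff: sample mean plus sample (n-1) standard deviation."""
    if len(scores) < 2:
        raise ScreeningError("threshold needs at least 2 scores (SD undefined)")
    arr = np.asarray(scores, dtype=float)
    return float(arr.mean() + arr.std(ddof=1))


def label_groups(records: Sequence[SPSRecord], threshold: float) -> list[GroupLabel]:
    """Assign each respondent to high (total strictly above threshold) or
    non_high; totals equal to the threshold go to non_high."""
    return [
        GroupLabel(
            user_id=r.user_id,
            group="high" if r.total > threshold else "non_high",
            threshold_used=threshold,
        )
        for r in records
    ]


@dataclass(frozen=True)
class ClassifierConfig:
    """Linear SVM defaults: unit regularization, features standardized on
    the training fold, fixed seed."""

    kernel: str = "linear"
    C: float = 1.0
    seed: int = 0


def _make_pipeline(config: ClassifierConfig) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=config.kernel, C=config.C, random_state=config.seed)),
        ]
    )


def _as_xy(features: Sequence[FeatureVector], labels: Sequence[GroupLabel]) -> tuple[np.ndarray, np.ndarray]:
    if len(features) != len(labels):
        raise ScreeningError("features and labels differ in length")
    by_user = {l.user_id: l.group for l in labels}
    X = np.asarray([f.values for f in features], dtype=float)
    try:
        y = np.asarray([1 if by_user[f.user_id] == "high" else 0 for f in features])
    except KeyError as exc:
        raise ScreeningError(f"no label for user {exc}") from None
    return X, y


def train_classifier(
    features: Sequence[FeatureVector],
    labels: Sequence[GroupLabel],
    config: ClassifierConfig = ClassifierConfig(),
) -> Pipeline:
    """Fit the SVM on all provided examples; needs both classes present."""
    X, y = _as_xy(features, labels)
    if len(np.unique(y)) < 2:
        raise ScreeningError("training set contains a single class")
    return _make_pipeline(config).fit(X, y)


def evaluate(
    predicted: Sequence[str],
    actual: Sequence[str],
    positive_class: str = "high",
    n: int | None = None,
) -> EvaluationReport:
    """Precision, recall and F-measure of ``predicted`` against ``actual``
    for the positive class; zero denominators yield 0."""
    if len(predicted) != len(actual):
        raise ScreeningError("predicted and actual differ in length")
    tp = sum(1 for p, a in zip(predicted, actual) if p == positive_class and a == positive_class)
    fp = sum(1 for p, a in zip(predicted, actual) if p == positive_class and a != positive_class)
    fn = sum(1 for p, a in zip(predicted, actual) if p != positive_class and a == positive_class)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return EvaluationReport(
        precision=precision,
        recall=recall,
        f_measure=f_measure(precision, recall),
        n=n if n is not None else len(actual),
    )


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ScreeningError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, the convention of printed report
    tables (0.555 -> 0.56), unlike banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation; requires n >= 3 and
    nonzero variance in both vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ScreeningError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ScreeningError("pearson needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ScreeningError("pearson undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def cross_validated_report(
    features: Sequence[FeatureVector],
    labels: Sequence[GroupLabel],
    config: ClassifierConfig = ClassifierConfig(),
    n_folds: int = 5,
) -> EvaluationReport:
    """Stratified k-fold cross-validation; reported precision, recall and
    F-measure are the means of the per-fold values."""
    X, y = _as_xy(features, labels)
    if len(np.unique(y)) < 2:
        raise ScreeningError("cross-validation needs both classes")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    fold_reports = []
    for train_idx, test_idx in skf.split(X, y):
        model = _make_pipeline(config).fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        names = ["high" if v == 1 else "non_high" for v in pred]
        actual = ["high" if v == 1 else "non_high" for v in y[test_idx]]
        fold_reports.append(evaluate(names, actual))
    return EvaluationReport(
        precision=float(np.mean([r.precision for r in fold_reports])),
        recall=float(np.mean([r.recall for r in fold_reports])),
        f_measure=float(np.mean([r.f_measure for r in fold_reports])),
        n=len(y),
    )


def permutation_null_f(
    features: Sequence[FeatureVector],
    labels: Sequence[GroupLabel],
    config: ClassifierConfig = ClassifierConfig(),
    n_folds: int = 5,
    n_permutations: int = 20,
    seed: int = 0,
) -> float:
    """Mean cross-validated F-measure after randomly permuting the labels —
    the chance-level baseline a real signal must beat."""
    rng = np.random.default_rng(seed)
    users = [f.user_id for f in features]
    groups = np.asarray([next(l.group for l in labels if l.user_id == u) for u in users])
    thr = labels[0].threshold_used if labels else 0.0
    fs = []
    for _ in range(n_permutations):
        permuted = rng.permutation(groups)
        plabels = [GroupLabel(user_id=u, group=g, threshold_used=thr) for u, g in zip(users, permuted)]
        fs.append(cross_validated_report(features, plabels, config, n_folds).f_measure)
    return float(np.mean(fs))


# ------------------------------------------------------------------- I/O


def load_sps(path: str | Path) -> list[SPSRecord]:
    """Read the wide questionnaire CSV: user_id plus item_01..item_36."""
    path = Path(path)
    records: list[SPSRecord] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != SPS_COLUMNS:
            raise ScreeningError(f"{path}: bad header; expected user_id,item_01..item_{N_ITEMS}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SPS_COLUMNS):
                raise ScreeningError(f"{path}: line {lineno}: expected {len(SPS_COLUMNS)} fields")
            try:
                items = tuple(int(v) for v in row[1:])
                records.append(SPSRecord(user_id=row[0], items=items))
            except (ValueError, ScreeningError) as exc:
                raise ScreeningError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_sps(records: Sequence[SPSRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SPS_COLUMNS)
        for r in records:
            writer.writerow([r.user_id, *r.items])
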