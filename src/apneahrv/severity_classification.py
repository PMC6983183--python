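"""Severity classification: quantile cut-off sweep with ROC evaluation.

The continuous responses (AHI, ODI, ESS) are dichotomized into high vs. low
at swept percentile cut-offs (``value >= cutoff`` is "high").  For each
cut-off a classifier (SVM / LDA / KNN / OPLS-DA) is trained on the HRV
feature table under repeated stratified k-fold cross-validation — features
standardized inside each training fold only — and every subject receives an
out-of-fold decision score (mean over repeats).  The operating point is the
classifier's native decision boundary (score 0), keeping sensitivity,
specificity and accuracy mutually consistent.  AUC is the Mann–Whitney
statistic (ties counted 1/2) with a DeLong 95% confidence interval; ROC
curves are reported at the accuracy-optimal cut-off.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("svm", "lda", "knn", "opls")
DEFAULT_PERCENTILES = tuple(range(10, 91, 5))


@dataclass
class ClassifierSpec:
    name: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}; expected {CLASSIFIER_NAMES}")


class OPLSDiscriminant(BaseEstimator):
    """Orthogonal PLS discriminant analysis (single predictive component).

    Variation orthogonal to the class contrast is removed by the NIPALS
    orthogonal-signal-correction step (``n_orthogonal`` components, default
    1), then a one-component PLS regression on the corrected matrix gives
    the discriminant score.  Classes are coded -1/+1; the decision boundary
    is score 0.
    """

    def __init__(self, n_orthogonal: int = 1):
        self.n_orthogonal = n_orthogonal

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("OPLS-DA requires exactly two classes")
        yy = np.where(np.asarray(y) == self.classes_[1], 1.0, -1.0)
        self._x_mean = X.mean(axis=0)
        self._y_mean = yy.mean()
        E = X - self._x_mean
        yc = yy - self._y_mean

        w = E.T @ yc
        w /= np.linalg.norm(w)
        self._w_ortho, self._p_ortho = [], []
        for _ in range(self.n_orthogonal):
            t = E @ w
            p = E.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            nrm = np.linalg.norm(w_o)
            if nrm < 1e-12:
                break  # no orthogonal variation left
            w_o /= nrm
            t_o = E @ w_o
            p_o = E.T @ t_o / (t_o @ t_o)
            E = E - np.outer(t_o, p_o)
            self._w_ortho.append(w_o)
            self._p_ortho.append(p_o)
        w = E.T @ yc
        w /= np.linalg.norm(w)
        t = E @ w
        self._w = w
        self._q = float(t @ yc / (t @ t))
        return self

    def _correct(self, X):
        E = np.asarray(X, dtype=float) - self._x_mean
        for w_o, p_o in zip(self._w_ortho, self._p_ortho):
            t_o = E @ w_o
            E = E - np.outer(t_o, p_o)
        return E

    def decision_function(self, X):
        return self._correct(X) @ self._w * self._q + self._y_mean

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])


def build_estimator(spec: ClassifierSpec) -> BaseEstimator:
    """Instantiate the sklearn-compatible estimator for a classifier spec."""
    hp = dict(spec.hyperparameters)
    if spec.name == "svm":
        return SVC(kernel=hp.pop("kernel", "rbf"), C=hp.pop("regularization", 1.0),
                   class_weight="balanced", **hp)
    if spec.name == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if spec.name == "knn":
        return KNeighborsClassifier(n_neighbors=hp.pop("k", 5), **hp)
    return OPLSDiscriminant(n_orthogonal=hp.pop("n_orthogonal", 1))


def _decision_scores(est, X) -> np.ndarray:
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    proba = est.predict_proba(X)[:, list(est.classes_).index(True)]
    return proba - 0.5  # native boundary at probability 1/2


def dichotomize(values: np.ndarray, cutoff: float) -> np.ndarray:
    """Binary labels: ``value >= cutoff`` is the high class.

    Degenerate (single-class) results are flagged with a warning; downstream
    metrics are undefined for them.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("response values must be finite")
    labels = values >= cutoff
    if labels.all() or not labels.any():
        logger.warning("dichotomize: cutoff %g yields a single class", cutoff)
    return labels


def cross_validated_scores(features: pd.DataFrame | np.ndarray, labels: np.ndarray,
                           spec: ClassifierSpec, folds: int = 10, repeats: int = 5,
                           seed: int = 0) -> np.ndarray:
    """Out-of-fold decision scores under repeated stratified k-fold CV.

    Features are standardized on each training fold only.  Every subject is
    scored out-of-fold once per repeat; the mean score across repeats is
    returned.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} member(s) < {folds} folds; reduce folds"
        )
    base = build_estimator(spec)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    total = np.zeros(len(y))
    for train, test in cv.split(X, y):
        scaler = StandardScaler().fit(X[train])
        est = clone(base).fit(scaler.transform(X[train]), y[train])
        total[test] += _decision_scores(est, scaler.transform(X[test]))
    return total / repeats


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_ci_95: tuple[float, float]


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float,
               alpha: float = 0.05) -> tuple[float, float]:
    """DeLong variance of the AUC via placement values."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    cmp_ = (pos[:, None] > neg[None, :]).astype(float)
    cmp_ += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_.mean(axis=1)  # placement of each positive among negatives
    v01 = cmp_.mean(axis=0)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.959963984540054 * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC points, Mann–Whitney AUC (ties 1/2) and DeLong 95% CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for ROC analysis")
    auc = _auc_mann_whitney(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(fpr=fpr, tpr=tpr, auc=auc,
                     auc_ci_95=_delong_ci(scores, labels, auc))


@dataclass
class CutoffSweepResult:
    response: str
    classifier: str
    table: pd.DataFrame = field(repr=False)  # one row per usable percentile
    optimal_percentile: float
    optimal_cutoff: float
    roc: RocResult = field(repr=False)

    @property
    def auc(self) -> float:
        return self.roc.auc

    @property
    def auc_ci_95(self) -> tuple[float, float]:
        return self.roc.auc_ci_95


def _operating_metrics(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    pred = scores >= 0.0
    tp = np.sum(pred & labels)
    tn = np.sum(~pred & ~labels)
    sens = tp / labels.sum()
    spec = tn / (~labels).sum()
    acc = (tp + tn) / labels.size
    return float(sens), float(spec), float(acc)


def cutoff_sweep(features: pd.DataFrame | np.ndarray, response: np.ndarray,
                 spec: ClassifierSpec, percentiles=DEFAULT_PERCENTILES,
                 folds: int = 10, repeats: int = 5, seed: int = 0,
                 response_name: str = "response") -> CutoffSweepResult:
    """Sweep percentile cut-offs of a continuous response.

    Per cut-off: dichotomize, cross-validate, evaluate sensitivity /
    specificity / accuracy at the native decision boundary, and AUC with
    DeLong CI.  Percentiles whose dichotomization leaves a class smaller
    than the fold count are skipped with a log entry.  The reported ROC
    corresponds to the cut-off maximizing accuracy (ties: lowest cut-off).
    """
    response = np.asarray(response, dtype=float)
    rows = []
    roc_by_pct: dict[float, RocResult] = {}
    for pct in percentiles:
        cutoff = float(np.percentile(response, pct))
        labels = dichotomize(response, cutoff)
        counts = np.bincount(labels.astype(int), minlength=2)
        if counts.min() < folds:
            logger.info("cutoff_sweep(%s): skipping percentile %s (class sizes %s)",
                        response_name, pct, counts.tolist())
            continue
        scores = cross_validated_scores(features, labels, spec,
                                        folds=folds, repeats=repeats, seed=seed)
        sens, spc, acc = _operating_metrics(scores, labels)
        roc = roc_auc(scores, labels)
        roc_by_pct[pct] = roc
        rows.append({
            "percentile": float(pct), "cutoff": cutoff, "n_high": int(counts[1]),
            "sensitivity": sens, "specificity": spc, "accuracy": acc,
            "auc": roc.auc, "auc_lo": roc.auc_ci_95[0], "auc_hi": roc.auc_ci_95[1],
        })
    if not rows:
        raise ValueError(f"no usable percentile for response {response_name!r}")
    table = pd.DataFrame(rows)
    best = table.sort_values(["accuracy", "cutoff"], ascending=[False, True]).iloc[0]
    return CutoffSweepResult(
        response=response_name,
        classifier=spec.name,
        table=table,
        optimal_percentile=float(best["percentile"]),
        optimal_cutoff=float(best["cutoff"]),
        roc=roc_by_pct[best["percentile"]],
    )


def compare_conditions(records, manifest, responses=("ahi", "odi", "ess"),
                       specs=(ClassifierSpec("svm"),),
                       conditions=(("belt", True), ("belt", False),
                                   ("patch", True), ("patch", False)),
                       filter_config=None, spectral_config=None,
                       percentiles=DEFAULT_PERCENTILES, folds: int = 10,
                       repeats: int = 5, seed: int = 0,
                       ) -> tuple[pd.DataFrame, dict]:
    """Cut-off sweeps for every sensor x filter x response x classifier cell.

    Returns a tidy table (one row per condition and percentile) and the dict
    of full :class:`CutoffSweepResult` objects keyed by
    ``(sensor, filtered, response, classifier)``.
    """
    from .hrv_features import cohort_feature_table

    tidy = []
    sweeps: dict[tuple, CutoffSweepResult] = {}
    for sensor, filtered in conditions:
        feats = cohort_feature_table(records, sensor, filtered,
                                     filter_config, spectral_config)
        for response in responses:
            values = manifest.response(response)
            for spec in specs:
                sweep = cutoff_sweep(feats, values, spec, percentiles=percentiles,
                                     folds=folds, repeats=repeats, seed=seed,
                                     response_name=response)
                sweeps[(sensor, filtered, response, spec.name)] = sweep
                t = sweep.table.copy()
                t.insert(0, "classifier", spec.name)
                t.insert(0, "response", response)
                t.insert(0, "filtered", filtered)
                t.insert(0, "sensor", sensor)
                tidy.append(t)
    return pd.concat(tidy, ignore_index=True), sweeps
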