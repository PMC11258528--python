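"""Linear SGD classifier with oversampling, calibration and Youden thresholding.

The prediction model is a linear classifier fitted by stochastic gradient
descent over three candidate losses (hinge, log, modified Huber) and three
penalties (L1, L2, elastic net) with the regularization strength α searched
log-uniformly over [1e-6, 1e6] by cross-validated AUC. Minority-class rows
are oversampled inside each training fold only. Decision scores are mapped
to probabilities by a Platt sigmoid fitted on non-oversampled training
rows, and the operating threshold is the Youden-index maximizer averaged
across validation folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold

LOSSES = ("hinge", "log", "modified_huber")
PENALTIES = ("l1", "l2", "elasticnet")
ALPHA_RANGE = (1e-6, 1e6)
_SKLEARN_LOSS = {"hinge": "hinge", "log": "log_loss", "modified_huber": "modified_huber"}


@dataclass
class HyperParams:
    loss: str = "log"
    penalty: str = "l2"
    alpha: float = 1e-4
    l1_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if self.penalty not in PENALTIES:
            raise ValueError(f"penalty must be one of {PENALTIES}")
        if not ALPHA_RANGE[0] <= self.alpha <= ALPHA_RANGE[1]:
            raise ValueError(f"alpha outside {ALPHA_RANGE}")
        if self.penalty == "elasticnet":
            if self.l1_ratio is None:
                raise ValueError("elasticnet requires l1_ratio")
            if not 0 <= self.l1_ratio <= 1:
                raise ValueError("l1_ratio must be in [0,1]")


@dataclass
class EvalMetrics:
    sensitivity: float
    specificity: float
    auc_roc: float
    threshold: float
    fold: int | str = "test"
    confusion: dict | None = None


@dataclass
class TrainedModel:
    """Linear weights + Platt calibration + operating threshold."""

    weights: np.ndarray
    intercept: float
    hyperparams: HyperParams
    calibration: tuple[float, float] | None = None  # (A, B): p = 1/(1+exp(A·f+B))
    threshold: float = 0.5
    feature_names: list[str] | None = None

    def decision(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.weights + self.intercept

    def predict_proba(self, X) -> np.ndarray:
        f = self.decision(X)
        if self.calibration is not None:
            a, b = self.calibration
            return 1.0 / (1.0 + np.exp(a * f + b))
        if self.hyperparams.loss == "log":
            return expit(f)
        raise ValueError("hinge / modified-Huber scores need calibration for probabilities")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "hyperparams": vars(self.hyperparams),
            "calibration": self.calibration,
            "threshold": self.threshold,
            "feature_names": self.feature_names,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(d["weights"]),
            intercept=d["intercept"],
            hyperparams=HyperParams(**d["hyperparams"]),
            calibration=None if d["calibration"] is None else tuple(d["calibration"]),
            threshold=d["threshold"],
            feature_names=d["feature_names"],
        )


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def oversample_minority(features, labels, seed: int = 0):
    """Duplicate minority rows uniformly with replacement until classes balance."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes required for oversampling")
    if counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    rng = np.random.default_rng(seed)
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=need, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X[idx], y[idx]


def sgd_fit(features, labels, hp: HyperParams, seed: int = 0, epochs: int = 1000, tol: float = 1e-3):
    """Fit the linear model by stochastic gradient descent (per-sample updates
    over shuffled epochs until the objective stalls). Labels may be 0/1 or ±1."""
    X = np.asarray(features, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    y = np.asarray(labels).astype(int)
    y = np.where(y <= 0, 0, 1)
    clf = SGDClassifier(
        loss=_SKLEARN_LOSS[hp.loss],
        penalty=hp.penalty,
        alpha=hp.alpha,
        l1_ratio=hp.l1_ratio if hp.l1_ratio is not None else 0.15,
        max_iter=epochs,
        tol=tol,
        shuffle=True,
        random_state=seed,
        # the step-decay schedule 1/(alpha·t) is unusable at very small alpha;
        # a stall-adaptive constant step plus Polyak–Ruppert averaging converges
        # to the same optimum for every loss without seed-to-seed variance.
        # Stability of the penalty update requires eta ≲ 1/alpha, hence the cap.
        learning_rate="adaptive",
        eta0=min(0.05, 1.0 / hp.alpha),
        average=True,
    )
    clf.fit(X, y)
    return clf


def auc_roc(labels, scores) -> float:
    """AUC as the probability of concordance, ties counted 1/2 (Mann-Whitney)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required for AUC")
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def youden_threshold(labels, probabilities) -> float:
    """Threshold maximizing J = sensitivity + specificity − 1.

    Candidates are midpoints between consecutive distinct probabilities plus
    the endpoints 0 and 1 (positive call: p ≥ threshold); exact ties go to
    the smallest candidate.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if y.sum() in (0, len(y)):
        raise ValueError("both classes required")
    distinct = np.unique(p)
    candidates = np.concatenate([[0.0], (distinct[:-1] + distinct[1:]) / 2.0, [1.0]])
    n1, n0 = y.sum(), len(y) - y.sum()
    best_t, best_j = 0.0, -np.inf
    for t in candidates:
        pred = p >= t
        tp = int((pred & (y == 1)).sum())
        tn = int((~pred & (y == 0)).sum())
        j = tp / n1 + tn / n0 - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return float(best_t)


def fit_platt(scores, labels) -> tuple[float, float]:
    """Maximum-likelihood sigmoid p = 1/(1+exp(A·f+B)) on decision scores."""
    y = np.asarray(labels).astype(int)
    if y.sum() in (0, len(y)):
        raise ValueError("both classes required for calibration")
    f = np.asarray(scores, dtype=float).reshape(-1, 1)
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(f, y)
    return (-float(lr.coef_[0, 0]), -float(lr.intercept_[0]))


def calibrate(model: TrainedModel, features, labels) -> TrainedModel:
    """Return a copy of ``model`` with a Platt sigmoid fitted on held-out rows."""
    a, b = fit_platt(model.decision(features), labels)
    return TrainedModel(
        weights=model.weights.copy(),
        intercept=model.intercept,
        hyperparams=model.hyperparams,
        calibration=(a, b),
        threshold=model.threshold,
        feature_names=model.feature_names,
    )


# ---------------------------------------------------------------------------
# model selection and validation
# ---------------------------------------------------------------------------

def _as_matrix(features):
    names = list(features.columns) if isinstance(features, pd.DataFrame) else None
    return np.asarray(features, dtype=float), names


def _clf_to_model(clf, hp, names) -> TrainedModel:
    return TrainedModel(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        hyperparams=hp,
        feature_names=names,
    )


def _oof_decision_scores(X, y, hp: HyperParams, seed: int, k: int = 5) -> np.ndarray:
    """Out-of-fold decision values: each row scored by a model that never saw it."""
    scores = np.empty(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    for fi, (tr, va) in enumerate(skf.split(X, y)):
        Xb, yb = oversample_minority(X[tr], y[tr], seed=seed + 101 * fi)
        clf = sgd_fit(Xb, yb, hp, seed=seed + 101 * fi)
        scores[va] = clf.decision_function(X[va])
    return scores


def fit_calibrated(features, labels, hp: HyperParams, seed: int = 0, k: int = 5) -> TrainedModel:
    """Oversample and fit on all rows; calibrate on out-of-fold decision values.

    The Platt sigmoid is fitted against scores from models that never saw
    the scored row, so the probability map is not optimistically steep and
    transfers to new cohorts.
    """
    X, names = _as_matrix(features)
    y = np.asarray(labels).astype(int)
    Xb, yb = oversample_minority(X, y, seed=seed)
    clf = sgd_fit(Xb, yb, hp, seed=seed)
    model = _clf_to_model(clf, hp, names)
    a, b = fit_platt(_oof_decision_scores(X, y, hp, seed, k=k), y)
    model.calibration = (a, b)
    return model


def sample_hyperparams(rng: np.random.Generator) -> HyperParams:
    loss = rng.choice(LOSSES)
    penalty = rng.choice(PENALTIES)
    alpha = 10.0 ** rng.uniform(np.log10(ALPHA_RANGE[0]), np.log10(ALPHA_RANGE[1]))
    l1_ratio = float(rng.uniform()) if penalty == "elasticnet" else None
    return HyperParams(loss=str(loss), penalty=str(penalty), alpha=float(alpha), l1_ratio=l1_ratio)


def hyperparameter_search(
    train_features,
    train_labels,
    space=None,
    n_iter: int = 25,
    seed: int = 0,
    k: int = 5,
    strategy: str = "random",
):
    """Pick the hyperparameters maximizing mean k-fold CV AUC.

    ``space`` may be an explicit list of :class:`HyperParams` candidates;
    otherwise ``n_iter`` candidates are drawn log-uniformly at random over
    the full loss × penalty × α grid. The scoring contract (stratified
    folds, oversampling inside the training folds only) is identical for
    any search strategy.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be ≥ 1")
    if strategy != "random":
        raise ValueError("available search strategies: 'random'")
    X, _ = _as_matrix(train_features)
    y = np.asarray(train_labels).astype(int)
    rng = np.random.default_rng(seed)
    candidates = list(space) if space is not None else [sample_hyperparams(rng) for _ in range(n_iter)]
    folds = list(StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31)).split(X, y))
    best_hp, best_score = None, -np.inf
    for hp in candidates:
        scores = []
        for fi, (tr, va) in enumerate(folds):
            Xb, yb = oversample_minority(X[tr], y[tr], seed=seed + fi)
            clf = sgd_fit(Xb, yb, hp, seed=seed + fi)
            scores.append(auc_roc(y[va], clf.decision_function(X[va])))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_score, best_hp = score, hp
    return best_hp, best_score


@dataclass
class CVResult:
    folds: list[EvalMetrics]
    mean_threshold: float
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)


def cross_validate(features, labels, hp: HyperParams, k: int = 5, seed: int = 0) -> CVResult:
    """Stratified k-fold validation with Youden thresholding.

    Each fold's model is fitted on the oversampled complement and calibrated
    out-of-fold. A Youden-optimal threshold is recorded per fold from its
    validation probabilities; the across-fold *mean* threshold is then the
    single operating point at which every fold's sensitivity and specificity
    are reported — and which the final model carries to the test set.
    """
    X, _ = _as_matrix(features)
    y = np.asarray(labels).astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    fold_probs: list[tuple[int, np.ndarray, np.ndarray]] = []
    fold_thresholds: list[float] = []
    for fi, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            raise ValueError("fold without both classes; stratification failed")
        model = fit_calibrated(X[tr], y[tr], hp, seed=seed + fi)
        p_va = model.predict_proba(X[va])
        fold_thresholds.append(youden_threshold(y[va], p_va))
        fold_probs.append((fi, y[va], p_va))
    t_mean = float(np.mean(fold_thresholds))
    metrics: list[EvalMetrics] = []
    for fi, y_va, p_va in fold_probs:
        pred = p_va >= t_mean
        sens = float((pred & (y_va == 1)).sum() / (y_va == 1).sum())
        spec = float((~pred & (y_va == 0)).sum() / (y_va == 0).sum())
        metrics.append(EvalMetrics(sens, spec, auc_roc(y_va, p_va), fold_thresholds[fi], fold=fi + 1))
    mean = {
        m: float(np.mean([getattr(f, m) for f in metrics]))
        for m in ("sensitivity", "specificity", "auc_roc")
    }
    sd = {
        m: float(np.std([getattr(f, m) for f in metrics], ddof=1))
        for m in ("sensitivity", "specificity", "auc_roc")
    }
    return CVResult(metrics, t_mean, mean, sd)


def train_model(features, labels, hp: HyperParams, seed: int = 0, k: int = 5) -> tuple[TrainedModel, CVResult]:
    """Cross-validate, then fit the final calibrated model on all training rows,
    carrying the across-fold mean Youden threshold."""
    cv = cross_validate(features, labels, hp, k=k, seed=seed)
    model = fit_calibrated(features, labels, hp, seed=seed)
    model.threshold = cv.mean_threshold
    return model, cv


def evaluate(model: TrainedModel, features, labels) -> EvalMetrics:
    """Sensitivity/specificity at the carried threshold plus AUC and the
    confusion matrix on untouched test rows."""
    X, _ = _as_matrix(features)
    y = np.asarray(labels).astype(int)
    p = model.predict_proba(X)
    pred = p >= model.threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    auc = auc_roc(y, p) if 0 < y.sum() < len(y) else float("nan")
    return EvalMetrics(sens, spec, auc, model.threshold, fold="test", confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn})
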