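"""Cross-validation, permutation testing, DQ2 and classification metrics.

Two cross-validation schemes are provided for the OPLS-DA fingerprint
classifier:

* leave-one-out (LOO): every subject is predicted once by a model fitted on
  the other n-1, with centring/scaling recomputed inside each fold;
* Monte Carlo: repeated stratified random 90/10 train/test splits (500
  repetitions by default); overall accuracy is the mean of the per-repetition
  accuracies and scores are pooled over all test appearances.

Significance is assessed with a label-permutation test whose statistic is the
full cross-validated accuracy, recomputed per permutation, with the add-one
estimator p = (1 + #{perm >= observed}) / (B + 1).

DQ2 is the discriminant Q2 of Westerhuis-type class prediction: residuals of
predictions that overshoot their own class label (beyond +1 for the positive
class, below -1 for the negative) are set to zero before computing
1 - PRESS / TSS, so a classifier is not penalised for being "too right".
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
import warnings

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedShuffleSplit

from .chemometrics import fit_oplsda, predict

__all__ = [
    "ModelConfig", "CVResult", "ConfusionMatrix", "PermutationResult",
    "loo_cv", "monte_carlo_cv", "permutation_test", "dq2", "q2",
    "roc_from_cv", "auc_rank", "confusion_metrics",
]


@dataclass(frozen=True)
class ModelConfig:
    """OPLS-DA hyperparameters shared by all folds of a CV run."""
    n_predictive: int = 1
    n_orthogonal: int = 1
    scaling: str = "uv"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with the responder (+1) class as positive."""
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def n_misclassified(self) -> int:
        return self.fp + self.fn


@dataclass
class CVResult:
    scheme: str                       # "LOO" | "MonteCarlo"
    y_true: np.ndarray                # pooled over folds / test appearances
    scores: np.ndarray                # pooled continuous out-of-fold scores
    labels: np.ndarray                # pooled hard labels
    subject_index: np.ndarray         # row of X each pooled prediction refers to
    repetition_accuracies: np.ndarray | None = None  # Monte Carlo only
    confusion: ConfusionMatrix = None
    accuracy: float = float("nan")
    dq2: float = float("nan")
    auc: float = float("nan")

    def summary(self) -> dict:
        c = self.confusion
        return {
            "scheme": self.scheme,
            "n": int(self.y_true.size) if self.scheme == "LOO" else int(np.unique(self.subject_index).size),
            "accuracy": self.accuracy,
            "sensitivity": c.sensitivity,
            "specificity": c.specificity,
            "confusion": {"TP": c.tp, "FP": c.fp, "TN": c.tn, "FN": c.fn},
            "n_misclassified": c.n_misclassified,
            "dq2": self.dq2,
            "auc": self.auc,
        }


@dataclass(frozen=True)
class PermutationResult:
    observed_accuracy: float
    permuted_accuracies: np.ndarray
    p_value: float

    @property
    def n_permutations(self) -> int:
        return self.permuted_accuracies.size

    @property
    def mean_permuted_accuracy(self) -> float:
        return float(self.permuted_accuracies.mean())


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if not np.array_equal(np.unique(y), [-1, 1]):
        raise ValueError("y must contain both classes coded -1/+1")
    return X, y


def _finalize(scheme: str, y_true, scores, labels, idx, rep_acc=None) -> CVResult:
    y_true = np.asarray(y_true, float)
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    conf = confusion_metrics(y_true, labels)
    acc = float(rep_acc.mean()) if rep_acc is not None else conf.accuracy
    res = CVResult(scheme=scheme, y_true=y_true, scores=scores, labels=labels,
                   subject_index=np.asarray(idx, int),
                   repetition_accuracies=rep_acc, confusion=conf, accuracy=acc)
    res.dq2 = dq2(y_true, scores)
    res.auc = auc_rank(y_true, scores)
    return res


def loo_cv(X: np.ndarray, y: np.ndarray, model_config: ModelConfig = ModelConfig()) -> CVResult:
    """Leave-one-out cross-validation of the OPLS-DA classifier."""
    X, y = _check_xy(X, y)
    n = y.size
    if n < 4 or min((y == 1).sum(), (y == -1).sum()) < 2:
        raise ValueError("LOO needs n >= 4 with at least 2 subjects per class")
    scores = np.empty(n)
    labels = np.empty(n, int)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        if np.unique(y[mask]).size < 2:
            raise ValueError(f"fold holding out subject {i} collapses to one class; "
                             "ensure at least 2 subjects per class")
        model = fit_oplsda(X[mask], y[mask], model_config.n_predictive,
                           model_config.n_orthogonal, model_config.scaling)
        s, l = predict(model, X[i:i + 1])
        scores[i], labels[i] = s[0], l[0]
    return _finalize("LOO", y, scores, labels, np.arange(n))


def monte_carlo_cv(X: np.ndarray, y: np.ndarray, train_fraction: float = 0.9,
                   repetitions: int = 500,
                   model_config: ModelConfig = ModelConfig(),
                   seed: int | np.random.Generator | None = 0) -> CVResult:
    """Repeated stratified random-split cross-validation (default 90/10 x 500).

    Accuracy is the mean of per-repetition accuracies; scores/labels are
    pooled over all test appearances (subjects recur across repetitions), and
    DQ2/AUC are computed on the pooled predictions.
    """
    X, y = _check_xy(X, y)
    if not (0.5 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0.5, 1)")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    splitter = StratifiedShuffleSplit(
        n_splits=repetitions, train_size=train_fraction,
        random_state=int(rng.integers(2 ** 31 - 1)))
    rep_acc = np.empty(repetitions)
    ys, ss, ls, idx = [], [], [], []
    for r, (tr, te) in enumerate(splitter.split(X, y)):
        model = fit_oplsda(X[tr], y[tr], model_config.n_predictive,
                           model_config.n_orthogonal, model_config.scaling)
        s, l = predict(model, X[te])
        rep_acc[r] = np.mean(l == y[te])
        ys.append(y[te]); ss.append(s); ls.append(l); idx.append(te)
    return _finalize("MonteCarlo", np.concatenate(ys), np.concatenate(ss),
                     np.concatenate(ls), np.concatenate(idx), rep_acc)


def _run_scheme(X, y, scheme: str, model_config: ModelConfig, rng, **kw) -> CVResult:
    if scheme == "loo":
        return loo_cv(X, y, model_config)
    if scheme == "mc":
        return monte_carlo_cv(X, y, model_config=model_config, seed=rng, **kw)
    raise ValueError(f"unknown scheme {scheme!r}; expected 'loo' or 'mc'")


def permutation_test(X: np.ndarray, y: np.ndarray, repetitions: int = 500,
                     scheme: str = "loo",
                     model_config: ModelConfig = ModelConfig(),
                     seed: int | None = 0,
                     observed: CVResult | None = None, **scheme_kw) -> PermutationResult:
    """Label-permutation test on the cross-validated accuracy.

    The full CV scheme is re-run per permutation; p uses the add-one
    estimator (1 + #{permuted >= observed}) / (B + 1), never exactly zero.
    """
    X, y = _check_xy(X, y)
    if repetitions <= 0:
        raise ValueError("repetitions must be positive")
    if repetitions < 10:
        warnings.warn("fewer than 10 permutations gives a very coarse p-value")
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = _run_scheme(X, y, scheme, model_config, rng, **scheme_kw)
    perm_acc = np.empty(repetitions)
    for b in range(repetitions):
        y_perm = rng.permutation(y)
        perm_acc[b] = _run_scheme(X, y_perm, scheme, model_config, rng, **scheme_kw).accuracy
    p = (1 + int(np.sum(perm_acc >= observed.accuracy))) / (repetitions + 1)
    return PermutationResult(observed.accuracy, perm_acc, p)


def q2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Plain predictive Q2 = 1 - PRESS/TSS on the +/-1 coded scale."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("all labels equal; Q2 undefined")
    return float(1 - np.sum((y - yhat) ** 2) / tss)


def dq2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Discriminant Q2: overshoot residuals are zeroed before 1 - PRESS/TSS.

    A residual is zeroed when the prediction lies beyond its own class label
    (y=+1 with yhat>+1, or y=-1 with yhat<-1). Consequently DQ2 >= Q2 always,
    with equality iff nothing overshoots.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat lengths differ")
    if np.unique(y).size < 2:
        raise ValueError("all labels equal; DQ2 undefined")
    e = y - yhat
    e[(y == 1) & (yhat > 1)] = 0.0
    e[(y == -1) & (yhat < -1)] = 0.0
    tss = np.sum((y - y.mean()) ** 2)
    return float(1 - np.sum(e ** 2) / tss)


def auc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formula; ties get half credit."""
    y = np.asarray(y, float)
    scores = np.asarray(scores, float)
    pos = y == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores; AUC is 0.5 by convention")
        return 0.5
    r = rankdata(scores)
    return float((r[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_from_cv(cv: CVResult) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr, threshold) over all score thresholds, plus AUC."""
    from sklearn.metrics import roc_curve

    if np.ptp(cv.scores) == 0:
        warnings.warn("constant scores; degenerate ROC, AUC 0.5")
        return np.array([[0, 0, np.inf], [1, 1, -np.inf]]), 0.5
    fpr, tpr, thr = roc_curve(cv.y_true, cv.scores, pos_label=1)
    return np.column_stack([fpr, tpr, thr]), auc_rank(cv.y_true, cv.scores)


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Confusion counts with responder (+1) as the positive class."""
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def write_report(cv: CVResult, perm: PermutationResult | None, path: str | Path) -> None:
    """Validation report as JSON plus a human-readable .txt next to it."""
    path = Path(path)
    d = cv.summary()
    if perm is not None:
        d["permutation"] = {
            "repetitions": perm.n_permutations,
            "mean_permuted_accuracy": perm.mean_permuted_accuracy,
            "p_value": perm.p_value,
        }
    path.write_text(json.dumps(d, indent=1))
    c = cv.confusion
    lines = [
        f"scheme: {cv.scheme}",
        f"accuracy: {100 * cv.accuracy:.0f}%  (misclassified {c.n_misclassified}/{c.n})",
        f"sensitivity: {100 * c.sensitivity:.0f}%   specificity: {100 * c.specificity:.0f}%",
        f"confusion [TP FP; FN TN]: [{c.tp} {c.fp}; {c.fn} {c.tn}]",
        f"DQ2: {cv.dq2:.2f}   AUC: {cv.auc:.2f}",
    ]
    if perm is not None:
        lines.append(f"permutation: mean accuracy {100 * perm.mean_permuted_accuracy:.1f}% "
                     f"over {perm.n_permutations} shuffles, p = {perm.p_value:.3g}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
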