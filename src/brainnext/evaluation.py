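"""Classifier harness: stratified k-fold cross-validation with a cubic-kernel
one-vs-all SVM by default, conventional comparator classifiers, and
confusion-matrix metrics.

"Cubic SVM" follows the common desk convention: a degree-3 polynomial kernel
(1 + gamma <x, x'>)^3 with gamma = 1/d on per-fold standardised features,
box constraint C = 1, one-vs-all coding decided by maximal decision value
(ties resolved to the lowest class index by argmax).  Overall metrics are
macro averages (unweighted over classes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from brainnext.errors import ConfigurationError, StratificationError

CLASSIFIER_KINDS = ("svm", "dt", "ld", "elr", "nb", "knn", "mlp", "rf")


@dataclass
class ClassifierConfig:
    kind: str = "svm"
    svm_degree: int = 3
    C: float = 1.0
    folds: int = 10
    stratified: bool = True
    seed: int = 0
    standardize: bool = True

    def validate(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ConfigurationError(f"unknown classifier kind {self.kind!r}")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.C <= 0:
            raise ConfigurationError("C must be > 0")


@dataclass
class EvalReport:
    confusion: np.ndarray                  # rows = truth, cols = prediction
    class_names: list[str]
    accuracy: float
    per_class: dict                        # name -> {precision, recall, f1}
    macro_precision: float
    macro_recall: float
    macro_f1: float
    fold_assignments: np.ndarray | None = None
    zero_division_warning: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "class_names": self.class_names,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def make_classifier(cfg: ClassifierConfig):
    """Instantiate the configured classifier (seeded where stochastic)."""
    cfg.validate()
    if cfg.kind == "svm":
        base = SVC(kernel="poly", degree=cfg.svm_degree, gamma="auto",
                   coef0=1.0, C=cfg.C)
        return OneVsRestClassifier(base)
    if cfg.kind == "dt":
        return DecisionTreeClassifier(random_state=cfg.seed)
    if cfg.kind == "ld":
        return LinearDiscriminantAnalysis()
    if cfg.kind == "elr":
        return LogisticRegression(max_iter=1000, random_state=cfg.seed)
    if cfg.kind == "nb":
        return GaussianNB()
    if cfg.kind == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if cfg.kind == "mlp":
        return MLPClassifier(hidden_layer_sizes=(100,), max_iter=500,
                             random_state=cfg.seed)
    if cfg.kind == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=cfg.seed)
    raise ConfigurationError(cfg.kind)


def compute_metrics(confusion: np.ndarray,
                    class_names: list[str] | None = None) -> EvalReport:
    """Per-class precision/recall/F1 and macro averages from a confusion
    matrix (rows = truth, columns = prediction).  Empty denominators yield 0
    and set ``zero_division_warning``."""
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ConfigurationError("confusion matrix must be square")
    if (cm < 0).any() or not np.issubdtype(cm.dtype, np.number):
        raise ConfigurationError("confusion matrix entries must be >= 0")
    k = cm.shape[0]
    names = class_names or [str(i) for i in range(k)]
    n = cm.sum()
    acc = float(np.trace(cm) / n) if n else 0.0
    warn = False
    per_class = {}
    precs, recs, f1s = [], [], []
    for c in range(k):
        col, row = cm[:, c].sum(), cm[c, :].sum()
        tp = cm[c, c]
        if col == 0 or row == 0:
            warn = True
        p = tp / col if col else 0.0
        r = tp / row if row else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        per_class[names[c]] = {"precision": float(p), "recall": float(r),
                               "f1": float(f1)}
        precs.append(p); recs.append(r); f1s.append(f1)
    return EvalReport(
        confusion=cm, class_names=list(names), accuracy=acc,
        per_class=per_class,
        macro_precision=float(np.mean(precs)),
        macro_recall=float(np.mean(recs)),
        macro_f1=float(np.mean(f1s)),
        zero_division_warning=warn,
    )


def cross_validate(features, y, cfg: ClassifierConfig | None = None,
                   class_names: list[str] | None = None) -> EvalReport:
    """Stratified k-fold CV with per-training-fold standardisation; pooled
    out-of-fold predictions form one confusion matrix."""
    cfg = cfg or ClassifierConfig()
    cfg.validate()
    X = features.values if hasattr(features, "values") else np.asarray(features)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = X.shape[0]
    if n < cfg.folds:
        raise StratificationError(f"n={n} < folds={cfg.folds}")
    classes, counts = np.unique(y, return_counts=True)
    if cfg.stratified and counts.min() < cfg.folds:
        raise StratificationError(
            f"class {classes[int(np.argmin(counts))]} has {counts.min()} "
            f"samples, fewer than {cfg.folds} folds")
    k = len(classes)
    lut = {c: i for i, c in enumerate(classes)}
    yi = np.array([lut[v] for v in y])
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                          random_state=cfg.seed)
    preds = np.empty(n, dtype=int)
    folds = np.empty(n, dtype=int)
    for fi, (tr, te) in enumerate(skf.split(X, yi)):
        Xtr, Xte = X[tr], X[te]
        if cfg.standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        clf = make_classifier(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xtr, yi[tr])
            preds[te] = clf.predict(Xte)
        folds[te] = fi
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (yi, preds), 1)
    names = class_names or [str(c) for c in classes]
    report = compute_metrics(cm, names)
    report.fold_assignments = folds
    return report
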