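"""Classical learning stage: feature analysis, the 13 model registry,
stratified validation, and accuracy reporting.

Feature relevance is scored by information gain,

    G(C, X) = H(C) - sum_x (|C_x| / |C|) * H(C | X = x),

with H the base-2 Shannon entropy over the three tissue classes and
continuous features discretized into 10 equal-frequency bins.  Models come
from a fixed registry of 13 configurations — 4 complex trees, 6 support
vector machines, 3 tree ensembles — mirroring an extensive classical sweep.
Accuracy is overall O = (T_NT + T_NEC + T_VT) / (N_NT + N_NEC + N_VT) and
per-class C_c = T_c / N_c from the 3x3 confusion matrix.

Model fitting itself (CART trees, libsvm SVMs, bagging, AdaBoost) is
delegated to scikit-learn behind this module's surface; the split/accuracy
arithmetic and information-theoretic analysis are native.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .expert import EXPERT_FEATURE_NAMES
from .synth import CLASS_LABELS
from .texture import TEXTURE_FEATURE_NAMES

#: Fixed order of the 61 combined features (8 expert + 53 texture).
COMBINED_FEATURE_NAMES = tuple(EXPERT_FEATURE_NAMES) + TEXTURE_FEATURE_NAMES
assert len(COMBINED_FEATURE_NAMES) == 61


# ---------------------------------------------------------------------------
# Information-theoretic feature analysis

def entropy(labels) -> float:
    """Base-2 Shannon entropy of a label sequence (0*log0 = 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def info_gain(values, labels, bins: int = 10) -> float:
    """Information gain of one feature for the class variable.

    Continuous features are discretized into ``bins`` equal-frequency bins
    (quantile edges); the gain is H(C) minus the bin-weighted conditional
    entropy.  Nonnegative up to numerical tolerance and bounded by H(C).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must have equal length")
    edges = np.unique(np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1]))
    binned = np.digitize(values, edges)
    h = entropy(labels)
    cond = 0.0
    for b in np.unique(binned):
        m = binned == b
        cond += m.mean() * entropy(labels[m])
    return h - cond


# ---------------------------------------------------------------------------
# Splits

@dataclass
class SplitPlan:
    """A stratified holdout plan: per-class train/test counts plus indices."""

    train_counts: dict[str, int]
    test_counts: dict[str, int]
    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float
    seed: int

    @property
    def n_train(self) -> int:
        return sum(self.train_counts.values())

    @property
    def n_test(self) -> int:
        return sum(self.test_counts.values())


def stratified_split(labels, fraction: float = 0.8, seed: int = 0) -> SplitPlan:
    """Stratified holdout preserving class proportions.

    Per class, the training count is floor(fraction * class total) — the
    rounding rule that reproduces the published 914/230 partition of the
    1,144-tile corpus — and the remainder goes to test.  Assignment within a
    class is randomized by ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_counts: dict[str, int] = {}
    test_counts: dict[str, int] = {}
    train_parts, test_parts = [], []
    for c in CLASS_LABELS:
        idx = np.flatnonzero(labels == c)
        n_train = int(np.floor(fraction * idx.size))
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
        train_counts[c] = n_train
        test_counts[c] = idx.size - n_train
    return SplitPlan(train_counts, test_counts,
                     np.sort(np.concatenate(train_parts)),
                     np.sort(np.concatenate(test_parts)),
                     fraction, seed)


# ---------------------------------------------------------------------------
# Model registry

@dataclass(frozen=True)
class ModelConfig:
    """One entry of the 13-model registry.

    family: "complex_tree" | "svm" | "ensemble"
    complex trees: ``max_splits`` in [30, 100], ``criterion`` gini/deviance;
    SVMs: ``kernel`` quadratic/cubic/gaussian, ``scheme`` one-vs-one /
    one-vs-all, soft-margin box constraint ``C`` (default 1, the objective's
    overfitting control);
    ensembles: ``method`` bagging/adaboost over decision-tree bases.
    """

    name: str
    family: str
    max_splits: int = 100
    criterion: str = "gini"
    kernel: str = "cubic"
    scheme: str = "one-vs-one"
    C: float = 1.0
    method: str = "bagging"
    n_estimators: int = 50


MODEL_REGISTRY: tuple[ModelConfig, ...] = (
    ModelConfig("tree_30_gini", "complex_tree", max_splits=30, criterion="gini"),
    ModelConfig("tree_30_deviance", "complex_tree", max_splits=30, criterion="deviance"),
    ModelConfig("tree_100_gini", "complex_tree", max_splits=100, criterion="gini"),
    ModelConfig("tree_100_deviance", "complex_tree", max_splits=100, criterion="deviance"),
    ModelConfig("svm_quadratic_ovo", "svm", kernel="quadratic", scheme="one-vs-one"),
    ModelConfig("svm_quadratic_ova", "svm", kernel="quadratic", scheme="one-vs-all"),
    ModelConfig("svm_cubic_ovo", "svm", kernel="cubic", scheme="one-vs-one"),
    ModelConfig("svm_cubic_ova", "svm", kernel="cubic", scheme="one-vs-all"),
    ModelConfig("svm_gaussian_ovo", "svm", kernel="gaussian", scheme="one-vs-one"),
    ModelConfig("svm_gaussian_ova", "svm", kernel="gaussian", scheme="one-vs-all"),
    ModelConfig("ensemble_bagged", "ensemble", method="bagging", n_estimators=50),
    ModelConfig("ensemble_adaboost", "ensemble", method="adaboost", n_estimators=50),
    ModelConfig("ensemble_adaboost_deep", "ensemble", method="adaboost",
                n_estimators=100, max_splits=30),
)
assert len(MODEL_REGISTRY) == 13


def _svm_kernel_args(kernel: str) -> dict:
    # Eq-6-style polynomial kernels (x.x/s + 1)^d with sklearn's "scale"
    # normalization; degree 3 is the hierarchical-classification default.
    if kernel == "quadratic":
        return dict(kernel="poly", degree=2, coef0=1.0, gamma="scale")
    if kernel == "cubic":
        return dict(kernel="poly", degree=3, coef0=1.0, gamma="scale")
    if kernel == "gaussian":
        return dict(kernel="rbf", gamma="scale")
    raise ValueError(f"unknown SVM kernel {kernel!r}")


def build_estimator(config: ModelConfig, seed: int = 0):
    """Instantiate the scikit-learn estimator for a registry entry.

    Trees split on the configured impurity criterion with a cap of
    ``max_splits`` internal splits (max_leaf_nodes = max_splits + 1); SVMs
    standardize features (z-score) before the kernel.
    """
    if config.family == "complex_tree":
        crit = "entropy" if config.criterion == "deviance" else "gini"
        return DecisionTreeClassifier(criterion=crit,
                                      max_leaf_nodes=config.max_splits + 1,
                                      random_state=seed)
    if config.family == "svm":
        svc = SVC(C=config.C, random_state=seed,
                  decision_function_shape="ovo",
                  **_svm_kernel_args(config.kernel))
        if config.scheme == "one-vs-all":
            est = OneVsRestClassifier(SVC(C=config.C, random_state=seed,
                                          **_svm_kernel_args(config.kernel)))
        else:
            est = svc
        return make_pipeline(StandardScaler(), est)
    if config.family == "ensemble":
        base = DecisionTreeClassifier(max_leaf_nodes=config.max_splits + 1,
                                      random_state=seed)
        if config.method == "bagging":
            return BaggingClassifier(estimator=base,
                                     n_estimators=config.n_estimators,
                                     random_state=seed)
        if config.method == "adaboost":
            stump = DecisionTreeClassifier(max_depth=3, random_state=seed)
            return AdaBoostClassifier(estimator=stump,
                                      n_estimators=config.n_estimators,
                                      random_state=seed)
        raise ValueError(f"unknown ensemble method {config.method!r}")
    raise ValueError(f"unknown model family {config.family!r}")


def fit(config: ModelConfig, X, y, seed: int = 0):
    """Train one registry model on a feature matrix (columns = the 61
    combined features or a selected subset)."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training labels are degenerate (single class)")
    est = build_estimator(config, seed)
    est.fit(np.asarray(X, dtype=float), y)
    return est


def predict(model, X) -> np.ndarray:
    return model.predict(np.asarray(X, dtype=float))


def predict_scores(model, X) -> pd.DataFrame:
    """Per-class scores normalized to sum 1, columns NT/NEC/VT.

    Trees and ensembles expose calibrated-ish class frequencies
    (``predict_proba``).  One-vs-one SVMs are scored by pairwise vote
    fractions; one-vs-all by softmax of the per-class margins.  The
    construction is documented because downstream ROC surfaces need a
    score, not just an argmax.
    """
    X = np.asarray(X, dtype=float)
    classes = None
    est = model
    if hasattr(model, "steps"):  # pipeline
        est = model.steps[-1][1]
    classes = list(est.classes_)
    if hasattr(est, "predict_proba") and not isinstance(est, SVC):
        probs = model.predict_proba(X)
    elif isinstance(est, SVC):
        dec = model.decision_function(X)  # ovo: (n, k*(k-1)/2)
        k = len(classes)
        votes = np.zeros((X.shape[0], k))
        col = 0
        for i in range(k):
            for j in range(i + 1, k):
                margin = dec[:, col]
                # soft vote: logistic squash of the pairwise margin
                pij = 1.0 / (1.0 + np.exp(-margin))
                votes[:, i] += pij
                votes[:, j] += 1.0 - pij
                col += 1
        probs = votes / votes.sum(axis=1, keepdims=True)
    else:  # one-vs-rest margins
        dec = model.decision_function(X)
        dec = dec - dec.max(axis=1, keepdims=True)
        e = np.exp(dec)
        probs = e / e.sum(axis=1, keepdims=True)
    df = pd.DataFrame(probs, columns=classes)
    return df[list(CLASS_LABELS)]


# ---------------------------------------------------------------------------
# Validation and accuracy

def kfold_cv(X, y, config: ModelConfig, k: int = 5, seed: int = 0) -> float:
    """Mean held-out overall accuracy over k stratified folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError("a class has fewer samples than folds")
    X = np.asarray(X, dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        model = fit(config, X[tr], y[tr], seed=seed)
        accs.append(float(np.mean(predict(model, X[te]) == y[te])))
    return float(np.mean(accs))


@dataclass
class ConfusionMatrix:
    """3x3 counts, rows = truth, cols = prediction, class order NT/NEC/VT."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=int))

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        m = np.zeros((3, 3), dtype=int)
        index = {c: i for i, c in enumerate(CLASS_LABELS)}
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            m[index[t], index[p]] += 1
        return cls(m)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """O = (T_NT + T_NEC + T_VT) / (N_NT + N_NEC + N_VT)."""
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


def class_accuracy(cm: ConfusionMatrix, c: str) -> float | None:
    """C_c = T_c / N_c; None (absent) when the class has no samples."""
    i = CLASS_LABELS.index(c)
    row = cm.counts[i].sum()
    if row == 0:
        return None
    return float(cm.counts[i, i] / row)


def feature_frame(tiles, expert_params=None, texture_config=None) -> pd.DataFrame:
    """Extract the combined 61-feature table for a list of tiles.

    Returns a DataFrame with ``tin``, ``label`` and the 61 feature columns in
    canonical order.
    """
    from .expert import ExpertParams, expert_vector
    from .texture import TextureConfig, texture_vector
    expert_params = expert_params or ExpertParams()
    texture_config = texture_config or TextureConfig()
    rows = []
    for t in tiles:
        row = {"tin": t.tin, "label": t.label}
        row.update(expert_vector(t, expert_params))
        row.update(texture_vector(t, texture_config))
        rows.append(row)
    return pd.DataFrame(rows, columns=["tin", "label", *COMBINED_FEATURE_NAMES])
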