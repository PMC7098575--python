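"""Models, transfer-learning protocol, evaluation and model comparison.

Two deep models mirror the study design: a CNN consuming gene-expression
images and an MLNN (dense network with batch normalization, dropout and
ReLU) consuming raw expression vectors.  Both are trained with the same
transfer-learning recipe: supervised pre-training on a large base cohort
set, then fine-tuning on the target cohort, optimizing the same fixed-time
progression objective in both phases, with random oversampling applied to
each phase's training data.

Evaluation follows repeated stratified k-fold cross-validation (10x5 at
full scale, i.e. 50 fold records).  The decision threshold is chosen on
training-fold scores at the ROC point maximizing sensitivity+specificity
(Youden's J) and applied to the validation fold; AUC itself is
threshold-free.  Model comparison uses one-sided paired Wilcoxon
signed-rank tests over the fold-wise AUC vectors with Hochberg step-up
correction.

Traditional ML baselines combine a dimensionality reducer (ANOVA k-best,
PCA, kernel PCA) with a classifier (logistic regression, SVM, shallow NN,
random forest), with SMOTE applied after the reducer inside each training
fold.  Hyper-parameters can be tuned jointly by a sequential Bayesian
(GP + expected-improvement) search.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA, KernelPCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import nn
from .survival_labels import random_oversample, smote_oversample

__all__ = [
    "ModelSpec",
    "CVResult",
    "Standardizer",
    "build_cnn",
    "build_mlnn",
    "pretrain_finetune",
    "repeated_cv",
    "roc_threshold",
    "classification_metrics",
    "hochberg_adjust",
    "compare_models",
    "run_ml_baseline",
    "bayesian_search",
    "make_nn_pipeline",
]

_SEED_MOD = 2**31


def _fold_seed(seed: int, repeat: int, fold: int, salt: int = 0) -> int:
    return (seed * 1_000_003 + repeat * 131 + fold * 17 + salt) % _SEED_MOD


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and phase hyper-parameters for the deep models.

    Convolution blocks are given per-block as filter counts, kernel sizes
    and pooling widths; ``dense_units`` lists the widths of the densely
    connected layers before the sigmoid output.  The phase parameters
    (learning rates, batch sizes, epochs) cover supervised pre-training and
    fine-tuning separately, since both are searched jointly.
    """

    kind: str = "cnn"  # cnn | mlnn | baseline
    conv_filters: tuple = (6,)
    kernel_sizes: tuple = (5,)
    pool_sizes: tuple = (4,)
    dense_units: tuple = (16,)
    dropout: float = 0.2
    batch_norm: bool = True
    pretrain_lr: float = 1e-3
    finetune_lr: float = 5e-4
    pretrain_epochs: int = 8
    finetune_epochs: int = 10
    pretrain_batch_size: int = 64
    finetune_batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("cnn", "mlnn", "baseline"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.pretrain_lr <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if len({len(self.conv_filters), len(self.kernel_sizes), len(self.pool_sizes)}) != 1:
            raise ValueError("conv_filters, kernel_sizes, pool_sizes must align")


def build_cnn(spec: ModelSpec, input_shape) -> nn.Sequential:
    """Build a CNN mapping an r x c single-channel image to a probability."""
    if spec.kind != "cnn":
        raise ValueError("spec.kind must be 'cnn'")
    rng = np.random.default_rng(spec.seed)
    h, w = input_shape
    layers: list = []
    c_in = 1
    for f, k, p in zip(spec.conv_filters, spec.kernel_sizes, spec.pool_sizes):
        if k > h or k > w:
            raise ValueError(f"kernel {k} larger than input {h}x{w}")
        layers += [nn.Conv2d(c_in, f, k, rng), nn.ReLU(), nn.MaxPool2d(p)]
        h, w = (h - k + 1) // p, (w - k + 1) // p
        if h == 0 or w == 0:
            raise ValueError("feature map collapsed to zero size; reduce pooling")
        c_in = f
    layers.append(nn.Flatten())
    n_feat = c_in * h * w
    for units in spec.dense_units:
        layers += [nn.Dense(n_feat, units, rng), nn.ReLU()]
        if spec.dropout > 0:
            layers.append(nn.Dropout(spec.dropout, rng))
        n_feat = units
    layers.append(nn.Dense(n_feat, 1, rng))
    return nn.Sequential(layers, input_kind="image")


def build_mlnn(spec: ModelSpec, input_length: int) -> nn.Sequential:
    """Build a dense network (batch norm + ReLU + dropout) on expression vectors."""
    if spec.kind != "mlnn":
        raise ValueError("spec.kind must be 'mlnn'")
    rng = np.random.default_rng(spec.seed)
    layers: list = []
    n_feat = input_length
    for units in spec.dense_units:
        layers.append(nn.Dense(n_feat, units, rng))
        if spec.batch_norm:
            layers.append(nn.BatchNorm1d(units))
        layers.append(nn.ReLU())
        if spec.dropout > 0:
            layers.append(nn.Dropout(spec.dropout, rng))
        n_feat = units
    layers.append(nn.Dense(n_feat, 1, rng))
    return nn.Sequential(layers, input_kind="vector")


class Standardizer:
    """Per-feature standardization fitted on training data only."""

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_


def pretrain_finetune(model_factory, base, target, spec: ModelSpec):
    """Train with the two-phase transfer-learning recipe.

    ``base`` and ``target`` are (features, labels) pairs sharing the same
    feature space.  The model is first trained on the (randomly
    oversampled) base set, then training continues on the (randomly
    oversampled) target training set with the fine-tuning learning rate and
    batch size.  Both phases optimize the same binary objective.
    """
    Xb, yb = base
    Xt, yt = target
    Xb, Xt = np.asarray(Xb), np.asarray(Xt)
    if Xb.shape[1:] != Xt.shape[1:]:
        raise ValueError(
            f"base and target feature shapes differ: {Xb.shape[1:]} vs {Xt.shape[1:]}"
        )
    model = model_factory(spec)
    if spec.pretrain_epochs > 0:
        Xb_os, yb_os = random_oversample(Xb, yb, seed=_fold_seed(spec.seed, 0, 0, 1))
        model.fit(Xb_os, yb_os, epochs=spec.pretrain_epochs, lr=spec.pretrain_lr,
                  batch_size=spec.pretrain_batch_size, seed=_fold_seed(spec.seed, 0, 0, 2))
    if spec.finetune_epochs > 0:
        Xt_os, yt_os = random_oversample(Xt, yt, seed=_fold_seed(spec.seed, 0, 0, 3))
        model.fit(Xt_os, yt_os, epochs=spec.finetune_epochs, lr=spec.finetune_lr,
                  batch_size=spec.finetune_batch_size, seed=_fold_seed(spec.seed, 0, 0, 4))
    return model


@dataclass(frozen=True)
class CVResult:
    """Fold-wise metric records from repeated stratified cross-validation.

    ``records`` has one row per (repeat, fold) with the columns repeat,
    fold, auc, sensitivity, specificity, f_measure, accuracy, mcc,
    threshold.  Results produced with identical (repeats, folds, seed) on
    the same samples are fold-wise paired.
    """

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = self.provenance.get("repeats", 0) * self.provenance.get("folds", 0)
        if expected and len(self.records) != expected:
            raise ValueError(
                f"expected {expected} fold records, got {len(self.records)}"
            )

    @property
    def auc_values(self) -> np.ndarray:
        ordered = self.records.sort_values(["repeat", "fold"])
        return ordered["auc"].to_numpy()

    def mean_auc(self) -> float:
        return float(self.records["auc"].mean())

    def summary(self) -> pd.Series:
        cols = ["auc", "sensitivity", "specificity", "f_measure", "accuracy", "mcc"]
        return self.records[cols].mean()


def roc_threshold(scores, labels) -> float:
    """Score cut maximizing sensitivity + specificity (Youden's J).

    On ties the lowest qualifying threshold is returned, which favours
    sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to choose a threshold")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # thresholds are sorted descending; the last maximal index is the lowest cut
    thr = thresholds[best[-1]]
    if np.isinf(thr):
        thr = thresholds[best[-1] + 1] if best[-1] + 1 < len(thresholds) else scores.max()
    return float(thr)


def classification_metrics(scores, labels, threshold: float) -> dict:
    """AUC plus confusion-matrix metrics at the given threshold.

    Predictions are positive where score >= threshold.  MCC uses the
    convention 0 when any marginal of the confusion matrix is empty;
    F-measure is 0 when precision + recall is 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    total = tp + fp + fn + tn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f_meas = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    acc = (tp + tn) / total if total else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    auc = (
        float(roc_auc_score(labels, scores))
        if len(np.unique(labels)) == 2
        else float("nan")
    )
    return {
        "auc": auc,
        "sensitivity": float(sens),
        "specificity": float(spec),
        "f_measure": float(f_meas),
        "accuracy": float(acc),
        "mcc": float(mcc),
    }


def repeated_cv(X, y, pipeline, repeats: int = 10, folds: int = 5, seed: int = 0,
                provenance: dict | None = None) -> CVResult:
    """Repeated stratified k-fold evaluation of a training pipeline.

    ``pipeline(X_train, y_train, X_val, seed)`` must fit every
    training-only step (resampling, reduction, the model itself) on the
    training fold and return ``(val_scores, train_scores)``.  The decision
    threshold is fitted on the training-fold scores and applied to the
    validation fold.  Returns repeats x folds records.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    if repeats < 1 or folds < 1:
        raise ValueError("repeats and folds must be >= 1")
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < folds:
        raise ValueError(
            f"each class needs at least {folds} members for {folds}-fold stratification"
        )
    rows = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=_fold_seed(seed, rep, 0))
        for fold, (tr, va) in enumerate(skf.split(X, y)):
            val_scores, train_scores = pipeline(
                X[tr], y[tr], X[va], _fold_seed(seed, rep, fold)
            )
            thr = roc_threshold(train_scores, y[tr])
            metrics = classification_metrics(val_scores, y[va], thr)
            rows.append({"repeat": rep, "fold": fold, **metrics, "threshold": thr})
    records = pd.DataFrame(rows)
    prov = {"repeats": repeats, "folds": folds, "seed": seed}
    prov.update(provenance or {})
    return CVResult(records=records, provenance=prov)


def hochberg_adjust(pvalues) -> np.ndarray:
    """Hochberg step-up adjusted p-values (monotone, >= raw, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _paired_wilcoxon_greater(x: np.ndarray, y: np.ndarray) -> float:
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(diff == 0):
        return 1.0
    return float(stats.wilcoxon(diff, alternative="greater",
                                zero_method="wilcox", mode="auto").pvalue)


def compare_models(cv_results, reference: CVResult, alternative: str = "greater") -> pd.DataFrame:
    """Paired one-sided Wilcoxon tests of the reference against each candidate.

    Fold-wise AUC vectors must be paired (same CV plan).  Returns one row
    per candidate with the raw and Hochberg-adjusted p-value of the
    hypothesis that the reference's AUC distribution is greater.
    """
    if alternative != "greater":
        raise ValueError("only alternative='greater' is supported")
    ref = reference.auc_values
    raw = []
    names = []
    for i, cand in enumerate(cv_results):
        vals = cand.auc_values
        if len(vals) != len(ref):
            raise ValueError(
                f"unpaired AUC vectors: reference has {len(ref)}, candidate {len(vals)}"
            )
        raw.append(_paired_wilcoxon_greater(ref, vals))
        names.append(cand.provenance.get("name", f"model_{i}"))
    adjusted = hochberg_adjust(raw)
    return pd.DataFrame(
        {"model": names, "p_raw": raw, "p_adjusted": adjusted}
    )


_REDUCERS = ("anova-k-best", "pca", "kpca")
_CLASSIFIERS = ("lr", "svm", "shallow-nn", "rf")


def _make_reducer(name: str, n_components: int, seed: int):
    if name == "anova-k-best":
        return SelectKBest(f_classif, k=n_components)
    if name == "pca":
        return PCA(n_components=n_components, random_state=seed)
    if name == "kpca":
        return KernelPCA(n_components=n_components, kernel="rbf", random_state=seed)
    raise ValueError(f"unknown reducer {name!r}; choose from {_REDUCERS}")


def _make_classifier(name: str, seed: int):
    if name == "lr":
        return LogisticRegression(max_iter=2000)
    if name == "svm":
        return SVC(kernel="rbf", gamma="scale", random_state=seed)
    if name == "shallow-nn":
        return MLPClassifier(hidden_layer_sizes=(32,), max_iter=800, random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {_CLASSIFIERS}")


def _scores_of(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def run_ml_baseline(reducer: str, classifier: str, X, y, repeats: int = 10,
                    folds: int = 5, seed: int = 0, n_components: int = 32,
                    smote_k: int = 5) -> CVResult:
    """Evaluate a reducer+classifier baseline under the shared CV protocol.

    Per fold: fit the reducer on the training fold, transform, balance the
    training data with SMOTE, fit the classifier, then score the untouched
    validation fold.
    """

    def pipeline(X_tr, y_tr, X_va, fold_seed):
        k = min(n_components, X_tr.shape[1])
        red = _make_reducer(reducer, k, fold_seed)
        scaler = Standardizer().fit(X_tr)
        X_tr_s, X_va_s = scaler.transform(X_tr), scaler.transform(X_va)
        if reducer == "anova-k-best":
            red.fit(X_tr_s, y_tr)
        else:
            red.fit(X_tr_s)
        Z_tr, Z_va = red.transform(X_tr_s), red.transform(X_va_s)
        k_nn = min(smote_k, int(np.bincount(y_tr).min()) - 1)
        if k_nn >= 1:
            Z_bal, y_bal = smote_oversample(Z_tr, y_tr, k_neighbors=k_nn, seed=fold_seed)
        else:
            Z_bal, y_bal = Z_tr, y_tr
        clf = _make_classifier(classifier, fold_seed)
        clf.fit(Z_bal, y_bal)
        return _scores_of(clf, Z_va), _scores_of(clf, Z_tr)

    return repeated_cv(
        X, y, pipeline, repeats=repeats, folds=folds, seed=seed,
        provenance={"name": f"{reducer}+{classifier}"},
    )


def make_nn_pipeline(spec: ModelSpec, base=None, image_shape=None,
                     standardize: bool = True):
    """Build a repeated_cv pipeline around the deep models.

    ``base`` is an optional (features, labels) pair used for supervised
    pre-training inside every fold; when omitted the model is trained on
    the target training fold only.  Image models require ``image_shape``.
    """

    def pipeline(X_tr, y_tr, X_va, fold_seed):
        fold_spec = replace(spec, seed=fold_seed)
        if standardize:
            flat = X_tr.reshape(len(X_tr), -1)
            scaler = Standardizer().fit(flat)
            X_tr_s = scaler.transform(flat).reshape(X_tr.shape)
            X_va_s = scaler.transform(X_va.reshape(len(X_va), -1)).reshape(X_va.shape)
        else:
            X_tr_s, X_va_s = X_tr, X_va
        if spec.kind == "cnn":
            shape = image_shape or X_tr.shape[1:]
            factory = lambda s: build_cnn(s, shape)
        else:
            factory = lambda s: build_mlnn(s, X_tr_s.shape[1])
        if base is not None:
            Xb, yb = base
            if standardize:
                Xb = scaler.transform(np.asarray(Xb).reshape(len(Xb), -1)).reshape(np.asarray(Xb).shape)
            model = pretrain_finetune(factory, (Xb, yb), (X_tr_s, y_tr), fold_spec)
        else:
            model = pretrain_finetune(
                factory, (X_tr_s[:0], y_tr[:0]), (X_tr_s, y_tr),
                replace(fold_spec, pretrain_epochs=0),
            )
        return model.predict_proba(X_va_s), model.predict_proba(X_tr_s)

    return pipeline


def bayesian_search(space: dict, objective, iterations: int = 10, seed: int = 0):
    """Sequential model-based maximization of ``objective`` over a box space.

    ``space`` maps parameter name to ``(low, high)`` for continuous,
    ``(low, high, "int")`` for integer, or a list of categorical choices.
    A third of the budget (at least 3 points) is random exploration; the
    rest follows expected improvement under a Matern GP surrogate.  Returns
    ``(best_config, log)`` where ``log`` is the full trial DataFrame.
    """
    if not space:
        raise ValueError("search space is empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed % _SEED_MOD)
    names = list(space)

    def sample_unit(n):
        return rng.random((n, len(names)))

    def decode(unit_row) -> dict:
        config = {}
        for u, name in zip(unit_row, names):
            spec = space[name]
            if isinstance(spec, list):  # categorical: lists; ranges: tuples
                config[name] = spec[min(int(u * len(spec)), len(spec) - 1)]
            elif len(spec) == 3 and spec[2] == "int":
                lo, hi = int(spec[0]), int(spec[1])
                config[name] = lo + min(int(u * (hi - lo + 1)), hi - lo)
            else:
                lo, hi = float(spec[0]), float(spec[1])
                config[name] = lo + u * (hi - lo)
        return config

    n_init = min(iterations, max(3, iterations // 3))
    units = [sample_unit(1)[0] for _ in range(n_init)]
    evals = [(u, float(objective(decode(u)))) for u in units]

    while len(evals) < iterations:
        U = np.array([u for u, _ in evals])
        Y = np.array([v for _, v in evals])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), alpha=1e-6, normalize_y=True,
            random_state=int(rng.integers(_SEED_MOD)),
        )
        gp.fit(U, Y)
        cand = sample_unit(256)
        mu, sigma = gp.predict(cand, return_std=True)
        best_y = Y.max()
        xi = 1e-3
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best_y - xi) / np.where(sigma > 0, sigma, 1.0)
            ei = (mu - best_y - xi) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)
            ei[sigma <= 0] = 0.0
        u_next = cand[int(np.argmax(ei))]
        evals.append((u_next, float(objective(decode(u_next)))))

    log = pd.DataFrame(
        [{**decode(u), "objective": v, "iteration": i} for i, (u, v) in enumerate(evals)]
    )
    best_u, _ = max(evals, key=lambda uv: uv[1])
    return decode(best_u), log
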