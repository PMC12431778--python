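"""Keypress decoding: split/CV protocol, manifold extraction, metrics.

The evaluation protocol mirrors standard practice for small-n neuro
decoding: repeated stratified 90/10 train/test splits; within each training
part an inner stratified k-fold cross-validation selects the decoder
configuration (grid search); minority classes are oversampled inside
training folds only, never in validation or test folds; the selected model
is refit on the full training part and scored once on the untouched test
split.  Reported metrics are averaged over split iterations.

The supervised manifold (LDA projection to n_classes - 1 dimensions)
followed by a linear discriminant classifier is the reference pipeline;
other classifiers and reducers are pluggable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, mutual_info_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import EpochWindow, FeatureMatrix, extract_epoch_features

__all__ = [
    "DecoderConfig",
    "DecodeResult",
    "ManifoldModel",
    "oversample_minority",
    "fit_manifold",
    "train_eval",
    "cv_accuracy",
    "optimize_window",
    "recode_sequence_elements",
    "decode_sequence_elements",
    "per_trial_two_class",
    "shuffle_control",
    "mrmr_importance",
]


@dataclass
class DecoderConfig:
    """Decoder family, reducer, and evaluation protocol parameters."""

    classifier: str = "lda"
    reducer: str = "lda"
    test_fraction: float = 0.10
    n_iterations: int = 8
    n_folds: int = 8
    oversample: bool = True
    seed: int = 0
    param_grid: list[dict] | None = None  # candidate classifier settings

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


#: Default hyperparameter grids searched by the inner CV.
DEFAULT_GRIDS = {
    "lda": [{"solver": "svd"}, {"solver": "lsqr", "shrinkage": "auto"}],
    "nb": [{}],
    "knn": [{"n_neighbors": 4}],
    "svm": [{"C": 1.0}, {"C": 10.0}],
    "dt": [{"max_leaf_nodes": 5}],
    "ensemble": [{"n_estimators": 100}],
}


def _make_classifier(name: str, params: dict, seed: int):
    if name == "lda":
        return LinearDiscriminantAnalysis(**params)
    if name == "nb":
        return GaussianNB(**params)
    if name == "knn":
        return KNeighborsClassifier(metric="euclidean", **params)
    if name == "svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if name == "dt":
        return DecisionTreeClassifier(random_state=seed, **params)
    if name == "ensemble":
        return RandomForestClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class DecodeResult:
    """Held-out decoding metrics, averaged over split iterations."""

    accuracy: float  # percent correct on held-out samples
    classes: list
    confusion: np.ndarray  # summed over iterations, rows = true classes
    per_class_f1: dict
    weighted_f1: float
    fn_rate: dict  # per true keypress: misses / actual count
    fp_rate: dict  # per prediction: false alarms / predicted count
    accuracy_iterations: np.ndarray | None = None
    chosen_window: EpochWindow | None = None
    importance: pd.DataFrame | None = None
    best_params: list | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "per_class_f1": {str(k): v for k, v in self.per_class_f1.items()},
            "weighted_f1": self.weighted_f1,
            "fn_rate": {str(k): v for k, v in self.fn_rate.items()},
            "fp_rate": {str(k): v for k, v in self.fp_rate.items()},
            "chosen_window": None
            if self.chosen_window is None
            else {"t": self.chosen_window.t, "dt": self.chosen_window.dt},
        }


def metrics_from_confusion(confusion: np.ndarray, classes) -> dict:
    """Accuracy, per-class F1/FN/FP and weighted F1 from a confusion matrix."""
    cm = np.asarray(confusion, dtype=float)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    diag = np.diag(cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(support > 0, diag / support, 0.0)
        precision = np.where(predicted > 0, diag / predicted, 0.0)
        f1 = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
    total = cm.sum()
    return {
        "accuracy": 100.0 * diag.sum() / total if total else np.nan,
        "per_class_f1": dict(zip(classes, f1)),
        "weighted_f1": float(np.sum(f1 * support) / support.sum()) if support.sum() else np.nan,
        "fn_rate": dict(zip(classes, 1.0 - recall)),
        "fp_rate": dict(zip(classes, 1.0 - precision)),
    }


def oversample_minority(X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Duplicate minority-class rows at random up to the majority count.

    Returns (X_res, y_res, provenance) where provenance holds the source row
    index of every output row.  Balanced input is returned unchanged.
    """
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        warnings.warn("single-class input: oversampling is a no-op")
        return X, y, np.arange(len(y))
    n_max = counts.max()
    keep = [np.arange(len(y))]
    for c, n in zip(classes, counts):
        if n < n_max:
            idx = np.flatnonzero(y == c)
            keep.append(rng.choice(idx, size=n_max - n, replace=True))
    prov = np.concatenate(keep)
    return X[prov], y[prov], prov


class ManifoldModel:
    """Dimensionality reducer fitted on training data only.

    Methods: ``none`` (identity), ``lda`` (supervised projection to at most
    n_classes - 1 dimensions), ``pca``, ``mds`` (classical/Torgerson scaling,
    equivalent to PCA scores for Euclidean dissimilarities and therefore
    equipped with an exact out-of-sample transform), and ``mrmr`` (selection
    of the top-ranked features).
    """

    def __init__(self, method: str = "lda", n_components: int | None = None):
        if method not in {"none", "lda", "pca", "mds", "mrmr"}:
            raise ValueError(f"unknown reducer {method!r}")
        self.method = method
        self.n_components = n_components
        self.fitted_ = False

    def fit(self, X: np.ndarray, y: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        n_comp = self.n_components
        if self.method == "lda":
            n_classes = len(np.unique(y))
            max_comp = n_classes - 1
            if n_comp is None:
                n_comp = max_comp
            if n_comp > max_comp:
                raise ValueError(f"lda supports at most {max_comp} components")
            est = LinearDiscriminantAnalysis(n_components=n_comp)
            try:
                est.fit(X, y)
            except np.linalg.LinAlgError:  # singular scatter: shrinkage fallback
                warnings.warn("singular within-class scatter; using shrinkage LDA")
                est = LinearDiscriminantAnalysis(
                    solver="eigen", shrinkage="auto", n_components=n_comp
                )
                est.fit(X, y)
            self._est = est
        elif self.method in {"pca", "mds"}:
            if n_comp is None:
                n_comp = min(X.shape) - 1
            n_comp = min(n_comp, min(X.shape))
            self._est = PCA(n_components=n_comp, random_state=0).fit(X)
        elif self.method == "mrmr":
            if n_comp is None:
                n_comp = max(1, X.shape[1] // 4)
            rank = mrmr_rank(X, y, n_select=n_comp)
            self._cols = rank["index"].to_numpy()[:n_comp]
        self.fitted_ = True
        self.n_components_ = n_comp
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted_:
            raise RuntimeError("ManifoldModel must be fitted before transform")
        X = np.asarray(X, dtype=float)
        if self.method == "none":
            return X
        if self.method == "mrmr":
            return X[:, self._cols]
        return self._est.transform(X)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


def fit_manifold(X: np.ndarray, y: np.ndarray, method: str = "lda",
                 n_components: int | None = None) -> ManifoldModel:
    """Fit a :class:`ManifoldModel` on training data."""
    return ManifoldModel(method, n_components).fit(X, y)


def _effective_folds(y: np.ndarray, n_folds: int) -> int:
    min_count = np.unique(y, return_counts=True)[1].min()
    if min_count < n_folds:
        warnings.warn(f"class with {min_count} samples < {n_folds} folds; reducing folds")
        return max(2, int(min_count))
    return n_folds


def _fit_score(X_tr, y_tr, X_te, y_te, config: DecoderConfig, params: dict, seed: int):
    """Oversample + reduce + classify on one train/eval split; returns (acc, pred)."""
    if config.oversample:
        X_tr, y_tr, _ = oversample_minority(X_tr, y_tr, seed=seed)
    reducer = ManifoldModel(config.reducer)
    Z_tr = reducer.fit_transform(X_tr, y_tr)
    clf = _make_classifier(config.classifier, params, seed)
    clf.fit(Z_tr, y_tr)
    pred = clf.predict(reducer.transform(X_te))
    return float(np.mean(pred == y_te)), pred


def train_eval(fm: FeatureMatrix, config: DecoderConfig) -> DecodeResult:
    """Full split/CV/oversampling protocol on a feature matrix.

    For each of ``n_iterations``: a stratified 90/10 split; an inner
    stratified k-fold grid search on the training part picks the classifier
    settings; the winner is refit on the whole training part and scored on
    the untouched test split.  The confusion matrix is summed over
    iterations and the accuracy averaged.
    """
    X, y = np.asarray(fm.X, dtype=float), np.asarray(fm.y)
    classes = list(np.unique(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = np.unique(y, return_counts=True)[1]
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples for a stratified split")
    grid = config.param_grid or DEFAULT_GRIDS[config.classifier]
    accs = np.empty(config.n_iterations)
    cm_sum = np.zeros((len(classes), len(classes)))
    best_params_per_iter = []
    for it in range(config.n_iterations):
        seed = config.seed + it
        splitter = StratifiedShuffleSplit(
            n_splits=1, test_size=config.test_fraction, random_state=seed
        )
        (tr, te), = splitter.split(X, y)
        X_tr, y_tr, X_te, y_te = X[tr], y[tr], X[te], y[te]
        n_folds = _effective_folds(y_tr, config.n_folds)
        if len(grid) == 1:
            best = grid[0]
        else:
            kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            val_scores = []
            for params in grid:
                scores = [
                    _fit_score(X_tr[a], y_tr[a], X_tr[b], y_tr[b], config, params, seed)[0]
                    for a, b in kf.split(X_tr, y_tr)
                ]
                val_scores.append(np.mean(scores))
            best = grid[int(np.argmax(val_scores))]
        acc, pred = _fit_score(X_tr, y_tr, X_te, y_te, config, best, seed)
        accs[it] = acc
        cm_sum += confusion_matrix(y_te, pred, labels=classes)
        best_params_per_iter.append(best)
    m = metrics_from_confusion(cm_sum, classes)
    return DecodeResult(
        accuracy=float(100.0 * accs.mean()),
        classes=classes,
        confusion=cm_sum,
        per_class_f1=m["per_class_f1"],
        weighted_f1=m["weighted_f1"],
        fn_rate=m["fn_rate"],
        fp_rate=m["fp_rate"],
        accuracy_iterations=100.0 * accs,
        chosen_window=fm.window,
        best_params=best_params_per_iter,
    )


def cv_accuracy(X: np.ndarray, y: np.ndarray, config: DecoderConfig | None = None,
                n_folds: int | None = None) -> float:
    """Single-pass stratified k-fold CV accuracy (fraction), used for ranking.

    Cheaper than :func:`train_eval`; used to rank regions, grow the hybrid
    space, and sweep the window grid, where only relative accuracy matters.
    """
    if config is None:
        config = DecoderConfig()
    n_folds = _effective_folds(y, n_folds or config.n_folds)
    kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    params = (config.param_grid or DEFAULT_GRIDS[config.classifier])[0]
    scores = [
        _fit_score(X[a], y[a], X[b], y[b], config, params, config.seed)[0]
        for a, b in kf.split(X, y)
    ]
    return float(np.mean(scores))


def optimize_window(
    ts,
    events: pd.DataFrame,
    grid: list[EpochWindow],
    config: DecoderConfig,
    space: str = "parcel",
    full_result: bool = True,
):
    """Select the KeyDown-locked window maximizing CV accuracy.

    Ties are broken toward the smallest width, then the smallest onset.
    Returns ``(window, DecodeResult)`` for the winning window (or
    ``(window, accuracy)`` when ``full_result`` is False).
    """
    if not grid:
        raise ValueError("window grid is empty")
    best_key = None
    best_window = None
    for w in grid:
        fm = extract_epoch_features(ts, events, w, space=space)
        acc = cv_accuracy(fm.X, fm.y, config)
        key = (-acc, w.dt, w.t)
        if best_key is None or key < best_key:
            best_key = key
            best_window = w
    fm = extract_epoch_features(ts, events, best_window, space=space)
    if full_result:
        return best_window, train_eval(fm, config)
    return best_window, -best_key[0]


FIVE_CLASS_NAMES = {1: "Little", 2: "Ring", 3: "Middle"}


def recode_sequence_elements(fm: FeatureMatrix) -> FeatureMatrix:
    """Relabel 4-class finger labels into 5 sequence-element classes.

    Index-finger keypresses split by ordinal position into Index_OP1 and
    Index_OP5; other fingers keep one class each.  Rows without an ordinal
    position (or index presses at other positions) are dropped.
    """
    op = fm.meta["ordinal_position"].to_numpy()
    y = fm.y
    labels = np.empty(len(y), dtype=object)
    keep = np.zeros(len(y), dtype=bool)
    for i in range(len(y)):
        if y[i] == 4:
            if op[i] == 1:
                labels[i], keep[i] = "Index_OP1", True
            elif op[i] == 5:
                labels[i], keep[i] = "Index_OP5", True
        elif y[i] in FIVE_CLASS_NAMES and not np.isnan(op[i]):
            labels[i], keep[i] = FIVE_CLASS_NAMES[int(y[i])], True
    return FeatureMatrix(
        X=fm.X[keep],
        y=labels[keep].astype(str),
        feature_names=fm.feature_names,
        meta=fm.meta[keep].reset_index(drop=True),
        space=fm.space,
        band=fm.band,
        window=fm.window,
    )


def decode_sequence_elements(fm: FeatureMatrix, config: DecoderConfig) -> DecodeResult:
    """5-class decoding of sequence elements (Index_OP1/Little/Middle/Ring/Index_OP5).

    Same protocol as :func:`train_eval`; oversampling is disabled because
    splitting the index keypresses by context already balances the classes.
    """
    if not set(np.unique(fm.y)) <= {"Index_OP1", "Little", "Ring", "Middle", "Index_OP5"}:
        fm = recode_sequence_elements(fm)
    cfg = DecoderConfig(**{**config.__dict__, "oversample": False})
    return train_eval(fm, cfg)


def per_trial_two_class(
    fm: FeatureMatrix,
    k: int = 5,
    config: DecoderConfig | None = None,
    classes: tuple = ("Index_OP1", "Index_OP5"),
) -> pd.DataFrame:
    """Trial-resolved 2-class CV accuracy with matched sample counts.

    Per trial the first ``k`` instances of each class (in time order) are
    retained, so that later trials do not benefit from more sequences being
    completed; trials with fewer than ``k`` instances of either class are
    reported missing.  Returns columns ``trial``, ``accuracy`` (percent),
    ``n_samples``.
    """
    if config is None:
        config = DecoderConfig(oversample=False)
    if not set(classes) <= set(np.unique(fm.y)):
        fm = recode_sequence_elements(fm)
    rows = []
    for tr in sorted(fm.meta["trial"].unique()):
        in_trial = fm.meta["trial"].to_numpy() == tr
        idx = []
        enough = True
        for c in classes:
            ci = np.flatnonzero(in_trial & (fm.y == c))
            ci = ci[np.argsort(fm.meta["onset"].to_numpy()[ci])]
            if len(ci) < k:
                enough = False
                break
            idx.append(ci[:k])
        if not enough:
            rows.append(dict(trial=int(tr), accuracy=np.nan, n_samples=0))
            continue
        idx = np.concatenate(idx)
        y_bin = fm.y[idx]
        acc = cv_accuracy(fm.X[idx], y_bin, config, n_folds=min(config.n_folds, k))
        rows.append(dict(trial=int(tr), accuracy=100.0 * acc, n_samples=len(idx)))
    return pd.DataFrame(rows)


def shuffle_control(fm: FeatureMatrix, config: DecoderConfig, n_shuffles: int = 100) -> np.ndarray:
    """Held-out accuracy distribution under label shuffling.

    A model is trained once on a stratified training split; the held-out
    labels are then permuted ``n_shuffles`` times and the fixed predictions
    rescored, estimating the chance level (~100/n_classes percent for
    balanced test sets).
    """
    X, y = np.asarray(fm.X, dtype=float), np.asarray(fm.y)
    splitter = StratifiedShuffleSplit(
        n_splits=1, test_size=config.test_fraction, random_state=config.seed
    )
    (tr, te), = splitter.split(X, y)
    params = (config.param_grid or DEFAULT_GRIDS[config.classifier])[0]
    _, pred = _fit_score(X[tr], y[tr], X[te], y[te], config, params, config.seed)
    rng = np.random.default_rng(config.seed)
    out = np.empty(n_shuffles)
    y_te = y[te]
    for i in range(n_shuffles):
        out[i] = 100.0 * np.mean(pred == rng.permutation(y_te))
    return out


def _binned(X: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Quantile-bin each column to integer codes (constant columns -> one bin)."""
    Xb = np.empty(X.shape, dtype=int)
    for j in range(X.shape[1]):
        col = X[:, j]
        qs = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
        Xb[:, j] = np.searchsorted(qs, col, side="right")
    return Xb


def mrmr_rank(X: np.ndarray, y: np.ndarray, n_select: int | None = None,
              n_bins: int = 8) -> pd.DataFrame:
    """Greedy minimum-redundancy maximum-relevance feature ranking.

    Relevance is the mutual information between the quantile-binned feature
    and the class label; redundancy is the mean mutual information with the
    already-selected features (MID criterion: relevance minus redundancy).
    Deterministic: ties break toward the lower feature index.
    """
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    if n_feat < 2:
        raise ValueError("need at least 2 features")
    if n_select is None:
        n_select = n_feat
    Xb = _binned(X, n_bins)
    relevance = np.array([mutual_info_score(Xb[:, j], y) for j in range(n_feat)])
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(n_feat)
    remaining = list(range(n_feat))
    while remaining and len(selected) < n_select:
        if selected:
            crit = relevance[remaining] - redundancy_sum[remaining] / len(selected)
        else:
            crit = relevance[remaining]
        j = remaining[int(np.argmax(crit))]
        selected.append(j)
        scores.append(float(crit.max()))
        remaining.remove(j)
        if remaining:
            mi_new = np.array([mutual_info_score(Xb[:, j], Xb[:, r]) for r in remaining])
            redundancy_sum[remaining] += mi_new
    return pd.DataFrame({"index": selected, "score": scores})


def mrmr_importance(fm: FeatureMatrix, n_bins: int = 8) -> pd.DataFrame:
    """Per-feature MRMR scores and ranking for a feature matrix."""
    rank = mrmr_rank(fm.X, fm.y, n_bins=n_bins)
    rank["feature"] = [fm.feature_names[i] for i in rank["index"]]
    rank["rank"] = np.arange(1, len(rank) + 1)
    return rank[["rank", "feature", "index", "score"]]
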