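"""Slice-level lung-presence gate and its model-selection protocol.

Phase 1 of the pipeline: decide, per axial slice, whether lung fields are
present at all, so that slices without a region of interest never reach
the segmentation stage. The selection protocol is: z-score features using
training-set statistics only, tune each classifier family by random
search with stratified 5-fold cross-validation (selecting the draw with
the highest mean validation accuracy), evaluate every extractor/classifier
combination on the held-out test set, and pick the combination with the
highest test F1 (precision-sensitivity harmonic mean).

Deep CNN feature extractors are a plugin interface here — register any
callable producing fixed-length vectors. The built-in extractor is a
deterministic hand-crafted descriptor (intensity histogram + moments +
dark-interior fraction) sufficient to separate lung from non-lung slices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import DegenerateInputError, InputError, RegistryError
from .imgdata import CTSlice, normalize_intensity

__all__ = [
    "FeatureVector",
    "Normalizer",
    "HyperparameterSpace",
    "ClassMetrics",
    "SelectionResult",
    "CLASSIFIER_FAMILIES",
    "register_extractor",
    "extract_features",
    "fit_normalizer",
    "apply_normalizer",
    "random_search_cv",
    "train_and_evaluate",
    "classification_metrics",
    "evaluate_combinations",
    "select_best_combination",
    "LungGate",
]

CLASSIFIER_FAMILIES = (
    "bayes", "mlp", "knn", "random_forest", "svm_linear", "svm_poly", "svm_rbf",
)


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    extractor_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.all(np.isfinite(v)):
            raise InputError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------- extractors

_EXTRACTORS: dict[str, Callable[[CTSlice], np.ndarray]] = {}


def register_extractor(name: str, fn: Callable[[CTSlice], np.ndarray]) -> None:
    """Register a feature-extractor plugin producing fixed-length vectors."""
    _EXTRACTORS[name] = fn


def _histogram_features(ct: CTSlice) -> np.ndarray:
    v = normalize_intensity(ct, "minmax").pixels.ravel()
    hist, _ = np.histogram(v, bins=32, range=(0.0, 1.0))
    hist = hist / v.size
    mean = float(v.mean())
    sd = float(v.std())
    skew = float(sps.skew(v)) if sd > 0 else 0.0
    kurt = float(sps.kurtosis(v)) if sd > 0 else 0.0
    nz = hist[hist > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    # dark-interior fraction: share of body pixels darker than half the
    # bright-body reference level -- large when lung fields are present
    body = v[v > 0.15]
    if body.size == 0:
        dark_frac = 0.0
    else:
        dark_frac = float(np.mean(body < 0.5 * np.quantile(body, 0.95)))
    return np.concatenate([hist, [mean, sd, skew, kurt, entropy, dark_frac]])


register_extractor("histogram", _histogram_features)


def extract_features(ct: CTSlice, extractor_id: str = "histogram") -> FeatureVector:
    """Run a registered extractor on one slice (deterministic)."""
    if extractor_id not in _EXTRACTORS:
        raise RegistryError(f"unknown extractor {extractor_id!r}; "
                            f"registered: {sorted(_EXTRACTORS)}")
    return FeatureVector(values=_EXTRACTORS[extractor_id](ct),
                         extractor_id=extractor_id)


# --------------------------------------------------------------- normalizer

@dataclass
class Normalizer:
    """Per-feature train-set mean/sd for z-scoring; constant features are
    dropped (their indices recorded in ``dropped``)."""

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray
    dropped: np.ndarray


def _stack(vectors: Sequence[FeatureVector]) -> np.ndarray:
    X = np.vstack([fv.values for fv in vectors])
    return X


def fit_normalizer(train: Sequence[FeatureVector]) -> Normalizer:
    if len(train) < 2:
        raise DegenerateInputError("need >= 2 training vectors to fit a normalizer")
    X = _stack(train)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    kept = np.flatnonzero(sd > 0)
    dropped = np.flatnonzero(sd == 0)
    return Normalizer(mean=mean[kept], sd=sd[kept], kept=kept, dropped=dropped)


def apply_normalizer(norm: Normalizer, fv: FeatureVector) -> FeatureVector:
    v = (fv.values[norm.kept] - norm.mean) / norm.sd
    return FeatureVector(values=v, extractor_id=fv.extractor_id)


def _transform_matrix(norm: Normalizer, vectors: Sequence[FeatureVector]) -> np.ndarray:
    X = _stack(vectors)
    return (X[:, norm.kept] - norm.mean) / norm.sd


# ------------------------------------------------------------ search space

@dataclass(frozen=True)
class HyperparameterSpace:
    """Printed tuning ranges per classifier family.

    MLP hidden neurons uniform integers in [2, 1001]; KNN neighbours in
    {1,3,5,7,9}; random-forest trees up to 1500; C log-uniform over
    [2^-5, 2^15]; polynomial degree in {3,5,7,9}; gamma log-uniform over
    [2^-15, 2^3]. MLP uses Adam, at most 4000 iterations, tolerance 1e-3.
    """

    mlp_neurons: tuple[int, int] = (2, 1001)
    knn_neighbors: tuple[int, ...] = (1, 3, 5, 7, 9)
    rf_max_trees: int = 1500
    c_log2_range: tuple[float, float] = (-5.0, 15.0)
    poly_degrees: tuple[int, ...] = (3, 5, 7, 9)
    gamma_log2_range: tuple[float, float] = (-15.0, 3.0)
    mlp_max_iter: int = 4000
    mlp_tol: float = 1e-3

    def sample(self, family: str, rng: np.random.Generator) -> dict:
        if family == "bayes":
            return {}
        if family == "mlp":
            return {"hidden": int(rng.integers(self.mlp_neurons[0],
                                               self.mlp_neurons[1] + 1))}
        if family == "knn":
            return {"n_neighbors": int(rng.choice(self.knn_neighbors))}
        if family == "random_forest":
            return {"n_trees": int(rng.integers(1, self.rf_max_trees + 1))}
        if family == "svm_linear":
            return {"C": float(2.0 ** rng.uniform(*self.c_log2_range))}
        if family == "svm_poly":
            return {"C": float(2.0 ** rng.uniform(*self.c_log2_range)),
                    "degree": int(rng.choice(self.poly_degrees))}
        if family == "svm_rbf":
            return {"C": float(2.0 ** rng.uniform(*self.c_log2_range)),
                    "gamma": float(2.0 ** rng.uniform(*self.gamma_log2_range))}
        raise RegistryError(f"unknown classifier family {family!r}")


def build_classifier(family: str, params: dict,
                     space: HyperparameterSpace | None = None, seed: int = 0):
    """Instantiate the sklearn estimator for one sampled draw."""
    space = space or HyperparameterSpace()
    if family == "bayes":
        return GaussianNB()
    if family == "mlp":
        return MLPClassifier(hidden_layer_sizes=(params["hidden"],),
                             solver="adam", max_iter=space.mlp_max_iter,
                             tol=space.mlp_tol, random_state=seed)
    if family == "knn":
        return KNeighborsClassifier(n_neighbors=params["n_neighbors"])
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=params["n_trees"],
                                      random_state=seed)
    if family == "svm_linear":
        return SVC(kernel="linear", C=params["C"], random_state=seed)
    if family == "svm_poly":
        return SVC(kernel="poly", C=params["C"], degree=params["degree"],
                   random_state=seed)
    if family == "svm_rbf":
        return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"],
                   random_state=seed)
    raise RegistryError(f"unknown classifier family {family!r}")


def random_search_cv(X: np.ndarray, y: np.ndarray, family: str,
                     space: HyperparameterSpace | None = None,
                     k: int = 5, n_draws: int = 60, seed: int = 0) -> dict:
    """Random hyperparameter search scored by mean stratified-CV accuracy.

    Returns the draw with the highest mean validation accuracy (ties go
    to the earliest draw). Fully deterministic under ``seed``.
    """
    space = space or HyperparameterSpace()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("both classes must be present for stratified CV")
    if n_draws < 1:
        raise InputError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    splits = list(skf.split(X, y))

    best_params: dict | None = None
    best_score = -np.inf
    for _ in range(n_draws):
        params = space.sample(family, rng)
        scores = []
        for tr, va in splits:
            clf = build_classifier(family, params, space, seed=seed % (2**31))
            clf.fit(X[tr], y[tr])
            scores.append(float(np.mean(clf.predict(X[va]) == y[va])))
        score = float(np.mean(scores))
        if score > best_score:  # strict: first draw wins ties
            best_score = score
            best_params = params
        if family == "bayes":
            break  # no hyperparameters to draw
    return {"params": best_params, "cv_accuracy": best_score}


# ------------------------------------------------------------------ metrics

@dataclass(frozen=True)
class ClassMetrics:
    """Percent-scale classification scores with their confusion counts.

    Undefined ratios (empty denominator) are NaN, reported as missing
    rather than zero.
    """

    acc: float
    sen: float
    prec: float
    spe: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int


def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> ClassMetrics:
    """Accuracy, sensitivity, precision, specificity and F1 (percent).

    F1 is the harmonic mean of precision and sensitivity,
    2*prec*sen/(prec+sen).
    """
    n = tp + fp + tn + fn
    if min(tp, fp, tn, fn) < 0 or n == 0:
        raise InputError("confusion counts must be nonnegative with positive sum")
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    prec = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    spe = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    if math.isnan(prec) or math.isnan(sen) or (prec + sen) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * prec * sen / (prec + sen)
    to_pct = lambda x: x * 100.0 if math.isfinite(x) else float("nan")
    return ClassMetrics(acc=to_pct(acc), sen=to_pct(sen), prec=to_pct(prec),
                        spe=to_pct(spe), f1=to_pct(f1),
                        tp=tp, fp=fp, tn=tn, fn=fn)


def train_and_evaluate(
    train_fv: Sequence[FeatureVector], y_train: np.ndarray,
    test_fv: Sequence[FeatureVector], y_test: np.ndarray,
    family: str,
    space: HyperparameterSpace | None = None,
    n_draws: int = 60,
    seed: int = 0,
) -> tuple[ClassMetrics, dict]:
    """Tune on the training split, refit, score on the held-out test set.

    The normalizer is fit on the training vectors only; the test set is
    transformed with those same statistics.
    """
    space = space or HyperparameterSpace()
    norm = fit_normalizer(train_fv)
    Xtr = _transform_matrix(norm, train_fv)
    Xte = _transform_matrix(norm, test_fv)
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)

    best = random_search_cv(Xtr, y_train, family, space,
                            n_draws=n_draws, seed=seed)
    clf = build_classifier(family, best["params"], space, seed=seed % (2**31))
    clf.fit(Xtr, y_train)
    pred = clf.predict(Xte)
    tp = int(np.sum((pred == 1) & (y_test == 1)))
    fp = int(np.sum((pred == 1) & (y_test == 0)))
    tn = int(np.sum((pred == 0) & (y_test == 0)))
    fn = int(np.sum((pred == 0) & (y_test == 1)))
    return classification_metrics(tp, fp, tn, fn), best


@dataclass(frozen=True)
class SelectionResult:
    extractor_id: str
    classifier_family: str
    hyperparameters: dict
    metrics: ClassMetrics
    report: pd.DataFrame


def evaluate_combinations(
    train_slices: Sequence[CTSlice], y_train: np.ndarray,
    test_slices: Sequence[CTSlice], y_test: np.ndarray,
    extractor_ids: Sequence[str] = ("histogram",),
    families: Sequence[str] = CLASSIFIER_FAMILIES,
    space: HyperparameterSpace | None = None,
    n_draws: int = 60,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every extractor/classifier combination on the test set.

    Returns the report table with one row per combination, mirroring the
    conventional columns Model / Classifier / ACC / SEN / PREC / SPE /
    F-Score (percent), plus the tuned hyperparameters.
    """
    rows = []
    for ext in extractor_ids:
        train_fv = [extract_features(s, ext) for s in train_slices]
        test_fv = [extract_features(s, ext) for s in test_slices]
        for fam in families:
            m, best = train_and_evaluate(train_fv, y_train, test_fv, y_test,
                                         fam, space, n_draws=n_draws, seed=seed)
            rows.append({
                "Model": ext, "Classifier": fam,
                "ACC": round(m.acc, 2), "SEN": round(m.sen, 2),
                "PREC": round(m.prec, 2), "SPE": round(m.spe, 2),
                "F-Score": round(m.f1, 2),
                "hyperparameters": best["params"],
                "_metrics": m,
            })
    return pd.DataFrame(rows)


def select_best_combination(report: pd.DataFrame) -> SelectionResult:
    """Pick the report row with the highest test F1.

    Ties break by higher accuracy, then lexicographic extractor id.
    """
    if report.empty:
        raise InputError("empty report table")
    df = report.dropna(subset=["F-Score"])
    if df.empty:
        raise DegenerateInputError("every F-Score is missing; cannot select")
    df = df.sort_values(["F-Score", "ACC", "Model"],
                        ascending=[False, False, True], kind="stable")
    row = df.iloc[0]
    return SelectionResult(
        extractor_id=row["Model"],
        classifier_family=row["Classifier"],
        hyperparameters=row["hyperparameters"],
        metrics=row["_metrics"],
        report=report.drop(columns=["_metrics"]),
    )


# ---------------------------------------------------------------- gate model

@dataclass
class LungGate:
    """A trained slice gate: extractor + normalizer + fitted classifier."""

    extractor_id: str
    normalizer: Normalizer
    classifier: object
    family: str
    hyperparameters: dict = field(default_factory=dict)

    @classmethod
    def fit(cls, slices: Sequence[CTSlice], labels: np.ndarray,
            extractor_id: str = "histogram", family: str = "knn",
            space: HyperparameterSpace | None = None,
            n_draws: int = 60, seed: int = 0) -> "LungGate":
        fv = [extract_features(s, extractor_id) for s in slices]
        norm = fit_normalizer(fv)
        X = _transform_matrix(norm, fv)
        y = np.asarray(labels)
        best = random_search_cv(X, y, family, space, n_draws=n_draws, seed=seed)
        clf = build_classifier(family, best["params"], space, seed=seed % (2**31))
        clf.fit(X, y)
        return cls(extractor_id=extractor_id, normalizer=norm, classifier=clf,
                   family=family, hyperparameters=best["params"] or {})

    def predict(self, ct: CTSlice) -> bool:
        fv = extract_features(ct, self.extractor_id)
        x = apply_normalizer(self.normalizer, fv).values[None, :]
        return bool(self.classifier.predict(x)[0] == 1)

    def save(self, path) -> None:
        import joblib
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "LungGate":
        import joblib
        return joblib.load(path)
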