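"""Model zoo: five algorithms, declared hyperparameter grids, grid search
and cross-validation maximizing MCC, and probability-score prediction.

The zoo combines each of the seven molecular representations with five
classifiers — Random Forest, Support Vector Machine, k-Nearest
Neighbors, Gaussian Process and Multi-Layer Perceptron.  Each algorithm
carries a fixed hyperparameter grid (cardinalities 6/5/14/5/12); grid
search evaluates every point by stratified 5-fold cross-validation on
the training set only and keeps the configuration with the highest mean
MCC, ties resolving to the earlier (lower-complexity) grid point.  The
winning configuration is refit on the full training set and emits a
probability score PS in [0,1] per compound (active call: PS > 0.5).

The SVM grid includes a Tanimoto kernel

    K(x, y) = <x,y> / (<x,x> + <y,y> - <x,y>)

which on binary fingerprints equals the Tanimoto similarity s/(a+b-s)
and extends it to the continuous hybrid vectors.  Because support
vector machines are not natively probabilistic, SVM probability scores
come from Platt-style sigmoid calibration fitted within the training
folds.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process import kernels as gp_kernels
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from cdk9screen import evaluate

ALGORITHMS = ("RF", "SVM", "KNN", "GP", "MLP")

# MLP settings that are not part of the searched grid
MLP_MAX_ITER = 150


def tanimoto_kernel_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Tanimoto (Jaccard) kernel K[i,j] = <x,y>/(<x,x>+<y,y>-<x,y>).

    Binary rows reduce to the fingerprint Tanimoto similarity; all-zero
    rows give 0 by convention.  The kernel is positive semidefinite.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    cross = X @ Y.T
    xx = np.einsum("ij,ij->i", X, X)[:, None]
    yy = np.einsum("ij,ij->i", Y, Y)[None, :]
    denom = xx + yy - cross
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
    return K


# ---------------------------------------------------------------------------
# Hyperparameter grids.  Points are declared in increasing-complexity order;
# grid search keeps the first argmax, which implements the documented
# tie-break (fewer trees / smaller k / narrower network wins ties).
# ---------------------------------------------------------------------------

def _rf_grid():
    return [
        {"n_estimators": n, "max_features": f}
        for n in (100, 500)
        for f in (None, "sqrt", "log2")
    ]


def _svm_grid():
    return [{"kernel": k} for k in ("linear", "poly", "rbf", "sigmoid", "tanimoto")]


def _knn_grid():
    return [
        {"n_neighbors": k, "weights": w}
        for k in (3, 5, 7, 9, 11, 13, 15)
        for w in ("uniform", "distance")
    ]


def _gp_grid():
    return [
        {"kernel": k}
        for k in ("DotProduct", "RationalQuadratic", "Matern", "WhiteKernel", "RBF")
    ]


def _mlp_grid():
    return [
        {"hidden_layers": l, "width": w, "batch_size": b}
        for l in (2, 3)
        for w in (100, 200, 1000)
        for b in (100, 200)
    ]


GRIDS: dict[str, list[dict]] = {
    "RF": _rf_grid(),
    "SVM": _svm_grid(),
    "KNN": _knn_grid(),
    "GP": _gp_grid(),
    "MLP": _mlp_grid(),
}

# Single-point grids for fast full-zoo runs (smoke tests, reduced pipelines)
REDUCED_GRIDS: dict[str, list[dict]] = {
    "RF": [{"n_estimators": 100, "max_features": "sqrt"}],
    "SVM": [{"kernel": "tanimoto"}],
    "KNN": [{"n_neighbors": 5, "weights": "uniform"}],
    "GP": [{"kernel": "RBF"}],
    "MLP": [{"hidden_layers": 2, "width": 100, "batch_size": 100}],
}

_GP_KERNELS = {
    "DotProduct": gp_kernels.DotProduct,
    "RationalQuadratic": gp_kernels.RationalQuadratic,
    "Matern": gp_kernels.Matern,
    "WhiteKernel": gp_kernels.WhiteKernel,
    "RBF": gp_kernels.RBF,
}


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    representation: str
    hyperparams: dict
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm}")


@dataclass
class CVResult:
    fold_mcc: list[float]
    mean: float
    sd: float


@dataclass
class GridSearchResult:
    best_params: dict
    best_mean_mcc: float
    evaluated: list[dict]  # one entry per grid point: params, mean, sd


@dataclass
class TrainedModel:
    spec: ModelSpec
    estimator: Any = field(repr=False)
    n_features: int = 0


def build_estimator(algorithm: str, params: dict, seed: int):
    """Instantiate the scikit-learn estimator for one grid point."""
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"],
            max_features=params["max_features"],
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "SVM":
        kernel = params["kernel"]
        base = SVC(
            kernel=tanimoto_kernel_matrix if kernel == "tanimoto" else kernel,
            random_state=seed,
        )
        # Platt-style sigmoid calibration fitted on training folds
        return CalibratedClassifierCV(base, method="sigmoid", cv=3, ensemble=False)
    if algorithm == "KNN":
        return KNeighborsClassifier(
            n_neighbors=params["n_neighbors"], weights=params["weights"], n_jobs=1
        )
    if algorithm == "GP":
        return GaussianProcessClassifier(
            kernel=_GP_KERNELS[params["kernel"]](), random_state=seed
        )
    if algorithm == "MLP":
        return MLPClassifier(
            hidden_layer_sizes=(params["width"],) * params["hidden_layers"],
            batch_size=params["batch_size"],
            activation="relu",
            solver="adam",
            max_iter=MLP_MAX_ITER,
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm}")


def _check_folds(y: np.ndarray, n_splits: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes present")
    if counts.min() < n_splits:
        raise ValueError(
            f"minority class has {counts.min()} members; "
            f"cannot form {n_splits} stratified folds without a degenerate fold"
        )


def five_fold_cv(
    algorithm: str,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_splits: int = 5,
) -> CVResult:
    """Stratified k-fold CV (default 5, i.e. 80/20 splits) scoring MCC.

    Folds are shuffled with the given seed, so the result is
    reproducible; refuses degenerate (single-class) folds.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    _check_folds(y, n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_mcc = []
    for train_idx, val_idx in skf.split(X, y):
        est = build_estimator(algorithm, params, seed)
        est.fit(X[train_idx], y[train_idx])
        ps = predict_ps_estimator(est, X[val_idx])
        c = evaluate.confusion_at_threshold(ps, y[val_idx], 0.5)
        fold_mcc.append(evaluate.mcc(c))
    arr = np.array(fold_mcc)
    return CVResult(fold_mcc=list(arr), mean=float(arr.mean()), sd=float(arr.std()))


def grid_search(
    algorithm: str,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    grid: Sequence[dict] | None = None,
) -> GridSearchResult:
    """Exhaustive search over the algorithm's grid, maximizing mean CV MCC.

    Every grid point is scored by the same stratified 5-fold scheme
    (tuning seed = seed + 1, independent of the assessment folds); the
    first point attaining the maximum wins, so exact ties go to the
    lower-complexity configuration declared earlier in the grid.
    """
    points = list(GRIDS[algorithm] if grid is None else grid)
    if not points:
        raise ValueError("empty grid")
    evaluated = []
    best_i, best_mean = 0, -np.inf
    for i, params in enumerate(points):
        cv = five_fold_cv(algorithm, params, X, y, seed=seed + 1)
        evaluated.append({"params": params, "mean_mcc": cv.mean, "sd_mcc": cv.sd})
        if cv.mean > best_mean:
            best_i, best_mean = i, cv.mean
    return GridSearchResult(
        best_params=points[best_i], best_mean_mcc=float(best_mean), evaluated=evaluated
    )


def fit_final(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> TrainedModel:
    """Refit the chosen configuration on the complete training set."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    est = build_estimator(spec.algorithm, spec.hyperparams, spec.seed)
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est, n_features=X.shape[1])


def predict_ps_estimator(estimator, X: np.ndarray) -> np.ndarray:
    """Probability of the active class from any fitted zoo estimator."""
    proba = estimator.predict_proba(np.asarray(X, dtype=np.float64))
    active_col = list(estimator.classes_).index(1)
    return np.clip(proba[:, active_col], 0.0, 1.0)


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Persist a trained model as a registry directory (spec.json + state)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = {
        "algorithm": model.spec.algorithm,
        "representation": model.spec.representation,
        "hyperparams": model.spec.hyperparams,
        "seed": model.spec.seed,
        "n_features": model.n_features,
    }
    (directory / "spec.json").write_text(json.dumps(spec, indent=2))
    with open(directory / "state.pkl", "wb") as fh:
        pickle.dump(model.estimator, fh)


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    spec = json.loads((directory / "spec.json").read_text())
    with open(directory / "state.pkl", "rb") as fh:
        estimator = pickle.load(fh)
    return TrainedModel(
        spec=ModelSpec(
            spec["algorithm"], spec["representation"], spec["hyperparams"], spec["seed"]
        ),
        estimator=estimator,
        n_features=spec["n_features"],
    )


def predict_ps(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Probability scores in [0,1]; the predicted label is active iff PS > 0.5."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature mismatch: model trained on {model.n_features} features, "
            f"got {X.shape[1]}"
        )
    return predict_ps_estimator(model.estimator, X)
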