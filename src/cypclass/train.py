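"""Per-isozyme single classifiers: split, preprocess, grid search, refit.

Each classifier is one (algorithm, feature set) combination: random forest
(500 trees, balanced class weights) or RBF-kernel SVM (balanced class
weights, Platt-scaled probabilities). Preprocessing drops zero-variance
columns, keeps the top ANOVA-F percentile, and z-scores non-binary columns
on the SVM path. Hyperparameters are chosen by grid search inside stratified
five-fold cross-validation, scored by the median fold MCC; the preprocessor
is refit within every fold so no validation information leaks into feature
selection or scaling.
"""

from __future__ import annotations

import enum
import itertools
import json
import statistics
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectPercentile, VarianceThreshold, f_classif
from sklearn.metrics import jaccard_score, matthews_corrcoef, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .curate import ActivityLabel, CypIsozyme, LabeledDataset
from .featurize import (
    EmbeddingTable,
    FeatureMatrix,
    FeatureSet,
    featurize_dataset,
    morgan_fingerprint,
)

DEFAULT_SEED = 42
DEFAULT_TEST_FRACTION = 0.2
RF_N_ESTIMATORS = 500
N_FOLDS = 5


class Algorithm(enum.Enum):
    RF = "RF"
    SVM = "SVM"


#: Deterministic tie-break ordering over candidate model types.
MODEL_ORDER = [
    (alg, fs) for alg in Algorithm for fs in FeatureSet
]


@dataclass(frozen=True)
class HyperparameterGrid:
    """Grid-search ranges; defaults are the full search space."""

    rf_min_samples_split: tuple = (2, 4, 8, 16, 32, 64, 128)
    rf_max_features: tuple = (0.05, 0.1, 0.2, 0.4, 0.8, "sqrt")
    svm_C: tuple = (1e-2, 1e-1, 1e0, 1e1, 1e2, 1e3)
    svm_gamma: tuple = (1e0, 1e-1, 1e-2, 1e-3, 1e-4, 1e-5)
    feature_percentile: tuple = (10, 40, 70, 100)

    def points(self, algorithm: Algorithm) -> list[dict]:
        """All hyperparameter points for one algorithm, in a fixed order."""
        if algorithm is Algorithm.RF:
            combos = itertools.product(
                self.rf_min_samples_split, self.rf_max_features, self.feature_percentile
            )
            return [
                {"min_samples_split": mss, "max_features": mf, "percentile": p}
                for mss, mf, p in combos
            ]
        combos = itertools.product(self.svm_C, self.svm_gamma, self.feature_percentile)
        return [{"C": c, "gamma": g, "percentile": p} for c, g, p in combos]


DEFAULT_GRID = HyperparameterGrid()

#: One-point grid for smoke runs and pipeline demonstrations.
FAST_GRID = HyperparameterGrid(
    rf_min_samples_split=(2,),
    rf_max_features=("sqrt",),
    svm_C=(1e1,),
    svm_gamma=(1e-2,),
    feature_percentile=(100,),
)


@dataclass(frozen=True)
class SingleClassifierSpec:
    cyp: CypIsozyme
    algorithm: Algorithm
    feature_set: FeatureSet
    seed: int = DEFAULT_SEED
    n_estimators: int = RF_N_ESTIMATORS


@dataclass
class CvResult:
    spec: SingleClassifierSpec
    chosen_params: dict
    fold_mcc: list[float]
    fold_jaccard: list[float]
    fold_auc: list[float]

    @property
    def median_mcc(self) -> float:
        return statistics.median(self.fold_mcc)

    @property
    def median_jaccard(self) -> float:
        return statistics.median(self.fold_jaccard)

    @property
    def median_auc(self) -> float:
        return statistics.median(self.fold_auc)


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

def split_train_test(
    dataset: LabeledDataset,
    cyp: CypIsozyme,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    seed: int = DEFAULT_SEED,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stratified shuffled split of a per-isozyme labeled subset.

    Returns (train_indices, test_indices, y) where y is the binary label
    vector (1 = substrate) over the subset's row order and the index arrays
    partition ``range(len(subset))``.
    """
    labels = dataset.labels_for(cyp)
    if any(l is ActivityLabel.MISSING for l in labels):
        raise ValueError("split requires a subset with defined labels only")
    y = np.array([1 if l is ActivityLabel.SUBSTRATE else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError(f"single-class data for {cyp}; cannot stratify")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, shuffle=True, stratify=y, random_state=seed
    )
    return train_idx, test_idx, y


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


class NonBinaryScaler(BaseEstimator, TransformerMixin):
    """Z-score columns that are not binary in the training data; leave
    binary ({0,1}-valued) columns untouched. Training statistics only."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.is_binary_ = np.array(
            [np.all(np.isin(X[:, j], (0.0, 1.0))) for j in range(X.shape[1])]
        )
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        self.scale_ = std
        self.mean_[self.is_binary_] = 0.0
        self.scale_[self.is_binary_] = 1.0
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_


def build_preprocessor(
    X: np.ndarray,
    y: np.ndarray,
    percentile: int,
    standardize: bool = False,
) -> Pipeline:
    """Fit variance filter + ANOVA-F percentile selector (+ optional scaler).

    Zero-variance columns are removed first; the top ``percentile`` percent
    of the remaining columns, ranked by the one-way ANOVA F statistic between
    the two classes, are kept.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0 or not np.any(X.std(axis=0) > 0):
        raise ValueError("all feature columns are constant")
    steps = [
        ("variance", VarianceThreshold(threshold=0.0)),
        ("select", SelectPercentile(f_classif, percentile=percentile)),
    ]
    if standardize:
        steps.append(("scale", NonBinaryScaler()))
    pipe = Pipeline(steps)
    # a perfectly separating feature has zero within-class variance; its
    # infinite F score is a valid "keep first" signal, not an error
    with np.errstate(divide="ignore", invalid="ignore"):
        pipe.fit(X, y)
    return pipe


def selected_feature_names(preprocessor: Pipeline, names: list[str]) -> list[str]:
    """Feature names surviving the variance and percentile filters."""
    mask = preprocessor.named_steps["variance"].get_support()
    kept = [n for n, m in zip(names, mask) if m]
    mask2 = preprocessor.named_steps["select"].get_support()
    return [n for n, m in zip(kept, mask2) if m]


# ---------------------------------------------------------------------------
# Learners
# ---------------------------------------------------------------------------

def make_learner(spec: SingleClassifierSpec, params: dict):
    if spec.algorithm is Algorithm.RF:
        return RandomForestClassifier(
            n_estimators=spec.n_estimators,
            class_weight="balanced",
            min_samples_split=params["min_samples_split"],
            max_features=params["max_features"],
            random_state=spec.seed,
            n_jobs=1,
        )
    return SVC(
        kernel="rbf",
        class_weight="balanced",
        C=params["C"],
        gamma=params["gamma"],
        probability=True,
        random_state=spec.seed,
    )


def _fold_metrics(y_true, y_pred, y_proba) -> tuple[float, float, float]:
    mcc = matthews_corrcoef(y_true, y_pred)
    jac = jaccard_score(y_true, y_pred, pos_label=1, zero_division=0)
    auc = (
        roc_auc_score(y_true, y_proba) if len(np.unique(y_true)) == 2 else float("nan")
    )
    return float(mcc), float(jac), float(auc)


def grid_search_cv(
    spec: SingleClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperparameterGrid = DEFAULT_GRID,
) -> CvResult:
    """Stratified five-fold grid search scored by median fold MCC.

    The preprocessor (variance filter, percentile selector, scaler for SVM)
    is refit inside each fold on that fold's training portion only. The
    returned result carries the per-fold MCC/Jaccard/AUC of the winning
    hyperparameter point; ties go to the earlier point in grid order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    minority = int(min(np.sum(y == 1), np.sum(y == 0)))
    if minority < N_FOLDS:
        raise ValueError(
            f"minority class has {minority} members; need >= {N_FOLDS} for "
            f"{N_FOLDS}-fold stratified CV"
        )
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X, y))
    standardize = spec.algorithm is Algorithm.SVM

    best: tuple[float, int] | None = None  # (median mcc, -index) for argmax
    best_result: CvResult | None = None
    for point_idx, params in enumerate(grid.points(spec.algorithm)):
        fold_mcc, fold_jac, fold_auc = [], [], []
        for train_rows, val_rows in folds:
            prep = build_preprocessor(
                X[train_rows], y[train_rows], params["percentile"], standardize
            )
            Xt = prep.transform(X[train_rows])
            Xv = prep.transform(X[val_rows])
            learner = make_learner(spec, params)
            learner.fit(Xt, y[train_rows])
            proba = learner.predict_proba(Xv)[:, list(learner.classes_).index(1)]
            pred = (proba > 0.5).astype(int)
            m, j, a = _fold_metrics(y[val_rows], pred, proba)
            fold_mcc.append(m)
            fold_jac.append(j)
            fold_auc.append(a)
        median = statistics.median(fold_mcc)
        if best is None or median > best[0]:
            best = (median, point_idx)
            best_result = CvResult(
                spec=spec,
                chosen_params=dict(params),
                fold_mcc=fold_mcc,
                fold_jaccard=fold_jac,
                fold_auc=fold_auc,
            )
    assert best_result is not None
    return best_result


@dataclass
class TrainedClassifier:
    """A refit single classifier plus everything needed at predict time."""

    spec: SingleClassifierSpec
    params: dict
    preprocessor: Pipeline
    learner: object
    feature_names: list[str]
    train_fingerprints: np.ndarray  # Morgan2 fingerprints for the AD check
    cv_result: CvResult | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Substrate-class probability for each row of raw features."""
        Xt = self.preprocessor.transform(np.asarray(X, dtype=float))
        proba = self.learner.predict_proba(Xt)
        return proba[:, list(self.learner.classes_).index(1)]

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        """Binary labels (1 = substrate) at the 0.5 probability threshold."""
        return (self.predict_proba(X) > 0.5).astype(int)


def train_final(
    spec: SingleClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    params: dict,
    train_smiles: list[str] | None = None,
    feature_names: list[str] | None = None,
    cv_result: CvResult | None = None,
) -> TrainedClassifier:
    """Refit preprocessor and learner on the full training split.

    SVM probabilities come from an internal cross-validated sigmoid (Platt)
    fit, seeded by the spec. ``train_smiles`` provides the structures whose
    Morgan2 fingerprints define the applicability domain.
    """
    X = np.asarray(X, dtype=float)
    standardize = spec.algorithm is Algorithm.SVM
    prep = build_preprocessor(X, y, params["percentile"], standardize)
    learner = make_learner(spec, params)
    learner.fit(prep.transform(X), y)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    kept = selected_feature_names(prep, list(feature_names))
    if train_smiles:
        from .curate import MoleculeRecord

        fps = np.array(
            [
                morgan_fingerprint(MoleculeRecord(record_id=s, smiles_canonical=s))
                for s in train_smiles
            ],
            dtype=np.uint8,
        )
    else:
        fps = np.zeros((0, 2048), dtype=np.uint8)
    return TrainedClassifier(
        spec=spec,
        params=dict(params),
        preprocessor=prep,
        learner=learner,
        feature_names=kept,
        train_fingerprints=fps,
        cv_result=cv_result,
    )


def select_best_model(candidates: list[CvResult]) -> CvResult:
    """Best candidate by median CV MCC; ties break by the fixed
    (algorithm, feature set) ordering."""
    if not candidates:
        raise ValueError("no candidate models to select from")

    def sort_key(res: CvResult):
        order = MODEL_ORDER.index((res.spec.algorithm, res.spec.feature_set))
        return (-res.median_mcc, order)

    return sorted(candidates, key=sort_key)[0]


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------

def save_bundle(model: TrainedClassifier, directory) -> None:
    """Persist a JSON manifest plus serialized learner state."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "cyp": model.spec.cyp.value,
        "algorithm": model.spec.algorithm.value,
        "feature_set": model.spec.feature_set.value,
        "seed": model.spec.seed,
        "n_estimators": model.spec.n_estimators,
        "params": model.params,
        "selected_features": model.feature_names,
        "cv": None
        if model.cv_result is None
        else {
            "chosen_params": model.cv_result.chosen_params,
            "fold_mcc": model.cv_result.fold_mcc,
            "fold_jaccard": model.cv_result.fold_jaccard,
            "fold_auc": model.cv_result.fold_auc,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(
        {
            "preprocessor": model.preprocessor,
            "learner": model.learner,
            "train_fingerprints": model.train_fingerprints,
        },
        directory / "state.joblib",
    )


def load_bundle(directory) -> TrainedClassifier:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    state = joblib.load(directory / "state.joblib")
    spec = SingleClassifierSpec(
        cyp=CypIsozyme(manifest["cyp"]),
        algorithm=Algorithm(manifest["algorithm"]),
        feature_set=FeatureSet(manifest["feature_set"]),
        seed=manifest["seed"],
        n_estimators=manifest["n_estimators"],
    )
    cv = None
    if manifest["cv"] is not None:
        cv = CvResult(
            spec=spec,
            chosen_params=manifest["cv"]["chosen_params"],
            fold_mcc=manifest["cv"]["fold_mcc"],
            fold_jaccard=manifest["cv"]["fold_jaccard"],
            fold_auc=manifest["cv"]["fold_auc"],
        )
    return TrainedClassifier(
        spec=spec,
        params=manifest["params"],
        preprocessor=state["preprocessor"],
        learner=state["learner"],
        feature_names=manifest["selected_features"],
        train_fingerprints=state["train_fingerprints"],
        cv_result=cv,
    )


# ---------------------------------------------------------------------------
# Convenience: train one classifier end to end on a per-isozyme subset
# ---------------------------------------------------------------------------

def train_classifier(
    dataset: LabeledDataset,
    spec: SingleClassifierSpec,
    grid: HyperparameterGrid = DEFAULT_GRID,
    test_fraction: float = DEFAULT_TEST_FRACTION,
    embedding_table: EmbeddingTable | None = None,
) -> tuple[TrainedClassifier, np.ndarray, np.ndarray, FeatureMatrix]:
    """Split, grid-search, and refit one classifier on a labeled subset.

    Returns the trained model, the train/test index arrays (into the
    per-isozyme subset row order), and the full feature matrix.
    """
    subset = dataset.subset_for(spec.cyp)
    train_idx, test_idx, y = split_train_test(
        subset, spec.cyp, test_fraction=test_fraction, seed=spec.seed
    )
    features = featurize_dataset(subset, spec.feature_set, embedding_table)
    X = features.values.to_numpy(dtype=float)
    cv = grid_search_cv(spec, X[train_idx], y[train_idx], grid)
    model = train_final(
        spec,
        X[train_idx],
        y[train_idx],
        cv.chosen_params,
        train_smiles=[subset.records[i].smiles_canonical for i in train_idx],
        feature_names=list(features.values.columns),
        cv_result=cv,
    )
    return model, train_idx, test_idx, features
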