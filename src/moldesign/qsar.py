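"""Fingerprint QSAR models: features, selection, tuned SVM/RF/GBDT, metrics.

Molecules are encoded as fixed-length binary fingerprints (topological, ECFP4,
Avalon at 1024 bits; Morgan at 2048 bits). Optional feature selection uses a
plug-in mutual-information ranking or an L1 (lasso) fit whose zeroed
coefficients drop columns. Classifiers/regressors from the SVM, random-forest
and gradient-boosting families are tuned by seeded random search over the
stated hyperparameter spaces with fivefold cross-validation; the selection
objective is the mean of train- and test-fold accuracy for classification and
the mean test-fold RMSE for regression. Feature selection is re-fit inside
every training fold so CV scores stay leakage-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold
from sklearn.svm import SVC, SVR

from .corpus import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintSpec",
    "SearchSpace",
    "CVReport",
    "compute_fingerprint",
    "fingerprint_matrix",
    "mutual_information",
    "select_features",
    "tune_and_fit",
    "classification_metrics",
    "regression_metrics",
    "ActivityModel",
]


@dataclass(frozen=True)
class FingerprintSpec:
    """A named standard fingerprint with its fixed parameters."""

    kind: str = "ecfp4"  # rdkit_topological | ecfp4 | avalon | morgan2048
    min_path: int = 1
    max_path: int = 7
    radius: int = 2
    use_chirality: bool = False

    @property
    def n_bits(self) -> int:
        return 2048 if self.kind == "morgan2048" else 1024


def compute_fingerprint(record, spec: FingerprintSpec | None = None) -> np.ndarray:
    """Deterministic 0/1 vector of length ``spec.n_bits`` for one molecule."""
    spec = spec or FingerprintSpec()
    smiles = record.canonical_smiles if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid molecule: {smiles!r}")
    if spec.kind == "rdkit_topological":
        fp = Chem.RDKFingerprint(
            mol, minPath=spec.min_path, maxPath=spec.max_path, fpSize=spec.n_bits
        )
    elif spec.kind == "ecfp4":
        fp = AllChem.GetMorganFingerprintAsBitVect(
            mol, radius=spec.radius, nBits=spec.n_bits, useChirality=spec.use_chirality
        )
    elif spec.kind == "avalon":
        from rdkit.Avalon import pyAvalonTools

        fp = pyAvalonTools.GetAvalonFP(mol, nBits=spec.n_bits)
    elif spec.kind == "morgan2048":
        fp = AllChem.GetMorganFingerprintAsBitVect(
            mol, radius=spec.radius, nBits=spec.n_bits, useChirality=spec.use_chirality
        )
    else:
        raise ValueError(f"unknown fingerprint kind: {spec.kind}")
    arr = np.zeros(spec.n_bits, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def fingerprint_matrix(smiles: Sequence, spec: FingerprintSpec | None = None) -> np.ndarray:
    spec = spec or FingerprintSpec()
    return np.array([compute_fingerprint(s, spec) for s in smiles])


def mutual_information(feature, labels) -> float:
    """Plug-in mutual information (natural log) between two binary vectors.

    MI = sum_{z,y} p(z,y) log( p(z,y) / (p(z) p(y)) ), with 0 log 0 := 0.
    """
    z = np.asarray(feature).astype(int)
    y = np.asarray(labels).astype(int)
    if z.shape != y.shape or z.size == 0:
        raise ValueError("feature and labels must be equal-length, nonempty")
    n = z.size
    mi = 0.0
    for zv in (0, 1):
        pz = np.mean(z == zv)
        for yv in (0, 1):
            pzy = np.sum((z == zv) & (y == yv)) / n
            py = np.mean(y == yv)
            if pzy > 0:
                mi += pzy * np.log(pzy / (pz * py))
    return float(max(mi, 0.0))


def select_features(
    matrix,
    labels,
    method: str = "mi",
    top_k: int = 256,
    lasso_alphas=None,
    seed: int = 0,
) -> np.ndarray:
    """Return selected column indices.

    mi: columns ranked by mutual information with the labels, top_k kept
    (constant columns have MI 0 and rank last). lasso: L1 linear fits over an
    alpha grid of 0.001..0.1 in steps of 0.001; the alpha with the best
    fivefold CV score is used and columns with nonzero coefficients are kept.
    """
    X = np.asarray(matrix)
    y = np.asarray(labels)
    if X.size == 0:
        raise ValueError("empty feature matrix")
    if not X.any():
        raise ValueError("all-zero feature matrix")
    if method == "mi":
        scores = np.array([mutual_information(X[:, j], y) for j in range(X.shape[1])])
        order = np.argsort(-scores, kind="stable")
        keep = order[: min(top_k, X.shape[1])]
        return np.sort(keep[scores[keep] > 0.0])
    if method == "lasso":
        alphas = (
            np.arange(1, 101) * 0.001 if lasso_alphas is None else np.asarray(lasso_alphas)
        )
        from sklearn.linear_model import LassoCV

        model = LassoCV(alphas=alphas, cv=5, random_state=seed, max_iter=5000)
        model.fit(X, y.astype(float))
        return np.flatnonzero(model.coef_ != 0.0)
    raise ValueError(f"unknown selection method: {method}")


@dataclass
class SearchSpace:
    """Hyperparameter distributions for the three model families."""

    svm_c: tuple[float, float] = (0.001, 1000.0)  # log-uniform
    svm_kernels: tuple[str, ...] = ("linear", "rbf", "sigmoid", "poly")
    svm_gamma: tuple[float, float] = (0.0001, 8.0)  # log-uniform, or 1/n_features
    rf_n_trees: tuple[int, int] = (50, 100)
    rf_max_depth: tuple[int, int] = (5, 30)
    rf_max_features: tuple[int, int] = (5, 20)
    gbdt_n_trees: tuple[int, int] = (50, 100)
    gbdt_max_depth: tuple[int, int] = (5, 20)
    gbdt_learning_rate: tuple[float, float] = (0.05, 0.15)
    gbdt_subsample: tuple[float, float] = (0.7, 1.0)

    def sample(self, family: str, task: str, rng: np.random.Generator, seed: int):
        if family == "svm":
            params = {
                "C": float(np.exp(rng.uniform(*np.log(self.svm_c)))),
                "kernel": str(rng.choice(self.svm_kernels)),
            }
            gamma = (
                "auto"  # 1 / n_features
                if rng.random() < 0.2
                else float(np.exp(rng.uniform(*np.log(self.svm_gamma))))
            )
            params["gamma"] = gamma
            est = SVC(**params, random_state=seed) if task == "classify" else SVR(**params)
        elif family == "rf":
            params = {
                "n_estimators": int(rng.integers(self.rf_n_trees[0], self.rf_n_trees[1] + 1)),
                "max_depth": int(rng.integers(self.rf_max_depth[0], self.rf_max_depth[1] + 1)),
                "max_features": int(
                    rng.integers(self.rf_max_features[0], self.rf_max_features[1] + 1)
                ),
            }
            cls = RandomForestClassifier if task == "classify" else RandomForestRegressor
            est = cls(**params, random_state=seed)
        elif family == "gbdt":
            params = {
                "n_estimators": int(
                    rng.integers(self.gbdt_n_trees[0], self.gbdt_n_trees[1] + 1)
                ),
                "max_depth": int(
                    rng.integers(self.gbdt_max_depth[0], self.gbdt_max_depth[1] + 1)
                ),
                "learning_rate": float(rng.uniform(*self.gbdt_learning_rate)),
                "subsample": float(rng.uniform(*self.gbdt_subsample)),
            }
            cls = GradientBoostingClassifier if task == "classify" else GradientBoostingRegressor
            est = cls(**params, random_state=seed)
        else:
            raise ValueError(f"unknown family: {family}")
        return est, params


@dataclass
class CVReport:
    """Fold-level and mean metrics of the winning configuration."""

    task: str
    chosen_params: dict
    fold_metrics: list[dict]
    mean_metrics: dict
    objective: float
    n_trials: int
    seed: int


def classification_metrics(y_pred, y_true) -> tuple[float, float]:
    """(accuracy, F1): Acc = (TP+TN)/all, F1 = 2TP / (2TP + FN + FP)."""
    y_pred = np.asarray(y_pred).astype(int)
    y_true = np.asarray(y_true).astype(int)
    if y_pred.size == 0 or y_pred.shape != y_true.shape:
        raise ValueError("predictions and labels must be equal-length, nonempty")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    acc = (tp + tn) / (tp + fp + tn + fn)
    f1 = 2 * tp / (2 * tp + fn + fp) if (2 * tp + fn + fp) > 0 else 0.0
    return float(acc), float(f1)


def regression_metrics(y_pred, y_true) -> tuple[float, float, float]:
    """(MRE, MAE, RMSE); MRE divides by y_true and rejects zeros."""
    y_pred = np.asarray(y_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    if y_pred.size == 0 or y_pred.shape != y_true.shape:
        raise ValueError("predictions and targets must be equal-length, nonempty")
    if np.any(y_true == 0):
        raise ValueError("y_true contains zeros; MRE is undefined")
    err = y_pred - y_true
    mre = float(np.mean(np.abs(err) / np.abs(y_true)))
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    return mre, mae, rmse


def _fold_metrics(task, model, Xtr, ytr, Xte, yte):
    if task == "classify":
        acc_tr, _ = classification_metrics(model.predict(Xtr), ytr)
        acc_te, f1_te = classification_metrics(model.predict(Xte), yte)
        return {"train_accuracy": acc_tr, "accuracy": acc_te, "f1": f1_te}
    mre, mae, rmse = regression_metrics(model.predict(Xte), yte)
    return {"mre": mre, "mae": mae, "rmse": rmse}


def tune_and_fit(
    features,
    y,
    family: str = "gbdt",
    task: str = "classify",
    space: SearchSpace | None = None,
    n_trials: int = 50,
    seed: int = 0,
    feature_selection: str | None = None,
    n_folds: int = 5,
):
    """Seeded random search over the family's space with fivefold CV.

    Classification maximises the mean of train- and test-fold accuracy;
    regression minimises mean test-fold RMSE. The winner is refit on all data.
    Returns (fitted model, CVReport, selected feature indices or None).
    """
    X = np.asarray(features)
    y = np.asarray(y)
    space = space or SearchSpace()
    if task == "classify":
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("labels are single-class; cannot fit a classifier")
        if counts.min() < n_folds:
            raise ValueError(f"need >= {n_folds} samples per class for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    folds = list(KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(X))
    best = None
    for trial in range(n_trials):
        est, params = space.sample(family, task, rng, seed)
        fold_stats = []
        for tr, te in folds:
            Xtr, Xte = X[tr], X[te]
            if feature_selection is not None:
                cols = select_features(Xtr, y[tr], method=feature_selection, seed=seed)
                if cols.size == 0:
                    cols = np.arange(X.shape[1])
                Xtr, Xte = Xtr[:, cols], Xte[:, cols]
            m = clone(est)
            m.fit(Xtr, y[tr])
            fold_stats.append(_fold_metrics(task, m, Xtr, y[tr], Xte, y[te]))
        if task == "classify":
            objective = float(
                np.mean([(f["train_accuracy"] + f["accuracy"]) / 2 for f in fold_stats])
            )
            better = best is None or objective > best[0]
        else:
            objective = float(np.mean([f["rmse"] for f in fold_stats]))
            better = best is None or objective < best[0]
        if better:
            best = (objective, est, params, fold_stats)
    objective, est, params, fold_stats = best
    cols = None
    if feature_selection is not None:
        cols = select_features(X, y, method=feature_selection, seed=seed)
        if cols.size == 0:
            cols = np.arange(X.shape[1])
    final = clone(est)
    final.fit(X if cols is None else X[:, cols], y)
    mean_metrics = {
        k: float(np.mean([f[k] for f in fold_stats])) for k in fold_stats[0]
    }
    report = CVReport(
        task=task,
        chosen_params=params,
        fold_metrics=fold_stats,
        mean_metrics=mean_metrics,
        objective=objective,
        n_trials=n_trials,
        seed=seed,
    )
    return final, report, cols


class ActivityModel(BaseEstimator):
    """Fingerprint QSAR estimator: SMILES in, activity out.

    ``fit(smiles, y)`` computes fingerprints, optionally selects features,
    tunes the chosen family by seeded random search with fivefold CV, and
    refits on all data. ``predict(smiles)`` returns labels (classify) or
    pIC50 values (regress).
    """

    def __init__(
        self,
        fingerprint: str = "ecfp4",
        family: str = "gbdt",
        task: str = "classify",
        feature_selection: str | None = None,
        n_trials: int = 20,
        seed: int = 0,
    ):
        self.fingerprint = fingerprint
        self.family = family
        self.task = task
        self.feature_selection = feature_selection
        self.n_trials = n_trials
        self.seed = seed

    def fit(self, X, y):
        spec = FingerprintSpec(kind=self.fingerprint)
        feats = fingerprint_matrix(list(X), spec)
        self.model_, self.cv_report_, self.selected_features_ = tune_and_fit(
            feats,
            np.asarray(y),
            family=self.family,
            task=self.task,
            n_trials=self.n_trials,
            seed=self.seed,
            feature_selection=self.feature_selection,
        )
        self.spec_ = spec
        return self

    def predict(self, X):
        feats = fingerprint_matrix(list(X), self.spec_)
        if self.selected_features_ is not None:
            feats = feats[:, self.selected_features_]
        return self.model_.predict(feats)
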