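"""Model suite: penalized logistic regression core plus tuned comparators.

The central estimator is an L1-penalized (lasso) logistic regression in the
glmnet parameterisation: the objective is ``(1/n) * negative log-likelihood
+ lambda * ||beta||_1`` with an unpenalised intercept and columns scaled to
unit (population) standard deviation, so coefficients are reported on the
original scale and shrink exactly to zero.  The penalty ``lambda`` is tuned
on a data-driven descending log grid by stratified 10-fold cross-validation
minimising misclassification error at the 0.5 probability cutoff; exact
ties are broken toward the largest (most parsimonious) lambda.

Comparators — unpenalised multivariable logistic regression (MLR), random
forest (RF), gradient-boosted trees (XGB) and two support vector machines
(SVM-L, SVM-R) — share a uniform fit/predict-probability contract and are
tuned by grid-search cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureMatrix

MODEL_TAGS = ("MLR", "LLR", "RF", "XGB", "SVM-L", "SVM-R")


class SchemaError(ValueError):
    """Prediction-time feature columns do not match the training schema."""


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_dataset(fm: FeatureMatrix, spec: SplitSpec = SplitSpec()) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Random disjoint/exhaustive split; train size = floor(fraction * N)."""
    n = fm.n_patients
    if n < 10:
        raise ValueError("need at least 10 patients to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(spec.train_fraction * n))
    return fm.subset(np.sort(perm[:n_train])), fm.subset(np.sort(perm[n_train:]))


@dataclass
class CoefficientSet:
    """Named log-odds coefficients from a fitted binary-outcome model."""

    intercept: float
    coefficients: dict[str, float]
    lam: float | None = None
    model_tag: str = "LLR"

    def odds_ratio(self, name: str) -> float:
        return float(np.exp(self.coefficients.get(name, 0.0)))

    def nonzero(self) -> dict[str, float]:
        return {k: v for k, v in self.coefficients.items() if v != 0.0}


def _as_matrix(X) -> tuple[sp.csr_matrix, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        return sp.csr_matrix(X.to_numpy(dtype=np.float64)), names
    X = np.asarray(X, dtype=np.float64)
    return sp.csr_matrix(X), [f"x{i}" for i in range(X.shape[1])]


class PenalizedLogisticRegression(BaseEstimator, ClassifierMixin):
    """Lasso logistic regression with a CV-tuned penalty.

    Parameters
    ----------
    fixed_lambda : float, optional
        Skip cross-validation and fit at this penalty.
    n_lambdas, lambda_min_ratio : grid of ``n_lambdas`` log-spaced penalties
        descending from the smallest all-zeroing value ``lambda_max``.
    cv : number of stratified folds for tuning (default 10).
    criterion : "class" (misclassification at the 0.5 cutoff) or "deviance".

    Fitted attributes: ``lambda_``, ``coef_``, ``intercept_``,
    ``coefficients_`` (name -> beta on the original scale, exact zeros
    preserved), ``cv_errors_``, ``lambda_grid_``, ``nonzero_features_``.
    """

    def __init__(
        self,
        fixed_lambda: float | None = None,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        cv: int = 10,
        criterion: str = "class",
        tol: float = 1e-7,
        max_iter: int = 1000,
        cv_tol: float = 1e-2,
        cv_max_iter: int = 100,
        random_state: int | None = 0,
    ):
        self.fixed_lambda = fixed_lambda
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.criterion = criterion
        self.tol = tol
        self.max_iter = max_iter
        self.cv_tol = cv_tol
        self.cv_max_iter = cv_max_iter
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _scale(self, X: sp.csr_matrix) -> tuple[sp.csr_matrix, np.ndarray]:
        # unit population-sd columns without centering: with a free
        # intercept this is equivalent to full standardization for an
        # L1-penalised linear model
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
        sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
        sd[sd == 0] = 1.0
        return X @ sp.diags(1.0 / sd), sd

    @staticmethod
    def _lambda_max(Xs: sp.csr_matrix, y: np.ndarray) -> float:
        resid = y - y.mean()
        return float(np.abs(Xs.T @ resid).max() / len(y))

    def _make_grid(self, Xs, y) -> np.ndarray:
        lam_max = max(self._lambda_max(Xs, y), 1e-10)
        return np.logspace(
            np.log10(lam_max), np.log10(lam_max * self.lambda_min_ratio), self.n_lambdas
        )

    def _new_solver(self, n: int, lam: float, *, coarse: bool = False) -> LogisticRegression:
        # liblinear coordinate descent is orders of magnitude faster than
        # saga on this sparse binary design; the intercept rides along as a
        # pseudo-feature whose penalty is made negligible by a large
        # intercept_scaling, preserving the glmnet objective
        return LogisticRegression(
            l1_ratio=1.0,
            solver="liblinear",
            C=1.0 / (n * lam),
            tol=self.cv_tol if coarse else self.tol,
            max_iter=self.cv_max_iter if coarse else self.max_iter,
            intercept_scaling=100.0,
            random_state=self.random_state,
        )

    @staticmethod
    def _refine_intercept(offset: np.ndarray, y: np.ndarray, b0: float) -> float:
        # 1-D Newton for the unpenalised intercept given fixed slopes:
        # removes the residual shrinkage liblinear applies to its
        # intercept pseudo-feature (matters only at very large penalties)
        b = b0
        for _ in range(25):
            p = 1.0 / (1.0 + np.exp(-(offset + b)))
            g = p.mean() - y.mean()
            h = max(np.mean(p * (1.0 - p)), 1e-12)
            step = g / h
            b -= step
            if abs(step) < 1e-12:
                break
        return float(b)

    def _path_fit(self, Xs, y, grid, *, coarse: bool = False) -> list[tuple[np.ndarray, float]]:
        """Fits along the descending penalty path; returns (coef, icpt) per lambda."""
        n = Xs.shape[0]
        out = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            for lam in grid:
                clf = self._new_solver(n, lam, coarse=coarse)
                clf.fit(Xs, y)
                coef = clf.coef_[0].copy()
                icpt = self._refine_intercept(Xs @ coef, y, float(clf.intercept_[0]))
                out.append((coef, icpt))
        return out

    def fit(self, X, y) -> "PenalizedLogisticRegression":
        Xm, names = _as_matrix(X)
        y = np.asarray(y).astype(int).ravel()
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both outcome classes")
        self.classes_ = classes
        self.feature_names_ = names
        self.n_features_in_ = Xm.shape[1]

        Xs_full, sd_full = self._scale(Xm)
        if self.fixed_lambda is not None:
            grid = np.asarray([float(self.fixed_lambda)])
            self.lambda_grid_ = grid
            self.cv_errors_ = None
            best = float(self.fixed_lambda)
        else:
            grid = self._make_grid(Xs_full, y)
            self.lambda_grid_ = grid
            folds = StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state)
            errors = np.zeros((self.cv, len(grid)))
            for k, (tr, te) in enumerate(folds.split(np.zeros(len(y)), y)):
                Xs_tr, sd_tr = self._scale(Xm[tr])
                Xs_te = Xm[te] @ sp.diags(1.0 / sd_tr)
                path = self._path_fit(Xs_tr, y[tr], grid, coarse=True)
                for j, (coef, icpt) in enumerate(path):
                    margin = Xs_te @ coef + icpt
                    if self.criterion == "class":
                        pred = margin > 0.0
                        errors[k, j] = np.mean(pred != y[te])
                    elif self.criterion == "deviance":
                        p = 1.0 / (1.0 + np.exp(-margin))
                        p = np.clip(p, 1e-12, 1 - 1e-12)
                        errors[k, j] = -2.0 * np.mean(
                            y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p)
                        )
                    else:
                        raise ValueError(f"unknown criterion {self.criterion!r}")
            self.cv_errors_ = errors.mean(axis=0)
            # grid is descending, argmin takes the first (largest-lambda) tie
            best = float(grid[int(np.argmin(self.cv_errors_))])
        self.lambda_ = best

        coef_s, icpt = self._path_fit(Xs_full, y, np.asarray([best]))[-1]
        self._sd_ = sd_full
        self.coef_ = coef_s / sd_full
        self.intercept_ = icpt
        self.coefficients_ = dict(zip(names, self.coef_.tolist()))
        self.nonzero_features_ = [n_ for n_, b in self.coefficients_.items() if b != 0.0]
        return self

    def refit_fixed(self, Xm: sp.csr_matrix, y: np.ndarray,
                    solver: LogisticRegression | None = None) -> tuple[np.ndarray, float, LogisticRegression]:
        """One fit at ``lambda_`` on a (resampled) design, reusing a warm solver.

        Bootstrap helper: returns original-scale coefficients, intercept and
        the solver for reuse.
        """
        Xs, sd = self._scale(Xm)
        n = Xm.shape[0]
        if solver is None:
            solver = self._new_solver(n, self.lambda_, coarse=True)
        solver.C = 1.0 / (n * self.lambda_)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            solver.fit(Xs, y)
        coef = solver.coef_[0]
        icpt = self._refine_intercept(Xs @ coef, y, float(solver.intercept_[0]))
        return coef / sd, icpt, solver

    # ------------------------------------------------------------------
    def _check_schema(self, X):
        if isinstance(X, pd.DataFrame):
            cols = [str(c) for c in X.columns]
            if cols != self.feature_names_:
                missing = sorted(set(self.feature_names_) - set(cols))
                extra = sorted(set(cols) - set(self.feature_names_))
                if missing or extra:
                    raise SchemaError(f"feature mismatch; missing={missing}, extra={extra}")
                X = X[self.feature_names_]
            return sp.csr_matrix(X.to_numpy(dtype=np.float64))
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return sp.csr_matrix(X)

    def decision_function(self, X) -> np.ndarray:
        Xm = self._check_schema(X)
        return np.asarray(Xm @ self.coef_ + self.intercept_).ravel()

    def predict_proba(self, X) -> np.ndarray:
        m = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-m))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def coefficient_set(self, model_tag: str = "LLR") -> CoefficientSet:
        return CoefficientSet(
            intercept=float(self.intercept_),
            coefficients=dict(self.coefficients_),
            lam=float(self.lambda_),
            model_tag=model_tag,
        )


# ----------------------------------------------------------------------
# comparator suite

_DEFAULT_GRIDS = {
    "RF": {"n_estimators": [100, 300], "max_features": ["sqrt", 0.3]},
    "XGB": {"max_depth": [3, 6], "learning_rate": [0.1, 0.3]},
    "SVM-L": {"C": [0.1, 1.0, 10.0]},
    "SVM-R": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.1]},
}


@dataclass
class FittedModel:
    """Uniform handle: tag + fitted estimator + training schema."""

    tag: str
    estimator: object
    feature_names: list[str] = field(default_factory=list)

    def _check(self, X):
        if isinstance(X, pd.DataFrame) and self.feature_names:
            cols = [str(c) for c in X.columns]
            missing = sorted(set(self.feature_names) - set(cols))
            extra = sorted(set(cols) - set(self.feature_names))
            if missing or extra:
                raise SchemaError(f"feature mismatch; missing={missing}, extra={extra}")
            return X[self.feature_names]
        return X

    def predict_proba(self, X) -> np.ndarray:
        X = self._check(X)
        return np.asarray(self.estimator.predict_proba(X))[:, 1]

    def predict_set(self, fm: FeatureMatrix) -> pd.DataFrame:
        p = self.predict_proba(fm.X)
        return pd.DataFrame(
            {"patient_id": fm.X.index, "y_true": fm.y.to_numpy(), "y_prob": p}
        )


def fit_llr(fm: FeatureMatrix, **kwargs) -> PenalizedLogisticRegression:
    """Fit the lasso core on a FeatureMatrix."""
    model = PenalizedLogisticRegression(**kwargs)
    model.fit(fm.X, fm.y.to_numpy())
    return model


def fit_comparators(
    X,
    y,
    model_tag: str,
    hyper_grid: dict | None = None,
    folds: int = 10,
    seed: int = 0,
) -> FittedModel:
    """Fit one member of the comparator suite with grid-search CV tuning."""
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}; expected one of {MODEL_TAGS}")
    names = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else []
    y = np.asarray(y).astype(int).ravel()
    if model_tag == "LLR":
        model = PenalizedLogisticRegression(cv=folds, random_state=seed)
        model.fit(X, y)
        return FittedModel("LLR", model, names)
    if model_tag == "MLR":
        est = LogisticRegression(C=np.inf, max_iter=5000)
        est.fit(X, y)
        return FittedModel("MLR", est, names)

    base = {
        "RF": RandomForestClassifier(random_state=seed, n_jobs=1),
        "XGB": XGBClassifier(
            eval_metric="logloss", n_jobs=1, random_state=seed, tree_method="hist"
        ),
        # SVM scores mapped to probabilities by sigmoid calibration on folds
        "SVM-L": CalibratedClassifierCV(
            SVC(kernel="linear", random_state=seed), ensemble=False
        ),
        "SVM-R": CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed), ensemble=False
        ),
    }[model_tag]
    grid = hyper_grid if hyper_grid is not None else _DEFAULT_GRIDS[model_tag]
    if model_tag.startswith("SVM"):
        grid = {f"estimator__{k}": v for k, v in grid.items()}
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    cv = StratifiedKFold(folds, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, cv=cv, scoring="accuracy", n_jobs=1)
    search.fit(X, y)
    return FittedModel(model_tag, search.best_estimator_, names)
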