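"""Benchmarking standard classifiers against the LKB model.

Four scikit-learn classifiers — adaptive boosting (AB), logistic
regression (LR), a Gini-impurity decision tree (DT) and gradient-boosted
trees (GB) — are tuned by exhaustive grid search maximizing mean
validation-fold ROC-AUC over stratified folds, refitted on the full
training set, and scored beside a fitted LKB model on both splits with
accuracy (threshold 0.5, ties positive), ROC-AUC and Brier score.

The classifiers consume a per-patient feature table (mean dose, maximum
dose, one-hot clinical covariates); the LKB row is scored from its NTCP
probabilities, which are computed from the raw DVHs — scalar features can
be ComBat-harmonized across centers before tuning, whole DVHs cannot, so
the asymmetry is deliberate.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from . import lkb
from .cohort import Cohort, check_disjoint
from .metrics import accuracy, brier, roc_auc

MODEL_IDS = ("AB", "LR", "DT", "GB")

#: conventional default search grids (configurable per ModelSpec)
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "AB": {"n_estimators": [50, 100, 200, 400], "learning_rate": [0.01, 0.1, 0.5, 1.0]},
    "LR": {"C": [1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0]},
    "DT": {"max_depth": [1, 2, 3, 4, 5, 6, 7, 8], "min_samples_leaf": [1, 5, 10, 20]},
    "GB": {
        "n_estimators": [50, 100, 200, 400],
        "learning_rate": [0.01, 0.1, 0.3],
        "max_depth": [1, 2, 3, 4],
    },
}


class BenchmarkError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One classifier arm: id, hyperparameter grid, CV folds, seed."""

    model_id: str
    grid: Optional[Mapping[str, Sequence]] = None
    folds: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise BenchmarkError(f"unknown model id {self.model_id!r}; choose {MODEL_IDS}")
        if self.folds < 2:
            raise BenchmarkError("folds must be >= 2")
        grid = self.effective_grid()
        for name, values in grid.items():
            if len(list(values)) == 0:
                raise BenchmarkError(f"empty candidate list for hyperparameter {name!r}")

    def effective_grid(self) -> dict:
        return dict(self.grid) if self.grid is not None else dict(DEFAULT_GRIDS[self.model_id])


def _make_estimator(model_id: str, seed: int):
    if model_id == "AB":
        return AdaBoostClassifier(random_state=seed)
    if model_id == "LR":
        return LogisticRegression(max_iter=5000)
    if model_id == "DT":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if model_id == "GB":
        return GradientBoostingClassifier(random_state=seed)
    raise BenchmarkError(f"unknown model id {model_id!r}")


def build_features(cohort: Cohort) -> pd.DataFrame:
    """Per-patient feature table: mean dose, max dose, one-hot covariates.

    Column order is fixed (doses first, covariates in sorted name order);
    two-level categorical covariates become a single indicator column.
    """
    table = pd.DataFrame(
        {
            "mean_dose": cohort.mean_doses(),
            "max_dose": [r.dvh.max_dose() for r in cohort],
        },
        index=cohort.patient_ids,
    )
    covariates = cohort.covariate_frame()
    for name in sorted(covariates.columns):
        col = covariates[name]
        if col.isna().all():
            raise BenchmarkError(f"covariate {name!r} has no observed values")
        if pd.api.types.is_numeric_dtype(col):
            table[name] = col.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            for dummy_name in sorted(dummies.columns):
                table[dummy_name] = dummies[dummy_name].to_numpy(dtype=float)
    table.index.name = "patient_id"
    return table


@dataclasses.dataclass(frozen=True)
class TunedModel:
    model_id: str
    estimator: object
    best_params: dict
    cv_auc: float
    tuning_time: float
    fitting_time: float


def tune_and_fit(spec: ModelSpec, features: pd.DataFrame, labels) -> TunedModel:
    """Grid search maximizing mean validation-fold ROC-AUC, then refit.

    Folds are stratified; the fold count may not exceed the minority-class
    count (each validation fold must contain both classes).
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise BenchmarkError("training labels contain a single class")
    if spec.folds > counts.min():
        raise BenchmarkError(
            f"folds={spec.folds} exceeds the minority-class count {counts.min()}; "
            "lower the fold count"
        )
    cv = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    search = GridSearchCV(
        _make_estimator(spec.model_id, spec.seed),
        param_grid=spec.effective_grid(),
        scoring="roc_auc",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    tic = time.perf_counter()
    search.fit(features.to_numpy(dtype=float), y)
    total = time.perf_counter() - tic
    fitting_time = float(search.refit_time_)
    return TunedModel(
        model_id=spec.model_id,
        estimator=search.best_estimator_,
        best_params=dict(search.best_params_),
        cv_auc=float(search.best_score_),
        tuning_time=total - fitting_time,
        fitting_time=fitting_time,
    )


@dataclasses.dataclass(frozen=True)
class ModelRow:
    model: str
    train_accuracy: float
    test_accuracy: float
    train_auc: float
    test_auc: float
    train_brier: float
    test_brier: float
    tuning_time: float
    fitting_time: float
    hyperparameters: dict
    failed: bool = False
    error: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class BenchmarkReport:
    rows: tuple[ModelRow, ...]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([r.to_dict() for r in self.rows])
        return frame.set_index("model")

    def to_dict(self) -> dict:
        return {"seed": self.seed, "rows": [r.to_dict() for r in self.rows]}

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().drop(columns=["hyperparameters"]).to_csv(path, float_format="%.6g")


def _score_row(
    model: str,
    p_train: np.ndarray,
    y_train: np.ndarray,
    p_test: np.ndarray,
    y_test: np.ndarray,
    tuning_time: float,
    fitting_time: float,
    hyperparameters: dict,
) -> ModelRow:
    return ModelRow(
        model=model,
        train_accuracy=accuracy(p_train, y_train),
        test_accuracy=accuracy(p_test, y_test),
        train_auc=roc_auc(p_train, y_train),
        test_auc=roc_auc(p_test, y_test),
        train_brier=brier(p_train, y_train),
        test_brier=brier(p_test, y_test),
        tuning_time=tuning_time,
        fitting_time=fitting_time,
        hyperparameters=hyperparameters,
    )


def benchmark(
    train: Cohort,
    test: Cohort,
    specs: Sequence[ModelSpec],
    lkb_fit: lkb.FitResult,
    seed: int = 0,
    features_train: Optional[pd.DataFrame] = None,
    features_test: Optional[pd.DataFrame] = None,
) -> BenchmarkReport:
    """Score every classifier arm plus the fitted LKB model on both splits.

    Pre-harmonized feature tables may be passed in (e.g. after ComBat);
    otherwise raw features are built from the cohorts.  A classifier arm
    that fails to fit is reported as a failed row instead of aborting.
    """
    check_disjoint(train, test)
    if not lkb_fit.converged:
        raise BenchmarkError("LKB fit did not converge; refusing to score it")
    if features_train is None:
        features_train = build_features(train)
    if features_test is None:
        features_test = build_features(test)
    if list(features_train.columns) != list(features_test.columns):
        raise BenchmarkError("train/test feature columns differ")
    y_train, y_test = train.labels, test.labels

    rows: list[ModelRow] = []
    p_train = lkb.predict(train, lkb_fit.params)
    p_test = lkb.predict(test, lkb_fit.params)
    rows.append(
        _score_row(
            "LKB", p_train, y_train, p_test, y_test,
            tuning_time=float("nan"),
            fitting_time=lkb_fit.elapsed,
            hyperparameters=lkb_fit.params.to_dict(),
        )
    )
    for spec in specs:
        try:
            tuned = tune_and_fit(spec, features_train, y_train)
            p_tr = tuned.estimator.predict_proba(features_train.to_numpy(float))[:, 1]
            p_te = tuned.estimator.predict_proba(features_test.to_numpy(float))[:, 1]
            rows.append(
                _score_row(
                    spec.model_id, p_tr, y_train, p_te, y_test,
                    tuning_time=tuned.tuning_time,
                    fitting_time=tuned.fitting_time,
                    hyperparameters=tuned.best_params,
                )
            )
        except Exception as exc:  # a failed arm must not abort the study
            rows.append(
                ModelRow(
                    model=spec.model_id,
                    train_accuracy=float("nan"),
                    test_accuracy=float("nan"),
                    train_auc=float("nan"),
                    test_auc=float("nan"),
                    train_brier=float("nan"),
                    test_brier=float("nan"),
                    tuning_time=float("nan"),
                    fitting_time=float("nan"),
                    hyperparameters={},
                    failed=True,
                    error=str(exc),
                )
            )
    return BenchmarkReport(rows=tuple(rows), seed=seed)
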