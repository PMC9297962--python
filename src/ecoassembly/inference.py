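"""Supervised-learning inference from community summary statistics.

Simulation-based inference proceeds in stages mirroring standard ABC-style
machine-learning workflows:

1. feature selection (a Boruta shadow-feature procedure) removes summary
   statistics that are invariant or uninformative for the target;
2. hyperparameters of the ensemble learner are tuned by random search over
   documented priors, scored by K-fold cross-validation;
3. a classifier maps summary statistics to the assembly-model class
   (neutral / filtering / competition) and reports class probabilities;
4. a regressor, trained on the simulations of the winning class after a
   second feature-selection round, yields point estimates (ensemble mean)
   and 95% prediction intervals from the conditional leaf-value
   distribution of the forest (quantile-regression-forest style);
5. posterior predictive simulations locate the observation among
   simulations at the estimated parameters in PCA space.

Random forests are the default learner; gradient boosting and AdaBoost are
selectable.  Masked (NaN) features are excluded from fitting, never imputed,
and the training/prediction masks must agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    explained_variance_score,
    precision_score,
    r2_score,
    recall_score,
)
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score
from sklearn.preprocessing import StandardScaler

from ecoassembly.sumstats import STAT_AXES, STAT_NAMES, SummaryVector

__all__ = [
    "TrainingTable",
    "FittedEstimator",
    "PredictionResult",
    "PPSReport",
    "MaskMismatchError",
    "boruta_select",
    "tune_hyperparameters",
    "train_classifier",
    "predict_assembly_model",
    "train_regressor",
    "estimate_parameters",
    "cross_validate",
    "posterior_predictive_check",
]

ALGORITHMS = ("random_forest", "gradient_boosting", "adaboost")
MODEL_CLASSES = ("neutral", "filtering", "competition")

#: Documented hyperparameter priors for the random-search tuner.
HYPERPARAMETER_PRIORS = {
    "n_estimators": (100, 1000),  # log-uniform integer
    "max_depth": (2, 32),  # uniform integer
    "max_features": (0.1, 0.25, 0.5, 0.75, 1.0),  # fractional grid
}


class MaskMismatchError(ValueError):
    """Observed summary mask does not match the mask used in training."""


@dataclass
class TrainingTable:
    """Rows of (parameter draw, summary vector) for the ML layer.

    ``frame`` holds parameter columns plus the canonical statistic columns;
    ``mask`` is the axis-availability mask shared by every row.
    """

    frame: pd.DataFrame
    mask: dict[str, bool]

    @property
    def feature_columns(self) -> list[str]:
        """Statistic columns whose axes are available under the mask."""
        return [
            c
            for c in STAT_NAMES
            if c in self.frame.columns
            and all(self.mask.get(ax, False) for ax in STAT_AXES[c])
        ]

    def features(self, columns: Sequence[str] | None = None) -> pd.DataFrame:
        cols = list(columns) if columns is not None else self.feature_columns
        X = self.frame[cols]
        # undefined statistics (e.g. all-zero pi) may be NaN row-wise even on
        # available axes; those rows cannot be fit
        return X.dropna()

    def restrict(self, mask: Mapping[str, bool]) -> "TrainingTable":
        """Re-mask the table (e.g. to mimic reduced data availability)."""
        new_mask = {k: bool(self.mask.get(k, False) and mask.get(k, False)) for k in self.mask}
        return TrainingTable(frame=self.frame, mask=new_mask)


@dataclass
class FittedEstimator:
    """A trained classifier or regressor plus everything needed to reuse it."""

    task: str  # "classify" | "regress"
    algorithm: str
    estimator: object
    features: list[str]
    mask: dict[str, bool]
    hyperparameters: dict
    cv_scores: np.ndarray | None = None
    seed: int | None = None
    target: str | None = None
    train_y: np.ndarray | None = None
    train_leaves: np.ndarray | None = None


@dataclass
class PredictionResult:
    """Classification probabilities or parameter estimates with intervals."""

    task: str
    class_probabilities: dict[str, float] | None = None
    best_class: str | None = None
    estimates: dict[str, tuple[float, float, float]] | None = None  # (lo, point, hi)
    feature_importances: dict[str, float] = field(default_factory=dict)


@dataclass
class PPSReport:
    """Posterior-predictive goodness-of-fit summary."""

    observed_pc: tuple[float, float]
    distance_percentile: float
    n_simulations: int
    n_failures: int


# ---------------------------------------------------------------------------
# estimator factory
# ---------------------------------------------------------------------------


def _make_estimator(task: str, algorithm: str, hyperparameters: dict | None, seed):
    hp = dict(hyperparameters or {})
    if algorithm == "random_forest":
        cls = RandomForestClassifier if task == "classify" else RandomForestRegressor
        hp.setdefault("n_estimators", 500)
        if task == "regress":
            # quantile-forest intervals need non-degenerate leaf pools
            hp.setdefault("min_samples_leaf", 5)
        return cls(random_state=seed, n_jobs=1, **hp)
    if algorithm == "gradient_boosting":
        cls = (
            GradientBoostingClassifier
            if task == "classify"
            else GradientBoostingRegressor
        )
        hp.pop("max_features", None)
        hp.setdefault("n_estimators", 200)
        return cls(random_state=seed, **hp)
    if algorithm == "adaboost":
        cls = AdaBoostClassifier if task == "classify" else AdaBoostRegressor
        hp = {k: v for k, v in hp.items() if k == "n_estimators"}
        hp.setdefault("n_estimators", 200)
        return cls(random_state=seed, **hp)
    raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {algorithm!r}")


# ---------------------------------------------------------------------------
# Boruta feature selection
# ---------------------------------------------------------------------------


def boruta_select(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    task: str = "classify",
    seed: int | None = None,
    max_iter: int = 100,
    alpha: float = 0.05,
    n_estimators: int = 100,
) -> list[str]:
    """Boruta shadow-feature selection.

    Every feature is duplicated as a permuted ("shadow") copy; across
    iterations a feature scores a hit whenever its ensemble importance
    exceeds the maximum shadow importance.  A two-sided binomial test at
    level ``alpha`` confirms (keeps) or rejects (drops) features; undecided
    features are kept, which is the conservative choice.  Constant features
    are always dropped.
    """
    if len(X) < 10:
        raise ValueError("boruta_select needs a reasonable number of rows")
    rng = np.random.default_rng(seed)
    X = X.copy()
    keep_varying = X.columns[X.nunique() > 1]
    X = X[keep_varying]
    if X.shape[1] == 0:
        raise RuntimeError(
            "all features are constant; review priors and summary statistics"
        )
    features = list(X.columns)
    hits = np.zeros(len(features), dtype=int)
    decided: dict[str, bool] = {}

    for it in range(1, max_iter + 1):
        active = [f for f in features if f not in decided]
        if not active:
            break
        shadow = X[active].apply(lambda col: rng.permutation(col.values))
        shadow.columns = [f"shadow_{c}" for c in active]
        Z = pd.concat([X[active], shadow], axis=1)
        est = _make_estimator(
            task,
            "random_forest",
            {"n_estimators": n_estimators},
            int(rng.integers(2**31)),
        )
        est.fit(Z.values, np.asarray(y))
        imp = est.feature_importances_
        shadow_max = imp[len(active) :].max()
        for j, f in enumerate(active):
            if imp[j] > shadow_max:
                hits[features.index(f)] += 1
        # binomial test on hit counts under the null p=0.5
        for f in active:
            k = hits[features.index(f)]
            test = stats.binomtest(k, it, 0.5)
            if test.pvalue < alpha:
                decided[f] = k > it / 2  # True = confirmed, False = rejected
    retained = [f for f in features if decided.get(f, True)]
    if not retained:
        raise RuntimeError(
            "all features rejected; review priors and summary statistics"
        )
    return retained


# ---------------------------------------------------------------------------
# hyperparameter tuning
# ---------------------------------------------------------------------------


def tune_hyperparameters(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    task: str = "classify",
    algorithm: str = "random_forest",
    n_draws: int = 10,
    cv: int = 5,
    seed: int | None = None,
) -> dict:
    """Random-search hyperparameter tuning scored by K-fold CV.

    Draws are taken from :data:`HYPERPARAMETER_PRIORS` (tree count
    log-uniform, depth uniform, features-per-split from a fractional grid);
    the configuration with the best mean CV score (accuracy or R^2) wins.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    best_score, best_hp = -np.inf, None
    lo, hi = HYPERPARAMETER_PRIORS["n_estimators"]
    dlo, dhi = HYPERPARAMETER_PRIORS["max_depth"]
    for _ in range(n_draws):
        hp = {
            "n_estimators": int(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            "max_depth": int(rng.integers(dlo, dhi + 1)),
            "max_features": float(rng.choice(HYPERPARAMETER_PRIORS["max_features"])),
        }
        est = _make_estimator(task, algorithm, hp, int(rng.integers(2**31)))
        scoring = "accuracy" if task == "classify" else "r2"
        folds = (
            StratifiedKFold(cv, shuffle=True, random_state=int(rng.integers(2**31)))
            if task == "classify"
            else KFold(cv, shuffle=True, random_state=int(rng.integers(2**31)))
        )
        score = cross_val_score(est, X.values, y, cv=folds, scoring=scoring).mean()
        if score > best_score:
            best_score, best_hp = score, hp
    return best_hp


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def train_classifier(
    table: TrainingTable,
    seed: int | None = None,
    algorithm: str = "random_forest",
    select_features: bool = True,
    tune_draws: int = 0,
    class_column: str = "model",
) -> FittedEstimator:
    """Train an assembly-model classifier on a simulation table.

    Feature selection (Boruta) and optional random-search tuning are run
    before the final fit.  Set ``tune_draws=0`` to use default
    hyperparameters and ``select_features=False`` to keep all features.
    """
    rng = np.random.default_rng(seed)
    X = table.features()
    y = table.frame.loc[X.index, class_column].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("classification needs at least 2 classes in the table")
    feats = list(X.columns)
    if select_features:
        feats = boruta_select(
            X, y, task="classify", seed=int(rng.integers(2**31)), max_iter=25
        )
        X = X[feats]
    hp = None
    if tune_draws > 0:
        hp = tune_hyperparameters(
            X, y, task="classify", algorithm=algorithm,
            n_draws=tune_draws, seed=int(rng.integers(2**31)),
        )
    est = _make_estimator("classify", algorithm, hp, int(rng.integers(2**31)))
    est.fit(X.values, y)
    return FittedEstimator(
        task="classify",
        algorithm=algorithm,
        estimator=est,
        features=feats,
        mask=dict(table.mask),
        hyperparameters=hp or {},
        seed=seed,
    )


def _observation_row(est: FittedEstimator, obs: SummaryVector) -> np.ndarray:
    if isinstance(obs, SummaryVector):
        for axis, needed in est.mask.items():
            if needed and not obs.mask.get(axis, False):
                raise MaskMismatchError(
                    f"axis {axis!r} was available in training but is masked in "
                    "the observation"
                )
        row = obs.values[est.features].to_numpy(dtype=float)
    else:
        row = pd.Series(obs)[est.features].to_numpy(dtype=float)
    if np.any(np.isnan(row)):
        bad = [f for f, v in zip(est.features, row) if np.isnan(v)]
        raise MaskMismatchError(f"observed summary has NaN for features {bad}")
    return row.reshape(1, -1)


def predict_assembly_model(est: FittedEstimator, obs: SummaryVector) -> PredictionResult:
    """Class probabilities for one observed community summary vector."""
    if est.task != "classify":
        raise ValueError("estimator was not trained for classification")
    row = _observation_row(est, obs)
    probs = est.estimator.predict_proba(row)[0]
    classes = list(est.estimator.classes_)
    prob_map = {c: float(p) for c, p in zip(classes, probs)}
    importances = getattr(est.estimator, "feature_importances_", None)
    return PredictionResult(
        task="classify",
        class_probabilities=prob_map,
        best_class=max(prob_map, key=prob_map.get),
        feature_importances=(
            dict(zip(est.features, map(float, importances)))
            if importances is not None
            else {}
        ),
    )


# ---------------------------------------------------------------------------
# regression with quantile prediction intervals
# ---------------------------------------------------------------------------


def train_regressor(
    table: TrainingTable,
    targets: Sequence[str],
    seed: int | None = None,
    algorithm: str = "random_forest",
    select_features: bool = True,
    tune_draws: int = 0,
) -> dict[str, FittedEstimator]:
    """Train one regressor per target parameter on a (class-filtered) table.

    A second feature-selection and tuning round runs per target.  For random
    forests the training responses and leaf assignments are retained so that
    :func:`estimate_parameters` can form conditional-quantile prediction
    intervals.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, FittedEstimator] = {}
    X_all = table.features()
    for target in targets:
        if target not in table.frame.columns:
            raise ValueError(f"target {target!r} absent from training table")
        y = table.frame.loc[X_all.index, target].to_numpy(dtype=float)
        feats = list(X_all.columns)
        if select_features:
            feats = boruta_select(
                X_all, y, task="regress", seed=int(rng.integers(2**31)), max_iter=25
            )
        X = X_all[feats]
        hp = None
        if tune_draws > 0:
            hp = tune_hyperparameters(
                X, y, task="regress", algorithm=algorithm,
                n_draws=tune_draws, seed=int(rng.integers(2**31)),
            )
        est = _make_estimator("regress", algorithm, hp, int(rng.integers(2**31)))
        est.fit(X.values, y)
        fitted = FittedEstimator(
            task="regress",
            algorithm=algorithm,
            estimator=est,
            features=feats,
            mask=dict(table.mask),
            hyperparameters=hp or {},
            seed=seed,
            target=target,
            train_y=y,
        )
        if algorithm == "random_forest":
            fitted.train_leaves = est.apply(X.values)
        out[target] = fitted
    return out


def _quantile_interval(
    fitted: FittedEstimator, row: np.ndarray, quantiles=(0.025, 0.975)
) -> tuple[float, float]:
    """Conditional quantiles from the forest's leaf-value distribution.

    For each tree, the training responses that share the observation's leaf
    are pooled (each tree contributing equal total weight); the pooled
    distribution's quantiles form the prediction interval.
    """
    est = fitted.estimator
    leaves_obs = est.apply(row)[0]  # (n_trees,)
    pooled_vals: list[np.ndarray] = []
    pooled_wts: list[np.ndarray] = []
    for t, leaf in enumerate(leaves_obs):
        in_leaf = fitted.train_leaves[:, t] == leaf
        vals = fitted.train_y[in_leaf]
        if vals.size:
            pooled_vals.append(vals)
            pooled_wts.append(np.full(vals.size, 1.0 / vals.size))
    values = np.concatenate(pooled_vals)
    weights = np.concatenate(pooled_wts)
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights) / weights.sum()
    lo = float(values[np.searchsorted(cum, quantiles[0])])
    hi = float(values[min(np.searchsorted(cum, quantiles[1]), values.size - 1)])
    return lo, hi


def estimate_parameters(
    estimators: Mapping[str, FittedEstimator], obs: SummaryVector
) -> PredictionResult:
    """Point estimates and 95% prediction intervals for each parameter."""
    estimates: dict[str, tuple[float, float, float]] = {}
    importances: dict[str, float] = {}
    for target, fitted in estimators.items():
        row = _observation_row(fitted, obs)
        point = float(fitted.estimator.predict(row)[0])
        if fitted.train_leaves is not None:
            lo, hi = _quantile_interval(fitted, row)
            lo, hi = min(lo, point), max(hi, point)
        else:
            lo = hi = point
        estimates[target] = (lo, point, hi)
        imp = getattr(fitted.estimator, "feature_importances_", None)
        if imp is not None:
            for f, v in zip(fitted.features, imp):
                importances[f"{target}:{f}"] = float(v)
    return PredictionResult(task="regress", estimates=estimates,
                            feature_importances=importances)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def cross_validate(
    table: TrainingTable,
    task: str = "classify",
    targets: Sequence[str] | None = None,
    K: int = 5,
    seed: int | None = None,
    algorithm: str = "random_forest",
    class_column: str = "model",
) -> dict:
    """Held-out K-fold performance report.

    Classification: per-class precision/recall, a row-normalized confusion
    matrix and the mean misclassification rate.  Regression: explained
    variance and R^2 per target parameter.
    """
    rng = np.random.default_rng(seed)
    X = table.features()
    if K > len(X):
        raise ValueError(f"K={K} exceeds the {len(X)} usable rows")
    if task == "classify":
        y = table.frame.loc[X.index, class_column].to_numpy()
        classes = sorted(np.unique(y))
        folds = StratifiedKFold(K, shuffle=True, random_state=int(rng.integers(2**31)))
        y_true, y_pred = [], []
        for tr, te in folds.split(X.values, y):
            est = _make_estimator("classify", algorithm, None, int(rng.integers(2**31)))
            est.fit(X.values[tr], y[tr])
            y_true.extend(y[te])
            y_pred.extend(est.predict(X.values[te]))
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        conf = confusion_matrix(y_true, y_pred, labels=classes).astype(float)
        conf /= conf.sum(axis=1, keepdims=True)
        return {
            "task": "classify",
            "classes": classes,
            "confusion": pd.DataFrame(conf, index=classes, columns=classes),
            "precision": dict(
                zip(classes, precision_score(y_true, y_pred, labels=classes,
                                             average=None, zero_division=0))
            ),
            "recall": dict(
                zip(classes, recall_score(y_true, y_pred, labels=classes,
                                          average=None, zero_division=0))
            ),
            "error_rate": 1.0 - accuracy_score(y_true, y_pred),
            "per_class_error": {
                c: 1.0 - conf[i, i] for i, c in enumerate(classes)
            },
        }
    # regression
    if not targets:
        raise ValueError("regression cross-validation needs target names")
    report = {"task": "regress", "r2": {}, "explained_variance": {}}
    folds = KFold(K, shuffle=True, random_state=int(rng.integers(2**31)))
    for target in targets:
        y = table.frame.loc[X.index, target].to_numpy(dtype=float)
        y_true, y_pred = [], []
        for tr, te in folds.split(X.values):
            est = _make_estimator("regress", algorithm, None, int(rng.integers(2**31)))
            est.fit(X.values[tr], y[tr])
            y_true.extend(y[te])
            y_pred.extend(est.predict(X.values[te]))
        report["r2"][target] = float(r2_score(y_true, y_pred))
        report["explained_variance"][target] = float(
            explained_variance_score(y_true, y_pred)
        )
    return report


# ---------------------------------------------------------------------------
# posterior predictive simulations
# ---------------------------------------------------------------------------


def posterior_predictive_check(
    obs: SummaryVector,
    best_params: Mapping[str, object],
    simulator: Callable[[Mapping[str, object], int], SummaryVector],
    n_sims: int = 100,
    seed: int | None = None,
) -> PPSReport:
    """Goodness-of-fit by posterior predictive simulation.

    ``simulator(params, seed)`` must return a :class:`SummaryVector`.
    Simulated statistics are centred/scaled and reduced with PCA; the report
    gives the observation's coordinates in the first two components and the
    percentile of its Euclidean distance (in the full PC space) from the
    simulated centroid relative to the simulated points, a centrality score
    in (0, 1] where values near 1 flag a poorly fitting model.
    """
    rng = np.random.default_rng(seed)
    rows = []
    failures = 0
    for _ in range(n_sims):
        try:
            sv = simulator(best_params, int(rng.integers(2**31)))
            rows.append(sv.values)
        except Exception:
            failures += 1
        if failures > n_sims // 2:
            raise RuntimeError(
                f"posterior predictive simulations aborted: {failures} of "
                f"{n_sims} failed"
            )
    sims = pd.DataFrame(rows).reset_index(drop=True)
    cols = [
        c for c in sims.columns
        if sims[c].notna().all() and not np.isnan(obs.values[c]) and sims[c].nunique() > 1
    ]
    sims = sims[cols]
    scaler = StandardScaler().fit(sims.values)
    Z = scaler.transform(sims.values)
    pca = PCA(n_components=min(len(cols), max(2, min(len(sims) - 1, 10)))).fit(Z)
    sim_pc = pca.transform(Z)
    obs_pc = pca.transform(scaler.transform(obs.values[cols].to_numpy().reshape(1, -1)))[0]
    d_sims = np.linalg.norm(sim_pc, axis=1)
    d_obs = float(np.linalg.norm(obs_pc))
    percentile = float((np.sum(d_sims <= d_obs) + 1) / (len(d_sims) + 1))
    return PPSReport(
        observed_pc=(float(obs_pc[0]), float(obs_pc[1])),
        distance_percentile=percentile,
        n_simulations=len(sims),
        n_failures=failures,
    )
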