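"""Presence / pseudo-absence ensemble species distribution modeling.

The workflow: presences are coupled with uniformly drawn pseudo-absences
(default 10,000); each of eight algorithms — MAXENT, CTA, MARS, GLM, GBM,
GAM, ANN, RF — is fitted on repeated stratified 75/25 calibration/validation
splits (default 10 repetitions); per-algorithm performance is the replicate
mean of sensitivity, specificity, AUC, TSS and omission rate at the
max-TSS threshold; algorithms with mean AUC above the gate (default 0.75)
enter the ensemble as an AUC-weighted mean of their probability surfaces,
re-thresholded by the max-TSS rule on pooled held-out predictions.  Variable
contributions are leave-one-variable-out correlation scores: the less an
omitted variable's refit correlates with the full model, the more it
contributed.

MAXENT is realized as an L1-penalized logistic presence/background model;
MARS as hinge-basis logistic regression; GAM as a spline-basis logistic
regression.  The remaining algorithms wrap scikit-learn directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, has_fit_parameter

from .occurrences import OccurrenceSet
from .prep import EnvStack
from .raster import RasterLayer

__all__ = [
    "ALGORITHMS",
    "EvaluationMetrics",
    "ModelRecord",
    "EnsembleResult",
    "TrainingTable",
    "EnsembleSDM",
    "generate_pseudo_absences",
    "build_training_table",
    "split_train_test",
    "fit_algorithm",
    "evaluate",
    "evaluate_scores",
    "max_tss_threshold",
    "build_ensemble",
    "variable_contributions",
    "normalize_contributions",
    "predict_raster",
    "fit_sdm_ensemble",
]

ALGORITHMS = ("MAXENT", "CTA", "MARS", "GLM", "GBM", "GAM", "ANN", "RF")
_TREE_ALGOS = {"CTA", "GBM", "RF"}


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------
@dataclass
class EvaluationMetrics:
    """Threshold-dependent skill of one presence/absence classifier.

    ``tss = sensitivity + specificity - 1`` and
    ``omission_rate = 1 - sensitivity`` hold by construction.
    """

    sensitivity: float
    specificity: float
    auc: float
    tss: float
    omission_rate: float
    threshold: float

    @classmethod
    def from_rates(
        cls,
        sensitivity: float,
        specificity: float,
        auc: float = float("nan"),
        threshold: float = float("nan"),
    ) -> "EvaluationMetrics":
        """Derive TSS and omission rate from a (sensitivity, specificity) pair."""
        return cls(
            sensitivity=sensitivity,
            specificity=specificity,
            auc=auc,
            tss=sensitivity + specificity - 1.0,
            omission_rate=1.0 - sensitivity,
            threshold=threshold,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "tss": self.tss,
            "omission_rate": self.omission_rate,
            "threshold": self.threshold,
        }


def max_tss_threshold(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Threshold (score >= t -> presence) maximizing sensitivity+specificity.

    Scans every distinct score; ties resolved to the lowest qualifying
    threshold (maximizes sensitivity), deterministically.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes required to choose a threshold")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    finite = np.isfinite(thr)
    fpr, tpr, thr = fpr[finite], tpr[finite], thr[finite]
    tss = tpr - fpr
    best = tss.max()
    # thr is decreasing; last index attaining the max is the lowest threshold
    idx = np.flatnonzero(tss >= best - 1e-12)[-1]
    return float(thr[idx])


def evaluate_scores(
    y_true: np.ndarray, scores: np.ndarray, threshold: float | None = None
) -> EvaluationMetrics:
    """Full metric set from held-out scores; threshold defaults to max-TSS."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("evaluation requires both classes in the test set")
    if threshold is None:
        threshold = max_tss_threshold(y, s)
    pred = s >= threshold
    sens = float((pred & (y == 1)).sum() / (y == 1).sum())
    spec = float((~pred & (y == 0)).sum() / (y == 0).sum())
    auc = float(roc_auc_score(y, s))
    return EvaluationMetrics(
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        tss=sens + spec - 1.0,
        omission_rate=1.0 - sens,
        threshold=float(threshold),
    )


def evaluate(
    predictor, test: "TrainingTable", threshold_rule: str = "max TSS"
) -> EvaluationMetrics:
    """Evaluate a fitted probability predictor on a held-out table."""
    if threshold_rule != "max TSS":
        raise ValueError(f"unknown threshold rule {threshold_rule!r}")
    scores = _suitability(predictor, test.X)
    return evaluate_scores(test.y, scores)


# ---------------------------------------------------------------------------
# Training data
# ---------------------------------------------------------------------------
@dataclass
class TrainingTable:
    """Labelled predictor rows tied to grid cells."""

    X: pd.DataFrame
    y: np.ndarray
    cells: np.ndarray               # (n, 2) row/col per row
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y) or len(self.y) != len(self.cells):
            raise ValueError("X, y, cells must align")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def categorical_names(self) -> list[str]:
        return [n for n, k in self.kinds.items() if k == "categorical"]

    def take(self, idx: np.ndarray) -> "TrainingTable":
        return TrainingTable(
            X=self.X.iloc[idx].reset_index(drop=True),
            y=self.y[idx],
            cells=self.cells[idx],
            kinds=self.kinds,
        )


def generate_pseudo_absences(
    stack: EnvStack,
    n: int = 10000,
    seed: int | np.random.Generator = 0,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Uniformly draw ``n`` distinct background cells.

    Non-nodata cells only; cells in ``exclude`` (e.g. presence cells,
    shape (k, 2)) are not eligible.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eligible = stack.valid_mask.copy()
    if exclude is not None and len(exclude):
        ex = np.asarray(exclude, dtype=int)
        eligible[ex[:, 0], ex[:, 1]] = False
    flat = np.flatnonzero(eligible.ravel())
    if n > flat.size:
        raise ValueError(
            f"requested {n} pseudo-absences but only {flat.size} eligible cells"
        )
    chosen = rng.choice(flat, size=n, replace=False)
    chosen.sort()
    ncols = stack.grid.shape[1]
    return np.column_stack([chosen // ncols, chosen % ncols])


def build_training_table(
    stack: EnvStack,
    occurrences: OccurrenceSet,
    pseudo_cells: np.ndarray,
) -> TrainingTable:
    """Presence (deduplicated per cell) + pseudo-absence predictor rows."""
    pres = occurrences.cells(stack.grid, dedupe=True)
    cells = np.vstack([pres, pseudo_cells])
    y = np.concatenate([np.ones(len(pres), int), np.zeros(len(pseudo_cells), int)])
    X = stack.table(cells[:, 0], cells[:, 1])
    return TrainingTable(X=X, y=y, cells=cells, kinds=dict(stack.kinds))


def split_train_test(
    table: TrainingTable,
    calibration_fraction: float = 0.75,
    seed: int | np.random.Generator = 0,
) -> tuple[TrainingTable, TrainingTable]:
    """Stratified calibration/validation split.

    Per class, ``floor(fraction * n_class)`` rows go to calibration — so 59
    presences split 44/15 at the default 75% — and the rest to validation.
    """
    if (table.y == 1).sum() < 4:
        raise ValueError("need at least 4 presences to split")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    train_idx, test_idx = [], []
    for label in (0, 1):
        idx = np.flatnonzero(table.y == label)
        if idx.size == 0:
            raise ValueError(f"class {label} is empty")
        perm = rng.permutation(idx)
        k = int(np.floor(calibration_fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    return (
        table.take(np.concatenate(train_idx)),
        table.take(np.concatenate(test_idx)),
    )


# ---------------------------------------------------------------------------
# Algorithms
# ---------------------------------------------------------------------------
class HingeBasis(BaseEstimator, TransformerMixin):
    """Per-feature hinge pairs max(0, x-t), max(0, t-x) at quantile knots.

    The adaptive-spline basis behind the MARS realization; feeding it to a
    penalized logistic regression approximates MARS' piecewise-linear fits.
    """

    def __init__(self, quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)):
        self.quantiles = quantiles

    def fit(self, X, y=None):
        arr = np.asarray(X, dtype=float)
        self.knots_ = np.quantile(arr, self.quantiles, axis=0)
        self.n_features_in_ = arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "knots_")
        arr = np.asarray(X, dtype=float)
        parts = [arr]
        for knots in self.knots_:
            parts.append(np.maximum(0.0, arr - knots))
            parts.append(np.maximum(0.0, knots - arr))
        return np.hstack(parts)


def _classifier(algorithm: str, random_state: int):
    if algorithm == "MAXENT":
        return LogisticRegression(
            penalty="l1", solver="liblinear", C=1.0,
            class_weight="balanced", random_state=random_state, max_iter=500,
        )
    if algorithm == "GLM":
        return LogisticRegression(
            penalty="l2", C=1e3, class_weight="balanced",
            random_state=random_state, max_iter=1000,
        )
    if algorithm in ("MARS", "GAM"):
        return LogisticRegression(
            penalty="l2", C=1.0, class_weight="balanced",
            random_state=random_state, max_iter=1000,
        )
    if algorithm == "CTA":
        return DecisionTreeClassifier(
            min_samples_leaf=5, class_weight="balanced",
            random_state=random_state,
        )
    if algorithm == "GBM":
        return GradientBoostingClassifier(
            n_estimators=100, max_depth=3, learning_rate=0.1,
            random_state=random_state,
        )
    if algorithm == "ANN":
        return MLPClassifier(
            hidden_layer_sizes=(16,), max_iter=300, alpha=1e-3,
            random_state=random_state,
        )
    if algorithm == "RF":
        return RandomForestClassifier(
            n_estimators=100, min_samples_leaf=2, class_weight="balanced",
            random_state=random_state, n_jobs=1,
        )
    raise ValueError(f"unsupported algorithm {algorithm!r}")


def make_algorithm(
    algorithm: str,
    continuous: list[str],
    categorical: list[str],
    random_state: int = 0,
) -> Pipeline:
    """A preprocessing + classifier pipeline for one algorithm.

    Encoding is centralized here: tree learners consume raw class codes,
    everything else gets one-hot categoricals and standardized continuous
    inputs (spline/hinge bases for GAM/MARS).
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(
            f"unsupported algorithm {algorithm!r}; choose from {ALGORITHMS}"
        )
    if algorithm in _TREE_ALGOS:
        pre = "passthrough"
    else:
        if algorithm == "GAM":
            cont_pipe = Pipeline([
                ("scale", StandardScaler()),
                ("spline", SplineTransformer(n_knots=5, degree=3)),
            ])
        elif algorithm == "MARS":
            cont_pipe = Pipeline([
                ("scale", StandardScaler()),
                ("hinge", HingeBasis()),
            ])
        else:
            cont_pipe = Pipeline([("scale", StandardScaler())])
        pre = ColumnTransformer(
            [
                ("cont", cont_pipe, continuous),
                ("cat", OneHotEncoder(handle_unknown="ignore"), categorical),
            ]
        )
    return Pipeline([("pre", pre), ("clf", _classifier(algorithm, random_state))])


def fit_algorithm(
    algorithm: str,
    train: TrainingTable,
    hyperparams: dict | None = None,
    random_state: int = 0,
) -> Pipeline:
    """Fit one algorithm on a training table; returns a probability model.

    Class imbalance (few presences vs many pseudo-absences) is handled by
    balanced weights where the learner accepts them.
    """
    if len(np.unique(train.y)) < 2:
        raise ValueError("degenerate training data: a single class present")
    cat = train.categorical_names
    cont = [n for n in train.X.columns if n not in cat]
    pipe = make_algorithm(algorithm, cont, cat, random_state=random_state)
    if hyperparams:
        pipe.set_params(**{f"clf__{k}": v for k, v in hyperparams.items()})
    clf = pipe.named_steps["clf"]
    fit_kw = {}
    if "class_weight" not in clf.get_params() and has_fit_parameter(
        clf, "sample_weight"
    ):
        n, n1 = len(train.y), int(train.y.sum())
        w1, w0 = n / (2.0 * n1), n / (2.0 * (n - n1))
        fit_kw["clf__sample_weight"] = np.where(train.y == 1, w1, w0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        pipe.fit(train.X, train.y, **fit_kw)
    return pipe


def _suitability(model, X: pd.DataFrame) -> np.ndarray:
    """Probability of presence, clamped to [0, 1]."""
    p = model.predict_proba(X)[:, 1]
    return np.clip(p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Records / results
# ---------------------------------------------------------------------------
@dataclass
class ModelRecord:
    algorithm: str
    replicate: int
    estimator: Pipeline
    metrics: EvaluationMetrics
    retained: bool = False


@dataclass
class EnsembleResult:
    """Mapped ensemble output plus its audit trail."""

    probability: RasterLayer
    threshold: float
    binary: RasterLayer
    metrics: EvaluationMetrics
    retained_models: list[ModelRecord]
    contributions: dict[str, float]
    algorithm_metrics: pd.DataFrame
    weights: dict[str, float]

    def metrics_table(self) -> pd.DataFrame:
        """One row per algorithm plus the ensemble (ESDM) row."""
        rows = self.algorithm_metrics.copy()
        esdm = {"algorithm": "ESDM", **self.metrics.as_dict()}
        return pd.concat(
            [rows, pd.DataFrame([esdm])], ignore_index=True
        )


# ---------------------------------------------------------------------------
# The estimator
# ---------------------------------------------------------------------------
class EnsembleSDM(BaseEstimator, ClassifierMixin):
    """AUC-gated, AUC-weighted multi-algorithm ensemble classifier.

    Parameters
    ----------
    algorithms : tuple of str
        Which of the eight algorithms to fit.
    n_replicates : int
        Repeated random calibration/validation splits per algorithm.
    calibration_fraction : float
        Fraction of each class used for calibration (default 0.75).
    auc_gate : float
        Strict lower AUC bound (replicate mean) for an algorithm to enter
        the ensemble (default 0.75).
    weighting : {"auc", "uniform"}
        Ensemble weights proportional to mean AUC, or equal.
    categorical_features : list of str, optional
        Columns treated as categorical (codes); inferred empty if None.
    random_state : int
        Seed for splits and learners; replicate seeds derived from it.

    Attributes (after fit)
    ----------------------
    models_ : list of ModelRecord (algorithm x replicate)
    algorithm_metrics_ : dict algorithm -> EvaluationMetrics (replicate means)
    retained_algorithms_, weights_ : gate survivors and their weights
    threshold_ : max-TSS cut on pooled held-out ensemble scores
    metrics_ : EvaluationMetrics of the pooled ensemble predictions
    """

    def __init__(
        self,
        algorithms: tuple[str, ...] = ALGORITHMS,
        n_replicates: int = 10,
        calibration_fraction: float = 0.75,
        auc_gate: float = 0.75,
        weighting: str = "auc",
        categorical_features: list[str] | None = None,
        random_state: int = 0,
    ):
        self.algorithms = algorithms
        self.n_replicates = n_replicates
        self.calibration_fraction = calibration_fraction
        self.auc_gate = auc_gate
        self.weighting = weighting
        self.categorical_features = categorical_features
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=int)
        kinds = {
            c: (
                "categorical"
                if self.categorical_features and c in self.categorical_features
                else "continuous"
            )
            for c in X.columns
        }
        table = TrainingTable(
            X=X.reset_index(drop=True),
            y=y,
            cells=np.zeros((len(y), 2), dtype=int),
            kinds=kinds,
        )
        self._fit_table(table)
        return self

    def _fit_table(self, table: TrainingTable) -> "EnsembleSDM":
        ss = np.random.SeedSequence([int(self.random_state) % (2**31), 11])
        rep_seeds = ss.generate_state(self.n_replicates)
        splits = [
            split_train_test(
                table,
                self.calibration_fraction,
                np.random.default_rng(int(s)),
            )
            for s in rep_seeds
        ]
        self.models_: list[ModelRecord] = []
        per_algo: dict[str, list[ModelRecord]] = {a: [] for a in self.algorithms}
        for algo in self.algorithms:
            for rep, (train, test) in enumerate(splits, start=1):
                est = fit_algorithm(
                    algo,
                    train,
                    random_state=int(rep_seeds[rep - 1] % (2**31)),
                )
                rec = ModelRecord(
                    algorithm=algo,
                    replicate=rep,
                    estimator=est,
                    metrics=evaluate(est, test),
                )
                per_algo[algo].append(rec)
                self.models_.append(rec)

        self.algorithm_metrics_: dict[str, EvaluationMetrics] = {}
        for algo, recs in per_algo.items():
            mean = lambda attr: float(
                np.mean([getattr(r.metrics, attr) for r in recs])
            )
            self.algorithm_metrics_[algo] = EvaluationMetrics(
                sensitivity=mean("sensitivity"),
                specificity=mean("specificity"),
                auc=mean("auc"),
                tss=mean("tss"),
                omission_rate=mean("omission_rate"),
                threshold=mean("threshold"),
            )

        gate = self.auc_gate
        retained = [
            a for a in self.algorithms if self.algorithm_metrics_[a].auc > gate
        ]
        if not retained:
            aucs = {
                a: round(m.auc, 4) for a, m in self.algorithm_metrics_.items()
            }
            raise RuntimeError(
                f"no algorithm passed the AUC gate {gate}; replicate-mean "
                f"AUCs: {aucs}"
            )
        for rec in self.models_:
            rec.retained = rec.algorithm in retained
        self.retained_algorithms_ = retained
        if self.weighting == "auc":
            w = np.array([self.algorithm_metrics_[a].auc for a in retained])
        elif self.weighting == "uniform":
            w = np.ones(len(retained))
        else:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        w = w / w.sum()
        self.weights_ = dict(zip(retained, (float(v) for v in w)))
        self._per_algo = per_algo

        # pooled held-out ensemble predictions -> ESDM metrics & threshold
        ys, ss_ = [], []
        for rep, (_, test) in enumerate(splits):
            score = np.zeros(len(test))
            for algo in retained:
                rec = per_algo[algo][rep]
                score += self.weights_[algo] * _suitability(
                    rec.estimator, test.X
                )
            ys.append(test.y)
            ss_.append(score)
        y_pool = np.concatenate(ys)
        s_pool = np.concatenate(ss_)
        self.threshold_ = max_tss_threshold(y_pool, s_pool)
        self.metrics_ = evaluate_scores(y_pool, s_pool, self.threshold_)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = len(
            next(iter(per_algo.values()))[0].estimator.feature_names_in_
        ) if hasattr(
            next(iter(per_algo.values()))[0].estimator, "feature_names_in_"
        ) else None
        return self

    # -- prediction -------------------------------------------------------
    def predict_suitability(self, X) -> np.ndarray:
        """Ensemble habitat-suitability probability in [0, 1].

        Per retained algorithm, replicate models are averaged into one
        probability surface before the AUC-weighted combination.
        """
        check_is_fitted(self, "weights_")
        X = pd.DataFrame(X)
        out = np.zeros(len(X))
        for algo in self.retained_algorithms_:
            recs = self._per_algo[algo]
            p = np.mean(
                [_suitability(r.estimator, X) for r in recs], axis=0
            )
            out += self.weights_[algo] * p
        return np.clip(out, 0.0, 1.0)

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_suitability(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_suitability(X) >= self.threshold_).astype(int)

    def algorithm_metrics_table(self) -> pd.DataFrame:
        check_is_fitted(self, "algorithm_metrics_")
        rows = [
            {"algorithm": a, **m.as_dict()}
            for a, m in self.algorithm_metrics_.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spec-surface helpers
# ---------------------------------------------------------------------------
def build_ensemble(
    table: TrainingTable,
    stack: EnvStack,
    auc_gate: float = 0.75,
    **params,
) -> tuple[EnsembleSDM, RasterLayer]:
    """Fit the gated ensemble on a training table and map it over the stack."""
    ens = EnsembleSDM(auc_gate=auc_gate, **params)
    ens.categorical_features = [
        n for n, k in table.kinds.items() if k == "categorical"
    ]
    ens._fit_table(table)
    prob = predict_raster(ens, stack)
    return ens, prob


def predict_raster(model, stack: EnvStack, batch: int = 200_000) -> RasterLayer:
    """Apply a suitability model to every valid cell of the stack."""
    grid = stack.grid
    valid = stack.valid_mask
    rows, cols = np.nonzero(valid)
    out = np.full(grid.shape, np.nan)
    fn = getattr(model, "predict_suitability", None)
    if fn is None:
        fn = lambda X: _suitability(model, X)
    for start in range(0, rows.size, batch):
        sl = slice(start, start + batch)
        X = stack.table(rows[sl], cols[sl])
        out[rows[sl], cols[sl]] = fn(X)
    return grid.copy_with(out, kind="continuous", name="ensemble_probability")


def variable_contributions(
    ens: EnsembleSDM,
    table: TrainingTable,
    eval_X: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Leave-one-variable-out contribution percentages.

    For each variable, each retained algorithm is refitted without it; the
    Pearson correlation r between full-model and omitted-model predictions
    over evaluation rows gives a raw score 1 - r (floored at 0), averaged
    across retained algorithms and normalized to sum to 100%.
    """
    check_is_fitted(ens, "weights_")
    names = list(table.X.columns)
    if len(names) < 2:
        raise ValueError("contributions need at least 2 variables")
    if eval_X is None:
        eval_X = table.X
    base_seed = int(ens.random_state) % (2**31)
    full_preds: dict[str, np.ndarray] = {}
    for algo in ens.retained_algorithms_:
        est = fit_algorithm(algo, table, random_state=base_seed)
        full_preds[algo] = _suitability(est, eval_X)

    raw: dict[str, float] = {}
    for var in names:
        keep = [n for n in names if n != var]
        sub = TrainingTable(
            X=table.X[keep],
            y=table.y,
            cells=table.cells,
            kinds={n: k for n, k in table.kinds.items() if n != var},
        )
        scores = []
        for algo in ens.retained_algorithms_:
            try:
                est = fit_algorithm(algo, sub, random_state=base_seed)
                p = _suitability(est, eval_X[keep])
                r = _pearson(full_preds[algo], p)
                scores.append(max(0.0, 1.0 - r))
            except Exception as exc:  # refit failure: flag, keep going
                warnings.warn(
                    f"contribution refit failed for {var!r}/{algo}: {exc}"
                )
        raw[var] = float(np.mean(scores)) if scores else float("nan")

    return normalize_contributions(raw)


def normalize_contributions(raw: dict[str, float]) -> dict[str, float]:
    """Rescale raw leave-one-out scores to percentages summing to 100.

    Non-finite scores (failed refits) are passed through unchanged and
    excluded from the normalization.
    """
    ok = {k: v for k, v in raw.items() if np.isfinite(v)}
    total = sum(ok.values())
    if total <= 0:
        return {k: (100.0 / len(ok) if np.isfinite(v) else v)
                for k, v in raw.items()}
    return {
        k: (100.0 * v / total if np.isfinite(v) else v)
        for k, v in raw.items()
    }


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_sdm_ensemble(
    stack: EnvStack,
    occurrences: OccurrenceSet,
    n_pseudo_absences: int = 10000,
    n_replicates: int = 10,
    calibration_fraction: float = 0.75,
    auc_gate: float = 0.75,
    weighting: str = "auc",
    algorithms: tuple[str, ...] = ALGORITHMS,
    compute_contributions: bool = True,
    seed: int = 0,
) -> EnsembleResult:
    """End-to-end ensemble fit on a predictor stack + occurrence set."""
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 7]))
    pres = occurrences.cells(stack.grid, dedupe=True)
    pseudo = generate_pseudo_absences(
        stack, n=n_pseudo_absences, seed=rng, exclude=pres
    )
    table = build_training_table(stack, occurrences, pseudo)
    ens = EnsembleSDM(
        algorithms=algorithms,
        n_replicates=n_replicates,
        calibration_fraction=calibration_fraction,
        auc_gate=auc_gate,
        weighting=weighting,
        categorical_features=[
            n for n, k in table.kinds.items() if k == "categorical"
        ],
        random_state=seed,
    )
    ens._fit_table(table)
    prob = predict_raster(ens, stack)
    binary = prob.copy_with(
        np.where(
            np.isnan(prob.values),
            np.nan,
            (prob.values >= ens.threshold_).astype(float),
        ),
        kind="categorical",
        name="binary_suitability",
    )
    contributions: dict[str, float] = {}
    if compute_contributions:
        # evaluate correlations on a deterministic subsample of valid cells
        valid_rows, valid_cols = np.nonzero(stack.valid_mask)
        m = valid_rows.size
        k = min(m, 2000)
        pick = (np.arange(k) * (m / k)).astype(int)
        eval_X = stack.table(valid_rows[pick], valid_cols[pick])
        contributions = variable_contributions(ens, table, eval_X)
    return EnsembleResult(
        probability=prob,
        threshold=float(ens.threshold_),
        binary=binary,
        metrics=ens.metrics_,
        retained_models=[r for r in ens.models_ if r.retained],
        contributions=contributions,
        algorithm_metrics=ens.algorithm_metrics_table(),
        weights=dict(ens.weights_),
    )
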