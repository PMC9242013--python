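"""Barrier-prediction model training and evaluation.

Seven regressor families over standardized feature tables, with direct or
delta targets (delta models fit DFT-minus-baseline and add the baseline
barrier back at prediction time), greedy forward feature selection, grid
hyperparameter tuning, k-fold CV, repeated-split double CV, learning curves
and permutation importances.

Leakage protection is structural and enforced: selection and tuning receive
a :class:`GuardedMatrix` that raises :class:`LeakageError` on any access to
rows outside the training split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from .featurize import FeatureTable, prune, standardize

FAMILIES = ("Ridge", "NNR", "RFR", "GBR", "SVR", "KRR", "GPR")
KERNEL_FAMILIES = ("SVR", "KRR", "GPR")


class LeakageError(RuntimeError):
    """A model-selection step touched rows outside the training split."""


class GuardedMatrix:
    """A row-access-guarded view of a feature matrix.

    Any attempt to read a row position outside the allowed set raises
    :class:`LeakageError`; selection and tuning only ever see train rows.
    """

    def __init__(self, values: np.ndarray, allowed_positions: Sequence[int]):
        self._values = np.asarray(values, dtype=float)
        self._allowed = frozenset(int(i) for i in allowed_positions)

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    def rows(self, positions: Sequence[int]) -> np.ndarray:
        idx = np.asarray(positions, dtype=int)
        bad = [int(i) for i in idx if int(i) not in self._allowed]
        if bad:
            raise LeakageError(
                f"guarded row positions accessed outside the train split: {bad[:5]}"
            )
        return self._values[idx]


def _rows(x, positions):
    if isinstance(x, GuardedMatrix):
        return x.rows(positions)
    return np.asarray(x, dtype=float)[np.asarray(positions, dtype=int)]


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

DEFAULT_GRIDS: dict[str, dict] = {
    "Ridge": {"alpha": [10.0**p for p in range(-3, 4)]},
    "NNR": {"n_neighbors": list(range(1, 16))},
    "RFR": {"n_estimators": [100, 300, 500], "max_depth": [3, 5, None]},
    "GBR": {"n_estimators": [100, 300, 500], "max_depth": [3, 5, None]},
    "SVR": {
        "C": [10.0**p for p in range(-2, 4)],
        "epsilon": [0.01, 0.1, 0.5],
        "gamma": ["scale", 1e-3, 1e-2, 1e-1, 1.0],
    },
    "KRR": {"alpha": [10.0**p for p in range(-4, 2)], "gamma": [None, 1e-2, 1e-1]},
    "GPR": {"nu": [1.5, 2.5]},
}


@dataclass
class ModelSpec:
    family: str
    kernel: str | None = None
    grid: dict | None = None
    mode: str = "direct"  # "direct" | "delta"
    seed: int = 0
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in KERNEL_FAMILIES and self.kernel is None:
            raise ValueError(f"{self.family} requires a kernel")
        if self.mode not in ("direct", "delta"):
            raise ValueError(f"unknown target mode {self.mode!r}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.family].items()}
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be non-empty")


def make_estimator(spec: ModelSpec, params: dict):
    fam = spec.family
    if fam == "Ridge":
        return Ridge(alpha=params["alpha"], random_state=spec.seed)
    if fam == "NNR":
        return KNeighborsRegressor(n_neighbors=params["n_neighbors"])
    if fam == "RFR":
        return RandomForestRegressor(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            random_state=spec.seed,
        )
    if fam == "GBR":
        return GradientBoostingRegressor(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"] or 3,
            random_state=spec.seed,
        )
    if fam == "SVR":
        kernel = {"RBF": "rbf", "polynomial": "poly"}[spec.kernel]
        return SVR(
            kernel=kernel,
            C=params["C"],
            epsilon=params["epsilon"],
            gamma=params["gamma"],
        )
    if fam == "KRR":
        kernel = {"RBF": "rbf", "polynomial": "poly"}[spec.kernel]
        kw = {"alpha": params["alpha"], "kernel": kernel}
        if params.get("gamma") is not None:
            kw["gamma"] = params["gamma"]
        if kernel == "poly":
            kw["degree"] = params.get("degree", 2)
        return KernelRidge(**kw)
    if fam == "GPR":
        if spec.kernel != "Matern":
            raise ValueError("GPR uses the Matern kernel")
        return _MaternGPR(
            nu=params["nu"],
            seed=spec.seed,
            maxiter=spec.options.get("gpr_maxiter", 25),
            ard=spec.options.get("gpr_ard", True),
        )
    raise AssertionError(fam)


class _MaternGPR:
    """Matern-kernel GP regressor with a per-dimension (ARD) length scale
    built at fit time and a capped L-BFGS hyperparameter budget."""

    def __init__(self, nu: float, seed: int, maxiter: int = 25, ard: bool = True):
        self.nu = nu
        self.seed = seed
        self.maxiter = maxiter
        self.ard = ard
        self._gp: GaussianProcessRegressor | None = None

    def _optimizer(self, obj, x0, bounds):
        from scipy.optimize import fmin_l_bfgs_b

        x_opt, f_opt, _ = fmin_l_bfgs_b(obj, x0, bounds=bounds, maxiter=self.maxiter)
        return x_opt, f_opt

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        scale = np.ones(x.shape[1]) if self.ard else 1.0
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
            length_scale=scale, nu=self.nu
        ) + WhiteKernel(1e-2, (1e-8, 1e1))
        self._gp = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            random_state=self.seed,
            optimizer=self._optimizer,
            n_restarts_optimizer=0,
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            self._gp.fit(x, y)
        return self

    def predict(self, x):
        if self._gp is None:
            raise RuntimeError("model not fitted")
        return self._gp.predict(np.asarray(x, dtype=float))


def _default_params(spec: ModelSpec) -> dict:
    # mid-grid settings used during feature selection (tuning comes later)
    return {k: v[len(v) // 2] for k, v in spec.grid.items()}


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def mae(pred, truth) -> tuple[float, float]:
    """Mean absolute error and its standard error SD(|e|)/sqrt(n)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if pred.size == 0:
        raise ValueError("empty vectors")
    abs_err = np.abs(pred - truth)
    se = float(abs_err.std(ddof=1) / np.sqrt(abs_err.size)) if abs_err.size > 1 else 0.0
    return float(abs_err.mean()), se


def split(
    table: FeatureTable, test_fraction: float = 0.2, seed: int = 0
) -> tuple[list, list]:
    """Seeded disjoint train/test row ids; literature rows go to neither."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    ids = [rid for rid in table.frame.index if table.split.loc[rid] != "literature"]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_test = int(round(len(ids) * test_fraction))
    test_ids = [ids[i] for i in sorted(order[:n_test])]
    train_ids = [ids[i] for i in sorted(order[n_test:])]
    if len(train_ids) < 5:
        raise ValueError("fewer than 5 training rows")
    return train_ids, test_ids


def _cv_mae(x, y, positions, spec: ModelSpec, params: dict, k_folds: int) -> float:
    positions = np.asarray(positions, dtype=int)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=spec.seed)
    scores = []
    for tr, va in kf.split(positions):
        est = make_estimator(spec, params)
        est.fit(_rows(x, positions[tr]), y[positions[tr]])
        pred = est.predict(_rows(x, positions[va]))
        scores.append(np.abs(pred - y[positions[va]]).mean())
    return float(np.mean(scores))


def select_features(
    x,
    y: np.ndarray,
    feature_names: Sequence[str],
    train_positions: Sequence[int],
    spec: ModelSpec,
    k_folds: int = 5,
    tol: float = 0.01,
    patience: int = 3,
    max_features: int | None = None,
) -> list[str]:
    """Greedy sequential forward selection by k-fold CV MAE on train rows.

    Expansion stops after ``patience`` consecutive additions that fail to
    improve the best CV MAE by more than ``tol``; the best-scoring prefix is
    returned (always at least one feature).
    """
    names = list(feature_names)
    n_feat = len(names)
    limit = min(max_features or n_feat, n_feat)
    params = _default_params(spec)
    selected: list[int] = []
    remaining = list(range(n_feat))
    best_score = np.inf
    best_len = 0
    no_improve = 0
    x_arr = x  # may be guarded

    def score_of(cols: list[int]) -> float:
        if isinstance(x_arr, GuardedMatrix):
            sub = GuardedMatrix(
                x_arr._values[:, cols], x_arr._allowed
            )
            return _cv_mae(sub, y, train_positions, spec, params, k_folds)
        return _cv_mae(
            np.asarray(x_arr, dtype=float)[:, cols],
            y,
            train_positions,
            spec,
            params,
            k_folds,
        )

    while remaining and len(selected) < limit:
        cand_scores = [(score_of(selected + [f]), f) for f in remaining]
        s_best, f_best = min(cand_scores, key=lambda t: (t[0], t[1]))
        selected.append(f_best)
        remaining.remove(f_best)
        if not np.isfinite(best_score):
            best_score, best_len = s_best, len(selected)
        elif s_best < best_score - tol:
            best_score, best_len = s_best, len(selected)
            no_improve = 0
        else:
            no_improve += 1
            if no_improve >= patience:
                break
    keep = selected[: max(best_len, 1)]
    return [names[i] for i in keep]


@dataclass
class FittedModel:
    """A tuned estimator plus everything needed to predict in barrier units."""

    estimator: object
    feature_names: list[str]
    column_positions: list[int]
    mode: str
    hyperparameters: dict = field(default_factory=dict)

    def predict(self, x_rows: np.ndarray, baseline: np.ndarray | None = None):
        pred = self.estimator.predict(np.asarray(x_rows, dtype=float))
        if self.mode == "delta":
            if baseline is None:
                raise ValueError("delta model requires baseline barriers")
            pred = pred + np.asarray(baseline, dtype=float)
        return pred


def tune_and_fit(
    x,
    y: np.ndarray,
    feature_names: Sequence[str],
    all_names: Sequence[str],
    train_positions: Sequence[int],
    spec: ModelSpec,
    k_folds: int = 5,
    baseline: np.ndarray | None = None,
) -> tuple[FittedModel, float]:
    """Grid-search hyperparameters by CV MAE, refit on the full train rows.

    In delta mode ``y`` is transformed to ``y - baseline`` before fitting and
    predictions add the baseline back, so the returned train CV MAE is in
    original barrier units either way.
    """
    if not feature_names:
        raise ValueError("no features to fit")
    cols = [list(all_names).index(f) for f in feature_names]
    y_fit = np.asarray(y, dtype=float)
    if spec.mode == "delta":
        if baseline is None:
            raise ValueError("delta mode requires baseline barriers")
        y_fit = y_fit - np.asarray(baseline, dtype=float)

    if isinstance(x, GuardedMatrix):
        x_sub = GuardedMatrix(x._values[:, cols], x._allowed)
    else:
        x_sub = np.asarray(x, dtype=float)[:, cols]

    best = None
    for params in _grid_points(spec.grid):
        score = _cv_mae(x_sub, y_fit, train_positions, spec, params, k_folds)
        if np.isfinite(score) and (best is None or score < best[0]):
            best = (score, params)
    if best is None:
        raise RuntimeError("hyperparameter grid exhausted with no finite score")
    cv_mae_score, params = best
    est = make_estimator(spec, params)
    est.fit(_rows(x_sub, train_positions), y_fit[np.asarray(train_positions, int)])
    model = FittedModel(
        estimator=est,
        feature_names=list(feature_names),
        column_positions=cols,
        mode=spec.mode,
        hyperparameters={k: (None if v is None else v) for k, v in params.items()},
    )
    return model, cv_mae_score


def _grid_points(grid: dict):
    keys = sorted(grid)
    def rec(i, acc):
        if i == len(keys):
            yield dict(acc)
            return
        for v in grid[keys[i]]:
            acc[keys[i]] = v
            yield from rec(i + 1, acc)
    yield from rec(0, {})


def evaluate(
    model: FittedModel,
    x_rows: np.ndarray,
    y: np.ndarray,
    baseline: np.ndarray | None = None,
    row_ids: Sequence | None = None,
) -> dict:
    """MAE +/- SE, per-row absolute errors and >mean+3SD outlier flags."""
    pred = model.predict(x_rows, baseline=baseline)
    m, se = mae(pred, y)
    abs_err = np.abs(pred - np.asarray(y, dtype=float))
    cut = abs_err.mean() + 3.0 * abs_err.std(ddof=0)
    ids = list(row_ids) if row_ids is not None else list(range(len(abs_err)))
    return {
        "mae": m,
        "se": se,
        "n": int(abs_err.size),
        "abs_errors": {str(r): float(e) for r, e in zip(ids, abs_err)},
        "outliers": [str(r) for r, e in zip(ids, abs_err) if e > cut],
    }


def permutation_importance(
    model: FittedModel,
    x_rows: np.ndarray,
    y: np.ndarray,
    baseline: np.ndarray | None = None,
    n_repeats: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Mean MAE degradation when each model feature column is shuffled."""
    rng = np.random.default_rng(seed)
    x_rows = np.asarray(x_rows, dtype=float)
    base_mae, _ = mae(model.predict(x_rows, baseline=baseline), y)
    out: dict[str, float] = {}
    for k, name in enumerate(model.feature_names):
        degradations = []
        for _ in range(n_repeats):
            xp = x_rows.copy()
            xp[:, k] = rng.permutation(xp[:, k])
            m, _ = mae(model.predict(xp, baseline=baseline), y)
            degradations.append(m - base_mae)
        out[name] = float(np.mean(degradations))
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    model: dict
    selected_features: list[str]
    hyperparameters: dict
    train_cv_mae: float
    test: dict | None
    literature: dict | None
    importances: dict
    learning_curve: list | None
    split_seed: int
    n_train: int
    n_test: int
    removals: list

    def to_json(self) -> str:
        payload = {
            "model": self.model,
            "selected_features": self.selected_features,
            "hyperparameters": self.hyperparameters,
            "train_cv_mae": self.train_cv_mae,
            "test": self.test,
            "literature": self.literature,
            "importances": self.importances,
            "learning_curve": self.learning_curve,
            "split_seed": self.split_seed,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "removals": self.removals,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_pipeline(
    table: FeatureTable,
    spec: ModelSpec,
    split_seed: int = 0,
    test_fraction: float = 0.2,
    k_folds: int = 5,
    do_select: bool = True,
    select_tol: float = 0.01,
    select_patience: int = 3,
    max_features: int | None = None,
    n_importance_repeats: int = 5,
    corr_threshold: float = 0.95,
) -> EvalReport:
    """Split -> prune -> standardize -> (select) -> tune -> evaluate.

    All preprocessing statistics, feature selection and tuning use only the
    training rows (enforced by :class:`GuardedMatrix`); test and literature
    rows appear only in the final evaluation and importances.
    """
    if table.target is None:
        raise ValueError("feature table has no target barriers")
    train_ids, test_ids = split(table, test_fraction, split_seed)
    lit_ids = table.rows_with_tag("literature")

    pruned, removals = prune(
        table, corr_threshold=corr_threshold, stats_rows=train_ids
    )
    std = standardize(pruned, stats_rows=train_ids)

    all_ids = list(std.frame.index)
    pos_of = {rid: i for i, rid in enumerate(all_ids)}
    train_pos = [pos_of[r] for r in train_ids]
    test_pos = [pos_of[r] for r in test_ids]
    lit_pos = [pos_of[r] for r in lit_ids]

    x_full = std.frame.to_numpy(dtype=float)
    y_full = std.target.to_numpy(dtype=float)
    baseline_full = None
    if spec.mode == "delta":
        if std.baseline is None:
            raise ValueError("delta mode requires a baseline barrier column")
        baseline_full = pruned.frame[std.baseline].to_numpy(dtype=float)

    guarded = GuardedMatrix(x_full, train_pos)
    names = std.feature_names
    if do_select:
        features = select_features(
            guarded,
            y_full,
            names,
            train_pos,
            spec,
            k_folds=k_folds,
            tol=select_tol,
            patience=select_patience,
            max_features=max_features,
        )
    else:
        features = list(names)
    model, cv_score = tune_and_fit(
        guarded,
        y_full,
        features,
        names,
        train_pos,
        spec,
        k_folds=k_folds,
        baseline=baseline_full,
    )

    cols = model.column_positions

    def block(positions, ids):
        if not positions:
            return None
        return evaluate(
            model,
            x_full[np.asarray(positions, int)][:, cols],
            y_full[np.asarray(positions, int)],
            baseline=None
            if baseline_full is None
            else baseline_full[np.asarray(positions, int)],
            row_ids=ids,
        )

    test_block = block(test_pos, test_ids)
    lit_block = block(lit_pos, lit_ids)

    importances = {}
    for set_name, positions in (
        ("train", train_pos),
        ("test", test_pos),
        ("literature", lit_pos),
    ):
        if not positions:
            continue
        importances[set_name] = permutation_importance(
            model,
            x_full[np.asarray(positions, int)][:, cols],
            y_full[np.asarray(positions, int)],
            baseline=None
            if baseline_full is None
            else baseline_full[np.asarray(positions, int)],
            n_repeats=n_importance_repeats,
            seed=spec.seed,
        )

    return EvalReport(
        model={
            "family": spec.family,
            "kernel": spec.kernel,
            "mode": spec.mode,
            "seed": spec.seed,
        },
        selected_features=model.feature_names,
        hyperparameters=model.hyperparameters,
        train_cv_mae=cv_score,
        test=test_block,
        literature=lit_block,
        importances=importances,
        learning_curve=None,
        split_seed=split_seed,
        n_train=len(train_ids),
        n_test=len(test_ids),
        removals=[[r.feature, r.reason, r.detail] for r in removals],
    )


def double_cv(
    table: FeatureTable,
    spec: ModelSpec,
    n_extra_splits: int = 5,
    base_seed: int = 0,
    **pipeline_kwargs,
) -> tuple[list[EvalReport], dict]:
    """Repeat the full pipeline at the original and extra split seeds."""
    if n_extra_splits < 1:
        raise ValueError("n_extra_splits must be >= 1")
    seeds = [base_seed] + [base_seed + 1 + i for i in range(n_extra_splits)]
    reports = [
        run_pipeline(table, spec, split_seed=s, **pipeline_kwargs) for s in seeds
    ]
    agg = {
        "mean_train_cv_mae": float(np.mean([r.train_cv_mae for r in reports])),
        "mean_test_mae": float(
            np.mean([r.test["mae"] for r in reports if r.test is not None])
        ),
        "seeds": seeds,
    }
    lits = [r.literature["mae"] for r in reports if r.literature is not None]
    if lits:
        agg["mean_literature_mae"] = float(np.mean(lits))
    return reports, agg


def learning_curve(
    x_train: np.ndarray,
    y_train: np.ndarray,
    spec: ModelSpec,
    train_sizes: Sequence[int],
    k_folds: int = 5,
    baseline: np.ndarray | None = None,
    seed: int = 0,
) -> list[dict]:
    """Train/CV MAE (mean, SD over folds) at increasing train-subset sizes."""
    x_train = np.asarray(x_train, dtype=float)
    y_fit = np.asarray(y_train, dtype=float)
    if spec.mode == "delta":
        if baseline is None:
            raise ValueError("delta mode requires baseline barriers")
        y_fit = y_fit - np.asarray(baseline, dtype=float)
    rng = np.random.default_rng(seed)
    params = _default_params(spec)
    points = []
    for size in train_sizes:
        if size > len(y_fit):
            raise ValueError(f"train size {size} exceeds available rows")
        idx = rng.permutation(len(y_fit))[:size]
        xs, ys = x_train[idx], y_fit[idx]
        kf = KFold(n_splits=k_folds, shuffle=True, random_state=spec.seed)
        cv_scores, train_scores = [], []
        for tr, va in kf.split(xs):
            est = make_estimator(spec, params)
            est.fit(xs[tr], ys[tr])
            cv_scores.append(np.abs(est.predict(xs[va]) - ys[va]).mean())
            train_scores.append(np.abs(est.predict(xs[tr]) - ys[tr]).mean())
        points.append(
            {
                "size": int(size),
                "cv_mae": float(np.mean(cv_scores)),
                "cv_sd": float(np.std(cv_scores)),
                "train_mae": float(np.mean(train_scores)),
                "train_sd": float(np.std(train_scores)),
            }
        )
    return points
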