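"""Three-algorithm regression comparison harness.

Trains and scores, per metal and season, the three regressors used for
surface-water metal prediction:

* random forest (15 trees),
* epsilon-insensitive SVR with an RBF kernel (epsilon 0.015, gamma 1.2,
  C 200),
* a three-layer perceptron (one hidden layer of 9 sigmoid neurons)
  trained with Levenberg-Marquardt on the flattened weights, with a
  quasi-Newton (BFGS) fallback.

Scoring uses RMSE, MAE, MAPE and R^2 on a seeded 70/30 split plus
k-fold cross-validation.  Note the MAPE convention here: the
denominator is the *predicted* value, not the observed one, so
predicted zeros are excluded element-wise with a warning.  Features are
z-scored (fit on the training part only) for SVR and the perceptron;
the forest sees raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .records import METALS, SampleRecord, replicate_means, to_frame

ALGORITHMS = ("random_forest", "svr", "ann")


@dataclass
class ModelConfig:
    """One algorithm plus its hyperparameters.

    Defaults follow the tuned values used in the study's training
    phase: RF 15 trees; SVR epsilon 0.015, RBF gamma 1.2, C 200; ANN
    3 layers with 9 hidden sigmoid neurons, 1000 iterations,
    Levenberg-Marquardt.  ``learning_rate`` is kept for completeness
    but has no role under LM/BFGS training.
    """

    algorithm: str = "random_forest"
    n_trees: int = 15
    epsilon: float = 0.015
    gamma: float = 1.2
    cost: float = 200.0
    hidden_neurons: int = 9
    epochs: int = 1000
    learning_rate: float = 0.01
    optimizer: str = "levenberg_marquardt"  # or "quasi_newton"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        for name in ("n_trees", "epsilon", "gamma", "cost", "hidden_neurons",
                     "epochs", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.optimizer not in ("levenberg_marquardt", "quasi_newton"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class MLPRegressorLM(BaseEstimator, RegressorMixin):
    """Single-hidden-layer sigmoid perceptron fit by Levenberg-Marquardt.

    The network is y = w2 . sigmoid(W1 x + b1) + b2 with ``n_hidden``
    hidden units.  All weights are flattened into one parameter vector
    and fit to the prediction residuals with
    ``scipy.optimize.least_squares(method="lm")``; ``optimizer=
    "quasi_newton"`` switches to BFGS on the summed squared error.
    Non-convergence leaves the best parameters found and attaches a
    warning.  Deterministic given ``random_state``.
    """

    def __init__(self, n_hidden: int = 9, max_iter: int = 1000,
                 optimizer: str = "levenberg_marquardt", random_state: int = 0):
        self.n_hidden = n_hidden
        self.max_iter = max_iter
        self.optimizer = optimizer
        self.random_state = random_state

    def _unpack(self, theta: np.ndarray, n_features: int):
        h, f = self.n_hidden, n_features
        w1 = theta[: h * f].reshape(h, f)
        b1 = theta[h * f: h * f + h]
        w2 = theta[h * f + h: h * f + 2 * h]
        b2 = theta[-1]
        return w1, b1, w2, b2

    def _forward(self, theta: np.ndarray, X: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = self._unpack(theta, X.shape[1])
        return expit(X @ w1.T + b1) @ w2 + b2

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.random_state)
        n_params = self.n_hidden * (X.shape[1] + 2) + 1
        theta0 = rng.normal(0.0, 0.5, size=n_params)

        if self.optimizer == "levenberg_marquardt":
            # MINPACK's LM needs at least as many residuals as
            # parameters; on smaller samples fall back to the
            # trust-region reflective variant of damped least squares.
            method = "lm" if len(y) >= n_params else "trf"
            res = least_squares(
                lambda t: self._forward(t, X) - y,
                theta0,
                method=method,
                max_nfev=self.max_iter,
            )
            self.theta_, converged = res.x, res.status > 0
        else:
            res = minimize(
                lambda t: 0.5 * np.sum((self._forward(t, X) - y) ** 2),
                theta0,
                method="BFGS",
                options={"maxiter": self.max_iter},
            )
            self.theta_, converged = res.x, res.success
        self.converged_ = bool(converged)
        if not self.converged_:
            warnings.warn(
                "perceptron training did not converge; returning best-so-far "
                "weights",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    def predict(self, X):
        return self._forward(self.theta_, np.asarray(X, dtype=float))


def build_model(config: ModelConfig):
    """Instantiate the estimator (with its scaler where one is used)."""
    if config.algorithm == "random_forest":
        return RandomForestRegressor(
            n_estimators=config.n_trees, random_state=config.seed
        )
    if config.algorithm == "svr":
        core = SVR(kernel="rbf", gamma=config.gamma, C=config.cost,
                   epsilon=config.epsilon)
    else:
        core = MLPRegressorLM(
            n_hidden=config.hidden_neurons,
            max_iter=config.epochs,
            optimizer=config.optimizer,
            random_state=config.seed,
        )
    return Pipeline([("scale", StandardScaler()), ("model", core)])


def train_model(config: ModelConfig, features, target):
    """Fit the configured estimator; NaN inputs are rejected."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be 2-D and aligned with target")
    if len(y) < 2:
        raise ValueError("need at least 2 training rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("features/target contain NaN or infinite values")
    model = build_model(config)
    model.fit(X, y)
    return model


def split_train_validate(data, fraction: float = 0.70, seed: int = 0):
    """Seeded shuffle split into train/validation index arrays.

    Train size is fraction*n rounded to nearest; the split is disjoint
    and exhaustive.  ``data`` may be a length, an array, or a DataFrame.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n = data if isinstance(data, int) else len(data)
    if n < 4:
        raise ValueError("need at least 4 records to split")
    idx = np.random.default_rng(seed).permutation(n)
    n_train = int(np.floor(fraction * n + 0.5))
    return idx[:n_train], idx[n_train:]


def evaluate(actual, predicted) -> dict[str, float]:
    """RMSE, MAE, MAPE (percent, predicted-value denominator) and R^2."""
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length, non-empty")
    err = a - p
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    nz = p != 0
    if nz.all():
        mape = float(100.0 * np.mean(np.abs(err / p)))
    elif nz.any():
        warnings.warn(
            f"MAPE: excluded {int((~nz).sum())} element(s) with predicted "
            "value 0",
            RuntimeWarning,
            stacklevel=2,
        )
        mape = float(100.0 * np.mean(np.abs(err[nz] / p[nz])))
    else:
        warnings.warn("MAPE undefined: all predicted values are 0",
                      RuntimeWarning, stacklevel=2)
        mape = float("nan")
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return {"rmse": rmse, "mae": mae, "mape_percent": mape, "r_squared": r2}


def kfold_validate(features, target, config: ModelConfig, k: int = 5,
                   seed: int = 0) -> pd.DataFrame:
    """Per-fold metrics plus a mean/sd summary over k seeded folds."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds the {len(y)} available records")
    rows = []
    for fold, (tr, va) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(X)
    ):
        model = train_model(config, X[tr], y[tr])
        m = evaluate(y[va], model.predict(X[va]))
        rows.append({"fold": fold, **m})
    df = pd.DataFrame(rows)
    metric_cols = ["rmse", "mae", "mape_percent", "r_squared"]
    summary = pd.DataFrame(
        [
            {"fold": "mean", **df[metric_cols].mean().to_dict()},
            {"fold": "sd", **df[metric_cols].std(ddof=1).to_dict()},
        ]
    )
    return pd.concat([df, summary], ignore_index=True)


@dataclass
class MetricsReport:
    """Tidy comparison table: one row per metal x season x model."""

    table: pd.DataFrame
    split_fraction: float = 0.70
    k_folds: int = 5
    predictions: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _design(records: list[SampleRecord], target_metal: str, season: str | None):
    """Feature/target layout: the other four metals + season indicator +
    coordinates predict the target metal."""
    df = to_frame(replicate_means(records))
    if season is not None:
        df = df[df["season"] == season]
    others = [m for m in METALS if m != target_metal]
    X = df[[f"{m}_mg_l" for m in others] + ["lon", "lat"]].copy()
    if season is None:
        X["season_idx"] = pd.factorize(df["season"])[0]
    y = df[f"{target_metal}_mg_l"].to_numpy()
    meta = df[["sample_id", "season"]].reset_index(drop=True)
    return X.to_numpy(dtype=float), y, meta


def compare_models(
    records: list[SampleRecord],
    metals=METALS,
    seasons: tuple[str | None, ...] | None = None,
    algorithms=ALGORITHMS,
    fraction: float = 0.70,
    k: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Run the full metal x season x algorithm comparison.

    Each cell fits on a seeded 70/30 split, scores the held-out 30%,
    and reports the k-fold cross-validated means alongside.
    """
    if seasons is None:
        seasons = tuple(sorted({r.season for r in records}))
    rows = []
    preds = []
    for metal in metals:
        for season in seasons:
            X, y, meta = _design(records, metal, season)
            if len(y) < max(4, k):
                continue
            tr, va = split_train_validate(len(y), fraction, seed)
            for algo in algorithms:
                config = ModelConfig(algorithm=algo, seed=seed)
                model = train_model(config, X[tr], y[tr])
                yhat = model.predict(X[va])
                m = evaluate(y[va], yhat)
                cv = kfold_validate(X, y, config, k=min(k, len(y)), seed=seed)
                cv_mean = cv[cv["fold"] == "mean"].iloc[0]
                rows.append(
                    {
                        "metal": metal,
                        "season": season if season is not None else "all",
                        "model": algo,
                        **m,
                        "cv_rmse": cv_mean["rmse"],
                        "cv_mae": cv_mean["mae"],
                        "cv_mape_percent": cv_mean["mape_percent"],
                        "cv_r_squared": cv_mean["r_squared"],
                    }
                )
                for i, j in enumerate(va):
                    preds.append(
                        {
                            "sample_id": meta.loc[j, "sample_id"],
                            "metal": metal,
                            "season": meta.loc[j, "season"],
                            "model": algo,
                            "observed": y[j],
                            "predicted": float(yhat[i]),
                        }
                    )
    return MetricsReport(
        table=pd.DataFrame(rows),
        split_fraction=fraction,
        k_folds=k,
        predictions=pd.DataFrame(preds),
    )
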