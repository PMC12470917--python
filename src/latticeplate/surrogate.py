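"""Multi-output neural surrogate of the FE responses, with baselines.

The surrogate is a fully connected multilayer perceptron
``a^(l) = f(W^(l) a^(l-1) + b^(l))`` with ReLU hidden activations and a
linear 3-neuron output head predicting (sigma_vM_max [MPa], delta_max
[mm], sigma_screw_max [MPa]) from the standardised design vector.
Training uses Adam on a Huber loss (mean squared error by switch),
He initialisation, L2 weight decay, inverted dropout after the first
two hidden layers, and early stopping on validation MAE with
best-checkpoint restore.  Implemented directly in numpy: the network
is small enough that a framework buys nothing, and full control keeps
training bit-reproducible under a fixed seed.

Targets are z-scored internally for optimisation (so the Huber
transition delta acts on a common scale) and predictions are returned
in native units; inputs are z-scored with training-split statistics
only.  A zero-mean Gaussian residual model per output, with sigma equal
to the held-out-test RMSE, feeds the downstream risk computation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.utils.validation import check_is_fitted

__all__ = ["Standardizer", "MLPSurrogate", "PolySurface", "EvalReport",
           "ResidualModel", "TrainingError", "split_stratified", "evaluate",
           "crossvalidate", "fit_residual_model", "poly_baseline",
           "random_search", "TARGET_NAMES"]

TARGET_NAMES = ("sigma_vm_max", "delta_max", "sigma_screw_max")


class TrainingError(RuntimeError):
    pass


class Standardizer:
    """z-scoring fitted on the training split only.

    Thin guard over :class:`~sklearn.preprocessing.StandardScaler` that
    refuses zero-variance inputs instead of silently passing them
    through (a constant input cannot be standardised and would hide a
    degenerate design grid).
    """

    def __init__(self) -> None:
        self._scaler = StandardScaler()

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, float)
        self._scaler.fit(X)
        if np.any(self._scaler.var_ == 0):
            bad = int(np.argmax(self._scaler.var_ == 0))
            raise ValueError(f"input column {bad} has zero variance on the "
                             "training split")
        return self

    def transform(self, X) -> np.ndarray:
        return self._scaler.transform(np.asarray(X, float))

    def inverse_transform(self, Z) -> np.ndarray:
        return self._scaler.inverse_transform(np.asarray(Z, float))

    @property
    def mean_(self) -> np.ndarray:
        return self._scaler.mean_

    @property
    def scale_(self) -> np.ndarray:
        return self._scaler.scale_


@dataclass
class EvalReport:
    """Per-output regression metrics on one split."""

    n: int
    output_names: tuple[str, ...]
    mae: np.ndarray  # native units
    mae_pct: np.ndarray  # % of the split's target mean
    rmse: np.ndarray
    r2: np.ndarray

    def as_dict(self) -> dict:
        return {"n": self.n,
                "outputs": {name: {"mae": float(self.mae[i]),
                                   "mae_pct": float(self.mae_pct[i]),
                                   "rmse": float(self.rmse[i]),
                                   "r2": float(self.r2[i])}
                            for i, name in enumerate(self.output_names)}}


@dataclass
class ResidualModel:
    """Zero-mean Gaussian surrogate-error model, one width per output."""

    sigma: np.ndarray  # (k,) in native units (MPa, mm, MPa)
    output_names: tuple[str, ...] = TARGET_NAMES

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, float)
        if np.any(self.sigma <= 0):
            raise ValueError("residual sigma must be strictly positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((n, len(self.sigma))) * self.sigma


def _huber(e: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Value and derivative of the Huber penalty, elementwise."""
    a = np.abs(e)
    quad = a <= delta
    val = np.where(quad, 0.5 * e ** 2, delta * (a - 0.5 * delta))
    grad = np.where(quad, e, delta * np.sign(e))
    return val, grad


class MLPSurrogate(BaseEstimator, RegressorMixin):
    """Feed-forward multi-output surrogate (sklearn estimator API).

    Parameters follow the selected training configuration: three hidden
    layers 64-32-16, ReLU, dropout 0.10 after the first two hidden
    layers, L2 weight decay 1e-4, Adam (lr 1e-3, beta1 0.9, beta2 0.999,
    eps 1e-8), batch size 64, Huber loss (delta 1.0) summed across
    outputs, early stopping patience 80 within a 2000-epoch cap.

    ``fit(X, y)`` carves an internal validation split of
    ``validation_fraction`` unless an explicit ``(X_val, y_val)`` pair is
    passed.  With a fixed ``random_state`` the fitted weights are
    bit-identical across runs on one platform.
    """

    def __init__(self, hidden_layer_sizes: tuple[int, ...] = (64, 32, 16),
                 dropout: float = 0.10, dropout_layers: int = 2,
                 weight_decay: float = 1e-4, learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 batch_size: int = 64, loss: str = "huber",
                 huber_delta: float = 1.0, patience: int = 80,
                 max_epochs: int = 2000, validation_fraction: float = 0.15,
                 standardize_targets: bool = True,
                 random_state: int | None = None):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout = dropout
        self.dropout_layers = dropout_layers
        self.weight_decay = weight_decay
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.batch_size = batch_size
        self.loss = loss
        self.huber_delta = huber_delta
        self.patience = patience
        self.max_epochs = max_epochs
        self.validation_fraction = validation_fraction
        self.standardize_targets = standardize_targets
        self.random_state = random_state

    # -- core forward/backward -------------------------------------------

    def _forward(self, Z: np.ndarray, coefs, intercepts,
                 drop_masks=None) -> list[np.ndarray]:
        acts = [Z]
        n_hidden = len(coefs) - 1
        for l in range(n_hidden):
            a = acts[-1] @ coefs[l] + intercepts[l]
            np.maximum(a, 0.0, out=a)
            if drop_masks is not None and l < self.dropout_layers:
                a *= drop_masks[l]
            acts.append(a)
        acts.append(acts[-1] @ coefs[-1] + intercepts[-1])
        return acts

    def _init_params(self, n_in: int, n_out: int, rng: np.random.Generator):
        sizes = [n_in, *self.hidden_layer_sizes, n_out]
        coefs, intercepts = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            coefs.append(rng.standard_normal((fan_in, fan_out))
                         * np.sqrt(2.0 / fan_in))
            intercepts.append(np.zeros(fan_out))
        return coefs, intercepts

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None) -> "MLPSurrogate":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if y.ndim == 1:
            y = y[:, None]
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("need 0 < patience < max_epochs")
        rng = np.random.default_rng(self.random_state)

        if X_val is None:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            perm = rng.permutation(len(X))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X, X_val = X[tr_idx], X[val_idx]
            y, y_val = y[tr_idx], y[val_idx]
        else:
            X_val = np.asarray(X_val, float)
            y_val = np.asarray(y_val, float)
            if y_val.ndim == 1:
                y_val = y_val[:, None]

        self.x_scaler_ = Standardizer().fit(X)
        Z = self.x_scaler_.transform(X)
        Zv = self.x_scaler_.transform(X_val)
        if self.standardize_targets:
            self.y_scaler_ = Standardizer().fit(y)
            T = self.y_scaler_.transform(y)
        else:
            self.y_scaler_ = None
            T = y

        n, k = Z.shape[1], T.shape[1]
        coefs, intercepts = self._init_params(n, k, rng)
        m_c = [np.zeros_like(w) for w in coefs]
        v_c = [np.zeros_like(w) for w in coefs]
        m_b = [np.zeros_like(b) for b in intercepts]
        v_b = [np.zeros_like(b) for b in intercepts]
        n_hidden = len(self.hidden_layer_sizes)
        keep = 1.0 - self.dropout

        best_mae = np.inf
        best_epoch = -1
        best_state = None
        history = []
        step = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(len(Z))
            epoch_loss = 0.0
            for start in range(0, len(Z), self.batch_size):
                idx = order[start:start + self.batch_size]
                Zb, Tb = Z[idx], T[idx]
                masks = None
                if self.dropout > 0:
                    masks = [(rng.random((len(idx), w)) < keep) / keep
                             for w in self.hidden_layer_sizes[:self.dropout_layers]]
                acts = self._forward(Zb, coefs, intercepts, masks)
                err = acts[-1] - Tb
                if self.loss == "huber":
                    val, dloss = _huber(err, self.huber_delta)
                elif self.loss == "mse":
                    val, dloss = 0.5 * err ** 2, err
                else:
                    raise ValueError(f"unknown loss '{self.loss}'")
                epoch_loss += float(val.sum())
                delta = dloss / len(idx)

                g_c = [None] * len(coefs)
                g_b = [None] * len(coefs)
                for l in range(len(coefs) - 1, -1, -1):
                    g_c[l] = acts[l].T @ delta + self.weight_decay * coefs[l]
                    g_b[l] = delta.sum(axis=0)
                    if l > 0:
                        delta = delta @ coefs[l].T
                        delta[acts[l] <= 0] = 0.0
                        if masks is not None and l - 1 < self.dropout_layers:
                            delta *= masks[l - 1]

                step += 1
                lr_t = self.learning_rate * \
                    np.sqrt(1 - self.beta2 ** step) / (1 - self.beta1 ** step)
                for l in range(len(coefs)):
                    m_c[l] = self.beta1 * m_c[l] + (1 - self.beta1) * g_c[l]
                    v_c[l] = self.beta2 * v_c[l] + (1 - self.beta2) * g_c[l] ** 2
                    coefs[l] -= lr_t * m_c[l] / (np.sqrt(v_c[l]) + self.eps)
                    m_b[l] = self.beta1 * m_b[l] + (1 - self.beta1) * g_b[l]
                    v_b[l] = self.beta2 * v_b[l] + (1 - self.beta2) * g_b[l] ** 2
                    intercepts[l] -= lr_t * m_b[l] / (np.sqrt(v_b[l]) + self.eps)

            if not np.isfinite(epoch_loss):
                raise TrainingError(f"training diverged (non-finite loss) at "
                                    f"epoch {epoch}")
            pred_val = self._forward(Zv, coefs, intercepts)[-1]
            if self.y_scaler_ is not None:
                pred_val = self.y_scaler_.inverse_transform(pred_val)
            val_mae = float(np.mean(np.abs(pred_val - y_val)))
            history.append({"epoch": epoch, "train_loss": epoch_loss / len(Z),
                            "val_mae": val_mae})
            if val_mae < best_mae:
                best_mae = val_mae
                best_epoch = epoch
                best_state = ([w.copy() for w in coefs],
                              [b.copy() for b in intercepts])
            elif epoch - best_epoch >= self.patience:
                break

        self.coefs_, self.intercepts_ = best_state
        self.best_epoch_ = best_epoch
        self.best_val_mae_ = best_mae
        self.n_iter_ = len(history)
        self.history_ = pd.DataFrame(history)
        self.n_features_in_ = n
        self.n_outputs_ = k
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, float)
        one = X.ndim == 1
        if one:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} inputs, got "
                             f"{X.shape[1]}")
        Z = self.x_scaler_.transform(X)
        out = self._forward(Z, self.coefs_, self.intercepts_)[-1]
        if self.y_scaler_ is not None:
            out = self.y_scaler_.inverse_transform(out)
        return out[0] if one else out

    @classmethod
    def from_weights(cls, coefs: Sequence[np.ndarray],
                     intercepts: Sequence[np.ndarray]) -> "MLPSurrogate":
        """Net with hand-set weights and identity scalers (for verification)."""
        net = cls(hidden_layer_sizes=tuple(w.shape[1] for w in coefs[:-1]),
                  standardize_targets=False, dropout=0.0)
        n_in = coefs[0].shape[0]
        sc = Standardizer()
        sc._scaler.fit(np.vstack([np.zeros(n_in), np.ones(n_in)]) * 2 - 0.5)
        sc._scaler.mean_ = np.zeros(n_in)
        sc._scaler.scale_ = np.ones(n_in)
        net.x_scaler_ = sc
        net.y_scaler_ = None
        net.coefs_ = [np.asarray(w, float) for w in coefs]
        net.intercepts_ = [np.asarray(b, float) for b in intercepts]
        net.n_features_in_ = n_in
        net.n_outputs_ = coefs[-1].shape[1]
        return net

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        check_is_fitted(self, "coefs_")
        header = {"params": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in self.get_params().items()},
                  "shapes": [list(w.shape) for w in self.coefs_],
                  "x_mean": self.x_scaler_.mean_.tolist(),
                  "x_scale": self.x_scaler_.scale_.tolist(),
                  "y_mean": (self.y_scaler_.mean_.tolist()
                             if self.y_scaler_ else None),
                  "y_scale": (self.y_scaler_.scale_.tolist()
                              if self.y_scaler_ else None)}
        flat = np.concatenate([w.ravel() for w in self.coefs_] +
                              [b.ravel() for b in self.intercepts_])
        payload = {"header": header, "weights": flat.tolist()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "MLPSurrogate":
        payload = json.loads(Path(path).read_text())
        header = payload["header"]
        params = dict(header["params"])
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        net = cls(**params)
        shapes = [tuple(s) for s in header["shapes"]]
        flat = np.array(payload["weights"])
        coefs, intercepts = [], []
        pos = 0
        for s in shapes:
            size = s[0] * s[1]
            coefs.append(flat[pos:pos + size].reshape(s))
            pos += size
        for s in shapes:
            intercepts.append(flat[pos:pos + s[1]])
            pos += s[1]
        net.coefs_, net.intercepts_ = coefs, intercepts
        sc = Standardizer()
        sc._scaler.fit(np.vstack([np.zeros(shapes[0][0]),
                                  np.ones(shapes[0][0])]))
        sc._scaler.mean_ = np.array(header["x_mean"])
        sc._scaler.scale_ = np.array(header["x_scale"])
        sc._scaler.var_ = sc._scaler.scale_ ** 2
        net.x_scaler_ = sc
        if header["y_mean"] is not None:
            ysc = Standardizer()
            ysc._scaler.fit(np.vstack([np.zeros(len(header["y_mean"])),
                                       np.ones(len(header["y_mean"]))]))
            ysc._scaler.mean_ = np.array(header["y_mean"])
            ysc._scaler.scale_ = np.array(header["y_scale"])
            ysc._scaler.var_ = ysc._scaler.scale_ ** 2
            net.y_scaler_ = ysc
        else:
            net.y_scaler_ = None
        net.n_features_in_ = shapes[0][0]
        net.n_outputs_ = shapes[-1][1]
        return net


class PolySurface(BaseEstimator, RegressorMixin):
    """Polynomial response-surface baseline on standardised inputs."""

    def __init__(self, degree: int = 2):
        self.degree = degree

    def fit(self, X, y) -> "PolySurface":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n_terms = PolynomialFeatures(self.degree).fit(
            np.zeros((1, X.shape[1]))).n_output_features_
        if len(X) < n_terms:
            raise ValueError(f"need at least {n_terms} rows for degree "
                             f"{self.degree} in {X.shape[1]} variables")
        self.pipeline_ = make_pipeline(StandardScaler(),
                                       PolynomialFeatures(self.degree),
                                       LinearRegression())
        self.pipeline_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(np.asarray(X, float))


# -- split / metrics / residuals -----------------------------------------


def split_stratified(df: pd.DataFrame,
                     fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                     seed: int = 0,
                     strata: Sequence[str] = ("P", "t_plate", "t_lat")
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/val/test split, stratified.

    Strata are the joint levels of the given columns; strata smaller
    than 3 rows are pooled (with a warning) before allocation.  Within
    every stratum the three splits receive their share to within one
    row, and global sizes match the fractions to within one row, via a
    largest-deficit assignment of the rounding remainders.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    cols = [c for c in strata if c in df.columns]
    if cols:
        labels = df[cols].apply(tuple, axis=1)
    else:
        labels = pd.Series([()] * len(df), index=df.index)
    counts = labels.value_counts()
    small = set(counts[counts < 3].index)
    if small:
        warnings.warn(f"{len(small)} strata with <3 rows pooled before the "
                      "split", stacklevel=2)
        labels = labels.where(~labels.isin(small), other="_pooled")

    targets = np.array(fractions) * len(df)
    allocated = np.zeros(3)
    parts: list[list[np.ndarray]] = [[], [], []]
    for label in sorted(labels.unique(), key=str):
        idx = labels.index[labels == label].to_numpy()
        idx = idx[rng.permutation(len(idx))]
        share = np.array(fractions) * len(idx)
        take = np.floor(share).astype(int)
        while take.sum() < len(idx):
            deficit = (allocated + take) - targets * \
                ((allocated.sum() + take.sum() + 1) / len(df))
            j = int(np.argmin(deficit + np.where(share - take <= 0, np.inf, 0)))
            take[j] += 1
        pos = 0
        for j in range(3):
            parts[j].append(idx[pos:pos + take[j]])
            pos += take[j]
        allocated += take
    out = tuple(df.loc[np.concatenate(p)].copy() if p else df.iloc[:0].copy()
                for p in parts)
    return out


def evaluate(model, X, y, output_names: Sequence[str] = TARGET_NAMES
             ) -> EvalReport:
    """MAE (native and % of split mean), RMSE and R-squared per output."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) == 0:
        raise ValueError("cannot evaluate on an empty split")
    if y.ndim == 1:
        y = y[:, None]
    pred = np.asarray(model.predict(X), float)
    if pred.ndim == 1:
        pred = pred[:, None]
    mae = mean_absolute_error(y, pred, multioutput="raw_values")
    rmse = np.sqrt(mean_squared_error(y, pred, multioutput="raw_values"))
    if np.allclose(y, y.mean(axis=0)):
        r2 = np.zeros(y.shape[1])
    else:
        r2 = r2_score(y, pred, multioutput="raw_values")
    mae_pct = 100.0 * mae / np.abs(y.mean(axis=0))
    return EvalReport(n=len(y), output_names=tuple(output_names[:y.shape[1]]),
                      mae=mae, mae_pct=mae_pct, rmse=rmse, r2=r2)


def crossvalidate(X, y, k: int = 5, seed: int = 0,
                  output_names: Sequence[str] = TARGET_NAMES,
                  **net_params) -> dict:
    """k-fold cross-validation of the surrogate; fold-averaged metrics."""
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if y.ndim == 1:
        y = y[:, None]
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, te) in enumerate(kf.split(X)):
        params = {"random_state": seed + 1000 + fold, **net_params}
        net = MLPSurrogate(**params)
        net.fit(X[tr], y[tr])
        reports.append(evaluate(net, X[te], y[te], output_names))
    return {"folds": reports,
            "r2_mean": np.mean([r.r2 for r in reports], axis=0),
            "r2_std": np.std([r.r2 for r in reports], axis=0),
            "mae_pct_mean": np.mean([r.mae_pct for r in reports], axis=0)}


def fit_residual_model(model, X_test, y_test,
                       output_names: Sequence[str] = TARGET_NAMES
                       ) -> ResidualModel:
    """Per-output sigma = RMSE of the untouched-test residuals."""
    report = evaluate(model, X_test, y_test, output_names)
    rmse = report.rmse.copy()
    if np.any(rmse == 0):
        raise ValueError("zero test residuals: a degenerate residual model "
                         "cannot feed the risk computation")
    floor = np.finfo(float).eps * np.maximum(1.0, np.abs(
        np.asarray(y_test, float).mean(axis=0)))
    return ResidualModel(sigma=np.maximum(rmse, floor),
                         output_names=tuple(report.output_names))


def poly_baseline(X_train, y_train, X_test, y_test, degree: int = 2
                  ) -> tuple[PolySurface, EvalReport]:
    """Fitted polynomial response surface plus its test-split report."""
    model = PolySurface(degree=degree).fit(X_train, y_train)
    return model, evaluate(model, X_test, y_test)


#: Hyperparameter ranges for the optional random search.
SEARCH_SPACE = {
    "hidden_layer_sizes": [(32,), (64, 32), (64, 32, 16), (128, 64, 32, 16)],
    "learning_rate": (1e-4, 1e-2),  # log-uniform
    "weight_decay": (1e-6, 1e-3),  # log-uniform
    "dropout": (0.0, 0.3),
    "batch_size": [32, 64, 128],
}


def random_search(X_train, y_train, X_val, y_val, n_trials: int = 10,
                  seed: int = 0, space: dict | None = None,
                  **fixed_params) -> tuple[dict, list[dict]]:
    """Seeded random search over the architecture/optimiser space.

    A deliberately simple replacement for sequential Bayesian
    hyperparameter optimisation: the default configuration is already
    the selected one, so the search is an optional refinement.  Returns
    the best parameter set (lowest validation MAE) and the trial log.
    """
    space = dict(SEARCH_SPACE if space is None else space)
    rng = np.random.default_rng(seed)
    trials = []
    for t in range(n_trials):
        params = dict(fixed_params)
        for name, choices in space.items():
            if isinstance(choices, list):
                params[name] = choices[rng.integers(len(choices))]
            else:
                lo, hi = choices
                if lo > 0 and hi / lo >= 100:  # span >= 2 decades: log scale
                    params[name] = float(np.exp(rng.uniform(np.log(lo),
                                                            np.log(hi))))
                else:
                    params[name] = float(rng.uniform(lo, hi))
        net = MLPSurrogate(random_state=seed + 100 + t, **params)
        net.fit(X_train, y_train, X_val=X_val, y_val=y_val)
        trials.append({"params": params, "val_mae": net.best_val_mae_})
    best = min(trials, key=lambda tr: tr["val_mae"])
    return best["params"], trials
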