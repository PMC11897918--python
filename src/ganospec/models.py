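"""Regressors and the evaluation protocol.

The headline model is the extreme learning machine (ELM): a single hidden
layer whose input weights and biases are drawn at random and never trained;
only the linear output weights are solved, as the minimum-norm least-squares
solution of ``H @ beta = y`` where ``H = g(X @ W.T + b)``.  Training is one
pseudoinverse, not an iterative descent.

The back-propagation neural network (BPNN) and decision tree (DT) are
standard models and delegate to scikit-learn, configured with the study's
stated hyperparameters (BPNN: 100 hidden neurons, tanh, lbfgs, 1000
iterations, initial learning rate 0.01).

Model quality is summarized by the training-set coefficient of determination
(R_T^2), the held-out prediction-set coefficient (R_P^2) and the mean squared
error of prediction (MSEP), each averaged over repeated refits with distinct
sub-seeds (default 10 runs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.neural_network import MLPRegressor
from sklearn.tree import DecisionTreeRegressor

from ._rng import substream

__all__ = [
    "ELMRegressor",
    "BPNNSpec",
    "DTSpec",
    "EvalReport",
    "elm_fit",
    "elm_predict",
    "bpnn_regressor",
    "bpnn_fit",
    "dt_regressor",
    "dt_fit",
    "r_squared",
    "mse",
    "evaluate_model",
    "interpret_r2",
    "make_model",
]

_ACTIVATIONS = {
    "logistic": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
}


class ELMRegressor(RegressorMixin, BaseEstimator):
    """Extreme learning machine for regression.

    Parameters
    ----------
    n_hidden : int, default 50
        Hidden neurons.  Kept below the training-set size by default so the
        network does not trivially interpolate.
    activation : {'logistic', 'tanh'}, default 'logistic'
        Hidden-layer nonlinearity (classical ELM uses the logistic sigmoid).
    random_state : int or None
        Seed for the hidden weights and biases, drawn uniform on [-1, 1].

    Attributes
    ----------
    input_weights_ : ndarray of shape (n_hidden, n_features)
    biases_ : ndarray of shape (n_hidden,)
    output_weights_ : ndarray of shape (n_hidden,)
        Minimum-norm least-squares solution of ``H @ beta = y``.
    """

    def __init__(self, n_hidden: int = 50, activation: str = "logistic",
                 random_state=None):
        self.n_hidden = n_hidden
        self.activation = activation
        self.random_state = random_state

    def _hidden(self, X: np.ndarray) -> np.ndarray:
        g = _ACTIVATIONS[self.activation]
        return g(X @ self.input_weights_.T + self.biases_)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree in sample count")
        if X.shape[0] < 2 or X.shape[1] < 1:
            raise ValueError("need at least 2 samples and 1 feature")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("ELM requires finite inputs")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        self.input_weights_ = rng.uniform(-1.0, 1.0, size=(self.n_hidden, X.shape[1]))
        self.biases_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = self._hidden(X)
        # minimum-norm least squares (pseudoinverse semantics, rank cutoff at
        # machine-epsilon scale) tolerates rank-deficient H
        self.output_weights_, *_ = np.linalg.lstsq(H, y, rcond=None)
        if not np.isfinite(self.output_weights_).all():
            raise ValueError("output weights are non-finite")
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        if X.shape[0] == 0:
            return np.empty(0)
        return self._hidden(X) @ self.output_weights_


@dataclass(frozen=True)
class BPNNSpec:
    """Hyperparameters of the back-propagation network, as configured in the study."""

    hidden_neurons: int = 100
    max_iterations: int = 1000
    initial_learning_rate: float = 0.01
    activation: str = "tanh"
    solver: str = "lbfgs"
    seed: int | None = None

    def __post_init__(self):
        if self.hidden_neurons < 1 or self.max_iterations < 1:
            raise ValueError("counts must be positive")
        if self.initial_learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass(frozen=True)
class DTSpec:
    """Decision-tree hyperparameters (none stated by the study; all config)."""

    max_depth: int | None = None
    min_samples_split: int = 2
    seed: int | None = None


def bpnn_regressor(spec: BPNNSpec = BPNNSpec()) -> MLPRegressor:
    return MLPRegressor(
        hidden_layer_sizes=(spec.hidden_neurons,),
        max_iter=spec.max_iterations,
        learning_rate_init=spec.initial_learning_rate,
        activation=spec.activation,
        solver=spec.solver,
        random_state=spec.seed,
    )


def dt_regressor(spec: DTSpec = DTSpec()) -> DecisionTreeRegressor:
    return DecisionTreeRegressor(
        max_depth=spec.max_depth,
        min_samples_split=spec.min_samples_split,
        random_state=spec.seed,
    )


def bpnn_fit(X, y, spec: BPNNSpec = BPNNSpec()) -> MLPRegressor:
    """Fit the BPNN; non-convergence is surfaced as a warning, not an error."""
    model = bpnn_regressor(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel())
    return model


def dt_fit(X, y, spec: DTSpec = DTSpec()) -> DecisionTreeRegressor:
    return dt_regressor(spec).fit(
        np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel()
    )


def elm_fit(X, y, n_hidden: int = 50, activation: str = "logistic",
            rng=None) -> ELMRegressor:
    """Functional wrapper over :class:`ELMRegressor`."""
    return ELMRegressor(n_hidden=n_hidden, activation=activation,
                        random_state=rng).fit(X, y)


def elm_predict(model: ELMRegressor, X) -> np.ndarray:
    return model.predict(X)


class UndefinedMetricError(ValueError):
    """R^2 requested for a constant reference vector."""


def r_squared(y, y_hat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot about mean(y)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat differ in length")
    if y.size < 2:
        raise ValueError("R^2 requires at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined for constant y")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def mse(y, y_hat) -> float:
    """Mean squared residual."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat differ in length")
    return float(np.mean((y - y_hat) ** 2))


def interpret_r2(r2: float) -> str:
    """Qualitative grade of a determination coefficient.

    Bands: > 0.90 excellent; (0.81, 0.90] good; [0.60, 0.81] usable;
    below 0.60 inadequate.
    """
    if not np.isfinite(r2):
        raise ValueError("R^2 must be finite")
    if r2 > 0.90:
        return "excellent"
    if r2 > 0.81:
        return "good"
    if r2 >= 0.60:
        return "usable"
    return "inadequate"


@dataclass
class EvalReport:
    """Mean R_T^2, R_P^2 and MSEP over repeated refits, with per-repeat values."""

    r2_train: float
    r2_pred: float
    msep: float
    n_repeats: int
    n_effective: int
    per_repeat: dict = field(default_factory=dict)

    def grade(self) -> str:
        return interpret_r2(self.r2_pred)


def make_model(name: str, seed=None, **kwargs):
    """Factory for the three study regressors by short name."""
    if name == "elm":
        return ELMRegressor(random_state=seed, **kwargs)
    if name == "bpnn":
        return bpnn_regressor(BPNNSpec(seed=seed, **kwargs))
    if name == "dt":
        return dt_regressor(DTSpec(seed=seed, **kwargs))
    raise ValueError(f"unknown model {name!r}; choose elm, bpnn or dt")


def _reseed(estimator, seed: int):
    # repeats draw fresh sub-seeds only where the caller left the seed open;
    # an explicitly fixed random_state makes every repeat identical
    est = clone(estimator)
    if est.get_params().get("random_state", "absent") is None:
        est.set_params(random_state=seed)
    return est


def evaluate_model(estimator, train, test, n_repeats: int = 10,
                   seed: int = 0) -> EvalReport:
    """Refit ``estimator`` ``n_repeats`` times with distinct sub-seeds.

    ``train`` and ``test`` are (X, y) pairs with disjoint records.  Reports
    the mean training R^2, prediction R^2 and MSEP (computed on the
    prediction set); repeats that fail to fit or produce non-finite scores
    are excluded with a warning and ``n_effective`` reflects the survivors.
    """
    X_tr, y_tr = (np.asarray(a, dtype=float) for a in train)
    X_te, y_te = (np.asarray(a, dtype=float) for a in test)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    sub_seeds = substream(seed, "evaluate").integers(0, 2**31 - 1, size=n_repeats)
    rows = {"r2_train": [], "r2_pred": [], "msep": []}
    for rep, sub in enumerate(sub_seeds):
        try:
            model = _reseed(estimator, int(sub))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_tr, y_tr)
            r2t = r_squared(y_tr, model.predict(X_tr))
            pred = model.predict(X_te)
            r2p = r_squared(y_te, pred)
            ms = mse(y_te, pred)
            if not all(map(np.isfinite, (r2t, r2p, ms))):
                raise ValueError("non-finite score")
        except Exception as exc:  # failed repeat: excluded, run continues
            warnings.warn(f"repeat {rep} excluded: {exc}")
            continue
        rows["r2_train"].append(r2t)
        rows["r2_pred"].append(r2p)
        rows["msep"].append(ms)
    if not rows["r2_pred"]:
        raise RuntimeError("every evaluation repeat failed")
    return EvalReport(
        r2_train=float(np.mean(rows["r2_train"])),
        r2_pred=float(np.mean(rows["r2_pred"])),
        msep=float(np.mean(rows["msep"])),
        n_repeats=n_repeats,
        n_effective=len(rows["r2_pred"]),
        per_repeat={k: np.array(v) for k, v in rows.items()},
    )
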