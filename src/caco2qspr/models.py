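"""Regression models: MLR, RBF networks, dual-RBF ensembles and adapters.

The RBF network computes

    yhat(x) = bias + sum_i w_i * phi(||x - c_i||)

with a Gaussian basis phi.  Two conventions are supported for the spread
``delta``: the MATLAB one, phi(d) = exp(-(0.8326 d / delta)^2), in which
phi(delta) = 0.5, and the classic one, phi(d) = exp(-d^2 / (2 delta^2)).
Training is greedy newrb-style construction: starting from a bias-only
model, the training point with the largest current absolute error becomes
the next center and the output layer is refit by least squares, until the
training MSE reaches the goal ``epsilon`` or the neuron budget is spent.
Small ``epsilon`` means a tighter fit (and eventually overfitting); the
spread ``delta`` controls smoothness.

The dual-RBF ensemble averages two RBF networks trained on the same data
with independently tuned (delta, epsilon); the averaging reduces variance,
turning two weak learners into a stronger one.

SVR, dual-SVR and gradient boosting are thin adapters around standard
implementations, so the pipeline can compare model families; only the
RBF machinery is native.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from caco2qspr.datatable import DescriptorTable, InputError
from caco2qspr.optimizer import OptimizerConfig, minimize

MATLAB_SPREAD_FACTOR = 0.8326  # sqrt(ln 2): phi(delta) = 0.5
FITNESS_FLOOR = 1e-4  # floor applied to non-positive R^2 terms inside fitness


@dataclass
class LinearModel:
    coefficients: np.ndarray
    intercept: float
    descriptor_names: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coefficients + self.intercept


def mlr_fit(table: DescriptorTable, ridge: float = 0.0) -> LinearModel:
    """Ordinary least squares with intercept; tiny-ridge fallback when rank-deficient."""
    X, y = table.X, table.y
    n, p = X.shape
    A = np.column_stack([X, np.ones(n)])
    if ridge == 0.0 and (p >= n or np.linalg.matrix_rank(A) < p + 1):
        warnings.warn("rank-deficient design; falling back to ridge 1e-8", stacklevel=2)
        ridge = 1e-8
    if ridge > 0.0:
        G = A.T @ A + ridge * np.eye(p + 1)
        beta = np.linalg.solve(G, A.T @ y)
    else:
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearModel(
        coefficients=beta[:p], intercept=float(beta[p]),
        descriptor_names=list(table.descriptor_names),
    )


@dataclass
class RBFModel:
    centers: np.ndarray           # k x p
    spread: float                 # delta > 0
    weights: np.ndarray           # length k
    output_bias: float
    activation_convention: str = "matlab"

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return rbf_predict(self, X)


@dataclass
class RBFTrainConfig:
    spread: float
    mse_goal: float = 0.0
    max_neurons: int | None = None
    activation_convention: str = "matlab"

    def __post_init__(self) -> None:
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if self.mse_goal < 0:
            raise ValueError("mse_goal must be >= 0")


def _phi(dist: np.ndarray, spread: float, convention: str) -> np.ndarray:
    if convention == "matlab":
        return np.exp(-((MATLAB_SPREAD_FACTOR * dist / spread) ** 2))
    if convention == "classic":
        return np.exp(-(dist**2) / (2 * spread**2))
    raise ValueError(f"unknown activation convention {convention!r}")


def _design(X: np.ndarray, centers: np.ndarray, spread: float, convention: str) -> np.ndarray:
    from scipy.spatial.distance import cdist

    return _phi(cdist(X, centers), spread, convention)


def rbf_predict(model: RBFModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.centers.shape[1]:
        raise InputError(
            f"input has {X.shape[1]} descriptors, model expects {model.centers.shape[1]}"
        )
    if model.k == 0:
        return np.full(X.shape[0], model.output_bias)
    Phi = _design(X, model.centers, model.spread, model.activation_convention)
    return Phi @ model.weights + model.output_bias


def rbf_train(table: DescriptorTable, cfg: RBFTrainConfig) -> RBFModel:
    """Greedy incremental RBF construction (newrb-equivalent).

    Each round adds the not-yet-used training point with the largest
    absolute residual as a center and refits (weights, bias) by least
    squares over the current centers.  Ties break to the lowest row index.
    """
    X, y = table.X, table.y
    n = X.shape[0]
    max_neurons = min(cfg.max_neurons or n, n)

    center_rows: list[int] = []
    bias = float(np.mean(y))
    weights = np.zeros(0)
    pred = np.full(n, bias)

    while True:
        mse = float(np.mean((y - pred) ** 2))
        if mse <= cfg.mse_goal or len(center_rows) >= max_neurons:
            break
        err = np.abs(y - pred)
        err[center_rows] = -np.inf  # a point is used as a center at most once
        new = int(np.argmax(err))
        center_rows.append(new)
        centers = X[center_rows]
        Phi = _design(X, centers, cfg.spread, cfg.activation_convention)
        A = np.column_stack([Phi, np.ones(n)])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        weights, bias = beta[:-1], float(beta[-1])
        pred = A @ beta

    return RBFModel(
        centers=X[center_rows].copy() if center_rows else np.empty((0, X.shape[1])),
        spread=cfg.spread,
        weights=weights,
        output_bias=bias,
        activation_convention=cfg.activation_convention,
    )


@dataclass
class DualRBFModel:
    member_a: RBFModel
    member_b: RBFModel
    hyper: tuple[float, float, float, float]  # (delta1, eps1, delta2, eps2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return 0.5 * (self.member_a.predict(X) + self.member_b.predict(X))


def dual_rbf_train(
    table: DescriptorTable,
    hyper: tuple[float, float, float, float],
    max_neurons: int | None = None,
    activation_convention: str = "matlab",
) -> DualRBFModel:
    """Train both ensemble members on the full table; prediction is their mean."""
    d1, e1, d2, e2 = hyper
    a = rbf_train(table, RBFTrainConfig(d1, e1, max_neurons, activation_convention))
    b = rbf_train(table, RBFTrainConfig(d2, e2, max_neurons, activation_convention))
    return DualRBFModel(member_a=a, member_b=b, hyper=tuple(float(h) for h in hyper))


_FAMILIES = ("mlr", "rbf", "dual_rbf", "svr", "dual_svr", "gbm")


@dataclass
class ModelSpec:
    """Model family + family-specific parameter map.

    Families: ``mlr`` (no params); ``rbf`` (delta, epsilon); ``dual_rbf``
    (delta1, epsilon1, delta2, epsilon2); ``svr`` (C, nu, width);
    ``dual_svr`` (C1, nu1, width1, C2, nu2, width2); ``gbm``
    (learning_rate, max_depth, n_estimators).
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; expected one of {_FAMILIES}")
        required = {
            "mlr": (),
            "rbf": ("delta", "epsilon"),
            "dual_rbf": ("delta1", "epsilon1", "delta2", "epsilon2"),
            "svr": ("C", "nu", "width"),
            "dual_svr": ("C1", "nu1", "width1", "C2", "nu2", "width2"),
            "gbm": ("learning_rate", "max_depth", "n_estimators"),
        }[self.family]
        missing = [k for k in required if k not in self.params]
        if missing:
            raise ValueError(f"family {self.family!r} missing params {missing}")


class _MeanEnsemble:
    def __init__(self, members):
        self.members = members

    def predict(self, X):
        return np.mean([m.predict(X) for m in self.members], axis=0)


def _svr(C: float, nu: float, width: float):
    from sklearn.svm import NuSVR

    # "width" is the Gaussian kernel width; sklearn parameterizes gamma = 1/(2 width^2)
    return NuSVR(C=C, nu=nu, gamma=1.0 / (2.0 * width**2))


def fit_model(table: DescriptorTable, spec: ModelSpec):
    """Fit the family named in ``spec``; returns an object with .predict(X)."""
    p = spec.params
    if spec.family == "mlr":
        return mlr_fit(table)
    if spec.family == "rbf":
        return rbf_train(
            table,
            RBFTrainConfig(
                p["delta"], p["epsilon"],
                p.get("max_neurons"), p.get("activation_convention", "matlab"),
            ),
        )
    if spec.family == "dual_rbf":
        return dual_rbf_train(
            table,
            (p["delta1"], p["epsilon1"], p["delta2"], p["epsilon2"]),
            p.get("max_neurons"), p.get("activation_convention", "matlab"),
        )
    if spec.family == "svr":
        return _svr(p["C"], p["nu"], p["width"]).fit(table.X, table.y)
    if spec.family == "dual_svr":
        a = _svr(p["C1"], p["nu1"], p["width1"]).fit(table.X, table.y)
        b = _svr(p["C2"], p["nu2"], p["width2"]).fit(table.X, table.y)
        return _MeanEnsemble([a, b])
    if spec.family == "gbm":
        import xgboost as xgb

        return xgb.XGBRegressor(
            learning_rate=p["learning_rate"],
            max_depth=int(p["max_depth"]),
            n_estimators=int(p["n_estimators"]),
            random_state=int(p.get("random_state", 0)),
            verbosity=0,
        ).fit(table.X, table.y)
    raise AssertionError("unreachable")


def _floored(value: float) -> float:
    """Fitness guard: non-positive or non-finite R^2 terms become 1e-4."""
    if not np.isfinite(value) or value <= 0:
        return FITNESS_FLOOR
    return float(value)


def fitness_robustness_only(r_cv5_sq: float) -> float:
    """Reciprocal cross-validation fitness used for boosting models."""
    return 1.0 / _floored(r_cv5_sq)


def fitness_balanced(r_sq: float, r_cv5_sq: float) -> float:
    """Reciprocal fitness balancing fit (R^2) and robustness (R_cv5^2)."""
    return 1.0 / _floored(r_sq) + 1.0 / _floored(r_cv5_sq)


DEFAULT_BOUNDS = {
    "rbf": [(0.1, 20.0), (1e-4, 0.1)],
    "dual_rbf": [(0.1, 20.0), (1e-4, 0.1), (0.1, 20.0), (1e-4, 0.1)],
    "svr": [(0.1, 50.0), (0.05, 0.95), (0.1, 20.0)],
    "dual_svr": [(0.1, 50.0), (0.05, 0.95), (0.1, 20.0)] * 2,
    "gbm": [(0.01, 0.3), (2, 8), (50, 800)],
}

_PARAM_NAMES = {
    "rbf": ("delta", "epsilon"),
    "dual_rbf": ("delta1", "epsilon1", "delta2", "epsilon2"),
    "svr": ("C", "nu", "width"),
    "dual_svr": ("C1", "nu1", "width1", "C2", "nu2", "width2"),
    "gbm": ("learning_rate", "max_depth", "n_estimators"),
}


def position_to_spec(
    family: str, position: Sequence[float], fixed_params: dict | None = None
) -> ModelSpec:
    names = _PARAM_NAMES[family]
    params = dict(zip(names, (float(v) for v in position)))
    if family == "gbm":
        params["max_depth"] = int(round(params["max_depth"]))
        params["n_estimators"] = int(round(params["n_estimators"]))
    if fixed_params:
        params.update(fixed_params)
    return ModelSpec(family=family, params=params)


def model_to_dict(model, spec: ModelSpec) -> dict:
    """JSON-serializable form; native families carry their full parameters,
    adapter families (svr/dual_svr/gbm) carry spec only and must be refit."""
    out = {"family": spec.family, "params": spec.params}
    if isinstance(model, LinearModel):
        out["coefficients"] = model.coefficients.tolist()
        out["intercept"] = model.intercept
        out["descriptor_names"] = model.descriptor_names
    elif isinstance(model, RBFModel):
        out["rbf"] = _rbf_to_dict(model)
    elif isinstance(model, DualRBFModel):
        out["member_a"] = _rbf_to_dict(model.member_a)
        out["member_b"] = _rbf_to_dict(model.member_b)
        out["hyper"] = list(model.hyper)
    return out


def _rbf_to_dict(m: RBFModel) -> dict:
    return {
        "centers": m.centers.tolist(),
        "spread": m.spread,
        "weights": m.weights.tolist(),
        "output_bias": m.output_bias,
        "activation_convention": m.activation_convention,
    }


def _rbf_from_dict(d: dict) -> RBFModel:
    return RBFModel(
        centers=np.asarray(d["centers"], dtype=float),
        spread=float(d["spread"]),
        weights=np.asarray(d["weights"], dtype=float),
        output_bias=float(d["output_bias"]),
        activation_convention=d["activation_convention"],
    )


def model_from_dict(d: dict):
    """Rebuild a native model from its JSON form; adapter families raise."""
    family = d["family"]
    if family == "mlr" and "coefficients" in d:
        return LinearModel(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            descriptor_names=list(d.get("descriptor_names", [])),
        )
    if family == "rbf" and "rbf" in d:
        return _rbf_from_dict(d["rbf"])
    if family == "dual_rbf" and "member_a" in d:
        return DualRBFModel(
            member_a=_rbf_from_dict(d["member_a"]),
            member_b=_rbf_from_dict(d["member_b"]),
            hyper=tuple(d["hyper"]),
        )
    raise ValueError(
        f"family {family!r} cannot be rebuilt from JSON; refit from the training table"
    )


def tune_hyperparams(
    table: DescriptorTable,
    family: str,
    fitness_kind: str = "balanced",
    bounds: Sequence[tuple[float, float]] | None = None,
    opt: OptimizerConfig | None = None,
    cv_seed: int = 0,
    fixed_params: dict | None = None,
) -> ModelSpec:
    """Swarm-optimize model hyperparameters on reciprocal R^2 fitness.

    ``robustness_only`` minimizes 1/R_cv5^2 (boosting models, which rarely
    overfit); ``balanced`` minimizes 1/R^2 + 1/R_cv5^2 (RBF/SVR families,
    where fit and robustness trade off).  Non-positive metrics are floored
    at 1e-4 so the fitness stays finite.
    """
    from caco2qspr.validation import cross_validate, r_squared

    if family == "mlr":
        return ModelSpec(family="mlr")
    if fitness_kind not in ("robustness_only", "balanced"):
        raise ValueError(f"unknown fitness kind {fitness_kind!r}")
    bounds = bounds if bounds is not None else DEFAULT_BOUNDS[family]
    opt = opt or OptimizerConfig(max_iterations=50, bounds=bounds)
    opt.bounds = bounds

    def fitness(position: np.ndarray) -> float:
        spec = position_to_spec(family, position, fixed_params)
        try:
            r_cv5_sq, _ = cross_validate(table, spec, seed=cv_seed)
            if fitness_kind == "robustness_only":
                return fitness_robustness_only(r_cv5_sq)
            model = fit_model(table, spec)
            r_sq = r_squared(table.y, model.predict(table.X), strict=False)
            return fitness_balanced(r_sq, r_cv5_sq)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1.0 / FITNESS_FLOOR

    result = minimize(fitness, opt)
    return position_to_spec(family, result.best_position, fixed_params)
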