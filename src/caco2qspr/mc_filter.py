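"""Monte-Carlo cross-validation residual profiling and abnormal-data removal.

Repeated random 90/10 splits of the modeling table are fit with MLR; the
held-out signed residuals are accumulated per compound.  A compound that is
consistently mispredicted (high mean absolute residual) or erratically
predicted (high residual standard deviation) is a candidate outlier.  The
two thresholds (``mean_lim`` in log units, ``std_lim``) are tuned by the
swarm optimizer to maximize the 5-fold cross-validated R^2 of an MLR model
on the retained compounds, under the constraint that no more than a small
fraction (default 2%) of the data may be deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from caco2qspr.datatable import DescriptorTable, InputError
from caco2qspr.models import ModelSpec
from caco2qspr.optimizer import OptimizerConfig, minimize
from caco2qspr.validation import cross_validate

PENALTY = 1e6  # additive penalty keeping infeasible threshold pairs connected

DEFAULT_BOUNDS = ((0.6, 1.8), (0.1, 0.35))


@dataclass
class MCResidualProfile:
    ids: list[str]
    mean_abs_residual: np.ndarray   # per compound, log units
    std_residual: np.ndarray        # std of signed held-out residuals
    n_test_appearances: np.ndarray  # int per compound
    n_iterations: int
    test_fraction: float
    seed: int

    @property
    def never_tested(self) -> list[str]:
        return [self.ids[i] for i in np.flatnonzero(self.n_test_appearances == 0)]


@dataclass
class MCFilterThresholds:
    mean_lim: float
    std_lim: float


@dataclass
class MCFilterResult:
    removed_ids: list[str]
    retained_table: DescriptorTable
    thresholds: MCFilterThresholds
    objective_value: float  # R_cv5^2 of MLR on the retained table
    removed_fraction: float
    history: list[float] = field(default_factory=list)


def _ridge_fit_predict(
    X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray, ridge: float = 1e-8
) -> np.ndarray:
    """MLR via ridge-stabilized normal equations; random 90% splits of wide
    tables can be rank-deficient, so the tiny ridge keeps every split solvable."""
    n, p = X_tr.shape
    A = np.column_stack([X_tr, np.ones(n)])
    G = A.T @ A + ridge * np.eye(p + 1)
    beta = np.linalg.solve(G, A.T @ y_tr)
    return np.column_stack([X_te, np.ones(X_te.shape[0])]) @ beta


def mc_residual_profile(
    table: DescriptorTable,
    n_iterations: int = 2000,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> MCResidualProfile:
    """Held-out residual distribution per compound over random splits."""
    if table.n < 20:
        raise InputError("need at least 20 compounds for MC residual profiling")
    if np.isnan(table.X).any():
        raise InputError("table must be fully numeric (curate first)")
    rng = np.random.default_rng(seed)
    n = table.n
    n_test = max(1, int(round(test_fraction * n)))

    sums = np.zeros(n)
    sums_abs = np.zeros(n)
    sums_sq = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for _ in range(n_iterations):
        perm = rng.permutation(n)
        te, tr = perm[:n_test], perm[n_test:]
        pred = _ridge_fit_predict(table.X[tr], table.y[tr], table.X[te])
        res = table.y[te] - pred
        np.add.at(sums, te, res)
        np.add.at(sums_abs, te, np.abs(res))
        np.add.at(sums_sq, te, res**2)
        np.add.at(counts, te, 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_abs = np.where(counts > 0, sums_abs / np.maximum(counts, 1), np.nan)
        mean_signed = sums / np.maximum(counts, 1)
        var = sums_sq / np.maximum(counts, 1) - mean_signed**2
        std = np.where(counts > 0, np.sqrt(np.maximum(var, 0.0)), np.nan)
    return MCResidualProfile(
        ids=list(table.ids),
        mean_abs_residual=mean_abs,
        std_residual=std,
        n_test_appearances=counts,
        n_iterations=n_iterations,
        test_fraction=test_fraction,
        seed=seed,
    )


def flag_abnormal(
    profile: MCResidualProfile,
    thresholds: MCFilterThresholds,
    rule: str = "union",
) -> list[str]:
    """Ids exceeding the residual thresholds.

    ``union``: flagged when mean_abs_residual > mean_lim OR
    std_residual > std_lim; ``intersection``: both must be exceeded.
    Never-tested compounds (NaN profile entries) are not flagged.
    """
    if rule not in ("union", "intersection"):
        raise ValueError(f"unknown rule {rule!r}")
    with np.errstate(invalid="ignore"):
        over_mean = profile.mean_abs_residual > thresholds.mean_lim
        over_std = profile.std_residual > thresholds.std_lim
    flags = (over_mean | over_std) if rule == "union" else (over_mean & over_std)
    return [profile.ids[i] for i in np.flatnonzero(flags)]


def optimize_thresholds(
    table: DescriptorTable,
    profile: MCResidualProfile,
    bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_BOUNDS,
    max_removed_frac: float = 0.02,
    opt: OptimizerConfig | None = None,
    rule: str = "union",
    cv_seed: int = 0,
) -> MCFilterResult:
    """Swarm-tune (mean_lim, std_lim) to maximize retained-data MLR R_cv5^2.

    Threshold pairs removing more than ``max_removed_frac`` of the data (or
    leaving too little to cross-validate) receive a large additive penalty
    rather than being rejected, so the search space stays connected.
    """
    if profile.ids != table.ids:
        raise InputError("profile was not computed on this table")
    opt = opt or OptimizerConfig(max_iterations=50, bounds=bounds, seed=0)
    opt.bounds = bounds
    mlr = ModelSpec(family="mlr")
    id_to_row = {cid: i for i, cid in enumerate(table.ids)}
    cache: dict[frozenset, float] = {}

    def retained_r_cv5(removed: frozenset) -> float:
        key = removed
        if key not in cache:
            keep = [i for i in range(table.n) if table.ids[i] not in removed]
            r, _ = cross_validate(table.subset_rows(keep), mlr, seed=cv_seed)
            cache[key] = r
        return cache[key]

    def fitness(position: np.ndarray) -> float:
        thr = MCFilterThresholds(mean_lim=float(position[0]), std_lim=float(position[1]))
        removed = frozenset(flag_abnormal(profile, thr, rule))
        frac = len(removed) / table.n
        penalty = PENALTY if frac > max_removed_frac else 0.0
        if table.n - len(removed) < 5:
            return PENALTY
        return -retained_r_cv5(removed) + penalty

    result = minimize(fitness, opt)
    thr = MCFilterThresholds(
        mean_lim=float(result.best_position[0]), std_lim=float(result.best_position[1])
    )
    removed = flag_abnormal(profile, thr, rule)
    frac = len(removed) / table.n
    if frac > max_removed_frac:
        # optimizer found nothing feasible below the cap: remove nothing
        removed, frac = [], 0.0
        thr = MCFilterThresholds(mean_lim=bounds[0][1], std_lim=bounds[1][1])
    keep = [i for i in range(table.n) if table.ids[i] not in set(removed)]
    retained = table.subset_rows(keep)
    objective, _ = cross_validate(retained, mlr, seed=cv_seed)
    return MCFilterResult(
        removed_ids=sorted(removed, key=id_to_row.get),
        retained_table=retained,
        thresholds=thr,
        objective_value=objective,
        removed_fraction=frac,
        history=result.history,
    )
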