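"""Model validation: CV metrics, Y-randomization, Golbraikh-Tropsha, rules of thumb.

The reported statistics follow OECD-style QSPR validation practice:

* R^2 / RMSE_F — fit on the training set;
* R_cv5^2 / RMSE_cv — 5-fold cross-validation, computed on the pooled
  out-of-fold predictions;
* R_T^2 / RMSE_T — external test-set prediction;
* Y-randomization — refit on shuffled endpoints must destroy performance;
* Golbraikh-Tropsha — through-origin slopes k, k' in (0.85, 1.15) and
  (R0ext^2 - R'0ext^2)/R0ext^2 < 0.1 on external predictions;
* Topliss ratio — at least 5 training compounds per model variable;
* overfit gap — R^2 - R_cv5^2 below 0.3.

R^2 here is the squared Pearson correlation of observed and predicted
values (sign- and affine-invariant); the coefficient of determination is
available via ``mode="determination"`` for external comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.model_selection import KFold

from caco2qspr.datatable import DescriptorTable, InputError
from caco2qspr.models import ModelSpec, fit_model


class MetricError(ValueError):
    """A metric is undefined for the given inputs (e.g. constant vector)."""


def r_squared(y, yhat, mode: str = "pearson", strict: bool = True) -> float:
    """Squared correlation of observed vs predicted.

    ``pearson`` (default): squared Pearson correlation coefficient.
    ``determination``: 1 - SS_res/SS_tot.
    With ``strict=False``, undefined cases return 0.0 instead of raising,
    for use inside optimizer fitness functions.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise InputError("y and yhat must be 1-D vectors of equal length")
    if len(y) < 3:
        raise InputError("need at least 3 points")
    if mode == "determination":
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            if strict:
                raise MetricError("constant observed vector")
            return 0.0
        return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    if np.std(y) == 0 or np.std(yhat) == 0:
        if strict:
            raise MetricError("constant input vector; correlation undefined")
        return 0.0
    r = float(np.corrcoef(y, yhat)[0, 1])
    return r * r


def rmse(y, yhat) -> float:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class Metrics:
    r_sq: float
    rmse_f: float
    r_cv5_sq: float
    rmse_cv: float
    r_t_sq: float | None = None
    rmse_t: float | None = None


def cross_validate(
    table: DescriptorTable,
    model_spec: ModelSpec,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """K-fold CV; metrics on the pooled out-of-fold prediction vector."""
    if table.n < n_folds:
        raise InputError(f"need at least {n_folds} compounds for {n_folds}-fold CV")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = np.empty(table.n)
    for fold, (tr, te) in enumerate(kf.split(table.X)):
        try:
            model = fit_model(table.subset_rows(tr), model_spec)
        except Exception as exc:  # noqa: BLE001 - annotate with fold index
            raise RuntimeError(f"training failed in fold {fold}") from exc
        pooled[te] = model.predict(table.X[te])
    return r_squared(table.y, pooled, strict=False), rmse(table.y, pooled)


@dataclass
class YRandReport:
    n_runs: int
    shuffled_r_sq: list[float] = field(default_factory=list)
    shuffled_r_cv5_sq: list[float] = field(default_factory=list)
    real_r_sq: float | None = None
    real_r_cv5_sq: float | None = None

    def summary(self) -> dict:
        def rng(v):
            return (float(min(v)), float(max(v))) if v else None

        return {
            "n_runs": self.n_runs,
            "shuffled_r_sq_range": rng(self.shuffled_r_sq),
            "shuffled_r_cv5_sq_range": rng(self.shuffled_r_cv5_sq),
            "real_r_sq": self.real_r_sq,
            "real_r_cv5_sq": self.real_r_cv5_sq,
        }


def y_randomization(
    table: DescriptorTable,
    model_spec: ModelSpec,
    n_runs: int = 1000,
    seed: int = 0,
    cv_seed: int = 0,
) -> YRandReport:
    """Refit on shuffled endpoints; real performance should far exceed all runs.

    Hyperparameters stay frozen at the values in ``model_spec``; only the
    endpoint vector is permuted.
    """
    rng = np.random.default_rng(seed)
    real = fit_model(table, model_spec)
    real_r_sq = r_squared(table.y, real.predict(table.X), strict=False)
    real_r_cv5_sq, _ = cross_validate(table, model_spec, seed=cv_seed)
    report = YRandReport(n_runs=n_runs, real_r_sq=real_r_sq, real_r_cv5_sq=real_r_cv5_sq)
    for _ in range(n_runs):
        y_shuf = rng.permutation(table.y)
        shuffled = DescriptorTable(
            ids=list(table.ids), descriptor_names=list(table.descriptor_names),
            X=table.X, y=y_shuf,
        )
        model = fit_model(shuffled, model_spec)
        report.shuffled_r_sq.append(r_squared(y_shuf, model.predict(table.X), strict=False))
        r_cv, _ = cross_validate(shuffled, model_spec, seed=cv_seed)
        report.shuffled_r_cv5_sq.append(r_cv)
    return report


@dataclass
class GTReport:
    k: float
    k_prime: float
    r0ext_sq: float
    r0ext_prime_sq: float
    ratio: float
    passes_k: bool
    passes_k_prime: bool
    passes_ratio: bool

    @property
    def passes(self) -> bool:
        return self.passes_k and self.passes_k_prime and self.passes_ratio

    def to_dict(self) -> dict:
        d = asdict(self)
        d["passes"] = self.passes
        return d


def golbraikh_tropsha(y, yhat) -> GTReport:
    """Through-origin regression diagnostics for external predictions."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) < 3 or y.shape != yhat.shape:
        raise InputError("need aligned vectors of length >= 3")
    s_yy = float(np.sum(yhat**2))
    s_oo = float(np.sum(y**2))
    denom_o = float(np.sum((y - y.mean()) ** 2))
    denom_p = float(np.sum((yhat - yhat.mean()) ** 2))
    if s_yy == 0 or s_oo == 0 or denom_o == 0 or denom_p == 0:
        raise MetricError("zero denominator in Golbraikh-Tropsha quantities")
    cross = float(np.sum(y * yhat))
    k = cross / s_yy
    k_prime = cross / s_oo
    r0 = 1.0 - float(np.sum((y - k * yhat) ** 2)) / denom_o
    r0p = 1.0 - float(np.sum((yhat - k_prime * y) ** 2)) / denom_p
    if r0 == 0:
        raise MetricError("R0ext^2 is zero; ratio undefined")
    ratio = (r0 - r0p) / r0
    return GTReport(
        k=k, k_prime=k_prime, r0ext_sq=r0, r0ext_prime_sq=r0p, ratio=ratio,
        passes_k=0.85 < k < 1.15,
        passes_k_prime=0.85 < k_prime < 1.15,
        passes_ratio=ratio < 0.1,
    )


def topliss_ratio(n_train: int, n_descriptors: int) -> tuple[float, bool]:
    """Training compounds per model variable; rule-of-thumb minimum 5."""
    if n_descriptors < 1:
        raise InputError("n_descriptors must be >= 1")
    ratio = n_train / n_descriptors
    return ratio, ratio >= 5.0


def overfit_gap(r_sq: float, r_cv5_sq: float) -> tuple[float, bool]:
    """R^2 - R_cv5^2; below 0.3 indicates acceptable overfitting."""
    gap = r_sq - r_cv5_sq
    return gap, gap < 0.3


def evaluate_model(
    train: DescriptorTable,
    model_spec: ModelSpec,
    test: DescriptorTable | None = None,
    cv_seed: int = 0,
) -> tuple[Metrics, object]:
    """Fit on ``train`` and assemble the standard metric block."""
    model = fit_model(train, model_spec)
    yhat_tr = model.predict(train.X)
    r_cv5_sq, rmse_cv = cross_validate(train, model_spec, seed=cv_seed)
    metrics = Metrics(
        r_sq=r_squared(train.y, yhat_tr, strict=False),
        rmse_f=rmse(train.y, yhat_tr),
        r_cv5_sq=r_cv5_sq,
        rmse_cv=rmse_cv,
    )
    if test is not None:
        yhat_te = model.predict(test.X)
        metrics.r_t_sq = r_squared(test.y, yhat_te, strict=False)
        metrics.rmse_t = rmse(test.y, yhat_te)
    return metrics, model
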