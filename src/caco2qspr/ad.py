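"""Applicability-domain estimation: leverage and importance-weighted distance.

Leverage is the classic hat-matrix diagnostic, h(x) = x' (X'X)^-1 x on the
training design, with warning threshold h* = 3 p / n.  It treats every
descriptor direction equally.

The importance-weighted distance (IWD) domain instead scales each
descriptor by its importance score before measuring distance:

  Step 1: v_ij = A_ij * Score_j         (weight each descriptor column)
  Step 2: C = column means of v          (weighted center of the training set)
  Step 3: d_i = || v_i - C ||            (Euclidean distance to the center)
  Step 4: threshold = u + 3 sigma_d      (mean + 3 SD of training distances)

A compound with d > u + 3 sigma_d lies outside the domain.  Classification
is invariant under positive rescaling of the score vector, since distances
and threshold scale together; with equal scores it reduces to unweighted
centroid distance.

Williams-plot data pair the domain measure with standardized prediction
residuals (residual / training RMSE); compounds beyond +-3 standardized
residuals are response outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from caco2qspr.datatable import InputError


@dataclass
class LeverageDomain:
    gram_inv: np.ndarray       # (X'X)^-1 of the training design
    warning_leverage: float    # h*
    p: int
    n_tr: int
    use_p_plus_1: bool = False


def leverage_fit(X_train: np.ndarray, use_p_plus_1: bool = False) -> LeverageDomain:
    """Leverage domain on the raw (uncentered, no-intercept) training design.

    h* = 3p/n by default; the 3(p+1)/n variant is selectable.  Rank-deficient
    designs fall back to a tiny ridge on the Gram matrix.
    """
    X = np.asarray(X_train, dtype=float)
    n, p = X.shape
    if n <= p:
        raise InputError("leverage requires more training compounds than descriptors")
    G = X.T @ X
    try:
        gram_inv = np.linalg.inv(G)
    except np.linalg.LinAlgError:
        warnings.warn("rank-deficient training design; ridge-stabilized Gram inverse", stacklevel=2)
        gram_inv = np.linalg.inv(G + 1e-8 * np.eye(p))
    h_star = 3.0 * (p + 1 if use_p_plus_1 else p) / n
    return LeverageDomain(gram_inv=gram_inv, warning_leverage=h_star, p=p, n_tr=n,
                          use_p_plus_1=use_p_plus_1)


def leverage_apply(domain: LeverageDomain, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row leverage and inside-domain flag (h <= h*)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != domain.p:
        raise InputError(f"input has {X.shape[1]} descriptors, domain expects {domain.p}")
    h = np.einsum("ij,jk,ik->i", X, domain.gram_inv, X)
    return h, h <= domain.warning_leverage


@dataclass
class IWDDomain:
    scores: np.ndarray      # length p, nonnegative, normalized to sum 1
    center: np.ndarray      # weighted centroid C
    u: float                # mean training distance
    sigma_d: float          # SD of training distances
    threshold: float        # u + 3 sigma_d
    n_tr: int

    @property
    def p(self) -> int:
        return len(self.scores)


def iwd_fit(X_train: np.ndarray, scores: np.ndarray, n_sigma: float = 3.0) -> IWDDomain:
    """Fit the importance-weighted-distance domain on the training design."""
    X = np.asarray(X_train, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (X.shape[1],):
        raise InputError("scores must align with descriptor columns")
    if np.any(scores < 0):
        raise InputError("scores must be nonnegative")
    total = scores.sum()
    if total == 0:
        raise InputError("all-zero importance scores give a degenerate domain")
    scores = scores / total  # harmless by scale invariance; aids conditioning
    V = X * scores
    center = V.mean(axis=0)
    d = np.linalg.norm(V - center, axis=1)
    u = float(d.mean())
    sigma_d = float(d.std())
    return IWDDomain(scores=scores, center=center, u=u, sigma_d=sigma_d,
                     threshold=u + n_sigma * sigma_d, n_tr=X.shape[0])


def iwd_apply(domain: IWDDomain, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row weighted distance and inside-domain flag (d <= threshold)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != domain.p:
        raise InputError(f"input has {X.shape[1]} descriptors, domain expects {domain.p}")
    d = np.linalg.norm(X * domain.scores - domain.center, axis=1)
    return d, d <= domain.threshold


@dataclass
class ADRow:
    id: str
    set_label: str
    distance: float            # leverage h or weighted distance d
    std_residual: float
    inside_ad: bool
    response_outlier: bool


@dataclass
class ADReport:
    rows: list[ADRow] = field(default_factory=list)
    coverage: dict = field(default_factory=dict)  # set label -> percentage or None

    def outlier_table(self) -> list[ADRow]:
        return [r for r in self.rows if r.response_outlier]


def williams_data(
    domain: LeverageDomain | IWDDomain,
    X: np.ndarray,
    y: np.ndarray,
    yhat: np.ndarray,
    rmse_ref: float,
    ids: list[str] | None = None,
    set_labels: list[str] | None = None,
    residual_band: float = 3.0,
) -> list[ADRow]:
    """Per-compound Williams-plot rows for either domain type.

    ``rmse_ref`` is the training RMSE, giving both train and test rows a
    common +-3 standardized-residual band.
    """
    if rmse_ref <= 0:
        raise InputError("rmse_ref must be positive")
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat):
        raise InputError("y and yhat must align")
    if isinstance(domain, LeverageDomain):
        dist, inside = leverage_apply(domain, X)
    else:
        dist, inside = iwd_apply(domain, X)
    std_res = (y - yhat) / rmse_ref
    ids = ids if ids is not None else [str(i) for i in range(len(y))]
    set_labels = set_labels if set_labels is not None else ["train"] * len(y)
    return [
        ADRow(
            id=ids[i], set_label=set_labels[i],
            distance=float(dist[i]), std_residual=float(std_res[i]),
            inside_ad=bool(inside[i]),
            response_outlier=bool(abs(std_res[i]) > residual_band),
        )
        for i in range(len(y))
    ]


def coverage(rows: list[ADRow]) -> dict:
    """AD coverage percentage per set label (2 d.p.); empty sets report None."""
    out: dict[str, float | None] = {}
    for label in sorted({r.set_label for r in rows}):
        members = [r for r in rows if r.set_label == label]
        if not members:
            out[label] = None
        else:
            out[label] = round(100.0 * sum(r.inside_ad for r in members) / len(members), 2)
    return out
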