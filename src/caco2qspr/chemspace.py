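"""Chemical-space reduction, SOM clustering, stratified splitting, diversity.

Train/test splitting follows a "cluster before classify" scheme: descriptors
are z-scored and reduced by PCA to the smallest number of components
explaining a target share of variance (default 90%), a self-organizing map
clusters the compounds in score space (default 3x3 grid, 9 clusters), and
within each cluster the compounds are sorted by endpoint and one of every
five is assigned to the test set — so the test set samples every structural
cluster and every local endpoint range.

Diversity is summarized by the continuous Tanimoto similarity on min-max
scaled descriptors, T(a,b) = sum(ab) / (sum(a^2) + sum(b^2) - sum(ab)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from caco2qspr.datatable import DescriptorTable, InputError

logger = logging.getLogger(__name__)


@dataclass
class PCAProjection:
    component_loadings: np.ndarray        # p x K
    explained_variance_ratio: np.ndarray  # length K
    K: int
    mean: np.ndarray                      # per-descriptor standardization
    std: np.ndarray


def pca_reduce(
    table: DescriptorTable, var_target: float = 0.90
) -> tuple[PCAProjection, np.ndarray]:
    """Z-score descriptors, take the fewest components reaching ``var_target``."""
    X = table.X
    if np.isnan(X).any():
        raise InputError("table contains nulls; curate first")
    std = X.std(axis=0, ddof=1)
    if np.any(std == 0):
        bad = [table.descriptor_names[j] for j in np.flatnonzero(std == 0)]
        raise InputError(f"zero-variance descriptors (prune first): {bad}")
    mean = X.mean(axis=0)
    Z = (X - mean) / std
    pca = PCA(svd_solver="full").fit(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    K = int(np.searchsorted(cum, var_target) + 1)
    K = min(K, len(cum))
    proj = PCAProjection(
        component_loadings=pca.components_[:K].T.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_[:K].copy(),
        K=K,
        mean=mean,
        std=std,
    )
    scores = Z @ proj.component_loadings
    return proj, scores


@dataclass
class SOMGrid:
    rows: int = 3
    cols: int = 3
    epochs: int = 500
    lr_start: float = 0.5
    lr_end: float = 0.01
    seed: int = 0
    codebook: np.ndarray | None = None  # (rows*cols) x K after training


def som_cluster(scores: np.ndarray, grid: SOMGrid | None = None) -> np.ndarray:
    """Kohonen SOM training and best-matching-unit labels.

    Online training with seeded uniform init from the data range, Gaussian
    neighborhood shrinking from max(rows, cols)/2 to 1 unit, and a linearly
    decaying learning rate.  Returns one cluster label (0..rows*cols-1) per
    row of ``scores``.
    """
    grid = grid or SOMGrid()
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] == 0:
        raise InputError("scores must be a non-empty 2-D matrix")
    n, k = scores.shape
    n_units = grid.rows * grid.cols
    if n < n_units:
        raise InputError(f"need at least {n_units} compounds for a {grid.rows}x{grid.cols} SOM")
    rng = np.random.default_rng(grid.seed)

    lo, hi = scores.min(axis=0), scores.max(axis=0)
    codebook = rng.uniform(lo, hi, size=(n_units, k))
    unit_pos = np.array([(r, c) for r in range(grid.rows) for c in range(grid.cols)], dtype=float)
    grid_d2 = ((unit_pos[:, None, :] - unit_pos[None, :, :]) ** 2).sum(axis=2)

    sigma_start = max(grid.rows, grid.cols) / 2.0
    total = grid.epochs
    for epoch in range(total):
        frac = epoch / max(total - 1, 1)
        lr = grid.lr_start + (grid.lr_end - grid.lr_start) * frac
        sigma = max(sigma_start + (1.0 - sigma_start) * frac, 1.0)
        for i in rng.permutation(n):
            x = scores[i]
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            h = np.exp(-grid_d2[bmu] / (2 * sigma**2))
            codebook += lr * h[:, None] * (x - codebook)

    grid.codebook = codebook
    d2 = ((scores[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


@dataclass
class SplitAssignment:
    labels: list[str]          # per compound: "train" or "test"
    cluster_ids: np.ndarray
    positions: np.ndarray      # 1-based sorted position within cluster

    @property
    def train_mask(self) -> np.ndarray:
        return np.array([lab == "train" for lab in self.labels])

    @property
    def test_mask(self) -> np.ndarray:
        return np.array([lab == "test" for lab in self.labels])


def stratified_split(
    table: DescriptorTable,
    clusters: np.ndarray,
    test_every: int = 5,
    offset: int = 3,
) -> SplitAssignment:
    """One-in-``test_every`` test picking within each cluster, sorted by endpoint.

    Compounds in each cluster are sorted ascending by y (ties by row order);
    those at 1-based positions congruent to ``offset`` modulo ``test_every``
    go to the test set.  The default offset 3 picks the middle of each block
    of five, so the test set samples the interior of local endpoint ranges
    and extremes stay in training.
    """
    clusters = np.asarray(clusters)
    if len(clusters) != table.n:
        raise InputError("cluster labels must cover all compounds")
    labels = ["train"] * table.n
    positions = np.zeros(table.n, dtype=int)
    mod_target = offset % test_every
    for c in np.unique(clusters):
        rows = np.flatnonzero(clusters == c)
        order = rows[np.argsort(table.y[rows], kind="stable")]
        for pos, i in enumerate(order, start=1):
            positions[i] = pos
            if pos % test_every == mod_target:
                labels[i] = "test"
    return SplitAssignment(labels=labels, cluster_ids=clusters.copy(), positions=positions)


def tanimoto_matrix(
    table: DescriptorTable, descriptor_subset: list[str] | None = None
) -> np.ndarray:
    """Continuous Tanimoto similarity on min-max scaled descriptors."""
    sub = table if descriptor_subset is None else table.subset_columns(descriptor_subset)
    X = sub.X
    if np.isnan(X).any():
        raise InputError("table contains nulls")
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng_ = np.where(hi > lo, hi - lo, 1.0)
    A = (X - lo) / rng_
    dot = A @ A.T
    sq = np.einsum("ij,ij->i", A, A)
    denom = sq[:, None] + sq[None, :] - dot
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, dot / np.where(denom == 0, 1.0, denom), 0.0)
    zero_rows = np.flatnonzero(sq == 0)
    if zero_rows.size:
        logger.warning("all-zero descriptor rows after scaling: %s", [table.ids[i] for i in zero_rows])
    np.fill_diagonal(sim, 1.0)  # self-similarity 1 by convention, even for zero rows
    return sim


@dataclass
class DiversityReport:
    mean_overall: float
    mean_train: float | None = None
    mean_test: float | None = None
    mean_cross: float | None = None
    endpoint_histogram: dict = field(default_factory=dict)


def _mean_offdiag(sim: np.ndarray, rows: np.ndarray, cols: np.ndarray | None = None) -> float | None:
    if cols is None:
        block = sim[np.ix_(rows, rows)]
        m = len(rows)
        if m < 2:
            return None
        return float((block.sum() - np.trace(block)) / (m * (m - 1)))
    if len(rows) == 0 or len(cols) == 0:
        return None
    return float(sim[np.ix_(rows, cols)].mean())


def diversity_report(
    sim: np.ndarray,
    split: SplitAssignment | None = None,
    y: np.ndarray | None = None,
    binwidth: float = 1.0,
) -> DiversityReport:
    """Mean off-diagonal similarity overall / within-train / within-test / cross,
    plus a per-log-unit endpoint histogram per split when y is given."""
    sim = np.asarray(sim)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise InputError("similarity matrix must be square")
    if not np.allclose(sim, sim.T, atol=1e-10):
        raise InputError("similarity matrix must be symmetric")
    all_rows = np.arange(sim.shape[0])
    report = DiversityReport(mean_overall=_mean_offdiag(sim, all_rows))
    if split is not None:
        tr = np.flatnonzero(split.train_mask)
        te = np.flatnonzero(split.test_mask)
        report.mean_train = _mean_offdiag(sim, tr)
        report.mean_test = _mean_offdiag(sim, te)
        report.mean_cross = _mean_offdiag(sim, tr, te)
    if y is not None:
        y = np.asarray(y, dtype=float)
        edges = np.arange(np.floor(y.min()), np.ceil(y.max()) + binwidth, binwidth)
        hist = {"bin_edges": edges.tolist(), "all": np.histogram(y, edges)[0].tolist()}
        if split is not None:
            hist["train"] = np.histogram(y[split.train_mask], edges)[0].tolist()
            hist["test"] = np.histogram(y[split.test_mask], edges)[0].tolist()
        report.endpoint_histogram = hist
    return report
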