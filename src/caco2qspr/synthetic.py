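"""Seeded generator of QSPR-like descriptor tables with known ground truth.

The generator emulates the statistical structure of a curated permeability
descriptor table: blocks of correlated descriptors (redundant structural
features), a sparse linear signal with an optional smooth nonlinearity
(tanh of the linear score — bounded and smooth, the regime where RBF
networks outperform MLR), Gaussian residual noise in log units, a small
fraction of grossly shifted outliers, and injected degeneracies (constant
columns, missing cells, duplicate structures).  Endpoints are affinely
mapped into the plausible log Papp range [-8, -3.5] and clipped.

Everything is reproducible from the seed, and the ground truth (true
support, effective coefficients, planted outlier ids, duplicate groups,
blob labels) is returned alongside the table so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from caco2qspr.datatable import CompoundRecord, DescriptorTable, InputError, records_to_table

ENDPOINT_RANGE = (-8.0, -3.5)


@dataclass
class SyntheticSpec:
    n: int = 1864
    p: int = 261
    support_size: int = 20
    coefficient_scale: float = 1.0
    nonlinear_fraction: float = 0.3
    noise_sd: float = 0.35
    block_size: int = 5
    block_r: float = 0.7
    n_constant: int = 0
    n_null_cells: int = 0
    outlier_fraction: float = 0.0
    outlier_shift_sd: float = 10.0
    duplicate_groups: int = 0
    endpoint_range: tuple[float, float] = ENDPOINT_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.support_size > self.p:
            raise InputError("support cannot exceed descriptor count")
        if not 0 <= self.outlier_fraction <= 0.05:
            raise InputError("outlier_fraction must be in [0, 0.05]")
        if not 0 <= self.nonlinear_fraction <= 1:
            raise InputError("nonlinear_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    support: list[str]
    coefficients: np.ndarray       # effective linear weights after endpoint mapping
    outlier_ids: list[str] = field(default_factory=list)
    duplicate_groups: list[list[str]] = field(default_factory=list)
    records: list[CompoundRecord] = field(default_factory=list)
    cluster_labels: np.ndarray | None = None


def _correlated_block_matrix(rng: np.random.Generator, n: int, p: int,
                             block_size: int, block_r: float) -> np.ndarray:
    """Standard-normal marginals with equicorrelation block_r within blocks."""
    X = np.empty((n, p))
    a, b = np.sqrt(block_r), np.sqrt(1.0 - block_r)
    for start in range(0, p, block_size):
        width = min(block_size, p - start)
        factor = rng.normal(size=(n, 1))
        noise = rng.normal(size=(n, width))
        X[:, start:start + width] = a * factor + b * noise
    return X


def generate(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Generate one table + ground truth, fully reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n, spec.p
    X = _correlated_block_matrix(rng, n, p, spec.block_size, spec.block_r)
    names = [f"d{j+1}" for j in range(p)]
    ids = [f"c{i+1}" for i in range(n)]

    # sparse signal spread across blocks so correlated twins stay distractors
    support_idx = np.linspace(0, p - 1, spec.support_size).astype(int)
    support_idx = np.unique(support_idx)
    beta = spec.coefficient_scale * rng.uniform(0.5, 1.5, size=len(support_idx))
    beta *= rng.choice([-1.0, 1.0], size=len(support_idx))
    z = X[:, support_idx] @ beta
    sz = z.std() if z.std() > 0 else 1.0
    signal = (1 - spec.nonlinear_fraction) * z + spec.nonlinear_fraction * sz * np.tanh(z / sz)

    # affine map of the noiseless signal into the interior of the endpoint range
    # the margin reserves headroom for noise so clipping stays rare, while
    # leaving the endpoint SD near the 0.6-0.8 log units typical of curated
    # permeability compilations
    lo, hi = spec.endpoint_range
    width = hi - lo
    margin = min(0.45 * width, 0.05 * width + spec.noise_sd)
    smin, smax = signal.min(), signal.max()
    scale = (width - 2 * margin) / (smax - smin) if smax > smin else 0.0
    shift = lo + margin - scale * smin
    y = scale * signal + shift
    effective_beta = scale * (1 - spec.nonlinear_fraction) * beta

    y = y + rng.normal(0, spec.noise_sd, size=n)
    outlier_ids: list[str] = []
    n_out = int(np.floor(spec.outlier_fraction * n))
    if n_out > 0:
        rows = rng.choice(n, size=n_out, replace=False)
        shift = spec.outlier_shift_sd * spec.noise_sd
        # shift toward the farther range bound so the gross error survives
        # the final clip (a shift off the near edge would be truncated away)
        signs = np.where(hi - y[rows] > y[rows] - lo, 1.0, -1.0)
        y[rows] += signs * shift
        outlier_ids = [ids[i] for i in sorted(rows)]
    np.clip(y, lo, hi, out=y)

    # degeneracies injected last
    if spec.n_constant > 0:
        const = np.ones((n, spec.n_constant))
        X = np.hstack([X, const])
        names = names + [f"const{j+1}" for j in range(spec.n_constant)]
    if spec.n_null_cells > 0:
        # avoid support and constant columns so signal and constancy stay intact
        non_support = [j for j in range(p) if j not in set(support_idx)]
        cells_i = rng.choice(n, size=spec.n_null_cells)
        cells_j = rng.choice(non_support, size=spec.n_null_cells)
        X[cells_i, cells_j] = np.nan

    table = DescriptorTable(ids=ids, descriptor_names=names, X=X, y=y)
    truth = GroundTruth(
        support=[f"d{j+1}" for j in support_idx],
        coefficients=effective_beta,
        outlier_ids=outlier_ids,
    )

    # optional duplicate-structure simulation, expressed as compound records
    if spec.duplicate_groups > 0:
        records = []
        for i in range(n):
            records.append(CompoundRecord(
                id=ids[i], smiles=f"S{i+1}", log_papp=float(y[i]),
                descriptors={names[j]: (None if np.isnan(X[i, j]) else float(X[i, j]))
                             for j in range(X.shape[1])},
            ))
        dup_rows = rng.choice(n, size=spec.duplicate_groups, replace=False)
        for g, i in enumerate(sorted(dup_rows)):
            jitter = rng.uniform(-0.2, 0.2)
            dup = CompoundRecord(
                id=f"{ids[i]}_dup", smiles=f"S{i+1}",
                log_papp=float(np.clip(y[i] + jitter, lo, hi)),
                descriptors=records[i].descriptors.copy(),
            )
            records.append(dup)
            truth.duplicate_groups.append([ids[i], dup.id])
        truth.records = records

    return table, truth


def generate_blobs(
    n: int, K_dims: int, n_blobs: int, separation: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated unit-variance Gaussian blobs with known labels.

    Blob centers sit on a 2-D lattice with spacing ``separation`` (embedded
    in the first two of ``K_dims`` dimensions), so separation 0 collapses
    all blobs onto one cloud.
    """
    if n < n_blobs:
        raise InputError("need at least one point per blob")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_blobs)))
    centers = np.zeros((n_blobs, K_dims))
    for b in range(n_blobs):
        centers[b, 0] = (b % side) * separation
        if K_dims > 1:
            centers[b, 1] = (b // side) * separation
    labels = rng.integers(0, n_blobs, size=n)
    # guarantee every blob is populated
    labels[:n_blobs] = np.arange(n_blobs)
    X = centers[labels] + rng.normal(size=(n, K_dims))
    return X, labels
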