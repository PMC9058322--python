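"""Descriptor importance and subset selection.

Importance is measured by scrambling: a model is trained once on the full
table, then each descriptor column is permuted in turn (several seeded
permutations) and the drop in R^2 of the predictions is recorded.  A
descriptor whose scrambling hurts accuracy carries information the model
uses; negative mean drops are clipped to zero.

Selection proceeds in a cascade: rank descriptors by importance, trace
R_cv5^2 of MLR models built on the top-k for growing k (the importance
curve), keep the best-k head, then run a swarm subset search (capped
cardinality, repair by importance rank) on the survivors, and finally cut
at a user-chosen size from a second importance curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from caco2qspr.datatable import DescriptorTable, InputError, _pearson
from caco2qspr.models import ModelSpec, fit_model
from caco2qspr.optimizer import OptimizerConfig, binary_subset_search
from caco2qspr.validation import cross_validate, r_squared


@dataclass
class ImportanceScores:
    descriptor_names: list[str]
    score: np.ndarray      # >= 0, clipped mean R^2 drop
    raw_drop: np.ndarray   # signed mean drop
    rank: np.ndarray       # 0 = most important
    n_repeats: int
    seed: int

    def top(self, k: int) -> list[str]:
        order = np.argsort(self.rank)
        return [self.descriptor_names[i] for i in order[:k]]

    def normalized(self) -> np.ndarray:
        """Scores rescaled to sum to 1 (for the importance-weighted AD)."""
        total = self.score.sum()
        if total == 0:
            raise InputError("all importance scores are zero; cannot normalize")
        return self.score / total


@dataclass
class ImportanceCurve:
    points: list[tuple[int, float]]  # (k, r_cv5_sq)
    best_k: int

    @property
    def best_r_cv5_sq(self) -> float:
        return dict(self.points)[self.best_k]


def mdi_importance(
    table: DescriptorTable,
    model_spec: ModelSpec,
    n_repeats: int = 10,
    seed: int = 0,
    retrain: bool = False,
) -> ImportanceScores:
    """Permutation (scrambling) importance of each descriptor.

    Default is permute-and-predict on the once-fitted model; with
    ``retrain=True`` the model is refit on each scrambled table instead
    (slower, accounts for compensation by correlated descriptors).
    """
    rng = np.random.default_rng(seed)
    model = fit_model(table, model_spec)
    base = r_squared(table.y, model.predict(table.X), strict=False)
    raw = np.zeros(table.p)
    for j in range(table.p):
        drops = []
        for _ in range(n_repeats):
            Xp = table.X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            if retrain:
                perm_table = DescriptorTable(
                    ids=list(table.ids), descriptor_names=list(table.descriptor_names),
                    X=Xp, y=table.y,
                )
                m = fit_model(perm_table, model_spec)
                pred = m.predict(Xp)
            else:
                pred = model.predict(Xp)
            drops.append(base - r_squared(table.y, pred, strict=False))
        raw[j] = np.mean(drops)
    score = np.maximum(raw, 0.0)
    # rank: descending score, ties by column order (stable argsort of -score)
    rank = np.empty(table.p, dtype=int)
    rank[np.argsort(-score, kind="stable")] = np.arange(table.p)
    return ImportanceScores(
        descriptor_names=list(table.descriptor_names),
        score=score, raw_drop=raw, rank=rank, n_repeats=n_repeats, seed=seed,
    )


def importance_curve(
    table: DescriptorTable,
    scores: ImportanceScores,
    k_max: int | None = None,
    cv_seed: int = 0,
) -> ImportanceCurve:
    """R_cv5^2 of MLR on the top-k descriptors, for k = 1..k_max."""
    k_max = k_max or table.p
    if k_max > table.p:
        raise InputError("k_max exceeds descriptor count")
    mlr = ModelSpec(family="mlr")
    ranked = scores.top(table.p)
    points = []
    for k in range(1, k_max + 1):
        sub = table.subset_columns(ranked[:k])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, _ = cross_validate(sub, mlr, seed=cv_seed)
        points.append((k, r))
    best_k = max(points, key=lambda t: (t[1], -t[0]))[0]
    return ImportanceCurve(points=points, best_k=best_k)


def hqpso_subset(
    table: DescriptorTable,
    candidates: list[str],
    max_selected: int = 60,
    opt: OptimizerConfig | None = None,
    mdi_rank: np.ndarray | None = None,
    cv_seed: int = 0,
) -> list[str]:
    """Swarm subset search maximizing MLR R_cv5^2 over descriptor subsets.

    Subsets never exceed ``max_selected``; oversized candidates are repaired
    by dropping the worst-ranked members (``mdi_rank``, lower = better;
    default = candidate order).
    """
    missing = [c for c in candidates if c not in table.descriptor_names]
    if missing:
        raise InputError(f"candidates not in table: {missing}")
    sub = table.subset_columns(candidates)
    mlr = ModelSpec(family="mlr")
    opt = opt or OptimizerConfig(max_iterations=60, seed=0, mode="binary")
    cache: dict[tuple, float] = {}

    def fitness(idx: np.ndarray) -> float:
        key = tuple(idx.tolist())
        if key not in cache:
            chosen = sub.subset_columns([candidates[i] for i in idx])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, _ = cross_validate(chosen, mlr, seed=cv_seed)
            cache[key] = -r
        return cache[key]

    priority = mdi_rank if mdi_rank is not None else np.arange(len(candidates), dtype=float)
    result = binary_subset_search(
        fitness, n_items=len(candidates), max_selected=min(max_selected, len(candidates)),
        config=opt, priority=np.asarray(priority, dtype=float),
    )
    return [candidates[i] for i in result.best_position]


def correlation_profile(
    table: DescriptorTable,
    subset: list[str] | None = None,
    importance_rank: np.ndarray | None = None,
) -> list[dict]:
    """Signed Pearson r of each descriptor with the endpoint.

    Rows ordered by the supplied importance ranking when given, else by
    column order; zero-variance descriptors report r = 0 with a warning.
    """
    names = subset if subset is not None else list(table.descriptor_names)
    sub = table.subset_columns(names)
    if np.isnan(sub.X).any():
        raise InputError("table contains nulls")
    rows = []
    for j, nm in enumerate(names):
        col = sub.X[:, j]
        if np.std(col) == 0:
            warnings.warn(f"descriptor {nm!r} has zero variance; r reported as 0", stacklevel=2)
            r = 0.0
        else:
            r = _pearson(col, sub.y)
        rows.append({"descriptor": nm, "r": r})
    if importance_rank is not None:
        order = np.argsort(np.asarray(importance_rank), kind="stable")
        rows = [rows[i] for i in order]
    return rows
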