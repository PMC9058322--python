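"""Descriptor tables and endpoint curation.

The universal currency of the pipeline is the :class:`DescriptorTable`:
compound ids, descriptor names, an n x p numeric matrix (NaN marks missing
cells) and an endpoint vector of log10 Papp values in log10(cm/s).

Curation follows standard QSPR practice for permeability data:

* endpoint bounds: compounds with log Papp above -3.5 or below -8 are
  dropped as experimentally unreliable;
* duplicate structures (same SMILES) are merged to their mean endpoint
  when they agree within a configurable log-unit range, and dropped
  entirely when they disagree;
* compounds with a missing value in an informative descriptor
  (variance > 0.3 among the other compounds) are removed;
* constant or still-incomplete descriptor columns are removed;
* of each descriptor pair correlated above |r| = 0.85, the member less
  correlated with the endpoint is removed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LOG_PAPP_MAX = -3.5
LOG_PAPP_MIN = -8.0


class ConfigurationError(ValueError):
    """A column mapping or option does not resolve against the input."""


class InputError(ValueError):
    """The input data violate a precondition."""


@dataclass
class CompoundRecord:
    """One compound: id, optional SMILES, endpoint, descriptor map.

    Exactly one of ``papp`` (cm/s) / ``log_papp`` (log10 cm/s) may be
    omitted; when both are given they must agree (log_papp = log10(papp)).
    Descriptor values may be None for missing cells.
    """

    id: str
    smiles: str | None = None
    papp: float | None = None
    log_papp: float | None = None
    descriptors: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.papp is None and self.log_papp is None:
            raise InputError(f"compound {self.id!r} has no endpoint (papp or log_papp)")
        if self.papp is not None:
            if self.papp <= 0:
                raise InputError(f"compound {self.id!r}: papp must be positive")
            implied = math.log10(self.papp)
            if self.log_papp is None:
                self.log_papp = implied
            elif abs(self.log_papp - implied) > 1e-9:
                raise InputError(
                    f"compound {self.id!r}: log_papp={self.log_papp} inconsistent "
                    f"with log10(papp)={implied}"
                )


@dataclass
class DescriptorTable:
    """Compound ids, descriptor names, numeric matrix and endpoint vector."""

    ids: list[str]
    descriptor_names: list[str]
    X: np.ndarray  # n x p, float, NaN = missing
    y: np.ndarray  # length n, log10 Papp

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if n < 1 or p < 1:
            raise InputError("descriptor table must have at least one row and column")
        if len(self.ids) != n or len(self.y) != n:
            raise InputError("ids / y length does not match matrix rows")
        if len(self.descriptor_names) != p:
            raise InputError("descriptor_names length does not match matrix columns")
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise InputError(f"duplicate compound ids: {dupes}")
        if len(set(self.descriptor_names)) != p:
            raise InputError("duplicate descriptor names")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, keep: Sequence[int]) -> "DescriptorTable":
        keep = list(keep)
        return DescriptorTable(
            ids=[self.ids[i] for i in keep],
            descriptor_names=list(self.descriptor_names),
            X=self.X[keep, :].copy(),
            y=self.y[keep].copy(),
        )

    def subset_columns(self, names: Sequence[str]) -> "DescriptorTable":
        idx = [self.descriptor_names.index(nm) for nm in names]
        return DescriptorTable(
            ids=list(self.ids),
            descriptor_names=list(names),
            X=self.X[:, idx].copy(),
            y=self.y.copy(),
        )

    def to_dataframe(self, id_col: str = "id", endpoint_col: str = "logPapp") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.descriptor_names)
        df.insert(0, endpoint_col, self.y)
        df.insert(0, id_col, self.ids)
        return df


@dataclass
class CurationReport:
    """Bookkeeping of what a curation step removed and why."""

    step: str
    n_in: int
    n_out: int
    dropped_out_of_range: list[str] = field(default_factory=list)
    merged_duplicates: list[list[str]] = field(default_factory=list)
    dropped_conflicting_duplicates: list[list[str]] = field(default_factory=list)
    dropped_null_compounds: list[str] = field(default_factory=list)
    dropped_constant_descriptors: list[str] = field(default_factory=list)
    dropped_null_descriptors: list[str] = field(default_factory=list)
    dropped_correlated_descriptors: list[dict] = field(default_factory=list)

    def reconciles(self) -> bool:
        dropped = (
            len(self.dropped_out_of_range)
            + len(self.dropped_null_compounds)
            + sum(len(g) for g in self.dropped_conflicting_duplicates)
        )
        merged_away = sum(len(g) - 1 for g in self.merged_duplicates)
        return self.n_out == self.n_in - dropped - merged_away

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def read_table(
    path: str,
    format: str = "csv",
    column_map: Mapping[str, str] | None = None,
) -> DescriptorTable:
    """Read a delimited descriptor table.

    ``column_map`` resolves the special columns: keys ``id_col`` and
    ``endpoint_col`` (required, defaults ``id`` / ``logPapp``) and optional
    ``smiles_col``.  Every other column is treated as a numeric descriptor;
    empty cells become NaN, never zero.
    """
    column_map = dict(column_map or {})
    id_col = column_map.get("id_col", "id")
    endpoint_col = column_map.get("endpoint_col", "logPapp")
    smiles_col = column_map.get("smiles_col")

    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise ConfigurationError(f"unknown format {format!r} (expected csv or tsv)")
    df = pd.read_csv(path, sep=sep)

    for col, role in ((id_col, "id"), (endpoint_col, "endpoint")):
        if col not in df.columns:
            raise ConfigurationError(f"{role} column {col!r} not found in {path}")
    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate compound ids in {path}: {dupes}")

    skip = {id_col, endpoint_col}
    if smiles_col:
        skip.add(smiles_col)
    desc_cols = [c for c in df.columns if c not in skip]
    X = df[desc_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[endpoint_col], errors="coerce").to_numpy(dtype=float)
    if np.isnan(y).any():
        bad = [ids[i] for i in np.flatnonzero(np.isnan(y))]
        raise InputError(f"non-numeric endpoint for compounds: {bad}")
    return DescriptorTable(ids=ids, descriptor_names=desc_cols, X=X, y=y)


def write_table(table: DescriptorTable, path: str, format: str = "csv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[format]
    table.to_dataframe().to_csv(path, sep=sep, index=False)


def records_to_table(records: Sequence[CompoundRecord]) -> DescriptorTable:
    """Assemble records into a table; descriptor set is the union, in first-seen order."""
    names: list[str] = []
    seen = set()
    for r in records:
        for nm in r.descriptors:
            if nm not in seen:
                seen.add(nm)
                names.append(nm)
    X = np.full((len(records), len(names)), np.nan)
    for i, r in enumerate(records):
        for j, nm in enumerate(names):
            v = r.descriptors.get(nm)
            if v is not None:
                X[i, j] = v
    return DescriptorTable(
        ids=[r.id for r in records],
        descriptor_names=names,
        X=X,
        y=np.array([r.log_papp for r in records], dtype=float),
    )


def curate_records(
    records: Sequence[CompoundRecord],
    dup_log_range_max: float = 0.5,
) -> tuple[DescriptorTable, CurationReport]:
    """Endpoint-bound filtering and duplicate-structure merging.

    Compounds with log Papp outside [-8, -3.5] (inclusive) are dropped.
    Groups sharing a SMILES are merged to their mean log Papp when their
    range is at most ``dup_log_range_max`` log units, and dropped entirely
    otherwise; compounds without a SMILES are never grouped.
    """
    report = CurationReport(step="curate_records", n_in=len(records), n_out=0)
    in_range: list[CompoundRecord] = []
    for r in records:
        if r.log_papp is None:
            raise InputError(f"compound {r.id!r} has no endpoint")
        if r.log_papp > LOG_PAPP_MAX or r.log_papp < LOG_PAPP_MIN:
            report.dropped_out_of_range.append(r.id)
        else:
            in_range.append(r)

    groups: dict[str, list[CompoundRecord]] = {}
    order: list[tuple[str, CompoundRecord | None]] = []  # preserve input order
    for r in in_range:
        if r.smiles is None:
            order.append(("", r))
        else:
            if r.smiles not in groups:
                groups[r.smiles] = []
                order.append((r.smiles, None))
            groups[r.smiles].append(r)

    kept: list[CompoundRecord] = []
    for smiles, single in order:
        if single is not None:
            kept.append(single)
            continue
        grp = groups[smiles]
        if len(grp) == 1:
            kept.append(grp[0])
            continue
        vals = [g.log_papp for g in grp]
        if max(vals) - min(vals) <= dup_log_range_max:
            merged = CompoundRecord(
                id=grp[0].id,
                smiles=smiles,
                log_papp=float(np.mean(vals)),
                descriptors=dict(grp[0].descriptors),
            )
            kept.append(merged)
            report.merged_duplicates.append([g.id for g in grp])
        else:
            report.dropped_conflicting_duplicates.append([g.id for g in grp])

    report.n_out = len(kept)
    if not kept:
        raise InputError("curation removed every compound")
    return records_to_table(kept), report


def drop_null_descriptor_compounds(
    table: DescriptorTable,
    var_threshold: float = 0.3,
) -> tuple[DescriptorTable, CurationReport]:
    """Drop compounds whose missing cell sits in an informative descriptor.

    For each missing cell (i, j), the variance of descriptor j over the
    compounds where it is present is computed; if it exceeds
    ``var_threshold`` the descriptor is considered informative and compound
    i is removed (so the column can be kept).  Remaining missing cells are
    later handled by whole-column removal in :func:`prune_constant_null`.
    """
    report = CurationReport(step="drop_null_descriptor_compounds", n_in=table.n, n_out=table.n)
    drop: set[int] = set()
    for j in range(table.p):
        col = table.X[:, j]
        null_rows = np.flatnonzero(np.isnan(col))
        if null_rows.size == 0:
            continue
        present = col[~np.isnan(col)]
        if present.size >= 2 and float(np.var(present, ddof=1)) > var_threshold:
            drop.update(null_rows.tolist())
    if drop:
        keep = [i for i in range(table.n) if i not in drop]
        if not keep:
            raise InputError("null-descriptor filtering removed every compound")
        report.dropped_null_compounds = [table.ids[i] for i in sorted(drop)]
        table = table.subset_rows(keep)
    report.n_out = table.n
    return table, report


def prune_constant_null(table: DescriptorTable) -> tuple[DescriptorTable, CurationReport]:
    """Remove descriptor columns that are constant or still contain missing cells."""
    report = CurationReport(step="prune_constant_null", n_in=table.n, n_out=table.n)
    keep: list[str] = []
    for j, nm in enumerate(table.descriptor_names):
        col = table.X[:, j]
        if np.isnan(col).any():
            report.dropped_null_descriptors.append(nm)
        elif np.all(col == col[0]):
            report.dropped_constant_descriptors.append(nm)
        else:
            keep.append(nm)
    if not keep:
        raise InputError("all descriptor columns were constant or incomplete")
    if len(keep) < table.p:
        table = table.subset_columns(keep)
    return table, report


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over pairwise-complete rows; 0.0 when degenerate."""
    mask = ~(np.isnan(a) | np.isnan(b))
    if mask.sum() < 3:
        return 0.0
    a, b = a[mask], b[mask]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def prune_correlated(
    table: DescriptorTable,
    r_threshold: float = 0.85,
    use_abs: bool = True,
) -> tuple[DescriptorTable, CurationReport]:
    """Greedy pairwise correlation pruning.

    Pairs with |r| above ``r_threshold`` are processed in descending |r|
    (ties by column order); within each pair the descriptor less correlated
    with the endpoint is dropped.  The result contains no surviving pair
    above the threshold.
    """
    report = CurationReport(step="prune_correlated", n_in=table.n, n_out=table.n)
    p = table.p
    Xc = table.X
    corr = np.corrcoef(Xc, rowvar=False)
    if p == 1:
        return table, report
    corr_key = np.abs(corr) if use_abs else corr
    r_y = np.array([abs(_pearson(Xc[:, j], table.y)) for j in range(p)])

    pairs = [
        (corr_key[i, j], i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if corr_key[i, j] > r_threshold
    ]
    # descending |r|; ties resolved by (i, j) column order
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = np.ones(p, dtype=bool)
    for r, i, j in pairs:
        if not (alive[i] and alive[j]):
            continue
        # drop the member with weaker endpoint correlation; tie -> later column
        loser = j if r_y[j] <= r_y[i] else i
        alive[loser] = False
        report.dropped_correlated_descriptors.append(
            {
                "dropped": table.descriptor_names[loser],
                "kept": table.descriptor_names[i if loser == j else j],
                "pair_r": float(corr[i, j]),
            }
        )
    keep = [table.descriptor_names[j] for j in range(p) if alive[j]]
    if len(keep) < p:
        table = table.subset_columns(keep)
    return table, report


def curate_table(
    table: DescriptorTable,
    var_threshold: float = 0.3,
    r_threshold: float = 0.85,
) -> tuple[DescriptorTable, list[CurationReport]]:
    """Full descriptor-side curation chain on an already-assembled table."""
    reports = []
    table, rep = drop_null_descriptor_compounds(table, var_threshold)
    reports.append(rep)
    table, rep = prune_constant_null(table)
    reports.append(rep)
    table, rep = prune_correlated(table, r_threshold)
    reports.append(rep)
    return table, reports
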