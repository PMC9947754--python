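"""Reading, writing and validating child-record tables and region adjacency graphs.

A :class:`Dataset` holds the two binary undernutrition outcomes (stunting,
wasting), categorical covariates with declared reference levels, continuous
covariates, and a district/region label per child.  Outcomes may be supplied
directly as 0/1 columns or derived from height-for-age / weight-for-height
z-scores with the standard "< -2 SD" cutoffs.

The companion :class:`AdjacencyGraph` stores the region neighbourhood
structure used by the spatial GMRF prior, readable from the BayesX-style
".gra" text dialect or a two-column edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "DataError",
    "GraphError",
    "TableSchema",
    "Dataset",
    "AdjacencyGraph",
    "derive_outcomes",
    "read_table",
    "write_table",
    "read_adjacency",
    "write_adjacency",
    "validate_dataset",
]

log = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A declared column is missing or mis-typed."""


class DataError(ValueError):
    """The data content is unusable (e.g. empty after filtering)."""


class GraphError(ValueError):
    """The adjacency structure is inconsistent."""


@dataclass(frozen=True)
class TableSchema:
    """Column-role declaration for a child-record CSV.

    Either ``y1``/``y2`` (binary columns) or ``haz``/``whz`` (z-score
    columns, outcomes derived on read) must be declared.  ``categorical``
    maps column name -> reference level; ``continuous`` lists real-valued
    covariate columns; ``region`` names the spatial identifier column.
    """

    region: str = "region"
    y1: str | None = "stunted"
    y2: str | None = "wasted"
    haz: str | None = None
    whz: str | None = None
    categorical: dict[str, str] = field(default_factory=dict)
    continuous: tuple[str, ...] = ()

    def modelled_columns(self) -> list[str]:
        cols = [self.region]
        cols += [self.haz, self.whz] if self.uses_zscores else [self.y1, self.y2]
        cols += list(self.categorical) + list(self.continuous)
        return cols

    @property
    def uses_zscores(self) -> bool:
        return self.haz is not None and self.whz is not None


@dataclass
class Dataset:
    """Typed child-record table ready for model building.

    ``y1``/``y2`` are the binary stunting/wasting indicators, ``frame``
    holds the covariates, ``categorical`` maps factor name -> reference
    level, ``continuous`` lists the smooth-effect covariates and ``region``
    the per-record region label.  ``n_dropped`` records how many raw rows
    were removed by listwise deletion of missing modelled columns.
    """

    y1: np.ndarray
    y2: np.ndarray
    frame: pd.DataFrame
    categorical: dict[str, str]
    continuous: tuple[str, ...]
    region_col: str = "region"
    haz: np.ndarray | None = None
    whz: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self):
        self.y1 = np.asarray(self.y1, dtype=int)
        self.y2 = np.asarray(self.y2, dtype=int)
        if self.n == 0:
            raise DataError("dataset has no records")
        for name, y in (("y1", self.y1), ("y2", self.y2)):
            if not np.isin(y, (0, 1)).all():
                raise DataError(f"{name} must be binary 0/1")
        if len(self.frame) != self.n:
            raise DataError("covariate frame and outcomes disagree in length")

    @property
    def n(self) -> int:
        return self.y1.size

    @property
    def region(self) -> pd.Series:
        return self.frame[self.region_col].astype(str)

    def levels(self, column: str) -> list[str]:
        """Ordered factor levels, reference first."""
        ref = self.categorical[column]
        vals = sorted(self.frame[column].astype(str).unique())
        if ref not in vals:
            raise SchemaError(f"reference level {ref!r} absent from column {column!r}")
        return [ref] + [v for v in vals if v != ref]


@dataclass
class AdjacencyGraph:
    """Regions with symmetric neighbour lists (indices into ``regions``)."""

    regions: list[str]
    neighbours: list[list[int]]

    def __post_init__(self):
        S = len(self.regions)
        if len(set(self.regions)) != S:
            raise GraphError("duplicate region labels")
        for s, nb in enumerate(self.neighbours):
            for r in nb:
                if not 0 <= r < S:
                    raise GraphError(f"neighbour index {r} out of range for {self.regions[s]!r}")
                if r == s:
                    raise GraphError(f"region {self.regions[s]!r} lists itself as neighbour")
                if s not in self.neighbours[r]:
                    raise GraphError(
                        f"asymmetric adjacency: {self.regions[s]!r} -> {self.regions[r]!r} "
                        "declared but not the reverse"
                    )
        islands = self.islands()
        if islands:
            log.warning("adjacency graph has island regions: %s", ", ".join(islands))

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def index(self, label: str) -> int:
        return self.regions.index(label)

    def islands(self) -> list[str]:
        return [self.regions[s] for s, nb in enumerate(self.neighbours) if not nb]

    def degree(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbours])


def derive_outcomes(haz, whz):
    """Binary stunting/wasting indicators from anthropometric z-scores.

    A child is stunted iff its height-for-age z-score is strictly below -2
    and wasted iff its weight-for-height z-score is strictly below -2; a
    score of exactly -2 is a non-case.
    """
    haz = np.asarray(haz, dtype=float)
    whz = np.asarray(whz, dtype=float)
    if not (np.isfinite(haz).all() and np.isfinite(whz).all()):
        raise DataError("z-scores must be finite; drop missing rows first")
    return (haz < -2.0).astype(int), (whz < -2.0).astype(int)


def read_table(path, schema: TableSchema) -> Dataset:
    """Read a child-record CSV, dropping rows with missing modelled columns.

    The number of dropped rows is logged and stored on ``Dataset.n_dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={schema.region: str})
    missing = [c for c in schema.modelled_columns() if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing declared columns: {missing}")
    kept = raw.dropna(subset=schema.modelled_columns())
    n_dropped = len(raw) - len(kept)
    if n_dropped:
        log.info("%d row(s) dropped for missing modelled values", n_dropped)
    if kept.empty:
        raise DataError("no records left after dropping missing values")

    haz = whz = None
    if schema.uses_zscores:
        haz = kept[schema.haz].to_numpy(dtype=float)
        whz = kept[schema.whz].to_numpy(dtype=float)
        y1, y2 = derive_outcomes(haz, whz)
    else:
        y1 = kept[schema.y1].to_numpy()
        y2 = kept[schema.y2].to_numpy()

    cols = [schema.region] + list(schema.categorical) + list(schema.continuous)
    frame = kept[cols].reset_index(drop=True)
    frame[schema.region] = frame[schema.region].astype(str)
    for c in schema.categorical:
        frame[c] = frame[c].astype(str)
    for c in schema.continuous:
        frame[c] = frame[c].astype(float)
    return Dataset(
        y1=y1,
        y2=y2,
        frame=frame,
        categorical=dict(schema.categorical),
        continuous=tuple(schema.continuous),
        region_col=schema.region,
        haz=haz,
        whz=whz,
        n_dropped=n_dropped,
    )


def write_table(ds: Dataset, path, schema: TableSchema | None = None) -> None:
    """Write a Dataset back to CSV (outcome columns named per ``schema``)."""
    y1_col = (schema.y1 if schema else None) or "stunted"
    y2_col = (schema.y2 if schema else None) or "wasted"
    out = ds.frame.copy()
    out.insert(0, y1_col, ds.y1)
    out.insert(1, y2_col, ds.y2)
    if ds.haz is not None:
        out["haz"] = ds.haz
    if ds.whz is not None:
        out["whz"] = ds.whz
    out.to_csv(path, index=False)


def read_adjacency(path, dialect: str = "gra") -> AdjacencyGraph:
    """Read a region adjacency graph.

    ``gra`` dialect: first line holds the region count S; then per region
    three lines — label, neighbour count, and the (1-based) neighbour
    indices on one line (blank when the region is an island).  ``edgelist``
    dialect: lines of ``A B`` pairs declaring undirected edges (a line with
    a single label declares an isolated region); region order is order of
    first appearance.
    """
    lines = Path(path).read_text().splitlines()
    if dialect == "gra":
        return _parse_gra(lines)
    if dialect in ("edgelist", "neighbour-list"):
        return _parse_edgelist(lines)
    raise ValueError(f"unknown adjacency dialect {dialect!r}")


def _parse_gra(lines: Sequence[str]) -> AdjacencyGraph:
    it = iter(lines)
    try:
        S = int(next(it).strip())
    except (StopIteration, ValueError) as exc:
        raise GraphError("gra file must start with the region count") from exc
    regions: list[str] = []
    neighbours: list[list[int]] = []
    for _ in range(S):
        try:
            label = next(it).strip()
            k = int(next(it).strip())
            idx_line = next(it).strip()
        except (StopIteration, ValueError) as exc:
            raise GraphError("truncated or malformed gra file") from exc
        idx = [int(t) for t in idx_line.split()] if idx_line else []
        if len(idx) != k:
            raise GraphError(f"region {label!r} declares {k} neighbours but lists {len(idx)}")
        for j in idx:
            if not 1 <= j <= S:
                raise GraphError(f"region {label!r} references unknown region index {j}")
        regions.append(label)
        neighbours.append([j - 1 for j in idx])  # file is 1-based
    return AdjacencyGraph(regions=regions, neighbours=neighbours)


def _parse_edgelist(lines: Sequence[str]) -> AdjacencyGraph:
    order: list[str] = []
    nb: dict[str, set[str]] = {}

    def add(label: str):
        if label not in nb:
            nb[label] = set()
            order.append(label)

    for ln in lines:
        toks = ln.split()
        if not toks:
            continue
        if len(toks) == 1:
            add(toks[0])
        elif len(toks) == 2:
            a, b = toks
            if a == b:
                raise GraphError(f"self-edge on region {a!r}")
            add(a)
            add(b)
            nb[a].add(b)
            nb[b].add(a)
        else:
            raise GraphError(f"malformed edge-list line: {ln!r}")
    idx = {r: i for i, r in enumerate(order)}
    return AdjacencyGraph(
        regions=order,
        neighbours=[sorted(idx[r] for r in nb[label]) for label in order],
    )


def write_adjacency(g: AdjacencyGraph, path) -> None:
    """Write a graph in the ".gra" dialect (1-based neighbour indices)."""
    out = [str(g.n_regions)]
    for label, nbs in zip(g.regions, g.neighbours):
        out.append(label)
        out.append(str(len(nbs)))
        out.append(" ".join(str(j + 1) for j in nbs))
    Path(path).write_text("\n".join(out) + "\n")


def validate_dataset(ds: Dataset, g: AdjacencyGraph) -> dict:
    """Report-only validation: unknown regions, constant columns, empty cells.

    Returns a dict with keys ``unknown_regions``, ``constant_columns`` and
    ``zero_cells`` (factor levels with no stunted or no wasted children);
    all empty on a fully valid dataset.
    """
    report: dict[str, list] = {
        "unknown_regions": [],
        "constant_columns": [],
        "zero_cells": [],
    }
    known = set(g.regions)
    report["unknown_regions"] = sorted(set(ds.region.unique()) - known)
    for c in list(ds.categorical) + list(ds.continuous):
        if ds.frame[c].nunique() <= 1:
            report["constant_columns"].append(c)
    for c in ds.categorical:
        col = ds.frame[c].astype(str)
        for lvl in sorted(col.unique()):
            m = (col == lvl).to_numpy()
            for yname, y in (("stunted", ds.y1), ("wasted", ds.y2)):
                if m.any() and y[m].sum() == 0:
                    report["zero_cells"].append(
                        {"covariate": c, "level": lvl, "outcome": yname}
                    )
    return report
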