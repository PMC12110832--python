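"""Readers and writers for the plain-text formats the pipeline consumes.

All tables are tab-delimited UTF-8 with a single header row and LF line
endings.  Missing expression values are encoded with a configurable token
(default ``"NA"``, case-sensitive).  Every reader validates on ingest and
raises :class:`~netlnc.errors.IngestError` naming the offending row/column;
nothing is silently dropped except self-loop edges, which are counted and
logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IngestError

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

#: Recognised feature classes.
LNCRNA = "lncRNA"
GENE = "gene"
FEATURE_CLASSES = frozenset({LNCRNA, GENE})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples expression values with a class label per feature.

    ``values`` is a float DataFrame indexed by feature id with sample ids as
    columns; missing entries are NaN.  ``feature_class`` maps every feature id
    to ``"lncRNA"`` or ``"gene"``.
    """

    values: pd.DataFrame
    feature_class: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise IngestError(f"duplicate feature id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise IngestError(f"duplicate sample id: {dup!r}")
        missing = [f for f in idx if f not in self.feature_class]
        if missing:
            raise IngestError(
                f"{len(missing)} feature(s) lack a class label, e.g. {missing[0]!r}"
            )
        bad = {c for c in self.feature_class.values()} - FEATURE_CLASSES
        if bad:
            raise IngestError(f"unknown feature class(es): {sorted(bad)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def lncrna_ids(self) -> list[str]:
        return [f for f in self.values.index if self.feature_class[f] == LNCRNA]

    @property
    def gene_ids(self) -> list[str]:
        return [f for f in self.values.index if self.feature_class[f] == GENE]

    def vector(self, feature_id: str) -> np.ndarray:
        """Expression of one feature across samples (float array, NaN = missing)."""
        try:
            return self.values.loc[feature_id].to_numpy(dtype=float)
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in matrix") from None

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PurityVector:
    """Per-sample tumor purity in [0, 1]; NaN marks missing samples."""

    values: pd.Series

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = self.values[(self.values < 0) | (self.values > 1)].index[0]
            raise IngestError(
                f"purity for sample {bad!r} outside [0, 1]: {self.values[bad]}"
            )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise IngestError(f"duplicate sample id in purity table: {dup!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Purity reindexed to ``sample_ids`` (missing samples become NaN)."""
        return self.values.reindex(sample_ids).to_numpy(dtype=float)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise IngestError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class EdgeList:
    """Undirected (node_a, node_b[, weight]) rows; self-loops removed on ingest."""

    edges: pd.DataFrame  # columns: node_a, node_b, weight (weight may be NaN)

    def __post_init__(self) -> None:
        required = {"node_a", "node_b"}
        if not required.issubset(self.edges.columns):
            raise IngestError(f"edge table must have columns {sorted(required)}")
        if "weight" not in self.edges.columns:
            self.edges = self.edges.assign(weight=np.nan)
        loops = self.edges["node_a"] == self.edges["node_b"]
        n_loops = int(loops.sum())
        if n_loops:
            logger.warning("dropped %d self-loop edge(s) on ingest", n_loops)
            self.edges = self.edges.loc[~loops].reset_index(drop=True)
        for col in ("node_a", "node_b"):
            if (self.edges[col].astype(str).str.len() == 0).any():
                raise IngestError(f"empty node id in column {col!r}")

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> Iterable[tuple[str, str]]:
        return zip(self.edges["node_a"], self.edges["node_b"])


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_feature_classes(path: str | Path) -> dict[str, str]:
    """Read a two-column (feature_id, class) map; classes must be lncRNA/gene."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise IngestError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            fid, cls = parts
            if lineno == 1 and cls not in FEATURE_CLASSES:
                continue  # header row
            if cls not in FEATURE_CLASSES:
                raise IngestError(f"{path}:{lineno}: unknown class {cls!r} for {fid!r}")
            if fid in out:
                raise IngestError(f"{path}:{lineno}: duplicate feature id {fid!r}")
            out[fid] = cls
    return out


def read_expression(
    path: str | Path,
    feature_class_map: Mapping[str, str],
    missing_token: str = MISSING_TOKEN,
) -> ExpressionMatrix:
    """Read a features-x-samples expression table.

    First column holds feature ids, the header row holds sample ids.  Cells
    equal to ``missing_token`` become NaN; any other non-numeric cell is an
    ingest error naming the row and column.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, header=0)
    except Exception as exc:  # malformed header / ragged rows
        raise IngestError(f"{path}: cannot parse expression table: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise IngestError(f"{path}: duplicate feature id {dup!r}")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        cells = df[col].where(df[col] != missing_token)
        converted = pd.to_numeric(cells, errors="coerce")
        bad = converted.isna() & cells.notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise IngestError(
                f"{path}: non-numeric cell at feature {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        numeric[col] = converted
    return ExpressionMatrix(values=numeric, feature_class=dict(feature_class_map))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise IngestError(
                    f"{path}:{lineno}: GMT line has {len(parts)} column(s), need >= 3"
                )
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise IngestError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise IngestError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def read_purity(path: str | Path, missing_token: str = MISSING_TOKEN) -> PurityVector:
    """Read a two-column (sample_id, purity) table; values must lie in [0, 1]."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, header=0)
    if df.shape[1] < 2:
        raise IngestError(f"{path}: purity table needs 2 columns")
    ids = df.iloc[:, 0]
    raw = df.iloc[:, 1].where(df.iloc[:, 1] != missing_token)
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any():
        i = bad.to_numpy().nonzero()[0][0]
        raise IngestError(f"{path}: non-numeric purity for sample {ids.iloc[i]!r}")
    return PurityVector(values=pd.Series(vals.to_numpy(dtype=float), index=list(ids)))


def read_edges(path: str | Path) -> EdgeList:
    """Read a two/three-column edge table (node_a, node_b[, weight])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, header=0)
    if df.shape[1] < 2:
        raise IngestError(f"{path}: edge table needs at least 2 columns")
    out = pd.DataFrame(
        {"node_a": df.iloc[:, 0].astype(str), "node_b": df.iloc[:, 1].astype(str)}
    )
    if df.shape[1] >= 3:
        w = pd.to_numeric(df.iloc[:, 2], errors="coerce")
        out["weight"] = w.to_numpy(dtype=float)
    return EdgeList(edges=out)


def read_score_table(path: str | Path, missing_token: str = MISSING_TOKEN) -> pd.DataFrame:
    """Read a samples-x-scores table (first column = sample id)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, header=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise IngestError(f"{path}: duplicate sample id {dup!r}")
    return df.astype(float)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "{:.12g}"


def _format_cell(value) -> str:
    if value is None:
        return MISSING_TOKEN
    if isinstance(value, bool) or isinstance(value, np.bool_):
        return "True" if value else "False"
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return MISSING_TOKEN
        return _FLOAT_FMT.format(float(value))
    return str(value)


def write_table(records: Sequence, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write records (dataclasses or mappings) as a deterministic, diffable TSV.

    Emits one header row; rows are sorted by their stringified key columns so
    repeated runs produce byte-identical output.  Floats use a fixed ``%.12g``
    format, which round-trips well below 1e-9.
    """
    path = Path(path)
    rows: list[dict] = []
    for rec in records:
        if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
            rows.append(dataclasses.asdict(rec))
        elif isinstance(rec, Mapping):
            rows.append(dict(rec))
        else:
            raise TypeError(f"cannot serialize record of type {type(rec).__name__}")
    if columns is None:
        columns = list(rows[0]) if rows else []
    rows.sort(key=lambda r: tuple(str(r.get(c, "")) for c in columns))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(row.get(c)) for c in columns) + "\n")


def read_records(path: str | Path, schema: Mapping[str, type]) -> list[dict]:
    """Read a TSV written by :func:`write_table` back into typed dicts."""
    path = Path(path)
    out: list[dict] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise IngestError(f"{path}:{lineno}: ragged row")
            rec = {}
            for col, cell in zip(header, cells):
                typ = schema.get(col, str)
                if cell == MISSING_TOKEN and typ is float:
                    rec[col] = float("nan")
                elif typ is bool:
                    rec[col] = cell == "True"
                else:
                    rec[col] = typ(cell)
            out.append(rec)
    return out
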