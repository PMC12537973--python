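"""Readers, writers and validated containers for every table the pipeline touches.

The central substrate is a gene x cell-line matrix of CRISPR gene-effect
(Chronos-style) dependency scores, where lower scores mean stronger
dependency and scores below -0.5 conventionally indicate essentiality.
DepMap portal exports ship this matrix in a wide CSV dialect with cell-line
model IDs as rows and ``"SYMBOL (EntrezID)"`` column headers; the reader
normalizes that dialect into symbol-keyed gene x cell-line orientation.

All other tables (cell-line grouping, expression counts, clinical follow-up,
result tables) are plain TSV with a header row.  Gene sets use the
Broad/MSigDB GMT dialect.  Missing dependency scores are kept as missing
(NaN) and never imputed; downstream statistics drop them per gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DependencyMatrix",
    "CellLineGrouping",
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "ClinicalTable",
    "read_dependency_csv",
    "write_dependency_csv",
    "read_gmt",
    "write_gmt",
    "read_grouping",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical",
    "write_table",
    "read_table",
    "normalize_depmap_symbol",
]

# DepMap wide headers look like "A1BG (1)"; the parenthesized numeric ID is
# metadata, the symbol is the primary key.
_DEPMAP_HEADER_RE = re.compile(r"^\s*(?P<symbol>.*?)\s+\((?P<gene_id>[^()]*)\)\s*$")

CLINICAL_COLUMNS = ["sample", "expression", "os_time", "os_event"]


def normalize_depmap_symbol(header: str) -> tuple[str, str | None]:
    """Split a DepMap-style column header into (symbol, gene_id).

    Headers without a trailing ``(...)`` block are returned unchanged with a
    ``None`` id, so normalization is idempotent.
    """
    m = _DEPMAP_HEADER_RE.match(header)
    if m:
        return m.group("symbol"), m.group("gene_id")
    return header.strip(), None


@dataclass
class DependencyMatrix:
    """Gene x cell-line dependency scores; NaN marks a missing score.

    ``scores`` is a float DataFrame indexed by gene symbol with cell-line
    identifiers as columns.  ``gene_ids`` optionally retains the numeric IDs
    parsed from DepMap headers.
    """

    scores: pd.DataFrame
    gene_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            dups = self.scores.index[self.scores.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbol(s): {', '.join(map(str, dups))}")
        if self.scores.columns.has_duplicates:
            dups = self.scores.columns[self.scores.columns.duplicated()].unique()
            raise ValueError(f"duplicate cell line(s): {', '.join(map(str, dups))}")
        self.scores = self.scores.astype(float)
        vals = self.scores.to_numpy()
        if np.isinf(vals).any():
            raise ValueError("dependency scores must be finite or missing (NaN)")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


@dataclass
class CellLineGrouping:
    """Cell line -> entity labels with a designated target entity.

    The target set holds every cell line labeled ``target_label``; all other
    cell lines form the background set.  Both must be non-empty before any
    statistic is computed.
    """

    mapping: dict[str, str]
    target_label: str

    def __post_init__(self) -> None:
        self.target = [c for c, e in self.mapping.items() if e == self.target_label]
        self.background = [c for c, e in self.mapping.items() if e != self.target_label]
        if not self.target:
            raise ValueError(
                f"no cell line carries the target label {self.target_label!r}"
            )
        if not self.background:
            raise ValueError("background set is empty: every cell line is a target")

    @property
    def n_target(self) -> int:
        return len(self.target)

    @property
    def n_background(self) -> int:
        return len(self.background)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


class GeneSetCollection:
    """Named gene sets (KEGG-style pathways) keyed by unique set name."""

    def __init__(self, sets: Sequence[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene-set name: {gene_set.name!r}")
        # dedup members preserving first occurrence
        seen: dict[str, None] = dict.fromkeys(gene_set.members)
        self._sets[gene_set.name] = GeneSet(
            gene_set.name, gene_set.description, tuple(seen)
        )

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values; ``is_counts`` flags raw read counts."""

    values: pd.DataFrame
    is_counts: bool = True

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")
        self.values = self.values.astype(float)
        if self.is_counts and (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClinicalTable:
    """Per-patient covariate plus overall-survival follow-up.

    Columns: ``sample`` (unique id), ``expression`` (the covariate used for
    stratification, e.g. a gene's transcript level or z-score), ``os_time``
    (>= 0, one unit throughout) and ``os_event`` (1 = death observed,
    0 = censored).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing column(s): {', '.join(missing)}")
        self.data = self.data[CLINICAL_COLUMNS].reset_index(drop=True)
        if self.data["sample"].duplicated().any():
            dups = self.data.loc[self.data["sample"].duplicated(), "sample"].unique()
            raise ValueError(f"duplicate sample id(s): {', '.join(map(str, dups))}")
        times = self.data["os_time"].to_numpy(dtype=float)
        if (times < 0).any() or not np.isfinite(times).all():
            raise ValueError("os_time must be finite and >= 0")
        events = self.data["os_event"].to_numpy()
        if not np.isin(events, [0, 1]).all():
            raise ValueError("os_event must be 0 (censored) or 1 (death observed)")
        self.data["os_event"] = self.data["os_event"].astype(int)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# readers / writers


def read_dependency_csv(path: str | Path, dialect: str = "depmap_wide") -> DependencyMatrix:
    """Read a dependency-score matrix.

    ``depmap_wide``: rows are cell-line model IDs, columns are
    ``"SYMBOL (ID)"`` headers (portal export layout); the matrix is
    transposed into gene x cell-line orientation and symbols become the
    primary key.  ``plain``: rows are genes, columns cell lines, first
    column holds the gene symbol.  Empty cells become missing scores.
    """
    path = Path(path)
    if dialect not in ("depmap_wide", "plain"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)

    gene_ids: dict[str, str] = {}
    if dialect == "depmap_wide":
        symbols: list[str] = []
        seen: set[str] = set()
        for col in raw.columns:
            sym, gid = normalize_depmap_symbol(col)
            if sym in seen:
                raise ValueError(f"duplicate gene symbol after normalization: {sym!r}")
            seen.add(sym)
            symbols.append(sym)
            if gid is not None:
                gene_ids[sym] = gid
        raw.columns = symbols
        raw = raw.T  # gene x cell line
    # numeric conversion with coordinates on failure
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        converted = pd.to_numeric(cells.replace("", np.nan), errors="coerce")
        bad = converted.isna() & (cells != "")
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric cell at row {row!r}, column {col!r}: {raw.at[row, col]!r}"
            )
        numeric[col] = converted
    return DependencyMatrix(scores=numeric, gene_ids=gene_ids)


def write_dependency_csv(
    dep: DependencyMatrix, path: str | Path, dialect: str = "depmap_wide"
) -> None:
    """Write a dependency matrix back out in the requested dialect."""
    path = Path(path)
    if dialect == "depmap_wide":
        wide = dep.scores.T.copy()
        headers = []
        for i, sym in enumerate(wide.columns):
            gid = dep.gene_ids.get(sym, str(i + 1))
            headers.append(f"{sym} ({gid})")
        wide.columns = headers
        wide.index.name = "ModelID"
        wide.to_csv(path, float_format="%.12g")
    elif dialect == "plain":
        out = dep.scores.copy()
        out.index.name = "gene"
        out.to_csv(path, float_format="%.12g")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: set name, description, then member symbols, tab-separated."""
    collection = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "GMT requires name, description and at least one member"
                )
            collection.add(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return collection


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def read_grouping(path: str | Path, target_label: str) -> CellLineGrouping:
    """Read a TSV with columns ``cell_line`` and ``entity``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_line", "entity"):
        if col not in df.columns:
            raise ValueError(f"grouping table missing column {col!r}")
    if df["cell_line"].duplicated().any():
        dups = df.loc[df["cell_line"].duplicated(), "cell_line"].unique()
        raise ValueError(f"duplicate cell line(s) in grouping: {', '.join(dups)}")
    mapping = dict(zip(df["cell_line"], df["entity"]))
    return CellLineGrouping(mapping=mapping, target_label=target_label)


def read_expression_tsv(path: str | Path, counts: bool = True) -> ExpressionMatrix:
    """Read a gene x sample expression TSV (first column = gene symbol)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, is_counts=counts)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    return ClinicalTable(data=df)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as headered TSV with full-precision numbers.

    Reals are written with 12 significant digits so a read-back reproduces
    them to that precision; integers round-trip bit-identically.
    """
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
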