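"""Readers, writers and domain types for gene score tables, geneset
collections (GMT) and tissue expression matrices.

Gene identity throughout the package is the exact symbol string after
case-folding to upper case and stripping surrounding whitespace. Alias or
HGNC-history resolution is deliberately out of scope: the sources this
pipeline consumes publish plain symbols, and silent aliasing would make
set arithmetic irreproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .errors import (
    DuplicateGeneError,
    DuplicateNameError,
    InvalidSymbolError,
    MissingColumnError,
    MissingValueError,
    NegativeExpressionError,
    NonNumericValueError,
    ParseError,
)

__all__ = [
    "normalize_symbol",
    "ThresholdRule",
    "GeneScoreTable",
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "read_score_table",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_report",
]


def normalize_symbol(raw: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, upper-case.

    Raises :class:`InvalidSymbolError` for empty symbols or symbols with
    internal whitespace. Idempotent: ``normalize_symbol(normalize_symbol(s))
    == normalize_symbol(s)``.
    """
    sym = str(raw).strip().upper()
    if not sym:
        raise InvalidSymbolError(f"empty gene symbol (from {raw!r})")
    if any(c.isspace() for c in sym):
        raise InvalidSymbolError(f"gene symbol contains internal whitespace: {raw!r}")
    return sym


_RULE_KINDS = ("ge", "le", "gt", "top_fraction", "membership")


@dataclass(frozen=True)
class ThresholdRule:
    """A per-source shortlisting rule.

    kind:
        ``ge`` / ``gt`` / ``le`` — keep genes whose score satisfies the
        comparison against ``value``;
        ``top_fraction`` — keep the top ``floor(value * n)`` genes by
        descending score (``value`` in (0, 1]);
        ``membership`` — keep every gene in the table (the score column
        is ignored; presence in the list is the evidence).
    """

    kind: str
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _RULE_KINDS:
            raise ValueError(f"unknown rule kind {self.kind!r}; expected one of {_RULE_KINDS}")
        if self.kind == "top_fraction" and not (0.0 < self.value <= 1.0):
            raise ValueError(f"top_fraction value must be in (0, 1], got {self.value}")
        if self.kind != "membership" and not math.isfinite(self.value):
            raise ValueError("threshold value must be finite")

    @classmethod
    def parse(cls, text: str) -> "ThresholdRule":
        """Parse ``"ge:0.9"``, ``"top_fraction:0.10"`` or ``"membership"``."""
        kind, _, val = text.partition(":")
        kind = kind.strip()
        if kind == "membership":
            return cls("membership")
        if not val:
            raise ValueError(f"rule {text!r} needs a value, e.g. 'ge:0.9'")
        return cls(kind, float(val))

    def __str__(self) -> str:  # used in manifests / reports
        return "membership" if self.kind == "membership" else f"{self.kind}:{self.value:g}"


@dataclass
class GeneScoreTable:
    """One scoring system's per-gene scores plus its shortlisting rule."""

    source_id: str
    scores: dict[str, float]
    rule: ThresholdRule

    def __post_init__(self) -> None:
        for g, s in self.scores.items():
            if not math.isfinite(s):
                raise NonNumericValueError(f"{self.source_id}: non-finite score for {g}")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols."""

    name: str
    genes: frozenset[str]
    description: str = ""

    @classmethod
    def from_iterable(cls, name: str, genes: Iterable[str], description: str = "") -> "GeneSet":
        return cls(name, frozenset(normalize_symbol(g) for g in genes), description)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def sorted(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named genesets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateNameError(f"duplicate geneset name(s): {', '.join(dup)}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


class ExpressionMatrix:
    """Genes x tissues grid of median TPM values (non-negative reals).

    Thin wrapper over a pandas DataFrame (index = normalized gene
    symbols, columns = tissue labels) that enforces the invariants:
    no missing cells, no negative values, no duplicate genes.
    """

    def __init__(self, values: pd.DataFrame):
        df = values.astype(float)
        if df.index.has_duplicates:
            dup = sorted(df.index[df.index.duplicated()].unique())
            raise DuplicateGeneError(f"duplicate gene symbol(s): {', '.join(map(str, dup))}")
        if df.isna().any().any():
            raise MissingValueError(
                "expression matrix has missing cells; pass fill_missing=0.0 to impute zeros"
            )
        if (df.to_numpy() < 0).any():
            raise NegativeExpressionError("negative TPM value in expression matrix")
        self._df = df

    @property
    def genes(self) -> list[str]:
        return list(self._df.index)

    @property
    def tissues(self) -> list[str]:
        return list(self._df.columns)

    @property
    def values(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        """Rows restricted to ``genes`` (matrix order kept; absent genes ignored)."""
        wanted = {normalize_symbol(g) for g in genes}
        return ExpressionMatrix(self._df.loc[[g for g in self._df.index if g in wanted]])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sep(delimiter: str) -> str:
    return {"tab": "\t", "comma": ","}.get(delimiter, delimiter)


def read_score_table(
    path: str | Path,
    source_id: str,
    rule: ThresholdRule,
    *,
    gene_col: str | int = 0,
    score_col: str | int = 1,
    delimiter: str = "tab",
) -> GeneScoreTable:
    """Read a two-or-more-column delimited score file into a GeneScoreTable.

    Columns are selected by header name or position. Duplicate symbols
    after normalization are an error, as are non-numeric scores.
    """
    df = pd.read_csv(path, sep=_sep(delimiter), dtype=str)
    for col in (gene_col, score_col):
        if isinstance(col, str) and col not in df.columns:
            raise MissingColumnError(f"{path}: column {col!r} not found (have {list(df.columns)})")
        if isinstance(col, int) and col >= df.shape[1]:
            raise MissingColumnError(f"{path}: column index {col} out of range ({df.shape[1]} columns)")
    genes = df[gene_col] if isinstance(gene_col, str) else df.iloc[:, gene_col]
    raw_scores = df[score_col] if isinstance(score_col, str) else df.iloc[:, score_col]

    scores: dict[str, float] = {}
    for g, s in zip(genes, raw_scores):
        sym = normalize_symbol(g)
        if sym in scores:
            raise DuplicateGeneError(f"{path}: duplicate gene {sym!r} after normalization")
        try:
            val = float(s)
        except (TypeError, ValueError) as exc:
            raise NonNumericValueError(f"{path}: non-numeric score {s!r} for gene {sym}") from exc
        if not math.isfinite(val):
            raise NonNumericValueError(f"{path}: non-finite score for gene {sym}")
        scores[sym] = val
    return GeneScoreTable(source_id=source_id, scores=scores, rule=rule)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: ``name<TAB>description<TAB>gene...``.

    Duplicate genes within a line are collapsed; duplicate set names are
    an error; input order is preserved.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, *genes = fields
            sets.append(GeneSet.from_iterable(name, (g for g in genes if g.strip()), desc))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description or "na", *s.sorted()]) + "\n")


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list ('#' comments allowed)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return GeneSet.from_iterable(name or Path(path).stem, genes)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")


def read_expression_matrix(
    path: str | Path,
    *,
    delimiter: str = "tab",
    fill_missing: float | None = None,
    gct: bool = False,
) -> ExpressionMatrix:
    """Read a genes x tissues TPM matrix from delimited text.

    First column holds gene symbols, remaining columns are tissue labels.
    Missing cells are a hard error unless ``fill_missing`` is given
    (typically 0.0). With ``gct=True`` the GCT 1.2 layout is accepted:
    two header lines are skipped and the Description column is dropped.
    """
    skip = 2 if gct else 0
    df = pd.read_csv(
        path, sep=_sep(delimiter), skiprows=skip, index_col=0,
        float_precision="round_trip",
    )
    if gct and df.columns.size and df.columns[0].lower() == "description":
        df = df.drop(columns=df.columns[0])
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise NonNumericValueError(f"{path}: non-numeric expression value ({exc})") from exc
    if fill_missing is not None:
        df = df.fillna(float(fill_missing))
    df.index = [normalize_symbol(g) for g in df.index]
    df.index.name = "gene"
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV at full precision so that read∘write is the identity."""
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# generic report writer
# ---------------------------------------------------------------------------

def write_report(result: object, path: str | Path) -> None:
    """Write any pipeline result to ``path``.

    Results exposing ``to_frame()`` are written as TSV with their own
    deterministic column order; mappings are written as sorted-key JSON.
    """
    if hasattr(result, "to_frame"):
        frame: pd.DataFrame = result.to_frame()  # type: ignore[attr-defined]
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif isinstance(result, Mapping):
        with open(path, "w") as fh:
            json.dump(dict(result), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise TypeError(f"don't know how to write a report for {type(result).__name__}")
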