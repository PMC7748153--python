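"""Tissue-grouped expression filtering and stratification.

Tissues are partitioned into a central-nervous-system (CNS) group and a
peripheral-tissue (PT) group; each gene gets the arithmetic mean of its
median-TPM values over each group. Against a TPM threshold ``t``
(default 3) genes fall into exactly one of three classes:

* ``excluded_low``  — below t in both groups (filtered out as low abundance);
* ``cns_specific``  — at/above t in CNS only;
* ``cns_pt``        — at/above t in PT (regardless of CNS level).

The boundary convention is "kept iff group mean >= t". "Average of the
median" means the plain mean over tissue-level median-TPM columns; brain
sub-regions each count as one tissue, with no re-weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets_io import ExpressionMatrix, GeneSet

__all__ = [
    "TissueGrouping",
    "StratificationResult",
    "group_means",
    "stratify",
    "export_heatmap_matrix",
    "PAPER_HEATMAP_BREAKPOINTS",
    "LABEL_EXCLUDED",
    "LABEL_CNS",
    "LABEL_CNS_PT",
]

CNS = "CNS"
PT = "PT"
LABEL_EXCLUDED = "excluded_low"
LABEL_CNS = "cns_specific"
LABEL_CNS_PT = "cns_pt"

# Published heatmap legend bands: 0 its own band, then 0-3, 9-31, 31-99, >99.
# The legend leaves 3-9 uncovered; with these breakpoints that range falls
# into the second band (3, 9].
PAPER_HEATMAP_BREAKPOINTS = (3.0, 9.0, 31.0, 99.0)


@dataclass
class TissueGrouping:
    """Mapping tissue label -> group label (CNS or PT)."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        bad = {t: g for t, g in self.assignment.items() if g not in (CNS, PT)}
        if bad:
            raise ValueError(f"group labels must be CNS or PT, got {bad}")
        groups = set(self.assignment.values())
        if groups != {CNS, PT}:
            raise ValueError(f"grouping must assign at least one tissue to each of CNS and PT, got {groups}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TissueGrouping":
        df = pd.read_csv(path, sep="\t", header=None, names=["tissue", "group"], comment="#")
        return cls(dict(zip(df["tissue"].astype(str), df["group"].astype(str).str.upper())))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tissue, group in self.assignment.items():
                fh.write(f"{tissue}\t{group}\n")

    def tissues(self, group: str) -> list[str]:
        return [t for t, g in self.assignment.items() if g == group]


@dataclass
class StratificationResult:
    """Per-gene group means and class label, plus the threshold used."""

    table: pd.DataFrame  # columns: gene, avg_cns, avg_pt, label
    t: float
    n_dropped_tissues: int = 0

    cns_specific: GeneSet = field(init=False)
    cns_pt: GeneSet = field(init=False)
    excluded: GeneSet = field(init=False)

    def __post_init__(self) -> None:
        by_label = {
            lab: frozenset(self.table.loc[self.table["label"] == lab, "gene"])
            for lab in (LABEL_CNS, LABEL_CNS_PT, LABEL_EXCLUDED)
        }
        self.cns_specific = GeneSet("cns_specific", by_label[LABEL_CNS])
        self.cns_pt = GeneSet("cns_pt", by_label[LABEL_CNS_PT])
        self.excluded = GeneSet("excluded_low", by_label[LABEL_EXCLUDED])

    def labels(self) -> dict[str, str]:
        return dict(zip(self.table["gene"], self.table["label"]))

    def to_frame(self) -> pd.DataFrame:
        return self.table[["gene", "avg_cns", "avg_pt", "label"]]


def group_means(matrix: ExpressionMatrix, grouping: TissueGrouping) -> pd.DataFrame:
    """Per-gene arithmetic mean of median TPM over each tissue group.

    Matrix tissues absent from the grouping are ignored; their count is
    attached as ``frame.attrs['n_dropped_tissues']``.
    """
    df = matrix.values
    cns_cols = [t for t in df.columns if grouping.assignment.get(t) == CNS]
    pt_cols = [t for t in df.columns if grouping.assignment.get(t) == PT]
    n_dropped = df.shape[1] - len(cns_cols) - len(pt_cols)
    if not cns_cols:
        raise ValueError("no CNS tissue of the grouping present in the matrix")
    if not pt_cols:
        raise ValueError("no PT tissue of the grouping present in the matrix")
    out = pd.DataFrame(
        {
            "gene": df.index,
            "avg_cns": df[cns_cols].mean(axis=1).to_numpy(),
            "avg_pt": df[pt_cols].mean(axis=1).to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["n_dropped_tissues"] = n_dropped
    return out


def stratify(
    matrix: ExpressionMatrix, grouping: TissueGrouping, t: float = 3.0
) -> StratificationResult:
    """Label every gene excluded_low / cns_specific / cns_pt at threshold t.

    The three label sets partition the input genes:
    below t in both groups -> excluded_low; at/above t only in CNS ->
    cns_specific; at/above t in PT -> cns_pt.
    """
    if t <= 0:
        raise ValueError(f"TPM threshold must be positive, got {t}")
    means = group_means(matrix, grouping)
    cns_hi = means["avg_cns"] >= t
    pt_hi = means["avg_pt"] >= t
    label = np.where(pt_hi, LABEL_CNS_PT, np.where(cns_hi, LABEL_CNS, LABEL_EXCLUDED))
    table = means.assign(label=label)
    return StratificationResult(
        table=table, t=t, n_dropped_tissues=means.attrs["n_dropped_tissues"]
    )


def export_heatmap_matrix(
    matrix: ExpressionMatrix,
    result: StratificationResult,
    bins: tuple[float, ...] = PAPER_HEATMAP_BREAKPOINTS,
) -> pd.DataFrame:
    """Bin-code the retained genes for heatmap rendering.

    Bin 0 is reserved for exactly-zero TPM (the "not expressed" band);
    values in ``(b_{i-1}, b_i]`` get bin i; values above the last
    breakpoint get the top bin. Rows come out in two blocks —
    cns_specific then cns_pt, each ordered by descending avg_cns — and
    excluded genes are omitted.
    """
    bins = tuple(float(b) for b in bins)
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])) or (bins and bins[0] <= 0):
        raise ValueError(f"breakpoints must be positive and strictly increasing, got {bins}")

    means = result.table.set_index("gene")
    ordered_genes: list[str] = []
    for geneset in (result.cns_specific, result.cns_pt):
        block = [g for g in geneset.genes if g in matrix.values.index]
        block.sort(key=lambda g: (-means.at[g, "avg_cns"], g))
        ordered_genes.extend(block)

    sub = matrix.values.loc[ordered_genes]
    vals = sub.to_numpy()
    coded = np.searchsorted(np.asarray(bins), vals, side="left") + 1
    coded[vals == 0.0] = 0
    out = pd.DataFrame(coded, index=sub.index, columns=sub.columns, dtype=int)
    out.index.name = "gene"
    out.attrs["blocks"] = {
        LABEL_CNS: len(result.cns_specific),
        LABEL_CNS_PT: len(result.cns_pt),
    }
    return out
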