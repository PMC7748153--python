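"""Pathway co-membership ("interaction") matrix over a study geneset.

Cell (i, j) counts the genes of the study geneset G shared by pathways
P_i and P_j; the diagonal holds |P_i ∩ G|. A pathway's connectivity
degree counts partner pathways sharing at least ``min_shared`` genes of
G, and the hub tally ranks individual genes by how many pathways contain
them — the genes that knit the pathway landscape together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genesets_io import GeneSet, GeneSetCollection

__all__ = [
    "InterconnectivityMatrix",
    "HubTally",
    "build_matrix",
    "connectivity_degree",
    "hub_genes",
]


@dataclass
class InterconnectivityMatrix:
    """Symmetric shared-gene counts between pathway pairs, restricted to G."""

    pathways: list[str]
    counts: np.ndarray  # square, symmetric, ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.pathways), len(self.pathways)):
            raise ValueError("counts shape does not match pathway list")
        if not np.array_equal(c, c.T):
            raise ValueError("interconnectivity matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.pathways, columns=self.pathways)
        df.insert(0, "pathway", self.pathways)
        return df

    def edge_list(self, min_shared: int = 1) -> pd.DataFrame:
        """Off-diagonal pairs with >= min_shared shared genes, for graph viewers."""
        rows = []
        for i, pi in enumerate(self.pathways):
            for j in range(i + 1, len(self.pathways)):
                if self.counts[i, j] >= min_shared:
                    rows.append({"pathway_a": pi, "pathway_b": self.pathways[j],
                                 "shared_genes": int(self.counts[i, j])})
        return pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "shared_genes"])


@dataclass
class HubTally:
    """Genes of G ranked by pathway-membership count (ties lexicographic)."""

    ranked: list[tuple[str, int]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranked, columns=["gene", "n_pathways"])


def build_matrix(pathways: GeneSetCollection, geneset: GeneSet) -> InterconnectivityMatrix:
    """Pairwise |P_i ∩ P_j ∩ G| counts in input pathway order."""
    if len(pathways) < 2:
        raise ValueError("need at least 2 pathways")
    restricted = [p.genes & geneset.genes for p in pathways]
    n = len(restricted)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = len(restricted[i])
        for j in range(i + 1, n):
            counts[i, j] = counts[j, i] = len(restricted[i] & restricted[j])
    return InterconnectivityMatrix(pathways=pathways.names, counts=counts)


def connectivity_degree(matrix: InterconnectivityMatrix, min_shared: int = 1) -> dict[str, int]:
    """Per-pathway count of partners sharing >= min_shared genes of G."""
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    c = matrix.counts
    off = c >= min_shared
    np.fill_diagonal(off, False)
    return {p: int(d) for p, d in zip(matrix.pathways, off.sum(axis=1))}


def hub_genes(pathways: GeneSetCollection, geneset: GeneSet, top_n: int = 20) -> HubTally:
    """Genes of G ranked by the number of pathways containing them."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    tally = {
        g: sum(1 for p in pathways if g in p.genes)
        for g in geneset.genes
    }
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return HubTally(ranked=ranked[:top_n])
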