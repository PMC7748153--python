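"""Per-source shortlisting, k-of-n consensus voting, multi-way Venn region
counts, and anchor-list intersection.

The consensus idea: a gene nominated independently by several scoring
systems (mutation intolerance, network propagation, machine-learned
damage scores, curated databases) is a stronger risk candidate than one
nominated by a single system. Voting is plain set membership: a gene
absent from a source's input table is a non-member of that shortlist
(vote 0), never missing data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .genesets_io import GeneScoreTable, GeneSet, ThresholdRule

__all__ = [
    "Shortlist",
    "ConsensusResult",
    "VennCounts",
    "shortlist",
    "consensus_vote",
    "venn_counts",
    "intersect_anchor",
]

MAX_VENN_SETS = 6


@dataclass
class Shortlist:
    """Genes passing one source's threshold rule."""

    source_id: str
    genes: frozenset[str]
    rule_applied: ThresholdRule
    n_input: int

    def __post_init__(self) -> None:
        if len(self.genes) > self.n_input:
            raise ValueError("shortlist larger than its input table")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": sorted(self.genes)})


@dataclass
class ConsensusResult:
    """Membership vectors, per-gene vote counts and the >= k consensus set."""

    source_ids: list[str]
    membership: dict[str, tuple[bool, ...]]
    k_required: int
    votes: dict[str, int] = field(init=False)
    consensus_genes: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.votes = {g: sum(v) for g, v in self.membership.items()}
        self.consensus_genes = frozenset(
            g for g, n in self.votes.items() if n >= self.k_required
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.membership):
            vec = self.membership[gene]
            row = {"gene": gene}
            row.update({sid: int(m) for sid, m in zip(self.source_ids, vec)})
            row["votes"] = self.votes[gene]
            row["consensus"] = int(gene in self.consensus_genes)
            rows.append(row)
        cols = ["gene", *self.source_ids, "votes", "consensus"]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class VennCounts:
    """Gene counts per exact membership pattern (2^n - 1 non-empty regions).

    Keys are tuples of source ids; each gene contributes to exactly the
    region matching its full membership pattern, so counts sum to the
    union size.
    """

    source_ids: list[str]
    region_counts: dict[tuple[str, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sources": "&".join(region), "n_sources": len(region), "count": count}
            for region, count in sorted(
                self.region_counts.items(), key=lambda kv: (len(kv[0]), kv[0])
            )
        ]
        return pd.DataFrame(rows, columns=["sources", "n_sources", "count"])


def shortlist(table: GeneScoreTable) -> Shortlist:
    """Apply the table's threshold rule and return the passing genes.

    ``top_fraction f`` keeps exactly ``floor(f * n)`` genes after sorting
    by descending score with lexicographic symbol tie-break — a
    deterministic cut when scores tie at the boundary.
    """
    rule = table.rule
    items = table.scores
    if rule.kind == "membership":
        kept = set(items)
    elif rule.kind == "ge":
        kept = {g for g, s in items.items() if s >= rule.value}
    elif rule.kind == "gt":
        kept = {g for g, s in items.items() if s > rule.value}
    elif rule.kind == "le":
        kept = {g for g, s in items.items() if s <= rule.value}
    elif rule.kind == "top_fraction":
        if not items:
            raise ValueError(f"{table.source_id}: top_fraction rule on empty table")
        n_keep = math.floor(rule.value * len(items))
        ranked = sorted(items, key=lambda g: (-items[g], g))
        kept = set(ranked[:n_keep])
    else:  # pragma: no cover - guarded by ThresholdRule
        raise ValueError(f"unknown rule kind {rule.kind}")
    return Shortlist(
        source_id=table.source_id,
        genes=frozenset(kept),
        rule_applied=rule,
        n_input=len(items),
    )


def consensus_vote(shortlists: list[Shortlist], k_required: int) -> ConsensusResult:
    """Genes present in at least ``k_required`` of the shortlists.

    ``k_required = 1`` yields the union, ``k_required = n`` the
    intersection; the consensus set is non-increasing in k.
    """
    n = len(shortlists)
    if n < 2:
        raise ValueError("consensus needs at least 2 shortlists")
    if not (1 <= k_required <= n):
        raise ValueError(f"k_required must be in [1, {n}], got {k_required}")
    source_ids = [s.source_id for s in shortlists]
    if len(set(source_ids)) != n:
        raise ValueError("shortlist source_ids must be unique")
    membership = {
        gene: tuple(gene in s.genes for s in shortlists)
        for gene in sorted(set().union(*(s.genes for s in shortlists)))
    }
    return ConsensusResult(source_ids=source_ids, membership=membership, k_required=k_required)


def venn_counts(shortlists: list[Shortlist]) -> VennCounts:
    """Tally genes by exact membership pattern across 2-6 shortlists."""
    n = len(shortlists)
    if not (2 <= n <= MAX_VENN_SETS):
        raise ValueError(f"venn_counts supports 2-{MAX_VENN_SETS} sets, got {n}")
    source_ids = [s.source_id for s in shortlists]
    # all 2^n - 1 non-empty regions, zero-initialized
    regions: dict[tuple[str, ...], int] = {}
    for mask in range(1, 2**n):
        key = tuple(sid for i, sid in enumerate(source_ids) if mask >> i & 1)
        regions[key] = 0
    for gene in set().union(*(s.genes for s in shortlists)):
        key = tuple(sid for sid, s in zip(source_ids, shortlists) if gene in s.genes)
        regions[key] += 1
    return VennCounts(source_ids=source_ids, region_counts=regions)


def intersect_anchor(
    consensus: ConsensusResult,
    anchor: GeneSet,
    exclusions: GeneSet | None = None,
    name: str = "consensus_anchor",
) -> GeneSet:
    """(consensus genes ∩ anchor) minus exclusions, as a named GeneSet.

    In the replication configuration the anchor is the curated database
    list and the exclusions are its lowest-evidence tier.
    """
    genes = consensus.consensus_genes & anchor.genes
    if exclusions is not None:
        genes -= exclusions.genes
    return GeneSet(name=name, genes=frozenset(genes),
                   description=f"consensus k>={consensus.k_required} ∩ {anchor.name}")
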