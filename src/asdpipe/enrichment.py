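"""Over-representation and geneset-overlap statistics.

The core test is the one-sided hypergeometric tail: with a background
universe of N genes of which K belong to set A, drawing n genes (set B)
uniformly without replacement, the p-value of observing an overlap of at
least x is

    P(X >= x) = sum_{k=x}^{min(K,n)} C(K,k) C(N-K, n-k) / C(N,n).

The tail is accumulated in log space (log-binomials via gammaln +
logsumexp), which stays accurate far into the tail where naive summation
of ratios underflows. Benjamini-Hochberg step-up FDR correction is also
implemented here rather than delegated, so the whole statistical surface
of the pipeline is in one audited place.

The background universe is always explicit. There is no hidden
genome-size constant: a universe baked into the code would silently
determine every p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .genesets_io import GeneSet, GeneSetCollection

__all__ = [
    "OverlapTestResult",
    "OraResult",
    "DegStudy",
    "DegOverlapTally",
    "hypergeom_tail",
    "overlap_test",
    "bh_fdr",
    "ora",
    "deg_overlap_tally",
]


@dataclass(frozen=True)
class OverlapTestResult:
    """One pairwise geneset overlap test against an explicit universe."""

    set_a: str
    set_b: str
    n_universe: int
    n_a: int
    n_b: int
    n_overlap: int
    p_value: float
    odds_ratio: float
    jaccard: float
    fdr: float = float("nan")
    n_dropped_a: int = 0  # genes of A outside the universe (dropped, not kept)
    n_dropped_b: int = 0

    COLUMNS = (
        "set_a", "set_b", "n_universe", "n_a", "n_b", "n_overlap",
        "p_value", "odds_ratio", "jaccard", "fdr",
    )

    def row(self) -> dict:
        return {c: getattr(self, c) for c in self.COLUMNS}


@dataclass
class OraResult:
    """Ranked over-representation results for a query against a collection.

    Tests are sorted ascending by p-value (ties broken by term name),
    BH-corrected across *all* terms tested, then truncated to ``top_k``.
    """

    results: list[OverlapTestResult]
    top_k: int
    fdr_max: float
    n_terms_tested: int

    @property
    def significant(self) -> list[OverlapTestResult]:
        return [r for r in self.results if r.fdr <= self.fdr_max]

    def to_frame(self) -> pd.DataFrame:
        rows = [r.row() for r in self.results]
        return pd.DataFrame(rows, columns=list(OverlapTestResult.COLUMNS))


def _log_binom(n: np.ndarray | float, k: np.ndarray | float) -> np.ndarray:
    return gammaln(np.asarray(n) + 1) - gammaln(np.asarray(k) + 1) - gammaln(np.asarray(n) - np.asarray(k) + 1)


def _check_counts(n_universe: int, n_a: int, n_b: int, n_overlap: int) -> None:
    if n_universe <= 0:
        raise ValueError("universe must be non-empty")
    if not (0 <= n_a <= n_universe and 0 <= n_b <= n_universe):
        raise ValueError(f"set sizes must lie in [0, {n_universe}]: n_a={n_a}, n_b={n_b}")
    lo = max(0, n_a + n_b - n_universe)
    if not (lo <= n_overlap <= min(n_a, n_b)):
        raise ValueError(
            f"overlap {n_overlap} impossible for n_universe={n_universe}, n_a={n_a}, n_b={n_b}"
        )


def hypergeom_tail(n_universe: int, n_a: int, n_b: int, n_overlap: int) -> float:
    """Upper-tail P(X >= n_overlap) of the hypergeometric, in log space."""
    _check_counts(n_universe, n_a, n_b, n_overlap)
    if n_overlap == 0:
        return 1.0
    ks = np.arange(n_overlap, min(n_a, n_b) + 1)
    log_terms = (
        _log_binom(n_a, ks)
        + _log_binom(n_universe - n_a, n_b - ks)
        - _log_binom(n_universe, n_b)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def overlap_test(a: GeneSet, b: GeneSet, universe: GeneSet) -> OverlapTestResult:
    """Full overlap statistics for two genesets against a universe.

    Genes outside the universe are dropped before counting and reported
    in the ``n_dropped_*`` fields. The odds ratio comes from the 2x2
    table, +inf when a denominator cell is zero; Jaccard is
    overlap / union within the universe.
    """
    if not universe.genes:
        raise ValueError("empty universe")
    a_in = a.genes & universe.genes
    b_in = b.genes & universe.genes
    n_u, n_a, n_b = len(universe), len(a_in), len(b_in)
    n_ov = len(a_in & b_in)
    p = hypergeom_tail(n_u, n_a, n_b, n_ov)

    t11 = n_ov
    t12 = n_a - n_ov
    t21 = n_b - n_ov
    t22 = n_u - n_a - n_b + n_ov
    odds = float("inf") if t12 * t21 == 0 else (t11 * t22) / (t12 * t21)
    union = n_a + n_b - n_ov
    jaccard = 0.0 if union == 0 else n_ov / union
    return OverlapTestResult(
        set_a=a.name, set_b=b.name,
        n_universe=n_u, n_a=n_a, n_b=n_b, n_overlap=n_ov,
        p_value=p, odds_ratio=odds, jaccard=jaccard,
        n_dropped_a=len(a.genes) - n_a, n_dropped_b=len(b.genes) - n_b,
    )


def bh_fdr(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_i = min_{j: p_(j) >= p_(i)} ( m * p_(j) / rank(j) ), capped at 1.
    Preserves the p-value rank ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty_like(p)
    adj[order] = adj_sorted
    return adj


def ora(
    query: GeneSet,
    terms: GeneSetCollection,
    universe: GeneSet,
    top_k: int = 50,
    fdr_max: float = 0.05,
) -> OraResult:
    """Over-representation of a query geneset across a term collection.

    One hypergeometric test per term; BH correction over all terms
    tested; then the list is cut to the ``top_k`` smallest p-values
    (term-name tie-break), mirroring the common "top K terms" reporting
    convention of ORA web tools.
    """
    if len(terms) == 0:
        raise ValueError("empty term collection")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    tests = [overlap_test(term, query, universe) for term in terms]
    fdrs = bh_fdr([t.p_value for t in tests])
    tests = [replace(t, fdr=float(f)) for t, f in zip(tests, fdrs)]
    tests.sort(key=lambda t: (t.p_value, t.set_a))
    return OraResult(
        results=tests[:top_k], top_k=top_k, fdr_max=fdr_max, n_terms_tested=len(tests)
    )


@dataclass(frozen=True)
class DegStudy:
    """One published differential-expression study: its up- and down-lists."""

    name: str
    up: GeneSet
    down: GeneSet


@dataclass
class DegOverlapTally:
    """Per-study overlap counts of a query with published DEG lists."""

    query_name: str
    n_query: int
    rows: list[dict] = field(default_factory=list)
    union_count: int = 0  # |query ∩ union over studies of (up ∪ down)|

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["study", "overlap", "up", "down"])


def deg_overlap_tally(query: GeneSet, studies: list[DegStudy]) -> DegOverlapTally:
    """Tally query genes dysregulated per study and at least once overall.

    Per study: |query ∩ (up ∪ down)|, |query ∩ up|, |query ∩ down|.
    The union count gives the "dysregulated at least once across
    studies" headline number.
    """
    tally = DegOverlapTally(query_name=query.name, n_query=len(query))
    dysregulated_any: set[str] = set()
    for study in studies:
        both = study.up.genes | study.down.genes
        tally.rows.append(
            {
                "study": study.name,
                "overlap": len(query.genes & both),
                "up": len(query.genes & study.up.genes),
                "down": len(query.genes & study.down.genes),
            }
        )
        dysregulated_any |= query.genes & both
    tally.union_count = len(dysregulated_any)
    return tally
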