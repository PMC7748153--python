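"""Seeded generators with planted ground truth.

Every pipeline stage is testable without downloads: these generators
emit score tables, a two-group tissue expression matrix and geneset
collections whose true structure (which genes are consensus risk genes,
which are CNS-specific, which term is enriched) is known by
construction and recorded in a :class:`SyntheticTruth` manifest.

Seeding: one top-level seed expands into independent per-component
streams via ``numpy.random.SeedSequence(seed, spawn_key=(index,))``
with a fixed component index per generator, so adding a new generator
never perturbs the streams of existing ones.

What the generators emulate — and what they do not: score sources are
conditionally independent Bernoulli nominators (a planted gene passes
each source's threshold with probability ``p_hit``, background with
``p_bg``); real scoring systems are correlated because they share
training data. Expression values are i.i.d. log-normal per tissue
(non-negative, heavy-tailed like median-TPM data) with class-specific
medians; real tissues are strongly correlated and genes are not
exchangeable. Conclusions from passing tests are about the pipeline's
set arithmetic and statistics, not about real-data performance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CNS, PT, TissueGrouping
from .genesets_io import (
    ExpressionMatrix,
    GeneScoreTable,
    GeneSet,
    GeneSetCollection,
    ThresholdRule,
)

__all__ = [
    "SyntheticTruth",
    "child_rng",
    "gen_score_sources",
    "gen_expression",
    "gen_genesets",
    "simulate_study",
    "STUDY_RULES",
]

# Component indices for seed derivation; append-only.
_COMPONENT_INDEX = {
    "scores": 0,
    "expression": 1,
    "genesets": 2,
    "anchor": 3,
    "pathways": 4,
    "disease": 5,
    "deg": 6,
}

# Replication-shaped source rules: mutation-intolerance pLi (>= 0.9),
# curated-database membership, network q-value (<= 0.05), top-decile
# percentile score, positive damage score.
STUDY_RULES: dict[str, ThresholdRule] = {
    "exac_pli": ThresholdRule("ge", 0.9),
    "sfari": ThresholdRule("membership"),
    "krishnan_q": ThresholdRule("le", 0.05),
    "duda_percentile": ThresholdRule("top_fraction", 0.10),
    "zhang_damage": ThresholdRule("gt", 0.0),
}


def child_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component random stream from one top-level seed."""
    idx = _COMPONENT_INDEX[component]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(idx,)))


@dataclass
class SyntheticTruth:
    """Planted ground truth sufficient to score any downstream stage."""

    seed: int
    planted_consensus: frozenset[str] = frozenset()
    planted_cns_specific: frozenset[str] = frozenset()
    planted_cns_pt: frozenset[str] = frozenset()
    planted_low: frozenset[str] = frozenset()
    planted_enriched_terms: frozenset[str] = frozenset()
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.planted_cns_specific & self.planted_cns_pt:
            raise ValueError("planted expression classes must be disjoint")

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            seed=self.seed,
            planted_consensus=self.planted_consensus | other.planted_consensus,
            planted_cns_specific=self.planted_cns_specific | other.planted_cns_specific,
            planted_cns_pt=self.planted_cns_pt | other.planted_cns_pt,
            planted_low=self.planted_low | other.planted_low,
            planted_enriched_terms=self.planted_enriched_terms | other.planted_enriched_terms,
            generator_params={**self.generator_params, **other.generator_params},
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_consensus": sorted(self.planted_consensus),
            "planted_cns_specific": sorted(self.planted_cns_specific),
            "planted_cns_pt": sorted(self.planted_cns_pt),
            "planted_low": sorted(self.planted_low),
            "planted_enriched_terms": sorted(self.planted_enriched_terms),
            "generator_params": self.generator_params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            planted_consensus=frozenset(d["planted_consensus"]),
            planted_cns_specific=frozenset(d["planted_cns_specific"]),
            planted_cns_pt=frozenset(d["planted_cns_pt"]),
            planted_low=frozenset(d.get("planted_low", [])),
            planted_enriched_terms=frozenset(d["planted_enriched_terms"]),
            generator_params=d["generator_params"],
        )


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _open_low(rng: np.random.Generator) -> float:
    """A draw in (0, 1] — strictly positive, so threshold offsets never vanish."""
    return 1.0 - rng.random()


def gen_score_sources(
    n_genes: int,
    n_sources: int,
    n_planted: int,
    p_hit: float,
    p_bg: float,
    rules: list[ThresholdRule] | None = None,
    seed: int = 0,
) -> tuple[list[GeneScoreTable], SyntheticTruth]:
    """Score tables where planted genes pass each source's rule independently
    with probability ``p_hit`` and background genes with ``p_bg``.

    For comparison rules the score is drawn uniformly on the passing or
    failing side of the threshold according to the per-gene Bernoulli
    draw, so shortlist membership is exactly that draw. The
    ``membership`` rule includes a gene's row iff its draw passes. For
    ``top_fraction f`` the draw decides the score band (passers above,
    others below) but the shortlist keeps exactly ``floor(f*n)`` genes,
    so realized membership can deviate from the Bernoulli target when
    the number of passers differs from the cut size — a documented
    approximation inherent to a rank-based rule.
    """
    if n_planted > n_genes:
        raise ValueError("n_planted exceeds n_genes")
    if not p_hit > p_bg:
        raise ValueError("p_hit must exceed p_bg")
    rng = child_rng(seed, "scores")
    genes = np.array(_gene_names(n_genes))
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    is_planted = np.zeros(n_genes, dtype=bool)
    is_planted[planted_idx] = True

    if rules is None:
        base = list(STUDY_RULES.values())
        rules = [base[i % len(base)] for i in range(n_sources)]
    if len(rules) != n_sources:
        raise ValueError("need one rule per source")

    tables: list[GeneScoreTable] = []
    for s_idx, rule in enumerate(rules):
        p = np.where(is_planted, p_hit, p_bg)
        passes = rng.random(n_genes) < p
        scores: dict[str, float] = {}
        for g, ok in zip(genes, passes):
            t = rule.value
            if rule.kind == "membership":
                if ok:
                    scores[g] = 1.0
                continue
            if rule.kind == "ge":
                scores[g] = t + rng.random() if ok else t - _open_low(rng)
            elif rule.kind == "gt":
                scores[g] = t + _open_low(rng) if ok else t - rng.random()
            elif rule.kind == "le":
                scores[g] = t - rng.random() if ok else t + _open_low(rng)
            elif rule.kind == "top_fraction":
                scores[g] = 1.0 + rng.random() if ok else rng.random()
        tables.append(
            GeneScoreTable(source_id=f"source_{s_idx}", scores=scores, rule=rule)
        )
    truth = SyntheticTruth(
        seed=seed,
        planted_consensus=frozenset(genes[is_planted]),
        generator_params={
            "scores": {
                "n_genes": n_genes, "n_sources": n_sources, "n_planted": n_planted,
                "p_hit": p_hit, "p_bg": p_bg, "rules": [str(r) for r in rules],
            }
        },
    )
    return tables, truth


def gen_expression(
    n_genes: int,
    n_cns_tissues: int = 13,
    n_pt_tissues: int = 40,
    class_fractions: tuple[float, float, float] = (0.285, 0.630, 0.085),
    mean_tpm_by_class: dict[str, tuple[float, float]] | None = None,
    log_sd: float = 0.5,
    t: float = 3.0,
    seed: int = 0,
    gene_names: list[str] | None = None,
) -> tuple[ExpressionMatrix, TissueGrouping, SyntheticTruth]:
    """Two-group median-TPM matrix with planted expression classes.

    ``class_fractions`` are (cns_specific, cns_pt, low) and must sum
    to 1; the defaults reproduce the roughly 29% / 63% / 8.5% split a
    consensus ASD geneset shows after tissue filtering. Each tissue
    value is log-normal with class-and-group-specific median:
    cns_specific genes sit at 5t in CNS and t/5 in PT, cns_pt at 5t in
    both, low at t/5 in both (t = 3 TPM by default), with ``log_sd``
    standard deviation on the natural-log scale. Tissue counts default
    to the 13 CNS / 40 peripheral split of the GTEx v7 median-TPM table.
    """
    if n_cns_tissues < 1 or n_pt_tissues < 1:
        raise ValueError("tissue counts must be positive")
    if not math.isclose(sum(class_fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"class fractions must sum to 1, got {class_fractions}")
    if mean_tpm_by_class is None:
        mean_tpm_by_class = {
            "cns_specific": (5.0 * t, t / 5.0),
            "cns_pt": (5.0 * t, 5.0 * t),
            "low": (t / 5.0, t / 5.0),
        }
    rng = child_rng(seed, "expression")
    genes = list(gene_names) if gene_names is not None else _gene_names(n_genes)
    if len(genes) != n_genes:
        raise ValueError("gene_names length must equal n_genes")

    n_cns = int(round(class_fractions[0] * n_genes))
    n_low = int(round(class_fractions[2] * n_genes))
    n_cnspt = n_genes - n_cns - n_low
    labels = np.array(
        ["cns_specific"] * n_cns + ["cns_pt"] * n_cnspt + ["low"] * n_low
    )
    rng.shuffle(labels)

    tissues = [f"CNS_{i:02d}" for i in range(n_cns_tissues)] + [
        f"PT_{i:02d}" for i in range(n_pt_tissues)
    ]
    values = np.empty((n_genes, len(tissues)))
    for cls, (med_cns, med_pt) in mean_tpm_by_class.items():
        mask = labels == cls
        k = int(mask.sum())
        if k == 0:
            continue
        values[mask, :n_cns_tissues] = rng.lognormal(
            math.log(med_cns), log_sd, size=(k, n_cns_tissues)
        )
        values[mask, n_cns_tissues:] = rng.lognormal(
            math.log(med_pt), log_sd, size=(k, n_pt_tissues)
        )

    df = pd.DataFrame(values, index=genes, columns=tissues)
    df.index.name = "gene"
    grouping = TissueGrouping(
        {tis: (CNS if tis.startswith("CNS_") else PT) for tis in tissues}
    )
    genes_arr = np.array(genes)
    truth = SyntheticTruth(
        seed=seed,
        planted_cns_specific=frozenset(genes_arr[labels == "cns_specific"]),
        planted_cns_pt=frozenset(genes_arr[labels == "cns_pt"]),
        planted_low=frozenset(genes_arr[labels == "low"]),
        generator_params={
            "expression": {
                "n_genes": n_genes, "n_cns_tissues": n_cns_tissues,
                "n_pt_tissues": n_pt_tissues,
                "class_fractions": list(class_fractions),
                "mean_tpm_by_class": {k: list(v) for k, v in mean_tpm_by_class.items()},
                "log_sd": log_sd, "t": t,
            }
        },
    )
    return ExpressionMatrix(df), grouping, truth


def gen_genesets(
    n_terms: int,
    term_size_range: tuple[int, int],
    universe: GeneSet,
    planted_term_genes: GeneSet | None = None,
    enrichment_odds: float = 10.0,
    seed: int = 0,
    name_prefix: str = "TERM",
    component: str = "genesets",
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Term collection with one planted enriched term.

    The planted term samples its members without replacement with weight
    ``enrichment_odds`` on ``planted_term_genes`` and 1 elsewhere;
    ``enrichment_odds=1`` makes it indistinguishable from background
    (the null generator) and ``math.inf`` fills it with planted genes
    up to its size. All other terms sample uniformly from the universe.
    """
    lo, hi = term_size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError(f"term sizes must satisfy 1 <= {lo} <= {hi} <= |universe|")
    rng = child_rng(seed, component)
    pool = np.array(universe.sorted())
    planted = planted_term_genes.genes if planted_term_genes is not None else frozenset()

    planted_idx = int(rng.integers(n_terms)) if planted else -1
    sets = []
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        if i == planted_idx:
            if math.isinf(enrichment_odds):
                core = np.array(sorted(planted))[:size]
                rest = size - len(core)
                if rest > 0:
                    bg = pool[~np.isin(pool, core)]
                    core = np.concatenate([core, rng.choice(bg, size=rest, replace=False)])
                members = core
            else:
                w = np.where(np.isin(pool, sorted(planted)), enrichment_odds, 1.0)
                members = rng.choice(pool, size=size, replace=False, p=w / w.sum())
            name = f"{name_prefix}_{i:03d}_PLANTED"
        else:
            members = rng.choice(pool, size=size, replace=False)
            name = f"{name_prefix}_{i:03d}"
        sets.append(GeneSet.from_iterable(name, members, description="synthetic term"))

    truth = SyntheticTruth(
        seed=seed,
        planted_enriched_terms=frozenset(
            [f"{name_prefix}_{planted_idx:03d}_PLANTED"] if planted_idx >= 0 else []
        ),
        generator_params={
            component: {
                "n_terms": n_terms, "term_size_range": [lo, hi],
                "enrichment_odds": enrichment_odds,
            }
        },
    )
    return GeneSetCollection(sets), truth


# ---------------------------------------------------------------------------
# full replication-shaped study
# ---------------------------------------------------------------------------

def simulate_study(
    seed: int,
    out_dir: str | Path,
    n_genes: int = 5000,
    n_planted: int = 350,
    p_hit: float = 0.9,
    p_bg: float = 0.05,
    k_required: int = 4,
    tpm_threshold: float = 3.0,
    n_terms: int = 40,
    n_deg_studies: int = 6,
) -> SyntheticTruth:
    """Emit a complete synthetic study to ``out_dir`` and return its truth.

    Files written: ``scores/<source>.tsv`` (5 sources with the
    replication threshold rules), ``expr.tsv`` + ``grouping.tsv``,
    ``anchor.txt`` (membership-source gene list standing in for the
    curated database) and ``exclusions.txt`` (its lowest-evidence tier),
    ``terms.gmt``, ``pathways.gmt``, ``disease.gmt``, ``deg.gmt``
    (``<study>__up`` / ``<study>__down`` sets), ``truth.json`` and a
    ready-to-run ``study.yaml``.
    """
    out = Path(out_dir)
    (out / "scores").mkdir(parents=True, exist_ok=True)

    rules = list(STUDY_RULES.values())
    source_names = list(STUDY_RULES.keys())
    tables, truth = gen_score_sources(
        n_genes=n_genes, n_sources=len(rules), n_planted=n_planted,
        p_hit=p_hit, p_bg=p_bg, rules=rules, seed=seed,
    )
    score_entries = []
    for name, table in zip(source_names, tables):
        path = out / "scores" / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write("gene\tscore\n")
            for g in sorted(table.scores):
                fh.write(f"{g}\t{table.scores[g]:.17g}\n")
        score_entries.append({"id": name, "path": str(path), "rule": str(table.rule)})

    # expression over the whole gene universe; the pipeline subsets it
    matrix, grouping, expr_truth = gen_expression(
        n_genes=n_genes, t=tpm_threshold, seed=seed
    )
    truth = truth.merge(expr_truth)
    from .genesets_io import write_expression_matrix  # local import avoids cycle at module load

    write_expression_matrix(matrix, out / "expr.tsv")
    grouping.to_tsv(out / "grouping.tsv")

    # anchor: the membership source's list; exclusions: a low-evidence tier
    membership_table = tables[source_names.index("sfari")]
    anchor_genes = sorted(membership_table.scores)
    rng = child_rng(seed, "anchor")
    n_excl = max(1, len(anchor_genes) // 20)
    excl = sorted(rng.choice(np.array(anchor_genes), size=n_excl, replace=False))
    with open(out / "anchor.txt", "w") as fh:
        fh.write("\n".join(anchor_genes) + "\n")
    with open(out / "exclusions.txt", "w") as fh:
        fh.write("\n".join(excl) + "\n")

    universe = GeneSet.from_iterable("universe", _gene_names(n_genes))
    planted_set = GeneSet("planted", truth.planted_consensus)

    from .genesets_io import write_gmt

    terms, term_truth = gen_genesets(
        n_terms=n_terms, term_size_range=(20, 120), universe=universe,
        planted_term_genes=planted_set, enrichment_odds=10.0, seed=seed,
        name_prefix="PHENO", component="genesets",
    )
    truth = truth.merge(term_truth)
    write_gmt(terms, out / "terms.gmt")

    pathways, pw_truth = gen_genesets(
        n_terms=20, term_size_range=(20, 80), universe=universe,
        planted_term_genes=planted_set, enrichment_odds=10.0, seed=seed,
        name_prefix="PATH", component="pathways",
    )
    truth = truth.merge(pw_truth)
    write_gmt(pathways, out / "pathways.gmt")

    disease, dz_truth = gen_genesets(
        n_terms=7, term_size_range=(50, 200), universe=universe,
        planted_term_genes=planted_set, enrichment_odds=5.0, seed=seed,
        name_prefix="DISEASE", component="disease",
    )
    truth = truth.merge(dz_truth)
    write_gmt(disease, out / "disease.gmt")

    deg_rng = child_rng(seed, "deg")
    pool = np.array(_gene_names(n_genes))
    deg_sets = []
    for i in range(n_deg_studies):
        for direction in ("up", "down"):
            size = int(deg_rng.integers(20, 150))
            members = deg_rng.choice(pool, size=size, replace=False)
            deg_sets.append(
                GeneSet.from_iterable(f"study{i}__{direction}", members, "synthetic DEG list")
            )
    write_gmt(GeneSetCollection(deg_sets), out / "deg.gmt")

    truth.to_json(out / "truth.json")

    config = {
        "sources": score_entries,
        "k_required": k_required,
        "anchor": str(out / "anchor.txt"),
        "exclusions": str(out / "exclusions.txt"),
        "expression": str(out / "expr.tsv"),
        "grouping": str(out / "grouping.tsv"),
        "tpm_threshold": tpm_threshold,
        "universe": "all_source_genes",
        "terms": str(out / "terms.gmt"),
        "pathways": str(out / "pathways.gmt"),
        "disease": str(out / "disease.gmt"),
        "deg": str(out / "deg.gmt"),
        "top_k": 50,
        "fdr_max": 0.05,
        "min_shared": 1,
        "out_dir": str(out / "results"),
    }
    import yaml

    with open(out / "study.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return truth
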