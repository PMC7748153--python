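"""Config-driven end-to-end orchestration.

Stage order mirrors the study design: per-source shortlisting →
k-of-n consensus (+ Venn counts) → anchor-list intersection with
low-evidence exclusions → tissue-expression stratification into
CNS-specific and CNS+PT genesets → over-representation against term
collections → DEG-overlap tally → pathway interconnectivity →
pairwise disease-overlap matrix.

All thresholds live in the config file; the code carries no magic
numbers. Outputs are deterministic given inputs: the manifest contains
no wall-clock timestamps (run timing goes to the log), so two runs of
the same study are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import consensus as cns
from . import enrichment, interconnectivity
from .errors import ConfigError
from .expression import TissueGrouping, export_heatmap_matrix, stratify
from .genesets_io import (
    GeneSet,
    GeneSetCollection,
    ThresholdRule,
    read_expression_matrix,
    read_gene_list,
    read_gmt,
    read_score_table,
    write_gene_list,
    write_report,
)

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline"]

log = logging.getLogger("asdpipe")

DEG_SUFFIXES = ("__up", "__down")


@dataclass
class SourceSpec:
    id: str
    path: str
    rule: ThresholdRule


@dataclass
class PipelineConfig:
    sources: list[SourceSpec]
    k_required: int
    anchor: str
    out_dir: str
    exclusions: str | None = None
    expression: str | None = None
    grouping: str | None = None
    tpm_threshold: float = 3.0
    universe: str = "all_source_genes"
    terms: str | None = None
    pathways: str | None = None
    disease: str | None = None
    deg: str | None = None
    top_k: int = 50
    fdr_max: float = 0.05
    min_shared: int = 1
    fill_missing_expression: bool = False


@dataclass
class RunManifest:
    """Per-stage counts and warnings; written as sorted-key JSON."""

    config: dict
    stage_counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = ""

    def check_consistency(self) -> None:
        """The stratification labels must partition the final geneset."""
        sc = self.stage_counts
        if "stratify" in sc:
            s = sc["stratify"]
            total = s["excluded_low"] + s["cns_specific"] + s["cns_pt"]
            if total != sc["anchor_intersect"]["n_genes"]:
                raise AssertionError(
                    f"stratification labels ({total}) do not partition the "
                    f"anchored geneset ({sc['anchor_intersect']['n_genes']})"
                )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "stage_counts": self.stage_counts,
            "warnings": self.warnings,
            "version": self.version,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a study config, collecting *all* errors.

    Returns ``(config, [])`` on success or ``(None, errors)`` with every
    problem found, not just the first.
    """
    errors: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        return None, [f"cannot read config {path}: {exc}"]

    sources: list[SourceSpec] = []
    raw_sources = raw.get("sources")
    if not raw_sources:
        errors.append("sources: at least one score source is required")
    else:
        for i, entry in enumerate(raw_sources):
            sid = entry.get("id", f"source_{i}")
            spath = entry.get("path")
            if not spath:
                errors.append(f"sources[{i}] ({sid}): missing 'path'")
            elif not Path(spath).exists():
                errors.append(f"sources[{i}] ({sid}): scores file not found: {spath}")
            try:
                rule = ThresholdRule.parse(str(entry.get("rule", "")))
            except ValueError as exc:
                errors.append(f"sources[{i}] ({sid}): bad rule: {exc}")
                rule = ThresholdRule("membership")
            sources.append(SourceSpec(id=sid, path=str(spath), rule=rule))

    k = raw.get("k_required")
    if not isinstance(k, int) or k < 1:
        errors.append(f"k_required: must be a positive integer, got {k!r}")
    elif raw_sources and k > len(raw_sources):
        errors.append(f"k_required: {k} exceeds the number of sources ({len(raw_sources)})")

    anchor = raw.get("anchor")
    if not anchor:
        errors.append("anchor: an anchor gene list is required")
    elif not Path(anchor).exists():
        errors.append(f"anchor: file not found: {anchor}")

    for key in ("exclusions", "expression", "grouping", "terms", "pathways", "disease", "deg"):
        val = raw.get(key)
        if val and not Path(val).exists():
            errors.append(f"{key}: file not found: {val}")

    universe = raw.get("universe", "all_source_genes")
    if universe != "all_source_genes" and not Path(universe).exists():
        errors.append(f"universe: file not found: {universe}")

    out_dir = raw.get("out_dir")
    if not out_dir:
        errors.append("out_dir: an output directory is required")

    tpm = raw.get("tpm_threshold", 3.0)
    if not isinstance(tpm, (int, float)) or tpm <= 0:
        errors.append(f"tpm_threshold: must be > 0, got {tpm!r}")

    if errors:
        return None, errors
    return (
        PipelineConfig(
            sources=sources,
            k_required=int(k),
            anchor=str(anchor),
            out_dir=str(out_dir),
            exclusions=raw.get("exclusions"),
            expression=raw.get("expression"),
            grouping=raw.get("grouping"),
            tpm_threshold=float(tpm),
            universe=str(universe),
            terms=raw.get("terms"),
            pathways=raw.get("pathways"),
            disease=raw.get("disease"),
            deg=raw.get("deg"),
            top_k=int(raw.get("top_k", 50)),
            fdr_max=float(raw.get("fdr_max", 0.05)),
            min_shared=int(raw.get("min_shared", 1)),
            fill_missing_expression=bool(raw.get("fill_missing_expression", False)),
        ),
        [],
    )


def _load_deg_studies(path: str) -> list[enrichment.DegStudy]:
    """Pair ``<study>__up`` / ``<study>__down`` GMT sets into DegStudy records."""
    coll = read_gmt(path)
    by_study: dict[str, dict[str, GeneSet]] = {}
    for s in coll:
        for suffix in DEG_SUFFIXES:
            if s.name.endswith(suffix):
                study = s.name[: -len(suffix)]
                by_study.setdefault(study, {})[suffix.strip("_")] = s
                break
        else:
            raise ValueError(f"DEG set {s.name!r} lacks an __up/__down suffix")
    empty = frozenset()
    return [
        enrichment.DegStudy(
            name=study,
            up=d.get("up", GeneSet(f"{study}__up", empty)),
            down=d.get("down", GeneSet(f"{study}__down", empty)),
        )
        for study, d in sorted(by_study.items())
    ]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all configured stages; any failure aborts with the stage named."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            "k_required": config.k_required,
            "tpm_threshold": config.tpm_threshold,
            "top_k": config.top_k,
            "fdr_max": config.fdr_max,
            "min_shared": config.min_shared,
            "sources": [{"id": s.id, "rule": str(s.rule)} for s in config.sources],
        },
        version=__version__,
    )

    # stage 1: shortlists
    tables = [
        read_score_table(s.path, source_id=s.id, rule=s.rule) for s in config.sources
    ]
    shortlists = [cns.shortlist(t) for t in tables]
    for sl in shortlists:
        write_gene_list(sl.genes, out / f"shortlist_{sl.source_id}.txt")
    manifest.stage_counts["shortlist"] = {
        sl.source_id: {"n_input": sl.n_input, "n_shortlisted": len(sl)} for sl in shortlists
    }
    log.info("shortlists: %s", {sl.source_id: len(sl) for sl in shortlists})

    # stage 2: consensus + venn
    result = cns.consensus_vote(shortlists, k_required=config.k_required)
    write_report(result, out / "consensus.tsv")
    write_gene_list(result.consensus_genes, out / "consensus_genes.txt")
    venn = cns.venn_counts(shortlists)
    write_report(venn, out / "venn.tsv")
    manifest.stage_counts["consensus"] = {
        "n_union": len(result.membership),
        "n_consensus": len(result.consensus_genes),
        "k_required": config.k_required,
    }
    log.info("consensus (k>=%d): %d of %d union genes",
             config.k_required, len(result.consensus_genes), len(result.membership))

    # stage 3: anchor intersection
    anchor = read_gene_list(config.anchor, name="anchor")
    exclusions = (
        read_gene_list(config.exclusions, name="exclusions") if config.exclusions else None
    )
    geneset = cns.intersect_anchor(result, anchor, exclusions, name="asd_geneset")
    write_gene_list(geneset.genes, out / "asd_geneset.txt")
    manifest.stage_counts["anchor_intersect"] = {
        "n_anchor": len(anchor),
        "n_excluded_by_list": len(exclusions) if exclusions else 0,
        "n_genes": len(geneset),
    }
    log.info("anchored geneset: %d genes", len(geneset))

    # stage 4: expression stratification
    combined = geneset
    strat = None
    if config.expression and config.grouping:
        matrix = read_expression_matrix(
            config.expression,
            fill_missing=0.0 if config.fill_missing_expression else None,
        )
        grouping = TissueGrouping.from_tsv(config.grouping)
        sub = matrix.subset(geneset.genes)
        missing = len(geneset) - len(sub)
        if missing:
            manifest.warnings.append(
                f"stratify: {missing} geneset gene(s) absent from the expression matrix"
            )
        strat = stratify(sub, grouping, t=config.tpm_threshold)
        write_report(strat, out / "stratification.tsv")
        write_gene_list(strat.cns_specific.genes, out / "geneset_cns_specific.txt")
        write_gene_list(strat.cns_pt.genes, out / "geneset_cns_pt.txt")
        write_gene_list(strat.excluded.genes, out / "geneset_excluded_low.txt")
        binned = export_heatmap_matrix(sub, strat)
        binned.to_csv(out / "heatmap_bins.tsv", sep="\t")
        if strat.n_dropped_tissues:
            manifest.warnings.append(
                f"stratify: {strat.n_dropped_tissues} matrix tissue(s) not in the grouping"
            )
        manifest.stage_counts["stratify"] = {
            "n_genes": len(sub),
            "excluded_low": len(strat.excluded),
            "cns_specific": len(strat.cns_specific),
            "cns_pt": len(strat.cns_pt),
            "tpm_threshold": config.tpm_threshold,
        }
        combined = GeneSet(
            "asd_geneset_expressed", strat.cns_specific.genes | strat.cns_pt.genes
        )
        write_gene_list(combined.genes, out / "asd_geneset_expressed.txt")
        log.info(
            "stratified %d genes: %d excluded, %d CNS-specific, %d CNS+PT",
            len(sub), len(strat.excluded), len(strat.cns_specific), len(strat.cns_pt),
        )

    # universe for all overlap statistics
    if config.universe == "all_source_genes":
        universe_genes: set[str] = set()
        for t in tables:
            universe_genes |= set(t.scores)
        universe = GeneSet("all_source_genes", frozenset(universe_genes))
    else:
        universe = read_gene_list(config.universe, name="universe")
    manifest.stage_counts["universe"] = {"n_genes": len(universe)}

    # stage 5: over-representation per geneset
    if config.terms:
        terms = read_gmt(config.terms)
        queries = [combined]
        if strat is not None:
            queries = [strat.cns_specific, strat.cns_pt, combined]
        for q in queries:
            if not q.genes:
                manifest.warnings.append(f"ora: query {q.name} is empty; skipped")
                continue
            res = enrichment.ora(
                q, terms, universe, top_k=config.top_k, fdr_max=config.fdr_max
            )
            write_report(res, out / f"ora_{q.name}.tsv")
            manifest.stage_counts.setdefault("ora", {})[q.name] = {
                "n_terms_tested": res.n_terms_tested,
                "n_significant": len(res.significant),
            }

    # stage 6: DEG overlap tally
    if config.deg:
        studies = _load_deg_studies(config.deg)
        tally = enrichment.deg_overlap_tally(combined, studies)
        write_report(tally, out / "deg_overlap.tsv")
        manifest.stage_counts["deg_overlap"] = {
            "n_studies": len(studies),
            "n_query": tally.n_query,
            "dysregulated_at_least_once": tally.union_count,
        }
        log.info("DEG overlap: %d/%d genes dysregulated at least once",
                 tally.union_count, tally.n_query)

    # stage 7: pathway interconnectivity
    if config.pathways:
        pathways = read_gmt(config.pathways)
        matrix = interconnectivity.build_matrix(pathways, combined)
        matrix.to_frame().to_csv(out / "interaction_matrix.tsv", sep="\t", index=False)
        degrees = interconnectivity.connectivity_degree(matrix, min_shared=config.min_shared)
        with open(out / "pathway_degrees.tsv", "w") as fh:
            fh.write("pathway\tdegree\n")
            for p in matrix.pathways:
                fh.write(f"{p}\t{degrees[p]}\n")
        matrix.edge_list(config.min_shared).to_csv(out / "pathway_edges.tsv", sep="\t", index=False)
        hubs = interconnectivity.hub_genes(pathways, combined, top_n=max(1, len(combined)))
        write_report(hubs, out / "hub_genes.tsv")
        manifest.stage_counts["interconnectivity"] = {
            "n_pathways": len(pathways.names),
            "n_edges": int(matrix.edge_list(config.min_shared).shape[0]),
        }

    # stage 8: disease-overlap matrix
    if config.disease:
        disease = read_gmt(config.disease)
        lists = [combined]
        if strat is not None:
            lists = [strat.cns_specific, strat.cns_pt, combined]
        lists = [l for l in lists if l.genes] + list(disease)
        tests = []
        for i, a in enumerate(lists):
            for b in lists[i + 1:]:
                tests.append(enrichment.overlap_test(a, b, universe))
        from dataclasses import replace as _replace

        fdrs = enrichment.bh_fdr([t.p_value for t in tests])
        tests = [_replace(t, fdr=float(f)) for t, f in zip(tests, fdrs)]
        import pandas as pd

        pd.DataFrame(
            [t.row() for t in tests], columns=list(enrichment.OverlapTestResult.COLUMNS)
        ).to_csv(out / "disease_overlap.tsv", sep="\t", index=False, float_format="%.17g")
        manifest.stage_counts["disease_overlap"] = {
            "n_lists": len(lists),
            "n_tests": len(tests),
            "n_significant": sum(1 for t in tests if t.fdr <= config.fdr_max),
        }

    manifest.check_consistency()
    manifest.to_json(out / "manifest.json")
    return manifest
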