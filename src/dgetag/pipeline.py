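"""End-to-end trio pipeline: reads -> tags -> expression -> calls -> reports.

Stages follow the assay protocol: clean raw reads into tags, build the
virtual CATG+17 library from the reference, map with at most one mismatch,
normalize to TPM, test the pairwise and midparent contrasts, classify gene
action, summarize presence/absence patterns, cross-reference a PAV list, and
run term enrichment. Every stage logs its tag accounting to stderr; all
outputs are TSV files reproducible from (config, seed).
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import pandas as pd

from . import io as dio
from . import simulate as sim
from .de import call_differential
from .enrichment import enrich, read_annotation
from .gene_action import classify_trio, gene_action_percentages, summarize_gene_action
from .io import PipelineConfig
from .presence import classify_presence, pav_crossref, pav_summary, presence_summary
from .tags import (
    ExpressionTable,
    build_virtual_library,
    extract_clean_tags,
    map_tags,
    strand_report,
)

log = logging.getLogger("dgetag")

GENOTYPES = ("P", "M", "F1")


def _setup_logging() -> None:
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)


def _simulate_inputs(config: PipelineConfig, outdir: Path) -> dict:
    block = dict(config.simulation)
    n_genes = int(block.get("n_genes", 500))
    depth = int(block.get("depth", 100_000))
    genes = sim.simulate_transcriptome(
        n_genes,
        length_range=tuple(block.get("length_range", (300, 3000))),
        gc=float(block.get("gc", 0.45)),
        frac_no_catg=float(block.get("frac_no_catg", 0.0)),
        seed=config.seed,
    )
    truth = sim.assign_gene_action_profiles(
        genes,
        mode_proportions=block.get("mode_proportions"),
        tpm_range=tuple(block.get("tpm_range", (20.0, 2000.0))),
        fold_effect=float(block.get("fold_effect", 4.0)),
        seed=config.seed + 1,
    )
    read_paths = {}
    for i, genotype in enumerate(GENOTYPES):
        reads, _counts = sim.simulate_library(
            truth,
            genes,
            genotype,
            depth=depth,
            error_rate=float(block.get("error_rate", 0.01)),
            antisense_fraction=float(block.get("antisense_fraction", 0.05)),
            seed=config.seed + 10 + i,
            adaptor=config.adaptor3,
        )
        path = outdir / f"reads_{genotype}.fastq"
        dio.write_fastq(reads, path)
        read_paths[genotype] = str(path)
        log.info("simulated %d reads for %s", len(reads), genotype)
    fasta = outdir / "reference.fasta"
    gmap = outdir / "gene_map.tsv"
    dio.write_fasta(genes, fasta)
    dio.write_gene_map(genes, gmap)
    dio.write_tsv(truth, outdir / "simulation_truth.tsv")
    return {"reference_fasta": str(fasta), "gene_map": str(gmap), "reads": read_paths}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full trio analysis; returns the result bundle in memory.

    Writes per-stage TSVs under ``outdir``: cleaning and mapping summaries,
    the expression table, per-contrast differential calls, gene-action calls
    plus summary, presence classes plus summary, the PAV report and any
    enrichment tables, and a JSON run log of seeds, thresholds and counts.
    """
    _setup_logging()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        paths = _simulate_inputs(config, outdir)
    else:
        paths = {
            "reference_fasta": config.reference_fasta,
            "gene_map": config.gene_map,
            "reads": dict(config.reads),
        }

    gene_map = dio.read_gene_map(paths["gene_map"])
    transcripts = dio.read_fasta(paths["reference_fasta"])
    library = build_virtual_library(transcripts, gene_map)
    gene_ids = sorted(set(gene_map.values()))
    log.info("virtual library: %d distinct CATG+17 keys, %d genes", len(library), len(gene_ids))

    mappings = {}
    cleaning_rows = []
    for genotype in GENOTYPES:
        clean = extract_clean_tags(dio.read_reads(paths["reads"][genotype]), config.adaptor3)
        mapping = map_tags(clean, library, max_mismatch=config.max_mismatch)
        mappings[genotype] = mapping
        s = mapping.summary
        assert (
            s["unambiguous_total"] + s["ambiguous_total"] + s["unknown_total"]
            == s["clean_total"]
        ), "tag partition identity violated"
        cleaning_rows.append({"library": genotype, **clean.report, **s})
        log.info(
            "%s: %d clean tags (%d distinct); unambiguous %d, ambiguous %d, unknown %d",
            genotype,
            s["clean_total"],
            s["distinct"],
            s["unambiguous_total"],
            s["ambiguous_total"],
            s["unknown_total"],
        )
    mapping_summary = pd.DataFrame(cleaning_rows)
    dio.write_tsv(mapping_summary, outdir / "mapping_summary.tsv")

    table = ExpressionTable.from_mappings(mappings, gene_ids)
    table.to_tsv(outdir / "expression_table.tsv")
    strands = strand_report(mappings)
    log.info("strand report: %s", strands)

    pairwise = {}
    for contrast in ("F1-vs-P", "F1-vs-M", "P-vs-M"):
        calls = call_differential(
            table,
            contrast,
            fdr_threshold=config.fdr_threshold,
            lfc_threshold=config.lfc_threshold,
            pseudo_tags=config.pseudo_tags,
        )
        pairwise[contrast] = calls
        dio.write_tsv(calls, outdir / f"de_{contrast.replace('-vs-', '_vs_')}.tsv")
        log.info(
            "%s: %d tested, %d significant", contrast, len(calls), int(calls["significant"].sum())
        )

    action = classify_trio(
        table,
        fdr_threshold=config.fdr_threshold,
        lfc_threshold=config.lfc_threshold,
        midparent_lfc_threshold=config.midparent_lfc_threshold,
        pseudo_tags=config.pseudo_tags,
        pairwise_calls=pairwise,
    )
    dio.write_tsv(action, outdir / "gene_action.tsv")
    action_summary = summarize_gene_action(action)
    action_pct = gene_action_percentages(action_summary)
    dio.write_tsv(
        pd.DataFrame([{**action_summary, **action_pct}]), outdir / "gene_action_summary.tsv"
    )
    log.info("gene action: %s", action_summary)

    presence = classify_presence(table, min_count=config.presence_min_count)
    dio.write_tsv(presence.reset_index(), outdir / "presence_classes.tsv")
    n_expressed = len(table.expressed_collectively(config.presence_min_count))
    psummary = presence_summary(presence, n_expressed=n_expressed)
    psummary["grid"].to_csv(outdir / "presence_summary.tsv", sep="\t")
    log.info("presence/absence universe: %d of %d expressed genes", psummary["total"], n_expressed)

    results = {
        "expression_table": table,
        "mapping_summary": mapping_summary,
        "strand_report": strands,
        "differential": pairwise,
        "gene_action": action,
        "gene_action_summary": {**action_summary, **action_pct},
        "presence": presence,
        "presence_summary": psummary,
        "n_expressed_collectively": n_expressed,
        "n_expressed_in_all": len(table.expressed_in_all(config.presence_min_count)),
    }

    if config.pav_list:
        pav_list = dio.read_tsv(config.pav_list)
        report = pav_crossref(presence, table, pav_list, gene_action_calls=action)
        dio.write_tsv(report, outdir / "pav_report.tsv")
        results["pav_report"] = report
        results["pav_summary"] = pav_summary(report)
        log.info("PAV report: %s", results["pav_summary"])

    universe = sorted(table.expressed_collectively(config.presence_min_count))
    de_sets = {
        "F1_vs_P": set(pairwise["F1-vs-P"].loc[pairwise["F1-vs-P"]["significant"], "gene_id"]),
        "F1_vs_M": set(pairwise["F1-vs-M"].loc[pairwise["F1-vs-M"]["significant"], "gene_id"]),
    }
    de_sets["union"] = de_sets["F1_vs_P"] | de_sets["F1_vs_M"]
    for kind, path, method in (
        ("go", config.go_annotation, "BH"),
        ("pathway", config.pathway_annotation, "storey"),
    ):
        if not path:
            continue
        annotation = read_annotation(path)
        for set_name, genes in de_sets.items():
            if not genes:
                continue
            res = enrich(
                genes, annotation, universe, method=method, lambda_=config.enrichment_lambda
            )
            dio.write_tsv(res, outdir / f"enrichment_{kind}_{set_name}.tsv")
            results[f"enrichment_{kind}_{set_name}"] = res
        log.info("%s enrichment written for %d gene sets", kind, len(de_sets))

    run_log = {
        "seed": config.seed,
        "fdr_threshold": config.fdr_threshold,
        "lfc_threshold": config.lfc_threshold,
        "midparent_lfc_threshold": config.midparent_lfc_threshold,
        "presence_min_count": config.presence_min_count,
        "max_mismatch": config.max_mismatch,
        "pseudo_tags": config.pseudo_tags,
        "enrichment_lambda": config.enrichment_lambda,
        "n_genes": len(gene_ids),
        "n_expressed_collectively": n_expressed,
        "gene_action_summary": action_summary,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return results
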