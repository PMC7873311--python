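"""End-to-end orchestration: run every stage on a data directory, write
all stage TSVs plus a run manifest with content digests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from epimemory import covariates as covariates_mod
from epimemory import ewas as ewas_mod
from epimemory import genesets as genesets_mod
from epimemory import integration as integration_mod
from epimemory import memory_chromatin as memory_mod
from epimemory import preprocess as preprocess_mod
from epimemory.datamodel import (
    CELL_TYPES,
    PipelineConfig,
    read_beta_matrix,
    read_expr_manifest,
    read_expression_matrix,
    read_gmt,
    read_manifest,
    read_sample_sheet,
    write_table,
)

logger = logging.getLogger("epimemory.pipeline")


def select_reference_cpgs(reference: pd.DataFrame, n: int = 200) -> pd.DataFrame:
    """Reference rows with the largest between-cell-type spread (the most
    discriminating CpGs), for use in deconvolution."""
    spread = reference.to_numpy().std(axis=1)
    order = np.argsort(-spread, kind="stable")[:n]
    return reference.iloc[np.sort(order)]


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    datadir: str | Path,
    outdir: str | Path,
    gmt_path: str | Path | None = None,
) -> dict:
    """Execute all stages in order; returns the run manifest dict.

    Expects in ``datadir``: sample_sheet.csv, beta_cord.tsv,
    beta_postnatal.tsv, expression.tsv, cpg_manifest.tsv,
    expr_manifest.tsv, reference_profiles.tsv (as written by
    ``synthdata.write_dataset``).
    """
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # fail-fast: load and validate every input before any fit
    sheet = read_sample_sheet(datadir / "sample_sheet.csv")
    cord = read_beta_matrix(datadir / "beta_cord.tsv")
    post = read_beta_matrix(datadir / "beta_postnatal.tsv")
    expr = read_expression_matrix(datadir / "expression.tsv")
    manifest = read_manifest(datadir / "cpg_manifest.tsv")
    expr_manifest = read_expr_manifest(datadir / "expr_manifest.tsv")
    reference = pd.read_csv(datadir / "reference_profiles.tsv", sep="\t",
                            index_col="probe_id")
    reference = reference.loc[:, list(CELL_TYPES)]
    gmt = read_gmt(gmt_path) if gmt_path else None

    stages: list[dict] = []
    counts: dict[str, int] = {}

    def emit(name: str, frame: pd.DataFrame) -> Path:
        path = outdir / f"{name}.tsv"
        write_table(frame, path)
        stages.append({"stage": name, "output": path.name, "sha256": _digest(path)})
        logger.info("stage %s -> %s (%d rows)", name, path.name, len(frame))
        return path

    # 1. covariate screen
    for outcome in ("GA", "SDscore"):
        emit(f"covariates_{outcome}", covariates_mod.covariate_screen(sheet, outcome))

    # 2. cell fractions (cord + postnatal), estimated from reference CpGs
    ref = select_reference_cpgs(reference)
    frac_cord = preprocess_mod.estimate_cell_fractions(cord.loc[ref.index], ref)
    frac_post = preprocess_mod.estimate_cell_fractions(post.loc[ref.index], ref)
    fractions = pd.concat([frac_cord, frac_post], ignore_index=True)
    emit("cell_fractions", fractions)

    # 3. dual-model EWAS + consensus + sensitivity
    r1 = ewas_mod.fit_ewas(cord, sheet, fractions, ewas_mod.model1_spec(), config)
    r2 = ewas_mod.fit_ewas(cord, sheet, fractions, ewas_mod.model2_spec(), config)
    emit("ewas_model1", r1)
    emit("ewas_model2", r2)
    consensus = ewas_mod.intersect_models(r1, r2, config.fdr_alpha)
    emit("consensus_ga", consensus.ga_related)
    emit("consensus_sd", consensus.sd_related)
    counts["ga_related_cpgs"] = len(consensus.ga_related)
    counts["sd_related_cpgs"] = len(consensus.sd_related)
    emit("sensitivity_overlap",
         ewas_mod.sensitivity_overlap(cord, sheet, fractions, consensus,
                                      config=config))

    # 4. island-relation enrichment
    ga_set = consensus.ga_related["probe_id"]
    if len(ga_set):
        emit("island_enrichment_ga",
             ewas_mod.enrich_island_relation(ga_set, manifest))

    # 5. gene lists (+ optional GMT enrichment)
    lists = genesets_mod.build_gene_lists(consensus, manifest,
                                          config.min_cpgs_per_gene)
    for cat, frame in lists.items():
        emit(f"gene_list_{cat}", frame)
    if gmt is not None:
        universe = set(manifest.loc[manifest["gene"] != "", "gene"])
        for cat, frame in lists.items():
            if len(frame):
                emit(f"gene_enrichment_{cat}",
                     genesets_mod.hypergeom_enrich(
                         set(frame["gene"]) & universe, gmt, universe,
                         config.enrichment_fdr))

    # 6. cis matching, transcript association, meth-expr correlation
    all_cpgs = pd.concat([consensus.ga_related, consensus.sd_related])["probe_id"]
    pairs = integration_mod.match_cis_pairs(all_cpgs, manifest, expr_manifest,
                                            config.cis_window_bp)
    emit("cis_pairs", pairs)
    counts["cis_pairs"] = len(pairs)
    matched = [p for p in pairs["expr_probe_id"].unique() if p in expr.index]
    assoc = integration_mod.fit_transcript_assoc(expr, sheet, fractions,
                                                 matched, config)
    emit("transcript_assoc", assoc)
    ga_transcripts = set(assoc.loc[assoc["q_ga"] < config.fdr_alpha,
                                   "expr_probe_id"])
    counts["ga_related_transcripts"] = len(ga_transcripts)
    sub_pairs = pairs[pairs["expr_probe_id"].isin(ga_transcripts)
                      & pairs["cpg_id"].isin(set(consensus.ga_related["probe_id"]))]
    methexpr = integration_mod.correlate_meth_expr(sub_pairs, cord, expr, manifest)
    emit("meth_expr_corr", methexpr)
    counts["meth_expr_combinations"] = int((methexpr["p"] < config.nominal_alpha).sum()) \
        if len(methexpr) else 0

    # 7. memory scoring and downstream characterization
    ga_ids = [c for c in consensus.ga_related["probe_id"]
              if c in cord.index and c in post.index]
    if len(ga_ids) >= 10:
        memory = memory_mod.cord_post_correlation(
            cord, post, sheet, ga_ids, config.memory_r_threshold)
        emit("memory_records", memory)
        counts["memory_candidates"] = int(memory["is_candidate"].sum())
        emit("interval_check", pd.DataFrame(
            [memory_mod.interval_check(cord, post, sheet, ga_ids)]))
        candidates = memory.loc[memory["is_candidate"], "cpg_id"]
        if len(candidates):
            emit("memory_state_distribution",
                 memory_mod.state_distribution(candidates, manifest, "T"))
            emit("memory_state_enrichment",
                 memory_mod.state_enrichment(
                     candidates, manifest, annotation="T",
                     alpha=config.nominal_alpha, family=config.bonferroni_family))
        emit("decile_trend", memory_mod.decile_trend(
            memory, manifest, ("ReprPC", "PromBiv")))
        overlap, ranked = memory_mod.overlap_and_rank(
            memory, methexpr, manifest, config.nominal_alpha)
        emit("overlap_genes_ranked", ranked)
        write_table(pd.DataFrame({"cpg_id": overlap}), outdir / "overlap_cpgs.tsv")
        stages.append({"stage": "overlap_cpgs", "output": "overlap_cpgs.tsv",
                       "sha256": _digest(outdir / "overlap_cpgs.tsv")})
        counts["overlap_cpgs"] = len(overlap)

    run_manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.rng_seed,
        "stages": stages,
        "counts": counts,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2)
    return run_manifest
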