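"""End-to-end orchestration: simulate -> affinity -> expression -> regulators
-> peak annotation -> methylation, with per-stage caching and a run manifest.

Every stage reads its inputs from and writes its outputs to ``outdir``, so
deleting one stage's outputs and re-running regenerates only that stage
and its dependents.  The manifest records the config snapshot, seed,
output digests, stage timings and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import fields
from pathlib import Path

import pandas as pd

from . import __version__, affinity, expression, io, methylation, peaks, regulators
from .errors import ConfigurationError
from .synthetic import GroundTruth, SyntheticConfig, generate_all

logger = logging.getLogger(__name__)

STAGE_OUTPUTS = {
    "simulate": ["genome.fa", "genes.bed", "peaks.tsv", "pfms.txt", "fpm.tsv",
                 "de.tsv", "clusters.tsv", "rrbs.tsv", "snupe.tsv", "ground_truth.json"],
    "affinity": ["A_LDC.tsv", "A_Co.tsv", "quotient.tsv"],
    "expression": ["degs.tsv"],
    "regulators": ["coefficients.tsv", "ranked_tfs.tsv", "Q.tsv", "E.tsv",
                   "regression_summary.json"],
    "annotate": ["peaks_annotated.tsv", "context_summary.tsv"],
    "methylation": ["dm_age.tsv", "dm_diet.tsv", "aging_loci.txt", "concordance.tsv"],
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _complete(outdir: Path, stage: str) -> bool:
    return all((outdir / f).exists() for f in STAGE_OUTPUTS[stage])


def make_synthetic_config(config: dict, seed: int | None = None) -> SyntheticConfig:
    known = {f.name for f in fields(SyntheticConfig)}
    params = {k: v for k, v in config.get("synthetic", {}).items() if k in known}
    if seed is not None:
        params["seed"] = seed
    return SyntheticConfig(**params)


def _stage_simulate(config: dict, outdir: Path, seed: int | None) -> None:
    cfg = make_synthetic_config(config, seed)
    data = generate_all(cfg)
    io.write_fasta(data["genome"], outdir / "genome.fa")
    io.genes_to_bed(data["genes"], outdir / "genes.bed")
    io.write_table(data["peaks"], outdir / "peaks.tsv")
    io.write_pfm(data["pwms"], outdir / "pfms.txt", counts=data["pwm_counts"])
    io.write_table(data["fpm"].reset_index(), outdir / "fpm.tsv")
    io.write_table(data["de"], outdir / "de.tsv")
    io.write_table(data["clusters"], outdir / "clusters.tsv")
    io.write_table(data["rrbs"], outdir / "rrbs.tsv")
    io.write_table(data["snupe"], outdir / "snupe.tsv")
    data["truth"].to_json(outdir / "ground_truth.json")


def _stage_affinity(config: dict, outdir: Path) -> None:
    acfg = config.get("affinity", {})
    window = acfg.get("window", 50_000)
    genes = io.genes_from_bed(outdir / "genes.bed")
    peak_df = io.read_table(outdir / "peaks.tsv", schema=["chrom", "start", "end", "logFC"])
    if "sequence" not in peak_df.columns:
        peak_df = io.attach_sequences(peak_df, io.read_fasta(outdir / "genome.fa"))
    pwms = io.read_pfm(outdir / "pfms.txt")
    de = io.read_table(outdir / "de.tsv", schema=["gene", "baseMean"])
    pwms = affinity.filter_expressed_tfs(pwms, de, acfg.get("min_base_mean", 10.0))
    up, down, _ = peaks.split_by_sign(peak_df)
    a_ldc = affinity.gene_scores(up, genes, pwms, window=window, condition="LDC",
                                 anchor=acfg.get("anchor", "tss"))
    a_co = affinity.gene_scores(down, genes, pwms, window=window, condition="Co",
                                anchor=acfg.get("anchor", "tss"))
    quotient = affinity.affinity_quotient(a_ldc, a_co, eps=acfg.get("pseudocount", 1e-6))
    io.write_matrix(a_ldc.matrix, outdir / "A_LDC.tsv")
    io.write_matrix(a_co.matrix, outdir / "A_Co.tsv")
    io.write_matrix(quotient.matrix, outdir / "quotient.tsv")


def _stage_expression(config: dict, outdir: Path) -> None:
    ecfg = config.get("expression", {})
    fpm = io.read_table(outdir / "fpm.tsv").set_index("gene")
    de = io.read_table(outdir / "de.tsv", schema=["gene", "log2FC", "padj"])
    retained = expression.fpm_filter(fpm, ecfg.get("min_fpm", 0.1), ecfg.get("min_samples", 4))
    sel = expression.select_degs(de, alpha=ecfg.get("alpha", 0.05), retained=retained)
    rows = ([(g, "up") for g in sel.up] + [(g, "down") for g in sel.down]
            + [(g, "zero") for g in sel.zero_lfc])
    io.write_table(pd.DataFrame(rows, columns=["gene", "direction"]), outdir / "degs.tsv")


def _stage_regulators(config: dict, outdir: Path, seed: int | None) -> None:
    rcfg = config.get("regulators", {})
    quotient = io.read_matrix(outdir / "quotient.tsv")
    degs = io.read_table(outdir / "degs.tsv", schema=["gene", "direction"])
    degs = degs[degs["direction"].isin(["up", "down"])]
    labels = degs.set_index("gene")["direction"]
    labels = labels[labels.index.isin(quotient.columns)]
    result = regulators.fit_dynamite(
        quotient, labels,
        ofolds=rcfg.get("ofolds", 10), ifolds=rcfg.get("ifolds", 6),
        alpha=rcfg.get("alpha", 0.01), seed=seed if seed is not None else 0,
    )
    ranked = regulators.rank_tfs(result, threshold=rcfg.get("threshold", 0.125))
    clusters = io.read_table(outdir / "clusters.tsv", schema=["gene", "cluster"])
    cl = clusters.set_index("gene")["cluster"]
    cl = cl[cl.index.isin(labels.index)]
    q = regulators.median_quotient(quotient, cl)
    e = regulators.effect_score(q, others_divisor=rcfg.get("others_divisor", "k-1"))
    io.write_table(result.coefficients.rename("coefficient").reset_index()
                   .rename(columns={"index": "tf"}), outdir / "coefficients.tsv")
    io.write_table(ranked.ranking.reset_index().assign(
        selected=lambda d: d["normalized_abs_coefficient"] >= ranked.threshold),
        outdir / "ranked_tfs.tsv")
    io.write_matrix(q, outdir / "Q.tsv")
    io.write_matrix(e, outdir / "E.tsv")
    with open(outdir / "regression_summary.json", "w") as fh:
        json.dump({"fold_accuracies": result.fold_accuracies,
                   "mean_accuracy": result.mean_accuracy,
                   "settings": result.settings}, fh, indent=1)


def _stage_annotate(config: dict, outdir: Path) -> None:
    pcfg = config.get("peak_annotation", {})
    genes = io.genes_from_bed(outdir / "genes.bed")
    peak_df = io.read_table(outdir / "peaks.tsv", schema=["chrom", "start", "end", "logFC"])
    up, down, _ = peaks.split_by_sign(peak_df)
    up, down = up.assign(sign="up"), down.assign(sign="down")
    labeled = peaks.annotate_context(
        pd.concat([up, down], ignore_index=True), genes,
        promoter_up=pcfg.get("promoter_up", 1000),
        promoter_down=pcfg.get("promoter_down", 500))
    summary = peaks.context_summary(labeled)
    drop = [c for c in labeled.columns if c == "sequence"]
    io.write_table(labeled.drop(columns=drop), outdir / "peaks_annotated.tsv")
    io.write_matrix(summary, outdir / "context_summary.tsv", index_name="sign")


def _stage_methylation(config: dict, outdir: Path) -> None:
    mcfg = config.get("methylation", {})
    rrbs = io.read_table(outdir / "rrbs.tsv", schema=methylation.RRBS_SCHEMA)
    kw = dict(min_cov=mcfg.get("min_cov", 5), min_diff=mcfg.get("min_diff", 0.05),
              max_var=mcfg.get("max_var", 0.05), alpha=mcfg.get("alpha", 0.05))
    dm_age = methylation.differential_cpgs(rrbs, "young", "aged", **kw)
    dm_diet = methylation.differential_cpgs(rrbs, "Co", "LDC", **kw)
    aging = methylation.select_aging_loci(
        dm_age, min_abs_diff=mcfg.get("aging_min_abs_diff", 0.30),
        fdr=mcfg.get("aging_fdr", 0.1))
    conc = methylation.concordance(dm_age, dm_diet,
                                   alpha=mcfg.get("concordance_alpha", 0.05))
    io.write_table(dm_age.reset_index(), outdir / "dm_age.tsv")
    io.write_table(dm_diet.reset_index(), outdir / "dm_diet.tsv")
    (outdir / "aging_loci.txt").write_text("".join(f"{s}\n" for s in aging))
    io.write_table(conc.reset_index(), outdir / "concordance.tsv")


def run_all(config: dict, outdir: str | Path, seed: int | None = None,
            force: bool = False) -> dict:
    """Run all stages in dependency order; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synthetic_mode = config.get("synthetic_mode", True)
    if not synthetic_mode:
        missing = [f for f in STAGE_OUTPUTS["simulate"] if not (outdir / f).exists()]
        if missing:
            raise ConfigurationError(
                f"non-synthetic mode: missing required inputs {missing}"
            )

    stage_fns = {
        "simulate": lambda: _stage_simulate(config, outdir, seed),
        "affinity": lambda: _stage_affinity(config, outdir),
        "expression": lambda: _stage_expression(config, outdir),
        "regulators": lambda: _stage_regulators(config, outdir, seed),
        "annotate": lambda: _stage_annotate(config, outdir),
        "methylation": lambda: _stage_methylation(config, outdir),
    }
    timings = {}
    for stage, fn in stage_fns.items():
        if stage == "simulate" and not synthetic_mode:
            continue
        if not force and _complete(outdir, stage):
            logger.info("stage %s: outputs present, skipping", stage)
            continue
        t0 = time.perf_counter()
        fn()
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s finished in %.2fs", stage, timings[stage])

    digests = {f: _digest(outdir / f) for outs in STAGE_OUTPUTS.values()
               for f in outs if (outdir / f).exists()}
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stage_timings": timings,
        "output_digests": digests,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
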