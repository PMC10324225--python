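"""Differential peak handling: sign split, genomic-context annotation and
domain-to-gene assignment.

Context labels use the precedence promoter > gene body > intergenic so the
three-way percentages always partition.  The promoter is a strand-oriented
window around the TSS (default 1000 bp upstream, 500 bp downstream).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

CONTEXTS = ["promoter", "gene_body", "intergenic"]


def split_by_sign(peaks: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Partition peaks by sign of logFC; returns (up, down, zero count).

    logFC > 0 is "up" (more accessible in the treatment condition),
    logFC < 0 is "down"; exact zeros are excluded and counted.
    """
    if "logFC" not in peaks.columns:
        raise ValidationError("peak table missing 'logFC' column")
    lfc = peaks["logFC"]
    if lfc.isna().any() or np.isinf(lfc).any():
        bad = peaks.index[lfc.isna() | np.isinf(lfc)].tolist()
        raise ValidationError(f"non-finite logFC for peaks {bad[:10]}")
    up = peaks[lfc > 0].copy()
    down = peaks[lfc < 0].copy()
    n_zero = int((lfc == 0).sum())
    logger.info("split_by_sign: %d up, %d down, %d zero of %d peaks",
                len(up), len(down), n_zero, len(peaks))
    return up, down, n_zero


def promoter_intervals(genes: pd.DataFrame, promoter_up: int = 1000,
                       promoter_down: int = 500) -> pd.DataFrame:
    """Strand-oriented promoter windows as half-open intervals.

    A position p is in the promoter iff its signed distance from the TSS
    (downstream positive) satisfies -promoter_up <= d < promoter_down.
    """
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["tss"] - promoter_up, genes["tss"] - promoter_down + 1)
    end = np.where(plus, genes["tss"] + promoter_down, genes["tss"] + promoter_up + 1)
    return pd.DataFrame({
        "chrom": genes["chrom"].to_numpy(),
        "start": np.maximum(start, 0),
        "end": end,
        "gene_id": genes["gene_id"].to_numpy(),
    })


def _overlaps_any(peaks: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean vector: does each peak overlap any interval (same chrom)?"""
    out = np.zeros(len(peaks), dtype=bool)
    by_chrom = {c: g for c, g in intervals.groupby("chrom")}
    for i, (chrom, start, end) in enumerate(zip(peaks["chrom"], peaks["start"], peaks["end"])):
        ivs = by_chrom.get(chrom)
        if ivs is None:
            continue
        out[i] = bool(((ivs["start"] < end) & (ivs["end"] > start)).any())
    return out


def annotate_context(peaks: pd.DataFrame, genes: pd.DataFrame,
                     promoter_up: int = 1000, promoter_down: int = 500) -> pd.DataFrame:
    """Label each peak promoter / gene_body / intergenic (that precedence)."""
    proms = promoter_intervals(genes, promoter_up, promoter_down)
    bodies = genes[["chrom", "start", "end"]]
    in_prom = _overlaps_any(peaks, proms)
    in_body = _overlaps_any(peaks, bodies)
    labels = np.where(in_prom, "promoter", np.where(in_body, "gene_body", "intergenic"))
    out = peaks.copy()
    out["context"] = labels
    return out


def context_summary(labeled_peaks: pd.DataFrame, sign_col: str = "sign") -> pd.DataFrame:
    """Percent of peaks per context for each sign class; rows sum to 100."""
    if sign_col not in labeled_peaks.columns:
        raise ValidationError(f"missing {sign_col!r} column")
    counts = (labeled_peaks.groupby([sign_col, "context"]).size()
              .unstack("context").reindex(columns=CONTEXTS).fillna(0))
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct


def _interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Distance between two half-open intervals; 0 iff they overlap.

    Adjacent intervals are 1 apart (bedtools-closest convention), so zero
    unambiguously means overlap.
    """
    if a_start < b_end and b_start < a_end:
        return 0
    return b_start - a_end + 1 if b_start >= a_end else a_start - b_end + 1


def domains_to_genes(domains: pd.DataFrame, genes: pd.DataFrame,
                     window: int = 50_000) -> pd.DataFrame:
    """Assign each domain its single closest gene within ``window`` bp.

    Distance is the minimal gap between the two intervals (0 on overlap).
    Ties are broken by smaller distance to the gene's TSS, then by
    lexicographic gene id.  Domains with no gene within the window are
    omitted from the result.
    """
    rows = []
    gene_by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for dom in domains.itertuples(index=False):
        cand = gene_by_chrom.get(dom.chrom)
        if cand is None:
            continue
        best = None
        for gene in cand.itertuples(index=False):
            dist = _interval_distance(dom.start, dom.end, gene.start, gene.end)
            if dist > window:
                continue
            mid = (dom.start + dom.end) / 2
            tss_dist = abs(mid - gene.tss)
            key = (dist, tss_dist, gene.gene_id)
            if best is None or key < best[0]:
                best = (key, gene.gene_id, dist)
        if best is not None:
            rows.append((dom.chrom, dom.start, dom.end, getattr(dom, "name", "."),
                         best[1], best[2]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "gene_id", "distance"])
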