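"""Expression-side filters and the k-cluster gene partition.

The filter chain is: drop genes with too few samples expressed
(FPM strictly above 0.1 in at least 4 samples), call differential genes
at adjusted p <= 0.05, label direction by the sign of log2FC, then
partition the differential genes into k clusters (k-means, default k=4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ConfigurationError, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class DEGSelection:
    """Up/down differential gene lists plus zero-logFC flagged genes."""

    up: list[str]
    down: list[str]
    zero_lfc: list[str]

    @property
    def genes(self) -> list[str]:
        return self.up + self.down


def fpm_filter(fpm: pd.DataFrame, min_fpm: float = 0.1, min_samples: int = 4) -> pd.Index:
    """Retain genes with FPM strictly above ``min_fpm`` in >= ``min_samples`` samples.

    ``fpm`` is genes x samples.  The comparison is strict: a value equal to
    ``min_fpm`` does not count as expressed.
    """
    if fpm.shape[1] < min_samples:
        raise ConfigurationError(
            f"need at least {min_samples} samples, got {fpm.shape[1]}"
        )
    n_above = (fpm > min_fpm).sum(axis=1)
    retained = fpm.index[n_above >= min_samples]
    logger.info("fpm_filter: %d of %d genes retained", len(retained), len(fpm))
    return retained


def select_degs(de_table: pd.DataFrame, alpha: float = 0.05,
                retained: pd.Index | None = None) -> DEGSelection:
    """Split differential genes into up/down lists by sign of log2FC.

    A gene is differential iff its adjusted p-value <= ``alpha`` ("maximal
    adjusted p-value" read as an attained upper bound).  Genes with
    log2FC == 0 and a passing p-value are flagged but carry no direction.
    """
    for col in ("gene", "log2FC", "padj"):
        if col not in de_table.columns:
            raise SchemaError(f"DE table missing column {col!r}")
    df = de_table
    if retained is not None:
        df = df[df["gene"].isin(retained)]
    sig = df[df["padj"] <= alpha]
    up = sorted(sig.loc[sig["log2FC"] > 0, "gene"])
    down = sorted(sig.loc[sig["log2FC"] < 0, "gene"])
    zero = sorted(sig.loc[sig["log2FC"] == 0, "gene"])
    if zero:
        logger.warning("select_degs: %d significant genes with log2FC == 0 flagged", len(zero))
    logger.info("select_degs: %d up, %d down of %d tested", len(up), len(down), len(df))
    return DEGSelection(up=up, down=down, zero_lfc=zero)


def cluster_genes(features: pd.DataFrame, k: int = 4, seed: int = 0,
                  n_restarts: int = 10, standardize: bool = True) -> pd.Series:
    """k-means partition of genes (rows of ``features``) into clusters 1..k.

    Rows are sorted by gene id before fitting so the result is invariant
    to input row order under a fixed seed.  Default features are per-sample
    expression, standardized per column; any externally built feature
    matrix (e.g. a network embedding) is accepted unchanged with
    ``standardize=False``.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > len(features):
        raise ConfigurationError(f"k={k} exceeds number of genes {len(features)}")
    feats = features.sort_index()
    x = feats.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, max_iter=300, tol=1e-6,
                random_state=seed)
    labels = km.fit_predict(x)
    # relabel clusters by order of first appearance for a stable 1..k coding
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    assignment = pd.Series([remap[lab] for lab in labels], index=feats.index, name="cluster")
    return assignment.reindex(features.index)
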