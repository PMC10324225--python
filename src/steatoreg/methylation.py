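"""DNA-methylation arm: chromatogram methylation index, differential-CpG
filter chain, aging-locus selection, and aging-vs-diet concordance.

The per-site test is a two-sided Welch t-test on arcsine-square-root
transformed methylation fractions (a stand-in for a moderated linear
model, which is not sensible at n = 2-4 per group; the filter thresholds,
which drive the outcome, are applied exactly).  Benjamini-Hochberg FDR is
implemented here rather than imported so it can be checked against an
independent oracle.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCallError, ValidationError

logger = logging.getLogger(__name__)

RRBS_SCHEMA = ["site", "sample", "group", "meth_reads", "total_reads"]
CONCORDANCE_CLASSES = ["concordant", "discordant", "age_only", "diet_only", "neither"]


def clock_loci() -> pd.DataFrame:
    """The bundled panel of age-associated CpG loci (BED6, mm10)."""
    from importlib.resources import files

    from .io import read_bed

    return read_bed(files("steatoreg.data").joinpath("clock_loci.bed"))


# ---------------------------------------------------------------------------
# chromatogram index
# ---------------------------------------------------------------------------

def methylation_index(h_m: float, h_um: float) -> float:
    """Methylated-peak height fraction h(M) / (h(M) + h(UM))."""
    if h_m < 0 or h_um < 0:
        raise ValidationError("peak heights must be non-negative")
    total = h_m + h_um
    if total == 0:
        raise UndefinedCallError("both peak heights are zero; call undefined")
    return h_m / total


def normalize_index(values: np.ndarray | pd.Series) -> np.ndarray:
    """Affinely rescale a locus panel's index values onto [0, 100]."""
    arr = np.asarray(values, dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        logger.warning("normalize_index: constant input, mapping all values to 0")
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo) * 100.0


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# per-site table machinery
# ---------------------------------------------------------------------------

def _beta_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long RRBS table -> per-site per-sample rows with beta and coverage."""
    missing = [c for c in RRBS_SCHEMA if c not in table.columns]
    if missing:
        raise ValidationError(f"RRBS table missing columns {missing}")
    df = table.copy()
    if (df["meth_reads"] > df["total_reads"]).any():
        raise ValidationError("meth_reads exceeds total_reads")
    with np.errstate(invalid="ignore"):
        df["beta"] = df["meth_reads"] / df["total_reads"]
    return df


def coverage_mask(table: pd.DataFrame, min_reads: int = 3) -> list:
    """Sites to exclude: any required sample has coverage below ``min_reads``."""
    df = _beta_table(table)
    low = df.groupby("site")["total_reads"].min() < min_reads
    excluded = sorted(low.index[low])
    if excluded:
        logger.info("coverage_mask: %d sites below %d reads", len(excluded), min_reads)
    return excluded


def site_statistics(table: pd.DataFrame, group_a: str, group_b: str) -> pd.DataFrame:
    """Per-site group means/variances, delta-beta (b - a) and Welch-t p-value.

    The test is on arcsine-sqrt transformed betas; groups need >= 2 samples.
    """
    df = _beta_table(table)
    df = df[df["group"].isin([group_a, group_b])]
    n_per = df.groupby(["site", "group"])["sample"].nunique().unstack("group")
    if n_per.isna().any().any() or (n_per < 2).any().any():
        raise ValidationError(f"each site needs >= 2 samples in both {group_a!r} and {group_b!r}")

    rows = []
    for site, sub in df.groupby("site"):
        a = sub.loc[sub["group"] == group_a, "beta"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "beta"].to_numpy()
        ta, tb = np.arcsin(np.sqrt(a)), np.arcsin(np.sqrt(b))
        if np.allclose(ta.var(ddof=1) + tb.var(ddof=1), 0):
            p = 1.0 if np.isclose(ta.mean(), tb.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(tb, ta, equal_var=False).pvalue)
        rows.append({
            "site": site,
            "mean_a": a.mean(), "mean_b": b.mean(),
            "var_a": a.var(ddof=1), "var_b": b.var(ddof=1),
            "delta_beta": b.mean() - a.mean(),
            "min_coverage": int(sub["total_reads"].min()),
            "pvalue": p,
        })
    out = pd.DataFrame(rows).set_index("site")
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def differential_cpgs(table: pd.DataFrame, group_a: str, group_b: str,
                      min_cov: int = 5, min_diff: float = 0.05,
                      max_var: float = 0.05, alpha: float = 0.05,
                      coverage_mode: str = "per_sample") -> pd.DataFrame:
    """Apply the differential-methylation filter chain between two groups.

    A site passes iff it is covered by >= ``min_cov`` reads (per sample by
    default; ``coverage_mode="group_mean"`` relaxes to the group-mean
    coverage), |delta beta| >= ``min_diff``, the beta variance is
    < ``max_var`` in BOTH groups, and BH-adjusted p < ``alpha``.  Returns
    the full per-site table with individual pass flags and ``passes``.
    """
    df = _beta_table(table)
    df = df[df["group"].isin([group_a, group_b])]
    if coverage_mode == "per_sample":
        cov_ok = df.groupby("site")["total_reads"].min() >= min_cov
    elif coverage_mode == "group_mean":
        cov_ok = df.groupby(["site", "group"])["total_reads"].mean().unstack("group").min(axis=1) >= min_cov
    else:
        raise ValidationError(f"unknown coverage_mode {coverage_mode!r}")

    covered = df[df["site"].isin(cov_ok.index[cov_ok])]
    if covered.empty:
        stats_df = pd.DataFrame(columns=["mean_a", "mean_b", "var_a", "var_b",
                                         "delta_beta", "min_coverage", "pvalue", "padj"],
                                index=pd.Index([], name="site"))
    else:
        stats_df = site_statistics(covered, group_a, group_b)
    stats_df["covered"] = True
    stats_df["passes_diff"] = stats_df["delta_beta"].abs() >= min_diff
    stats_df["passes_var"] = (stats_df["var_a"] < max_var) & (stats_df["var_b"] < max_var)
    stats_df["passes_fdr"] = stats_df["padj"] < alpha
    stats_df["passes"] = (stats_df["passes_diff"] & stats_df["passes_var"]
                          & stats_df["passes_fdr"])
    dropped = cov_ok.index[~cov_ok]
    if len(dropped):
        extra = pd.DataFrame(index=pd.Index(dropped, name="site"),
                             columns=stats_df.columns)
        extra["covered"] = False
        for col in ("passes_diff", "passes_var", "passes_fdr", "passes"):
            extra[col] = False
        stats_df = pd.concat([stats_df, extra]).sort_index()
    logger.info("differential_cpgs %s vs %s: %d of %d sites pass all filters",
                group_b, group_a, int(stats_df["passes"].sum()), len(stats_df))
    return stats_df


def select_aging_loci(stats_df: pd.DataFrame, min_abs_diff: float = 0.30,
                      fdr: float = 0.1) -> list:
    """Loci with |delta beta| strictly > ``min_abs_diff`` and FDR p strictly < ``fdr``."""
    mask = (stats_df["delta_beta"].abs() > min_abs_diff) & (stats_df["padj"] < fdr)
    return sorted(stats_df.index[mask.fillna(False)])


# ---------------------------------------------------------------------------
# concordance across contrasts
# ---------------------------------------------------------------------------

def _direction(delta: float) -> int:
    return int(np.sign(delta))


def classify_locus(age_delta: float, age_significant: bool,
                   diet_delta: float, diet_significant: bool) -> str:
    """Concordance class of one locus given its two contrasts."""
    if age_significant and diet_significant:
        if _direction(age_delta) == _direction(diet_delta) and _direction(age_delta) != 0:
            return "concordant"
        return "discordant"
    if age_significant:
        return "age_only"
    if diet_significant:
        return "diet_only"
    return "neither"


def concordance(age_stats: pd.DataFrame, diet_stats: pd.DataFrame,
                loci: list | None = None, alpha: float = 0.05,
                use_adjusted: bool = False) -> pd.DataFrame:
    """Classify loci by agreement of the aging and diet contrasts.

    Significance follows the plain two-group t-test p-value by default
    (set ``use_adjusted`` for BH-adjusted calls).  Loci missing from
    either contrast are skipped with a log entry.
    """
    if loci is None:
        loci = sorted(set(age_stats.index) & set(diet_stats.index))
    pcol = "padj" if use_adjusted else "pvalue"
    rows = []
    for locus in loci:
        if locus not in age_stats.index or locus not in diet_stats.index:
            logger.warning("concordance: locus %s missing a contrast; skipped", locus)
            continue
        a, d = age_stats.loc[locus], diet_stats.loc[locus]
        if a[["delta_beta", pcol]].isna().any() or d[["delta_beta", pcol]].isna().any():
            logger.warning("concordance: locus %s has undefined statistics; skipped", locus)
            continue
        a_sig, d_sig = bool(a[pcol] < alpha), bool(d[pcol] < alpha)
        rows.append({
            "site": locus,
            "age_delta": a["delta_beta"], "age_significant": a_sig,
            "diet_delta": d["delta_beta"], "diet_significant": d_sig,
            "class": classify_locus(a["delta_beta"], a_sig, d["delta_beta"], d_sig),
        })
    return pd.DataFrame(rows).set_index("site") if rows else pd.DataFrame(
        columns=["age_delta", "age_significant", "diet_delta", "diet_significant", "class"])


def snupe_site_statistics(snupe: pd.DataFrame, group_a: str, group_b: str,
                          technology: str | None = None) -> pd.DataFrame:
    """Two-group comparison of chromatogram methylation indices per locus.

    Shares the concordance engine with RRBS: returns the same columns
    (delta is the difference of mean indices, b minus a).
    """
    df = snupe.copy()
    if technology is not None:
        df = df[df["technology"] == technology]
    df = df[df["group"].isin([group_a, group_b])]
    df["index"] = [methylation_index(m, u) for m, u in zip(df["h_M"], df["h_UM"])]
    rows = []
    for locus, sub in df.groupby("locus"):
        a = sub.loc[sub["group"] == group_a, "index"].to_numpy()
        b = sub.loc[sub["group"] == group_b, "index"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            logger.warning("snupe_site_statistics: locus %s has <2 replicates; skipped", locus)
            continue
        p = float(stats.ttest_ind(b, a, equal_var=False).pvalue)
        rows.append({"site": locus, "mean_a": a.mean(), "mean_b": b.mean(),
                     "var_a": a.var(ddof=1), "var_b": b.var(ddof=1),
                     "delta_beta": b.mean() - a.mean(), "pvalue": p})
    out = pd.DataFrame(rows).set_index("site")
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
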