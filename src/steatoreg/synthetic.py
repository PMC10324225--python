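"""Synthetic inputs with the statistical structure the analysis assumes.

Everything is a pure function of (config, seed): each generator draws from
its own named substream of the root seed, so adding a generator never
perturbs the others.  The generators plant known signal — motif-bearing
peaks whose accessibility shifts between conditions, DE genes clustered
by the TF that drives them, CpGs with age- and diet-dependent shifts —
and record it in a :class:`GroundTruth` object so the full pipeline can
be held to a plant-and-recover contract.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .affinity import BASES, PositionWeightModel
from .errors import ConfigurationError, SizingError

logger = logging.getLogger(__name__)

CONDITIONS = ("Co", "LDC")
METH_GROUPS = ("young", "mid_aged", "aged", "Co", "LDC")


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 200
    n_tfs: int = 10
    n_active_tfs: int = 2
    n_clusters: int = 4
    genome_length: int = 2_000_000
    n_peaks: int = 300
    motif_length: int = 8
    effect_size: float = 1.5
    n_samples_per_group: int = 4
    n_cpgs: int = 200
    aging_delta: float = -0.4
    diet_delta: float = 0.3
    # layout / noise knobs (conventions, not estimates)
    de_fraction: float = 0.4
    gene_length: int = 2_000
    peak_width: int = 200
    peak_tss_jitter: int = 5_000
    base_accessibility: float = 100.0
    nb_dispersion: float = 0.1
    expression_sigma: float = 0.25
    expression_base_mean: float = 5.0
    rrbs_depth: int = 60
    n_aging_cpgs: int = 20
    n_diet_cpgs: int = 20
    n_opposite_cpgs: int = 10
    snupe_scale: float = 1000.0
    snupe_sigma: float = 0.1

    def validate(self) -> None:
        if self.n_active_tfs > self.n_tfs:
            raise ConfigurationError("n_active_tfs exceeds n_tfs")
        if self.n_clusters < 2:
            raise ConfigurationError("n_clusters must be >= 2")
        for name in ("n_genes", "n_tfs", "genome_length", "n_peaks", "motif_length",
                     "n_samples_per_group", "n_cpgs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.motif_length > self.peak_width:
            raise ConfigurationError(
                f"motif_length {self.motif_length} exceeds peak_width {self.peak_width}"
            )
        if self.n_opposite_cpgs > min(self.n_aging_cpgs, self.n_diet_cpgs):
            raise ConfigurationError("n_opposite_cpgs exceeds a planted-locus count")
        if self.n_aging_cpgs + self.n_diet_cpgs - self.n_opposite_cpgs > self.n_cpgs:
            raise ConfigurationError("planted CpG counts exceed n_cpgs")


@dataclass
class GroundTruth:
    active_tfs: list = field(default_factory=list)       # [{"tf": ..., "cluster": ...}]
    gene_clusters: dict = field(default_factory=dict)    # gene -> cluster index
    de_direction: dict = field(default_factory=dict)     # gene -> "up" / "down"
    dm_cpgs: list = field(default_factory=list)          # [{"site", "age_direction", "diet_direction"}]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(cfg: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# genome + genes
# ---------------------------------------------------------------------------

def generate_genome(cfg: SyntheticConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """One uniform-composition chromosome plus non-overlapping gene bodies."""
    cfg.validate()
    rng = _rng(cfg, "genome")
    slot = cfg.genome_length // cfg.n_genes
    if slot < cfg.gene_length + 2 * cfg.peak_width:
        raise SizingError(
            f"genome_length {cfg.genome_length} cannot host {cfg.n_genes} genes "
            f"of length {cfg.gene_length}"
        )
    codes = rng.integers(0, 4, size=cfg.genome_length, dtype=np.uint8)
    seq = bytes(np.frombuffer(BASES.encode(), dtype=np.uint8)[codes]).decode()
    rows = []
    for i in range(cfg.n_genes):
        margin = slot - cfg.gene_length
        start = i * slot + int(rng.integers(margin // 4, margin - margin // 4))
        end = start + cfg.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end - 1
        rows.append((f"gene{i:04d}", "chr1", start, end, strand, tss))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"])
    return {"chr1": seq}, genes


# ---------------------------------------------------------------------------
# regulatory landscape
# ---------------------------------------------------------------------------

def _make_pwm(name: str, width: int, rng: np.random.Generator) -> tuple[PositionWeightModel, np.ndarray]:
    consensus = rng.integers(0, 4, size=width)
    counts = np.full((4, width), 5.0)
    counts[consensus, np.arange(width)] = 85.0
    return PositionWeightModel.from_counts(name, counts), counts


def generate_regulatory_landscape(cfg: SyntheticConfig, genome: dict[str, str],
                                  genes: pd.DataFrame):
    """Plant motifs and differential accessibility; return the full landscape.

    Returns ``(genome, peaks, pwms, pwm_counts, truth)`` where ``genome``
    is a copy with active-TF consensus motifs written into the planted
    peaks, ``peaks`` carries per-sample accessibility counts and logFC,
    and ``truth`` records the planted structure.
    """
    cfg.validate()
    rng = _rng(cfg, "landscape")
    chrom = "chr1"
    seq = bytearray(genome[chrom], "ascii")

    pwms, counts_by_name = [], {}
    for t in range(cfg.n_tfs):
        pwm, counts = _make_pwm(f"TF{t:03d}", cfg.motif_length, rng)
        pwms.append(pwm)
        counts_by_name[pwm.name] = counts

    truth = GroundTruth()
    active_idx = rng.choice(cfg.n_tfs, size=cfg.n_active_tfs, replace=False)
    tf_of_cluster: dict[int, PositionWeightModel] = {}
    for k, ti in enumerate(sorted(active_idx)):
        cluster = (k % cfg.n_clusters) + 1
        truth.active_tfs.append({"tf": pwms[ti].name, "cluster": cluster})
        tf_of_cluster.setdefault(cluster, pwms[ti])

    # DE genes and their clusters (round-robin over a random gene subset)
    n_de = max(cfg.n_clusters, int(round(cfg.de_fraction * cfg.n_genes)))
    if n_de > cfg.n_genes:
        raise ConfigurationError("de_fraction too large for n_genes")
    de_genes = sorted(rng.choice(genes["gene_id"].to_numpy(), size=n_de, replace=False))
    targeted = {a["cluster"] for a in truth.active_tfs}
    if targeted == set(range(1, cfg.n_clusters + 1)):
        logger.warning("every cluster is targeted by an active TF; no 'down' DE genes")
    # contiguous blocks along the chromosome: genes of one cluster are
    # positional neighbours, so 50-kb windows rarely straddle two clusters
    for j, gene in enumerate(de_genes):
        cluster = min(j * cfg.n_clusters // n_de, cfg.n_clusters - 1) + 1
        truth.gene_clusters[gene] = cluster
        truth.de_direction[gene] = "up" if cluster in targeted else "down"

    # one peak near every DE gene's TSS; motif planted when the cluster is targeted
    if cfg.n_peaks < n_de:
        raise ConfigurationError(f"n_peaks {cfg.n_peaks} < number of DE genes {n_de}")
    tss_by_gene = genes.set_index("gene_id")["tss"]
    peak_rows = []
    planted = np.zeros(cfg.n_peaks, dtype=bool)
    for pi, gene in enumerate(de_genes):
        jitter = int(rng.integers(-cfg.peak_tss_jitter, cfg.peak_tss_jitter))
        start = int(np.clip(tss_by_gene[gene] + jitter, 0,
                            cfg.genome_length - cfg.peak_width))
        end = start + cfg.peak_width
        cluster = truth.gene_clusters[gene]
        if cluster in tf_of_cluster:
            pwm = tf_of_cluster[cluster]
            pos = start + (cfg.peak_width - pwm.width) // 2
            seq[pos:pos + pwm.width] = pwm.consensus.encode()
            planted[pi] = True
        peak_rows.append((chrom, start, end, f"peak{pi:05d}"))
    for pi in range(n_de, cfg.n_peaks):
        start = int(rng.integers(0, cfg.genome_length - cfg.peak_width))
        peak_rows.append((chrom, start, start + cfg.peak_width, f"peak{pi:05d}"))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "name"])

    # negative-binomial accessibility; planted peaks gain 2^effect_size in LDC
    r = 1.0 / cfg.nb_dispersion
    mu = np.full((cfg.n_peaks, 2), cfg.base_accessibility)  # columns Co, LDC
    mu[planted, 1] *= 2.0 ** cfg.effect_size
    for ci, cond in enumerate(CONDITIONS):
        for s in range(cfg.n_samples_per_group):
            p = r / (r + mu[:, ci])
            peaks[f"{cond}_{s + 1}"] = rng.negative_binomial(r, p)
    co_cols = [f"Co_{s + 1}" for s in range(cfg.n_samples_per_group)]
    ldc_cols = [f"LDC_{s + 1}" for s in range(cfg.n_samples_per_group)]
    peaks["mean_Co"] = peaks[co_cols].mean(axis=1)
    peaks["mean_LDC"] = peaks[ldc_cols].mean(axis=1)
    peaks["logFC"] = np.log2((peaks["mean_LDC"] + 1) / (peaks["mean_Co"] + 1))
    peaks["planted"] = planted

    new_genome = {chrom: seq.decode()}
    peaks["sequence"] = [new_genome[chrom][s:e] for s, e in zip(peaks["start"], peaks["end"])]
    return new_genome, peaks, pwms, counts_by_name, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression_tables(cfg: SyntheticConfig, truth: GroundTruth,
                               genes: pd.DataFrame):
    """Per-sample FPM matrix plus a DE table from a two-group Welch test.

    Planted DE genes shift their mean log2 FPM by +/- effect_size in the
    LDC samples (sign from the planted direction); the DE table's p-values
    come from an actual test on the simulated samples, so with
    effect_size = 0 the adjusted-p distribution is null-calibrated.
    """
    from scipy import stats as sps

    from .methylation import bh_adjust

    rng = _rng(cfg, "expression")
    n = cfg.n_samples_per_group
    samples = [f"Co_{i + 1}" for i in range(n)] + [f"LDC_{i + 1}" for i in range(n)]
    gene_ids = genes["gene_id"].to_numpy()
    base = rng.normal(cfg.expression_base_mean, 1.5, size=len(gene_ids))
    log2fpm = base[:, None] + rng.normal(0, cfg.expression_sigma, size=(len(gene_ids), 2 * n))
    for gi, gene in enumerate(gene_ids):
        direction = truth.de_direction.get(gene)
        if direction is not None:
            shift = cfg.effect_size if direction == "up" else -cfg.effect_size
            log2fpm[gi, n:] += shift
    fpm = pd.DataFrame(2.0 ** log2fpm, index=pd.Index(gene_ids, name="gene"), columns=samples)

    co, ldc = log2fpm[:, :n], log2fpm[:, n:]
    lfc = ldc.mean(axis=1) - co.mean(axis=1)
    pvals = sps.ttest_ind(ldc, co, axis=1, equal_var=False).pvalue
    de = pd.DataFrame({
        "gene": gene_ids,
        "baseMean": fpm.mean(axis=1).to_numpy(),
        "log2FC": lfc,
        "pvalue": pvals,
        "padj": bh_adjust(pvals),
    })
    clusters = pd.DataFrame(
        sorted(truth.gene_clusters.items()), columns=["gene", "cluster"]
    )
    return fpm, de, clusters


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def generate_methylation_tables(cfg: SyntheticConfig, truth: GroundTruth | None = None):
    """RRBS count table and chromatogram peak heights for all contrasts.

    Planted aging loci shift their mean beta by ``aging_delta`` from young
    to aged (half-shift in mid-aged); planted diet loci shift by
    ``diet_delta`` from Co to LDC.  The first ``n_opposite_cpgs`` planted
    loci are opposite-direction: their diet shift is forced to the sign
    opposite the aging shift.  Means falling outside [0, 1] are clipped
    with a warning.
    """
    cfg.validate()
    if truth is None:
        truth = GroundTruth()
    rng = _rng(cfg, "methylation")
    sites = [f"cpg{i:05d}" for i in range(cfg.n_cpgs)]
    base = rng.uniform(0.2, 0.8, size=cfg.n_cpgs)

    age_shift = np.zeros(cfg.n_cpgs)
    diet_shift = np.zeros(cfg.n_cpgs)
    n_opp, n_age, n_diet = cfg.n_opposite_cpgs, cfg.n_aging_cpgs, cfg.n_diet_cpgs
    if cfg.aging_delta != 0:
        age_shift[:n_age] = cfg.aging_delta
    if cfg.diet_delta != 0:
        diet_shift[:n_opp] = -np.sign(cfg.aging_delta or 1) * abs(cfg.diet_delta)
        diet_shift[n_age:n_age + (n_diet - n_opp)] = cfg.diet_delta
    for i in range(cfg.n_cpgs):
        if age_shift[i] == 0 and diet_shift[i] == 0:
            continue
        truth.dm_cpgs.append({
            "site": sites[i],
            "age_direction": int(np.sign(age_shift[i])),
            "diet_direction": int(np.sign(diet_shift[i])),
        })

    # keep planted shifts realizable: move the base fraction into a range
    # where no group mean leaves [0, 1]; infeasible deltas still clip below
    lo_shift = np.minimum(np.minimum(age_shift, diet_shift), 0.0)
    hi_shift = np.maximum(np.maximum(age_shift, diet_shift), 0.0)
    feasible = (0.02 - lo_shift) <= (0.98 - hi_shift)
    base = np.where(feasible, np.clip(base, 0.02 - lo_shift, 0.98 - hi_shift), base)

    group_beta = {
        "young": base,
        "mid_aged": base + age_shift / 2.0,
        "aged": base + age_shift,
        "Co": base,
        "LDC": base + diet_shift,
    }
    for g, b in group_beta.items():
        if (b < 0).any() or (b > 1).any():
            logger.warning("group %s: %d planted means clipped to [0,1]",
                           g, int(((b < 0) | (b > 1)).sum()))
            group_beta[g] = np.clip(b, 0.0, 1.0)

    rows = []
    for group in METH_GROUPS:
        betas = group_beta[group]
        for s in range(cfg.n_samples_per_group):
            total = rng.poisson(cfg.rrbs_depth, size=cfg.n_cpgs) + 1
            meth = rng.binomial(total, betas)
            for i in range(cfg.n_cpgs):
                rows.append((sites[i], "chr1", 1000 + 10 * i, f"{group}_{s + 1}",
                             group, int(meth[i]), int(total[i])))
    rrbs = pd.DataFrame(rows, columns=["site", "chrom", "pos", "sample", "group",
                                       "meth_reads", "total_reads"])

    # chromatogram heights for the planted loci plus an equal-size null panel
    planted_sites = [d["site"] for d in truth.dm_cpgs]
    n_null = min(len(planted_sites) if planted_sites else 5, cfg.n_cpgs - len(planted_sites))
    null_sites = [s for s in sites if s not in set(planted_sites)][:n_null]
    panel = planted_sites + null_sites
    snupe_rows = []
    for tech in ("SNuPE", "MiSeq"):
        for group in METH_GROUPS:
            betas = group_beta[group]
            for s in range(cfg.n_samples_per_group):
                noise = rng.lognormal(0.0, cfg.snupe_sigma, size=(len(panel), 2))
                for li, locus in enumerate(panel):
                    b = betas[sites.index(locus)]
                    snupe_rows.append((
                        locus, f"{group}_{s + 1}", group, tech,
                        cfg.snupe_scale * b * noise[li, 0],
                        cfg.snupe_scale * (1 - b) * noise[li, 1],
                    ))
    snupe = pd.DataFrame(snupe_rows, columns=["locus", "sample", "group",
                                              "technology", "h_M", "h_UM"])
    return rrbs, snupe, truth


# ---------------------------------------------------------------------------
# convenience: everything at once
# ---------------------------------------------------------------------------

def generate_all(cfg: SyntheticConfig) -> dict:
    """Run every generator; returns a dict of all artifacts plus GroundTruth."""
    genome, genes = generate_genome(cfg)
    genome, peaks, pwms, pwm_counts, truth = generate_regulatory_landscape(cfg, genome, genes)
    fpm, de, clusters = generate_expression_tables(cfg, truth, genes)
    rrbs, snupe, truth = generate_methylation_tables(cfg, truth)
    return {
        "genome": genome, "genes": genes, "peaks": peaks, "pwms": pwms,
        "pwm_counts": pwm_counts, "fpm": fpm, "de": de, "clusters": clusters,
        "rrbs": rrbs, "snupe": snupe, "truth": truth,
    }
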