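"""Independent brute-force reference implementations used to check the
package.  These deliberately share no code with steatoreg: plain loops,
textbook formulas, no vectorization."""

import math

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


def site_probability(freq, site, background=0.25, lam=0.7,
                     r0_slope=0.584, r0_intercept=-5.66):
    """Occupancy probability of one site from first principles."""
    width = len(freq[0])
    consensus = 0.0
    for j in range(width):
        consensus += max(math.log(freq[b][j] / background) for b in range(4))
    score = 0.0
    for j, base in enumerate(site):
        if base == "N":
            continue
        score += math.log(freq[BASE_ROW[base]][j] / background)
    energy = consensus - score
    ln_r0 = r0_slope * width + r0_intercept
    k = math.exp(ln_r0 - energy / lam)
    return k / (1.0 + k)


def revcomp(seq):
    return "".join(COMP[b] for b in reversed(seq))


def region_affinity(freq, sequence):
    """Sum of site probabilities over every position on both strands."""
    width = len(freq[0])
    total = 0.0
    for pos in range(len(sequence) - width + 1):
        site = sequence[pos:pos + width]
        total += site_probability(freq, site)
        total += site_probability(freq, revcomp(site))
    return total


def gene_scores(peak_records, gene_records, freqs, window):
    """peak_records: (chrom, start, end, sequence); gene_records:
    (gene_id, chrom, tss); freqs: {tf_name: 4xW freq}.  Returns nested dict
    scores[tf][gene]."""
    out = {}
    for tf, freq in freqs.items():
        out[tf] = {}
        for gene_id, gchrom, tss in gene_records:
            total = 0.0
            for chrom, start, end, seq in peak_records:
                if chrom != gchrom:
                    continue
                if start < tss + window and end > tss - window:
                    total += region_affinity(freq, seq)
            out[tf][gene_id] = total
    return out


def bh_adjust(pvalues):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = indexed[rank_from_top - 1]
        value = pvalues[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def interval_distance(a_start, a_end, b_start, b_end):
    if a_start < b_end and b_start < a_end:
        return 0
    if b_start >= a_end:
        return b_start - a_end + 1
    return a_start - b_end + 1


def closest_gene(domain, gene_records, window):
    """domain: (chrom, start, end); gene_records: (gene_id, chrom, start,
    end, tss).  Returns (gene_id, distance) or None."""
    best = None
    for gene_id, chrom, start, end, tss in gene_records:
        if chrom != domain[0]:
            continue
        d = interval_distance(domain[1], domain[2], start, end)
        if d > window:
            continue
        mid = (domain[1] + domain[2]) / 2
        key = (d, abs(mid - tss), gene_id)
        if best is None or key < best[0]:
            best = (key, gene_id, d)
    return None if best is None else (best[1], best[2])
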