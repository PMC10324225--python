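"""Biophysical TF binding-affinity scoring and per-condition TF-gene scores.

A position weight matrix is scored against DNA with a thermodynamic
occupancy model: every site of width ``W`` (both strands are separate
sites) gets a binding probability ``p = K / (1 + K)`` with
``K = R0 * exp(-E / lambda)`` where ``E`` is the mismatch energy of the
site relative to the matrix consensus, measured in natural-log-odds
units against a uniform background.  Region affinities are plain sums of
site probabilities; TF-gene scores sum region affinities over all peaks
overlapping a window around each gene's TSS.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

logger = logging.getLogger(__name__)

# Occupancy-model constants (classic defaults for the scoring scheme;
# exposed so a config can override them).
TRAP_LAMBDA = 0.7
TRAP_R0_SLOPE = 0.584
TRAP_R0_INTERCEPT = -5.66

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)

DEFAULT_BACKGROUND = np.full(4, 0.25)


def ln_r0(width: int) -> float:
    """Log equilibrium constant of the consensus site as a function of width."""
    return TRAP_R0_SLOPE * width + TRAP_R0_INTERCEPT


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a DNA string over {A,C,G,T,N} (case-insensitive) to int codes 0-4."""
    try:
        return np.array([_CODE[b] for b in sequence.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValidationError(f"invalid base {exc} in sequence") from exc


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass
class PositionWeightModel:
    """A TF's column-stochastic frequency matrix plus derived log-odds.

    ``freq`` is 4 x W (rows A, C, G, T); columns sum to one.  ``log_odds``
    is the natural-log ratio against ``background``; with the +1-count
    pseudo-frequency applied upstream it is finite everywhere.
    """

    name: str
    freq: np.ndarray
    background: np.ndarray = field(default_factory=lambda: DEFAULT_BACKGROUND.copy())

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape[0] != 4:
            raise ValidationError(f"PWM {self.name!r}: expected 4 rows, got {self.freq.shape[0]}")
        colsums = self.freq.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValidationError(f"PWM {self.name!r}: columns do not sum to 1")
        if np.any(self.freq <= 0):
            raise ValidationError(
                f"PWM {self.name!r}: zero/negative frequencies; apply a pseudo-frequency first"
            )

    @property
    def width(self) -> int:
        return self.freq.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.freq / self.background[:, None])

    @property
    def consensus_score(self) -> float:
        """Best achievable log-odds score (sum of per-column maxima)."""
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=0))

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 1.0,
                    background: np.ndarray | None = None) -> "PositionWeightModel":
        """Build from a raw count matrix, adding ``pseudocount`` per cell."""
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValidationError(f"PWM {name!r}: negative counts")
        if np.any(counts.sum(axis=0) == 0):
            raise ValidationError(f"PWM {name!r}: zero column sum")
        counts = counts + pseudocount
        freq = counts / counts.sum(axis=0, keepdims=True)
        kwargs = {} if background is None else {"background": np.asarray(background, float)}
        return cls(name=name, freq=freq, **kwargs)


@dataclass
class AffinityGeneScore:
    """Per-condition TF x gene affinity matrix (rows TFs, columns genes)."""

    condition: str
    matrix: pd.DataFrame
    window: int


@dataclass
class AffinityQuotient:
    """Pseudocounted log2 ratio of two conditions' TF-gene scores."""

    matrix: pd.DataFrame
    pseudocount: float = 1e-6


# ---------------------------------------------------------------------------
# site / region scoring
# ---------------------------------------------------------------------------

def _padded_log_odds(pwm: PositionWeightModel) -> np.ndarray:
    """Log-odds with a fifth, all-zero row so N bases score as background."""
    lo = pwm.log_odds
    return np.vstack([lo, np.zeros((1, lo.shape[1]))])


def _strand_site_probs(pwm: PositionWeightModel, codes: np.ndarray) -> np.ndarray:
    """Occupancy probability of every width-W site of one encoded strand."""
    w = pwm.width
    n_sites = codes.size - w + 1
    if n_sites <= 0:
        return np.empty(0)
    lo = _padded_log_odds(pwm)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    site_scores = lo[windows, np.arange(w)].sum(axis=1)
    energy = pwm.consensus_score - site_scores
    k = np.exp(ln_r0(w) - energy / TRAP_LAMBDA)
    return k / (1.0 + k)


def site_affinity(pwm: PositionWeightModel, sequence: str, position: int,
                  strand: str = "+") -> float:
    """Binding probability of the single site occupying [position, position+W).

    ``strand='-'`` scores the reverse complement of that same stretch; the
    two strands are independent sites and are never max-combined.
    """
    w = pwm.width
    if position < 0 or position + w > len(sequence):
        raise IndexError(
            f"site [{position}, {position + w}) outside sequence of length {len(sequence)}"
        )
    site = sequence[position:position + w]
    if strand == "-":
        site = reverse_complement(site)
    codes = encode_sequence(site)
    return float(_strand_site_probs(pwm, codes)[0])


def region_affinity(pwm: PositionWeightModel, sequence: str) -> float:
    """Sum of site binding probabilities over all positions on both strands.

    Regions shorter than the matrix width score 0 (no site fits); this is
    logged rather than raised.
    """
    if len(sequence) < pwm.width:
        logger.warning(
            "region of length %d shorter than PWM %s width %d; affinity 0",
            len(sequence), pwm.name, pwm.width,
        )
        return 0.0
    fwd = encode_sequence(sequence)
    rev = _COMPLEMENT_CODE[fwd][::-1]
    return float(_strand_site_probs(pwm, fwd).sum() + _strand_site_probs(pwm, rev).sum())


# ---------------------------------------------------------------------------
# gene-level aggregation
# ---------------------------------------------------------------------------

def gene_scores(peaks: pd.DataFrame, genes: pd.DataFrame,
                pwms: list[PositionWeightModel], window: int = 50_000,
                condition: str = "", anchor: str = "tss") -> AffinityGeneScore:
    """Aggregate peak affinities into a TF x gene score matrix.

    ``peaks`` needs columns chrom/start/end/sequence; ``genes`` needs
    gene_id/chrom/start/end/tss.  A peak contributes its full region
    affinity to every gene whose window it overlaps (no proration).
    ``anchor`` selects the window reference: ``"tss"`` (default) uses
    [tss - window, tss + window); ``"body"`` expands the gene body by
    ``window`` on both sides.
    """
    if anchor not in ("tss", "body"):
        raise ValueError(f"unknown anchor {anchor!r}")
    aff = np.zeros((len(pwms), len(peaks)))
    for ti, pwm in enumerate(pwms):
        aff[ti] = [region_affinity(pwm, s) for s in peaks["sequence"]]

    mat = np.zeros((len(pwms), len(genes)))
    peak_chrom = peaks["chrom"].to_numpy()
    peak_start = peaks["start"].to_numpy()
    peak_end = peaks["end"].to_numpy()
    for gi, gene in enumerate(genes.itertuples(index=False)):
        if anchor == "tss":
            lo, hi = gene.tss - window, gene.tss + window
        else:
            lo, hi = gene.start - window, gene.end + window
        mask = (peak_chrom == gene.chrom) & (peak_start < hi) & (peak_end > lo)
        if mask.any():
            mat[:, gi] = aff[:, mask].sum(axis=1)

    matrix = pd.DataFrame(mat, index=[p.name for p in pwms], columns=list(genes["gene_id"]))
    return AffinityGeneScore(condition=condition, matrix=matrix, window=window)


def affinity_quotient(a_ldc: AffinityGeneScore, a_co: AffinityGeneScore,
                      eps: float = 1e-6) -> AffinityQuotient:
    """Elementwise log2((A_LDC + eps) / (A_Co + eps)) on aligned matrices."""
    m_ldc, m_co = a_ldc.matrix, a_co.matrix
    if not (m_ldc.index.equals(m_co.index) and m_ldc.columns.equals(m_co.columns)):
        raise AlignmentError("TF/gene index sets of the two conditions differ")
    q = np.log2((m_ldc + eps) / (m_co + eps))
    return AffinityQuotient(matrix=q, pseudocount=eps)


def filter_expressed_tfs(pwms: list[PositionWeightModel], de_table: pd.DataFrame,
                         min_base_mean: float = 10.0) -> list[PositionWeightModel]:
    """Drop TFs whose gene is not expressed (baseMean below the cutoff).

    TFs absent from the table are kept (no expression evidence either way).
    """
    if "baseMean" not in de_table.columns or "gene" not in de_table.columns:
        raise KeyError("de_table needs 'gene' and 'baseMean' columns")
    base = de_table.set_index("gene")["baseMean"]
    kept = [p for p in pwms if p.name not in base.index or base[p.name] >= min_base_mean]
    logger.info("expressed-TF filter: %d of %d motifs retained", len(kept), len(pwms))
    return kept
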