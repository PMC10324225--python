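"""Readers and writers for the external formats the pipeline touches.

All interval coordinates are 0-based half-open internally.  Parsers never
silently drop records: skipped lines are counted and logged.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .affinity import PositionWeightModel
from .errors import PFMParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3-BED6 file into a DataFrame with BED6 columns.

    Missing name/score/strand fields are filled with ".", 0 and ".".
    Raises :class:`ValidationError` (with the line number) on start >= end.
    """
    rows = []
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                skipped += 1
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            if start < 0:
                raise ValidationError(f"{path}:{lineno}: negative start {start}")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    if skipped:
        logger.info("read_bed(%s): skipped %d header/blank lines", path, skipped)
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write BED6; accepts any DataFrame with at least chrom/start/end."""
    df = intervals.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]].tolist()
        raise ValidationError(f"start >= end for rows {bad}")
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def genes_from_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 gene file; derives the strand-aware TSS column.

    TSS = start for '+' genes and end - 1 for '-' genes (half-open input).
    """
    df = read_bed(path)
    if not set(df["strand"]).issubset({"+", "-"}):
        raise ValidationError(f"{path}: gene strands must be '+' or '-'")
    df = df.rename(columns={"name": "gene_id"})
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df[["gene_id", "chrom", "start", "end", "strand", "tss"]]


def genes_to_bed(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.rename(columns={"gene_id": "name"}).assign(score=0)
    write_bed(out, path)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, schema: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV with header row; ``schema`` lists required column names."""
    df = pd.read_csv(path, sep="\t")
    if schema:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_matrix(df: pd.DataFrame, path: str | Path, index_name: str = "TF") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA entirely into memory as {name: sequence}."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValidationError(f"{path}: sequence before first header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def attach_sequences(peaks: pd.DataFrame, genome: dict[str, str]) -> pd.DataFrame:
    """Add a 'sequence' column to a peak table from an in-memory genome."""
    missing = sorted(set(peaks["chrom"]) - set(genome))
    if missing:
        raise ValidationError(f"chromosomes absent from genome: {missing}")
    seqs = [genome[c][s:e] for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])]
    out = peaks.copy()
    out["sequence"] = seqs
    return out


def attach_sequences_from_fasta(peaks: pd.DataFrame, fasta_path: str | Path) -> pd.DataFrame:
    """Like :func:`attach_sequences` but random-accesses an indexed FASTA."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    missing = sorted(set(peaks["chrom"]) - set(fa.keys()))
    if missing:
        raise ValidationError(f"chromosomes absent from genome: {missing}")
    out = peaks.copy()
    out["sequence"] = [
        str(fa[c][s:e]).upper() for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])
    ]
    return out


# ---------------------------------------------------------------------------
# JASPAR PFM text
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^\s*([ACGT])?\s*\[?\s*([-0-9.eE+\s]+?)\s*\]?\s*$")


def read_pfm(path: str | Path, pseudocount: float = 1.0) -> list[PositionWeightModel]:
    """Parse a JASPAR-style PFM text file into weight models.

    Each record is a ``>name`` header followed by 4 rows (A, C, G, T),
    optionally letter-prefixed and bracketed.  Counts are normalized to
    column-stochastic frequencies after adding ``pseudocount`` per cell.
    """
    records: list[tuple[str, list[list[float]], int]] = []
    name, rows, first_line = None, [], 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, rows, first_line))
                parts = line[1:].split()
                name = parts[-1] if len(parts) > 1 else parts[0]
                rows, first_line = [], lineno
            else:
                if name is None:
                    raise PFMParseError(f"{path}:{lineno}: matrix row before any '>' header")
                m = _ROW_RE.match(line)
                if not m:
                    raise PFMParseError(f"{path}:{lineno}: unparseable matrix row")
                try:
                    values = [float(tok) for tok in m.group(2).split()]
                except ValueError as exc:
                    raise PFMParseError(f"{path}:{lineno}: bad number in row") from exc
                rows.append(values)
    if name is not None:
        records.append((name, rows, first_line))
    if not records:
        raise PFMParseError(f"{path}: empty PFM file")

    pwms = []
    for name, rows, lineno in records:
        if len(rows) != 4:
            raise PFMParseError(f"{path}:{lineno}: motif {name!r} has {len(rows)} rows, expected 4")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise PFMParseError(f"{path}:{lineno}: motif {name!r} has ragged rows {sorted(widths)}")
        counts = np.array(rows, dtype=float)
        if np.any(counts < 0):
            raise PFMParseError(f"{path}:{lineno}: motif {name!r} has negative counts")
        if np.any(counts.sum(axis=0) == 0):
            raise PFMParseError(f"{path}:{lineno}: motif {name!r} has a zero column sum")
        pwms.append(PositionWeightModel.from_counts(name, counts, pseudocount=pseudocount))
    return pwms


def write_pfm(pwms: list, path: str | Path, counts: dict[str, np.ndarray] | None = None,
              scale: int = 100) -> None:
    """Write JASPAR 2016 PFM text.

    If raw ``counts`` are given per motif name they are written verbatim;
    otherwise frequencies are scaled to integer pseudo-counts.
    """
    with open(path, "w") as fh:
        for i, pwm in enumerate(pwms, start=1):
            mat = counts[pwm.name] if counts and pwm.name in counts else np.round(pwm.freq * scale)
            fh.write(f">M{i:04d} {pwm.name}\n")
            for base, row in zip("ACGT", mat):
                fh.write(f"{base} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg


def merge_config(file_cfg: dict, cli_overrides: dict) -> dict:
    """CLI flags win over config-file values (None CLI values ignored)."""
    merged = dict(file_cfg)
    merged.update({k: v for k, v in cli_overrides.items() if v is not None})
    return merged
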