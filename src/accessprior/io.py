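"""Readers and writers for the standard formats the pipeline consumes.

All genomic formats are the BED family (0-based, half-open).  FASTA random
access goes through :mod:`pyfaidx`; everything else is plain text.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .core import CountMatrix, GeneModel, GenomicInterval, Peak, ValidationError
from .pwm import Pwm


class ParseError(ValueError):
    """Raised for a malformed input line; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


# ---------------------------------------------------------------------------
# Peaks (BED6 / narrowPeak)
# ---------------------------------------------------------------------------

def read_peaks(path, dialect: str = "bed6") -> list[Peak]:
    """Read peaks from BED6 or ENCODE narrowPeak, preserving input order.

    BED6 maps column 5 (score) to ``Peak.score``; narrowPeak maps column 7
    (signalValue), the caller's enrichment measure.
    """
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    min_cols = 6 if dialect == "bed6" else 10
    score_col = 4 if dialect == "bed6" else 6
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(
                    path, lineno, f"expected >= {min_cols} columns, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[score_col])
                strand = fields[5] if fields[5] in ("+", "-", ".") else "."
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            try:
                peaks.append(Peak(GenomicInterval(chrom, start, end, strand), name, score))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks(peaks: Sequence[Peak], path, dialect: str = "bed6") -> None:
    """Write peaks as BED6 or narrowPeak; round-trips with :func:`read_peaks`."""
    if dialect not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        for p in peaks:
            if dialect == "bed6":
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t"
                    f"{p.score!r}\t{p.interval.strand}\n"
                )
            else:
                # narrowPeak: score column 5 clamped to BED 0-1000 int; the
                # authoritative score lives in signalValue (column 7).
                bed_score = int(min(1000, max(0, round(p.score))))
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{bed_score}\t"
                    f"{p.interval.strand}\t{p.score!r}\t-1\t-1\t-1\n"
                )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path, dialect: str = "bed6") -> list[GeneModel]:
    """Read gene models.

    ``bed6``: the interval is the gene body; TSS = start on '+', end-1 on '-';
    the name column is the gene id (``id|symbol`` splits into both).
    ``tsv4``: columns (gene_id, chrom, tss, strand), gene body defaults to a
    1 bp span at the TSS.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "bed6":
                    chrom, start, end, name, _, strand = fields[:6]
                    start, end = int(start), int(end)
                    tss = start if strand == "+" else end - 1
                elif dialect == "tsv4":
                    name, chrom, tss, strand = fields[:4]
                    tss = int(tss)
                    start, end = tss, tss + 1
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except (ValueError, IndexError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            gene_id, _, symbol = name.partition("|")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=symbol or gene_id,
                    chrom=chrom,
                    tss=tss,
                    strand=strand,
                    span=GenomicInterval(chrom, start, end, strand),
                )
            )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            name = g.gene_id if g.symbol == g.gene_id else f"{g.gene_id}|{g.symbol}"
            fh.write(
                f"{g.chrom}\t{g.span.start}\t{g.span.end}\t{name}\t0\t{g.strand}\n"
            )


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# Count matrices and condition sheets
# ---------------------------------------------------------------------------

def read_count_matrix(counts_path, conditions_path) -> CountMatrix:
    """Read a TSV count table (features x samples) plus a CSV condition sheet.

    The condition sheet has columns ``sample,condition``.
    """
    table = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(conditions_path)
    conditions = dict(zip(sheet["sample"].astype(str), sheet["condition"].astype(str)))
    return CountMatrix(table, conditions=conditions)


def write_count_matrix(cm: CountMatrix, counts_path, conditions_path) -> None:
    cm.to_frame().rename_axis("feature_id").to_csv(counts_path, sep="\t")
    pd.DataFrame(
        {"sample": cm.sample_ids, "condition": [cm.conditions[s] for s in cm.sample_ids]}
    ).to_csv(conditions_path, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width])
                fh.write("\n")


def open_fasta(path) -> Fasta:
    """Index-based random access to a genome FASTA."""
    return Fasta(str(path), sequence_always_upper=True)


def fetch_sequence(fasta: Fasta, interval: GenomicInterval) -> str:
    contig = fasta[interval.chrom]
    if interval.end > len(contig):
        raise ValidationError(
            f"interval {interval.chrom}:[{interval.start},{interval.end}) "
            f"extends beyond contig end {len(contig)}"
        )
    return str(contig[interval.start : interval.end])


# ---------------------------------------------------------------------------
# PWMs (JASPAR and MEME minimal)
# ---------------------------------------------------------------------------

def read_pwms_jaspar(path, pseudocount: float = 1e-3) -> list[Pwm]:
    """Parse JASPAR-style PFM records::

        >MA0001.1 NAME
        A [ 1 2 3 ]
        C [ 0 1 0 ]
        ...

    Count columns are normalized to probabilities.
    """
    pwms: list[Pwm] = []
    motif_id = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = list(fh) + [">"]  # sentinel flushes the last record
    for line in lines:
        line = line.strip()
        if line.startswith(">"):
            if motif_id is not None and rows:
                pwms.append(_pwm_from_rows(motif_id, rows, pseudocount))
            motif_id = line[1:].split()[0] if len(line) > 1 else None
            rows = {}
        elif line and line[0] in "ACGT":
            base = line[0]
            body = line[1:].replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in body.split()]
    return pwms


def _pwm_from_rows(motif_id: str, rows: dict[str, list[float]], pseudocount: float) -> Pwm:
    mat = np.array([rows[b] for b in "ACGT"], dtype=float).T  # L x 4
    col_sums = mat.sum(axis=1, keepdims=True)
    if np.any(col_sums <= 0):
        raise ValidationError(f"{motif_id}: PFM column with zero total")
    return Pwm(motif_id=motif_id, probs=mat / col_sums, pseudocount=pseudocount)


def write_pwms_jaspar(pwms: Sequence[Pwm], path, counts_scale: int = 100) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(
                    f"{v:.4f}" for v in pwm.probs[:, bi] * counts_scale
                )
                fh.write(f"{base} [ {vals} ]\n")


def read_pwms_meme(path, pseudocount: float = 1e-3) -> list[Pwm]:
    """Parse MEME minimal motif format (letter-probability matrices)."""
    pwms: list[Pwm] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("Background letter frequencies"):
            freqs = lines[i + 1].split()
            background = np.array(
                [float(freqs[freqs.index(b) + 1]) for b in "ACGT"]
            )
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while j < len(lines) and not lines[j].startswith("letter-probability"):
                j += 1
            if j == len(lines):
                raise ValidationError(f"MOTIF {motif_id}: missing probability matrix")
            rows = []
            j += 1
            while j < len(lines) and lines[j]:
                try:
                    rows.append([float(x) for x in lines[j].split()])
                except ValueError:
                    break
                j += 1
            pwms.append(
                Pwm(
                    motif_id=motif_id,
                    probs=np.array(rows, dtype=float),
                    background=background.copy(),
                    pseudocount=pseudocount,
                )
            )
            i = j
            continue
        i += 1
    return pwms


def write_pwms_meme(pwms: Sequence[Pwm], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write(
                "Background letter frequencies\n"
                f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
            )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.length} nsites= 20\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


__all__ = [
    "ParseError",
    "read_peaks",
    "write_peaks",
    "read_gene_models",
    "write_gene_models",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_count_matrix",
    "write_count_matrix",
    "write_fasta",
    "open_fasta",
    "fetch_sequence",
    "read_pwms_jaspar",
    "write_pwms_jaspar",
    "read_pwms_meme",
    "write_pwms_meme",
    "read_gmt",
]
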