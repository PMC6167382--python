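"""PWM scanning over peak sequences and peak-set motif enrichment.

Scanning is exhaustive over both strands of every peak sequence.  The hit
threshold is principled: either an exact score p-value cutoff from the
dynamic-programming null distribution (default 1e-4) or a
fraction-of-maximum score.  Enrichment of a motif in a target peak set
against the all-peaks universe is a hypergeometric upper tail on the count
of peaks with >= 1 hit, BH-adjusted across motifs; the exclusivity filter
keeps motifs significant in exactly one of the two differential peak-set
analyses.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Peak, ValidationError
from .nbglm import bh_adjust
from .pwm import (
    Pwm,
    encode_sequence,
    logodds_matrix,
    max_score,
    threshold_for_pvalue,
)


@dataclass(frozen=True)
class HitPolicy:
    """How a scanning window becomes a motif hit.

    ``score_pvalue``: exact null tail probability cutoff (used when set);
    ``fraction_of_max``: fallback threshold as a fraction of the maximum
    achievable score.
    """

    score_pvalue: float | None = 1e-4
    fraction_of_max: float = 0.8
    scale: int = 1000

    def threshold(self, pwm: Pwm) -> int:
        matrix = logodds_matrix(pwm, self.scale)
        if self.score_pvalue is not None:
            return threshold_for_pvalue(pwm, self.score_pvalue, self.scale)
        return int(np.ceil(self.fraction_of_max * max_score(matrix)))


def scan_sequences(
    sequences: Mapping[str, str],
    pwms: Sequence[Pwm],
    policy: HitPolicy | None = None,
) -> pd.DataFrame:
    """Scan named sequences with every PWM on both strands.

    Returns a DataFrame (motif_id, peak_id, offset, strand, logodds_score)
    with integer-scaled scores; ``offset`` is the 0-based window start on
    the forward sequence for either strand.  Windows containing non-ACGT
    characters never match.
    """
    policy = policy or HitPolicy()
    rows: list[tuple[str, str, int, str, int]] = []
    names = list(sequences)
    if not names:
        return pd.DataFrame(
            columns=["motif_id", "peak_id", "offset", "strand", "logodds_score"]
        )
    # concatenate all sequences with sentinel spacers so one vectorized
    # pass per (motif, strand) covers every peak; windows crossing a
    # boundary contain a sentinel and never match
    max_len = max(len(pwm.probs) for pwm in pwms)
    spacer = np.full(max_len, -1, dtype=np.int64)
    pieces: list[np.ndarray] = []
    starts = np.empty(len(names), dtype=np.int64)
    lengths = np.empty(len(names), dtype=np.int64)
    pos = 0
    for i, name in enumerate(names):
        enc = encode_sequence(sequences[name])
        starts[i] = pos
        lengths[i] = enc.size
        pieces.append(enc)
        pieces.append(spacer)
        pos += enc.size + max_len
    concat = np.concatenate(pieces)
    concat_safe = np.where(concat >= 0, concat, 0)
    bad_csum = np.concatenate([[0], np.cumsum(concat < 0)])
    valid_cache: dict[int, np.ndarray] = {}
    for pwm in pwms:
        thr = policy.threshold(pwm)
        L = pwm.length
        n_win = concat.size - L + 1
        if L not in valid_cache:
            valid_cache[L] = (bad_csum[L:] - bad_csum[:-L]) == 0
        valid = valid_cache[L]
        for strand, mat in (
            ("+", logodds_matrix(pwm, policy.scale)),
            ("-", logodds_matrix(pwm.reverse_complement(), policy.scale)),
        ):
            scores = np.zeros(n_win, dtype=np.int64)
            for k in range(L):
                scores += mat[k][concat_safe[k : k + n_win]]
            hit_pos = np.nonzero(valid & (scores >= thr))[0]
            if hit_pos.size == 0:
                continue
            seq_idx = np.searchsorted(starts, hit_pos, side="right") - 1
            offsets = hit_pos - starts[seq_idx]
            ok = offsets + L <= lengths[seq_idx]
            for p, si, off in zip(hit_pos[ok], seq_idx[ok], offsets[ok]):
                rows.append(
                    (pwm.motif_id, names[si], int(off), strand, int(scores[p]))
                )
    return pd.DataFrame(
        rows, columns=["motif_id", "peak_id", "offset", "strand", "logodds_score"]
    )


def scan_peaks(
    fasta,
    peaks: Sequence[Peak],
    pwms: Sequence[Pwm],
    policy: HitPolicy | None = None,
) -> pd.DataFrame:
    """Extract peak sequences from an indexed FASTA and scan them."""
    from .io import fetch_sequence

    sequences = {p.peak_id: fetch_sequence(fasta, p.interval) for p in peaks}
    return scan_sequences(sequences, pwms, policy)


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif_id: str
    peak_set: str
    n_target: int
    k_target: int
    n_universe: int
    k_universe: int
    fold: float
    p: float
    q: float = float("nan")
    rank: int = 0


def motif_set_enrichment(
    hits: pd.DataFrame,
    target_peaks: Sequence[str],
    universe_peaks: Sequence[str],
    peak_set_name: str = "target",
) -> pd.DataFrame:
    """Hypergeometric enrichment of each motif in ``target_peaks``.

    A peak counts once however many hits it carries.  p = P(X >= k_target)
    for X ~ Hypergeom(N=n_universe, K=k_universe, n=n_target); q is BH
    across motifs; rank orders by ascending p with ties broken by
    descending fold.
    """
    target = set(target_peaks)
    universe = set(universe_peaks)
    if not target <= universe:
        raise ValidationError("target peaks must be a subset of the universe")
    n_t, n_u = len(target), len(universe)
    motif_ids = sorted(hits["motif_id"].unique()) if len(hits) else []
    rows = []
    for motif_id in motif_ids:
        hit_peaks = set(hits.loc[hits["motif_id"] == motif_id, "peak_id"]) & universe
        k_u = len(hit_peaks)
        k_t = len(hit_peaks & target)
        p = float(stats.hypergeom.sf(k_t - 1, n_u, k_u, n_t)) if k_t > 0 else 1.0
        expected = n_t * k_u / n_u if n_u else np.nan
        fold = k_t / expected if expected else float("nan")
        rows.append((motif_id, peak_set_name, n_t, k_t, n_u, k_u, fold, p))
    table = pd.DataFrame(
        rows,
        columns=[
            "motif_id", "peak_set", "n_target", "k_target",
            "n_universe", "k_universe", "fold", "p",
        ],
    )
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        order = table.sort_values(
            ["p", "fold"], ascending=[True, False], kind="mergesort"
        ).index
        ranks = pd.Series(np.arange(1, len(table) + 1), index=order)
        table["rank"] = ranks.reindex(table.index).astype(int)
    else:
        table["q"] = []
        table["rank"] = []
    return table


def exclusivity_filter(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Motifs significant (q < cutoff) in exactly one of two analyses.

    Returns one row per motif: which analyses it was significant in, the
    exclusivity verdict, and its within-analysis ranks.  Both result tables
    must cover the same motif universe.
    """
    motifs_a = set(results_a["motif_id"])
    motifs_b = set(results_b["motif_id"])
    if motifs_a != motifs_b:
        raise ValidationError(
            "exclusivity requires identical motif universes in both analyses"
        )
    a = results_a.set_index("motif_id")
    b = results_b.set_index("motif_id")
    name_a = a["peak_set"].iloc[0] if len(a) else "A"
    name_b = b["peak_set"].iloc[0] if len(b) else "B"
    rows = []
    for motif_id in sorted(motifs_a):
        sig_in = []
        if a.loc[motif_id, "q"] < q_cutoff:
            sig_in.append(name_a)
        if b.loc[motif_id, "q"] < q_cutoff:
            sig_in.append(name_b)
        rows.append(
            {
                "motif_id": motif_id,
                "significant_in": ",".join(sig_in),
                "exclusive": len(sig_in) == 1,
                "exclusive_to": sig_in[0] if len(sig_in) == 1 else "",
                f"rank_{name_a}": int(a.loc[motif_id, "rank"]),
                f"rank_{name_b}": int(b.loc[motif_id, "rank"]),
                f"q_{name_a}": float(a.loc[motif_id, "q"]),
                f"q_{name_b}": float(b.loc[motif_id, "q"]),
            }
        )
    verdicts = pd.DataFrame(rows)
    if len(verdicts):
        # order exclusive motifs by their within-analysis rank
        verdicts["_order"] = [
            (row[f"rank_{name_a}"] if row["exclusive_to"] == name_a else row[f"rank_{name_b}"])
            if row["exclusive"]
            else np.inf
            for row in rows
        ]
        verdicts = (
            verdicts.sort_values(["_order", "motif_id"])
            .drop(columns="_order")
            .reset_index(drop=True)
        )
    return verdicts


def peaks_with_motif(hits: pd.DataFrame, motif_id: str) -> set[str]:
    return set(hits.loc[hits["motif_id"] == motif_id, "peak_id"])


def write_hits_bed(hits: pd.DataFrame, peaks: Sequence[Peak], path) -> None:
    """Export hits as BED6 in genome coordinates (score = scaled log-odds)."""
    peak_lookup = {p.peak_id: p for p in peaks}
    with open(path, "w") as fh:
        for row in hits.itertuples(index=False):
            p = peak_lookup[row.peak_id]
            start = p.start + row.offset
            fh.write(
                f"{p.chrom}\t{start}\t{start + 1}\t{row.motif_id}\t"
                f"{row.logodds_score}\t{row.strand}\n"
            )


__all__ = [
    "HitPolicy",
    "scan_sequences",
    "scan_peaks",
    "MotifEnrichmentResult",
    "motif_set_enrichment",
    "exclusivity_filter",
    "peaks_with_motif",
    "write_hits_bed",
]
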