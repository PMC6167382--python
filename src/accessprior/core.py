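"""Domain types and interval algebra for accessibility analysis.

Coordinates are 0-based, half-open (BED convention) everywhere in the
package; 1-based coordinates appear only in external display formatting.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosomal span ``[start, end)`` with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two half-open intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """An accessibility peak: an interval plus identity and caller score."""

    interval: GenomicInterval
    peak_id: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"peak score must be >= 0, got {self.score}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site.

    ``tss`` is a 0-based position contained in ``span`` (the gene body).
    """

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    strand: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError("gene strand must be '+' or '-'")
        if not (self.span.start <= self.tss < self.span.end):
            raise ValidationError(
                f"TSS {self.tss} outside gene body [{self.span.start}, {self.span.end})"
            )
        if self.chrom != self.span.chrom:
            raise ValidationError("gene chrom differs from span chrom")


class CountMatrix:
    """Non-negative integer counts (features x samples) with a condition sheet."""

    def __init__(
        self,
        counts: np.ndarray | pd.DataFrame,
        feature_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
        conditions: Mapping[str, str] | None = None,
    ) -> None:
        if isinstance(counts, pd.DataFrame):
            feature_ids = list(counts.index) if feature_ids is None else list(feature_ids)
            sample_ids = list(counts.columns) if sample_ids is None else list(sample_ids)
            counts = counts.to_numpy()
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be 2-dimensional")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValidationError("counts must be non-negative integers")
        if feature_ids is None or sample_ids is None:
            raise ValidationError("feature_ids and sample_ids are required")
        feature_ids = [str(f) for f in feature_ids]
        sample_ids = [str(s) for s in sample_ids]
        if len(set(feature_ids)) != len(feature_ids):
            raise ValidationError("feature_ids must be unique")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("sample_ids must be unique")
        if counts.shape != (len(feature_ids), len(sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        conditions = dict(conditions or {})
        missing = [s for s in sample_ids if s not in conditions]
        if missing:
            raise ValidationError(f"samples without a condition: {missing}")
        self.counts = counts.astype(np.int64)
        self.feature_ids = list(feature_ids)
        self.sample_ids = list(sample_ids)
        self.conditions = {s: conditions[s] for s in sample_ids}
        self._feature_index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.feature_ids, columns=self.sample_ids
        )

    def samples_for(self, condition_labels: Iterable[str]) -> list[str]:
        labels = set(condition_labels)
        return [s for s in self.sample_ids if self.conditions[s] in labels]

    def column_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: j for j, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=int)

    def feature_row(self, feature_id: str) -> np.ndarray:
        return self.counts[self._feature_index[feature_id]]

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        idx = [self._feature_index[f] for f in feature_ids]
        return CountMatrix(
            self.counts[idx], list(feature_ids), self.sample_ids, self.conditions
        )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_close_peaks(peaks: Sequence[Peak], max_gap: int = 150) -> list[Peak]:
    """Merge same-chromosome peaks whose edge-to-edge gap is < ``max_gap``.

    The gap between consecutive peaks is ``next.start - prev.end``; peaks
    separated by fewer than ``max_gap`` bp (strict) are united.  The merged
    peak spans min(start)..max(end), carries the maximum member score, and
    keeps the first member's id.  Output is sorted by (chrom, start).
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    merged: list[Peak] = []
    cur = ordered[0]
    cur_members = [cur]
    for p in ordered[1:]:
        if p.chrom == cur.chrom and p.start - cur.end < max_gap:
            new_iv = GenomicInterval(
                cur.chrom, cur.start, max(cur.end, p.end), cur.interval.strand
            )
            cur = Peak(new_iv, cur.peak_id, max(cur.score, p.score))
            cur_members.append(p)
        else:
            merged.append(cur)
            cur = p
            cur_members = [p]
    merged.append(cur)
    return merged


def merge_members(peaks: Sequence[Peak], max_gap: int = 150) -> dict[str, list[str]]:
    """Map each merged peak id to the member peak ids it absorbed.

    Companion to :func:`merge_close_peaks` for aggregating per-peak counts.
    """
    if not peaks:
        return {}
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    groups: dict[str, list[str]] = {}
    cur_id = ordered[0].peak_id
    cur_chrom, cur_end = ordered[0].chrom, ordered[0].end
    groups[cur_id] = [cur_id]
    for p in ordered[1:]:
        if p.chrom == cur_chrom and p.start - cur_end < max_gap:
            groups[cur_id].append(p.peak_id)
            cur_end = max(cur_end, p.end)
        else:
            cur_id, cur_chrom, cur_end = p.peak_id, p.chrom, p.end
            groups[cur_id] = [cur_id]
    return groups


class PeakIndex:
    """Interval-tree index over a peak collection for fast overlap queries."""

    def __init__(self, peaks: Sequence[Peak]) -> None:
        self.peaks = list(peaks)
        self._trees: dict[str, IntervalTree] = {}
        for i, p in enumerate(self.peaks):
            self._trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, i)

    def query(self, window: GenomicInterval) -> list[Peak]:
        """Peaks with >= 1 bp intersection with ``window`` (half-open)."""
        tree = self._trees.get(window.chrom)
        if tree is None:
            return []
        idx = sorted(iv.data for iv in tree.overlap(window.start, window.end))
        return [self.peaks[i] for i in idx]


def overlap_query(peaks: Sequence[Peak], window: GenomicInterval) -> list[Peak]:
    """Peaks overlapping ``window`` by >= 1 bp, in input order."""
    return [p for p in peaks if p.interval.overlaps(window)]


__all__ = [
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "CountMatrix",
    "ValidationError",
    "merge_close_peaks",
    "merge_members",
    "overlap_query",
    "PeakIndex",
]
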