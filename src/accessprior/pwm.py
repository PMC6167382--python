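"""Position weight matrices: log-odds scoring and exact score p-values.

A :class:`Pwm` stores per-position base probabilities over {A, C, G, T} with
a 0-order background.  Scoring converts the matrix to integer-scaled log-odds
so that the null distribution of the total window score can be computed
*exactly* by dynamic-programming convolution of the per-column score
distributions -- no sampling, no Gaussian approximation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ValidationError

ALPHABET = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT index space

BASE_TO_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    BASE_TO_INDEX[ord(_b)] = _i
    BASE_TO_INDEX[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to ACGT indices; non-ACGT characters become -1."""
    return BASE_TO_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(
        np.int64
    )


@dataclass(frozen=True)
class Pwm:
    """A position probability matrix with background and pseudocount.

    ``probs`` has shape (L, 4); each row sums to 1.  ``background`` is the
    0-order genomic base composition the log-odds are taken against.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValidationError("probs must be an L x 4 matrix with L >= 1")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each PWM column must sum to 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValidationError("background must be 4 probabilities summing to 1")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            motif_id=self.motif_id,
            probs=self.probs[::-1, _COMPLEMENT],
            background=self.background[_COMPLEMENT],
            pseudocount=self.pseudocount,
        )

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=1))


def logodds_matrix(pwm: Pwm, scale: int = 1000) -> np.ndarray:
    """Integer-scaled log2-odds matrix, shape (L, 4).

    score(pos, b) = round(scale * log2((p + pseudocount * bg_b) / bg_b)).
    """
    if np.any(pwm.background <= 0):
        raise ValidationError("background frequencies must all be positive")
    with np.errstate(divide="ignore"):
        lods = np.log2((pwm.probs + pwm.pseudocount * pwm.background) / pwm.background)
    return np.round(lods * scale).astype(np.int64)


def max_score(matrix: np.ndarray) -> int:
    """Maximum achievable integer score: sum of per-column maxima."""
    return int(matrix.max(axis=1).sum())


def min_score(matrix: np.ndarray) -> int:
    return int(matrix.min(axis=1).sum())


def score_distribution(matrix: np.ndarray, background: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact null distribution of the total window score.

    Convolves the per-column score distributions of a background-distributed
    k-mer.  Returns ``(pmf, offset)`` where ``pmf[s - offset]`` is the
    probability of total integer score ``s``.
    """
    background = np.asarray(background, dtype=float)
    offset = min_score(matrix)
    span = max_score(matrix) - offset
    pmf = np.zeros(span + 1)
    pmf[0] = 1.0
    for col in matrix:
        new = np.zeros_like(pmf)
        col_min = int(col.min())
        for b in range(4):
            shift = int(col[b]) - col_min
            new[shift:] += background[b] * pmf[: len(pmf) - shift if shift else None]
        pmf = new
    return pmf, offset


def score_pvalue(pwm: Pwm, threshold: int, scale: int = 1000) -> float:
    """P(total score >= threshold) for a background k-mer, exact at integer
    resolution."""
    matrix = logodds_matrix(pwm, scale)
    pmf, offset = score_distribution(matrix, pwm.background)
    idx = threshold - offset
    if idx <= 0:
        return 1.0
    if idx >= len(pmf):
        return 0.0
    return float(pmf[idx:].sum())


def threshold_for_pvalue(pwm: Pwm, alpha: float, scale: int = 1000) -> int:
    """Smallest integer threshold t with P(score >= t) <= alpha."""
    matrix = logodds_matrix(pwm, scale)
    pmf, offset = score_distribution(matrix, pwm.background)
    tail = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
    # tail[i] = P(score >= offset + i); find smallest i with tail <= alpha
    idx = int(np.searchsorted(-tail, -alpha, side="left"))
    return offset + idx


__all__ = [
    "Pwm",
    "ALPHABET",
    "encode_sequence",
    "logodds_matrix",
    "max_score",
    "min_score",
    "score_distribution",
    "score_pvalue",
    "threshold_for_pvalue",
]
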