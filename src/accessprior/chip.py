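"""Efficiency-adjusted ChIP-qPCR fold enrichment over IgG.

Quantification follows the efficiency-aware delta-delta-Ct scheme: each
immunoprecipitate Ct (S) is compared with an input-adjusted Ct (IA), and
the fold enrichment of the specific antibody over the IgG control is

    fold = E^(IA_tf - S_tf) / E^(IA_igg - S_igg)

where E is the primer's per-cycle amplification efficiency (2 = perfect
doubling).  With E = 2 this is exactly the textbook 2^(-ddCt).  The input
adjustment subtracts log_E(1/input_fraction) from the input Ct so that a
10% input aliquot is projected back to 100% of material.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError


@dataclass(frozen=True)
class ChipSample:
    """One qPCR measurement for one locus and antibody.

    ``E`` is the primer efficiency per cycle (~1.7-2.1); ``sample_ct`` the
    immunoprecipitate Ct; ``input_ct`` the Ct of the diluted input aliquot;
    ``input_fraction`` the aliquot's fraction of total chromatin.
    """

    locus_id: str
    antibody: str
    E: float
    sample_ct: float
    input_ct: float
    input_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.E <= 1:
            raise ValidationError(f"primer efficiency must exceed 1, got {self.E}")
        if not (0 < self.input_fraction <= 1):
            raise ValidationError("input_fraction must lie in (0, 1]")
        for name in ("sample_ct", "input_ct"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValidationError(f"{self.locus_id}/{self.antibody}: missing {name}")

    @property
    def input_adjusted_ct(self) -> float:
        return input_adjust(self.input_ct, self.E, self.input_fraction)


def input_adjust(input_ct: float, E: float, input_fraction: float = 0.10) -> float:
    """Input-adjusted Ct: IA = input_ct - log_E(1/input_fraction).

    Projects the diluted input aliquot back to the full amount of
    chromatin; with E = 2 and a 10% input, the offset is log2(10) = 3.32.
    """
    if E <= 1:
        raise ValidationError(f"primer efficiency must exceed 1, got {E}")
    if not (0 < input_fraction <= 1):
        raise ValidationError("input_fraction must lie in (0, 1]")
    return input_ct - math.log(1.0 / input_fraction) / math.log(E)


def fold_enrichment(tf: ChipSample, igg: ChipSample) -> float:
    """Fold enrichment of the TF antibody over IgG at one locus.

    fold = E^(IA-S)_tf / E^(IA-S)_igg, each sample using its own primer
    efficiency (a warning-worthy but tolerated mismatch).
    """
    if tf.locus_id != igg.locus_id:
        raise ValidationError(
            f"fold_enrichment compares one locus, got {tf.locus_id} vs {igg.locus_id}"
        )
    num = tf.E ** (tf.input_adjusted_ct - tf.sample_ct)
    den = igg.E ** (igg.input_adjusted_ct - igg.sample_ct)
    return num / den


def percent_input(sample: ChipSample) -> float:
    """Recovery of the immunoprecipitate as a fraction of total input."""
    return sample.E ** (sample.input_adjusted_ct - sample.sample_ct)


def summarize_replicates(
    folds: np.ndarray | list[float], log_scale: bool = True
) -> dict[str, float]:
    """Mean, SEM, and a one-sample test of fold enrichment against 1.

    The test is a two-tailed one-sample t-test of log(fold) against 0
    (fold ratios are multiplicative); set ``log_scale=False`` for a linear
    test against 1.  With < 2 replicates the summary carries no test and
    is flagged.
    """
    folds = np.asarray(folds, dtype=float)
    n = folds.size
    mean = float(folds.mean()) if n else float("nan")
    sem = float(folds.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
    out = {"n": n, "mean": mean, "sem": sem, "p": float("nan"), "tested": False}
    if n >= 2:
        values = np.log(folds) if log_scale else folds - 1.0
        if np.allclose(values.std(ddof=1), 0.0):
            out["p"] = 1.0 if np.allclose(values.mean(), 0.0) else 0.0
        else:
            t, p = stats.ttest_1samp(values, 0.0)
            out["p"] = float(p)
        out["tested"] = True
    return out


def delta_delta_ct(
    target_ct: float,
    reference_ct: float,
    target_ct_control: float,
    reference_ct_control: float,
    E: float = 2.0,
) -> float:
    """Housekeeping-normalized relative expression (classic ddCt, E fixed
    at 2 by default): E^-((target-ref) - (target_ctrl-ref_ctrl))."""
    ddct = (target_ct - reference_ct) - (target_ct_control - reference_ct_control)
    return E ** (-ddct)


def analyze_chip_table(table: pd.DataFrame, log_scale: bool = True) -> pd.DataFrame:
    """Per-locus fold enrichment from a replicate-level qPCR table.

    Expects columns (locus_id, antibody, replicate, E, Ct_sample, Ct_input,
    input_fraction); ``antibody`` distinguishes the specific antibody
    ("TF") from the "IgG" control within each locus/replicate pair.
    Returns one row per locus with mean fold, SEM, and the one-sample p.
    """
    required = {"locus_id", "antibody", "replicate", "E", "Ct_sample", "Ct_input"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"chip table missing columns: {sorted(missing)}")
    if "input_fraction" not in table.columns:
        table = table.assign(input_fraction=0.10)
    rows = []
    for locus, grp in table.groupby("locus_id"):
        folds = []
        for rep, rep_grp in grp.groupby("replicate"):
            by_ab = {ab: g.iloc[0] for ab, g in rep_grp.groupby("antibody")}
            if "TF" not in by_ab or "IgG" not in by_ab:
                raise ValidationError(
                    f"locus {locus} replicate {rep}: need both TF and IgG rows"
                )
            samples = {
                ab: ChipSample(
                    locus_id=str(locus),
                    antibody=ab,
                    E=float(r["E"]),
                    sample_ct=float(r["Ct_sample"]),
                    input_ct=float(r["Ct_input"]),
                    input_fraction=float(r["input_fraction"]),
                )
                for ab, r in by_ab.items()
            }
            folds.append(fold_enrichment(samples["TF"], samples["IgG"]))
        summary = summarize_replicates(np.array(folds), log_scale=log_scale)
        rows.append({"locus_id": locus, **summary})
    return pd.DataFrame(rows)


__all__ = [
    "ChipSample",
    "input_adjust",
    "fold_enrichment",
    "percent_input",
    "summarize_replicates",
    "delta_delta_ct",
    "analyze_chip_table",
]
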