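"""Knockout-transcriptome intersection for functional target nomination.

Combines two knockout-vs-sham differential expression analyses -- an
"overall" analysis across several patient-derived lines (q < 0.05, any
fold change) and a "migratory" spheroid analysis (q < 0.05 and
|log2FC| > 1) -- takes the genes downregulated in both, and intersects
them with the genes carrying motif-bearing differential accessibility
peaks in their regulatory domains.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import ValidationError


@dataclass
class KoGeneSets:
    """The Venn strata of the knockout integration."""

    overall_de: set[str] = field(default_factory=set)
    migratory_de: set[str] = field(default_factory=set)
    overlap: set[str] = field(default_factory=set)
    downregulated_overlap: set[str] = field(default_factory=set)
    motif_annotated: set[str] = field(default_factory=set)
    final: set[str] | None = None


def ko_de_sets(
    overall_results: pd.DataFrame,
    migratory_results: pd.DataFrame,
    q_cutoff: float = 0.05,
    migratory_lfc_cutoff: float = 1.0,
    downregulated_in: str = "both",
) -> KoGeneSets:
    """Construct the knockout gene sets from two DE result tables.

    ``overall``: q < cutoff, any fold change.  ``migratory``: q < cutoff
    and |log2FC| > cutoff.  ``downregulated_overlap`` keeps overlap members
    with negative fold change in both analyses (``downregulated_in="both"``,
    the conservative reading) or in either (``"either"``).
    """
    for name, table in (("overall", overall_results), ("migratory", migratory_results)):
        dup = table["feature_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"{name} results contain duplicate gene ids after harmonization: "
                f"{sorted(table.loc[dup, 'feature_id'])[:5]}"
            )
    if downregulated_in not in ("both", "either"):
        raise ValidationError("downregulated_in must be 'both' or 'either'")
    ov = overall_results.set_index("feature_id")
    mg = migratory_results.set_index("feature_id")
    overall_de = set(ov.index[ov["q"] < q_cutoff])
    migratory_de = set(
        mg.index[(mg["q"] < q_cutoff) & (mg["log2fc"].abs() > migratory_lfc_cutoff)]
    )
    overlap = overall_de & migratory_de
    down_overall = {g for g in overlap if ov.loc[g, "log2fc"] < 0}
    down_migratory = {g for g in overlap if mg.loc[g, "log2fc"] < 0}
    if downregulated_in == "both":
        down = down_overall & down_migratory
    else:
        down = down_overall | down_migratory
    return KoGeneSets(
        overall_de=overall_de,
        migratory_de=migratory_de,
        overlap=overlap,
        downregulated_overlap=down,
    )


def intersect_with_motif_genes(
    sets: KoGeneSets, motif_annotated: set[str]
) -> KoGeneSets:
    """Complete the Venn: final = downregulated overlap with motif-annotated
    genes (genes having >= 1 motif-bearing differential peak)."""
    sets.motif_annotated = set(motif_annotated)
    sets.final = sets.downregulated_overlap & sets.motif_annotated
    return sets


def venn_membership(sets: KoGeneSets) -> pd.DataFrame:
    """One row per gene with boolean columns for every stratum."""
    if sets.final is None:
        raise ValidationError("run intersect_with_motif_genes first")
    genes = sorted(
        sets.overall_de | sets.migratory_de | sets.motif_annotated
    )
    return pd.DataFrame(
        {
            "gene_id": genes,
            "overall_de": [g in sets.overall_de for g in genes],
            "migratory_de": [g in sets.migratory_de for g in genes],
            "downregulated_overlap": [
                g in sets.downregulated_overlap for g in genes
            ],
            "motif_annotated": [g in sets.motif_annotated for g in genes],
            "final": [g in sets.final for g in genes],
        }
    )


__all__ = ["KoGeneSets", "ko_de_sets", "intersect_with_motif_genes", "venn_membership"]
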