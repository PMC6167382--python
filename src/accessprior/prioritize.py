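"""The TF-candidate decision layer and target nomination.

A motif becomes a selected TF candidate when three conditions conjoin:

1. its enrichment is *exclusive* to the tumor-specific peak-set analysis,
2. its cognate TF gene sits in the top expression quartile genome-wide,
3. that gene is differentially overexpressed in the tumor stem-cell
   fraction (NB Wald p < alpha with positive fold change).

Downstream, putative binding targets are nominated among strongly
overexpressed genes (log2FC above a cutoff) carrying at least one
motif-bearing differential peak in their regulatory domain, ranked by the
number of such peaks and then by best motif score.

Supporting analyses mirror the expression-support arm: paired one-sided
Wilcoxon ordering of gene-family members, Spearman coexpression selection,
and one-tailed Fisher gene-set enrichment on quantile-normalized
expression.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountMatrix, ValidationError
from .nbglm import ContrastSpec, bh_adjust, normalized_log_expression, run_contrast


# ---------------------------------------------------------------------------
# Gates
# ---------------------------------------------------------------------------

def expression_percentile_gate(
    expression_means: pd.Series,
    tf_genes: Sequence[str],
    percentile_cutoff: float = 75.0,
) -> pd.DataFrame:
    """Genome-wide expression percentile per TF gene; pass iff >= cutoff.

    ``expression_means`` must cover the full gene universe: the percentile
    is a rank among *all* genes x 100 / m.  TF genes absent from the table
    are flagged missing and fail.
    """
    m = len(expression_means)
    ranks = pd.Series(
        stats.rankdata(expression_means.to_numpy(), method="average"),
        index=expression_means.index,
    )
    rows = []
    for gene in tf_genes:
        if gene in ranks.index:
            pct = float(ranks[gene] * 100.0 / m)
            rows.append((gene, pct, pct >= percentile_cutoff, False))
        else:
            rows.append((gene, float("nan"), False, True))
    return pd.DataFrame(
        rows, columns=["gene_id", "percentile", "passed", "missing"]
    ).set_index("gene_id")


def overexpression_gate(
    counts: CountMatrix,
    tf_genes: Sequence[str],
    condition_a: str = "E+",
    condition_b: str = "E-",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential-overexpression gate: NB Wald on the full matrix, pass
    iff the TF gene has p < alpha with log2FC > 0 toward condition A."""
    contrast = ContrastSpec("overexpression", (condition_a,), (condition_b,))
    _, table = run_contrast(counts, contrast)
    table = table.set_index("feature_id")
    rows = []
    for gene in tf_genes:
        if gene in table.index:
            p = float(table.loc[gene, "p"])
            lfc = float(table.loc[gene, "log2fc"])
            rows.append((gene, lfc, p, p < alpha and lfc > 0, False))
        else:
            rows.append((gene, float("nan"), float("nan"), False, True))
    return pd.DataFrame(
        rows, columns=["gene_id", "log2fc", "p", "passed", "missing"]
    ).set_index("gene_id")


def select_candidates(
    verdicts: pd.DataFrame,
    enrichment_target: pd.DataFrame,
    percentile_gate: pd.DataFrame,
    overexpression: pd.DataFrame,
    motif_gene_map: Mapping[str, str],
    target_set_name: str = "tumor_specific",
) -> pd.DataFrame:
    """Conjoin exclusivity and both expression gates into an audit table.

    One row per motif, ordered by enrichment rank in the target analysis;
    ``selected`` is True only for motifs exclusive to ``target_set_name``
    whose cognate gene passes both gates.  Motifs without a cognate gene
    mapping are retained with an audit note and never selected.
    """
    ranks = enrichment_target.set_index("motif_id")["rank"]
    v = verdicts.set_index("motif_id")
    rows = []
    for motif_id in v.index:
        gene = motif_gene_map.get(motif_id)
        exclusive = bool(v.loc[motif_id, "exclusive"])
        exclusive_to = v.loc[motif_id, "exclusive_to"]
        entry = {
            "motif_id": motif_id,
            "gene_id": gene if gene else "",
            "enrichment_rank": int(ranks.get(motif_id, 0)),
            "exclusive": exclusive,
            "exclusive_to": exclusive_to,
            "expression_percentile": float("nan"),
            "percentile_pass": False,
            "overexpression_lfc": float("nan"),
            "overexpression_p": float("nan"),
            "overexpression_pass": False,
            "selected": False,
            "fail_reason": "",
        }
        reasons = []
        if gene is None:
            reasons.append("no cognate gene mapping")
        else:
            if gene in percentile_gate.index:
                entry["expression_percentile"] = float(
                    percentile_gate.loc[gene, "percentile"]
                )
                entry["percentile_pass"] = bool(percentile_gate.loc[gene, "passed"])
            if gene in overexpression.index:
                entry["overexpression_lfc"] = float(overexpression.loc[gene, "log2fc"])
                entry["overexpression_p"] = float(overexpression.loc[gene, "p"])
                entry["overexpression_pass"] = bool(overexpression.loc[gene, "passed"])
        if not (exclusive and exclusive_to == target_set_name):
            reasons.append("not exclusive to " + target_set_name)
        if gene is not None and not entry["percentile_pass"]:
            reasons.append("below expression percentile gate")
        if gene is not None and not entry["overexpression_pass"]:
            reasons.append("not differentially overexpressed")
        entry["selected"] = not reasons
        entry["fail_reason"] = "; ".join(reasons)
        rows.append(entry)
    table = pd.DataFrame(rows).sort_values(
        ["enrichment_rank", "motif_id"], kind="mergesort"
    )
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Target nomination
# ---------------------------------------------------------------------------

def nominate_targets(
    de_table: pd.DataFrame,
    gene_motif_peaks: Mapping[str, Sequence[str]],
    hit_scores: Mapping[str, float],
    log2fc_cutoff: float = 3.0,
) -> pd.DataFrame:
    """Rank putative binding targets of the selected motif.

    ``de_table`` is a per-gene differential result (feature_id, log2fc, q);
    ``gene_motif_peaks`` maps gene_id -> motif-bearing differential peak ids
    in its regulatory domain; ``hit_scores`` maps peak_id -> best motif
    log-odds score in that peak.  Nominated genes have log2FC > cutoff
    (strict) and >= 1 motif-bearing peak; ranking is by peak count
    descending, best score descending, then gene_id.
    """
    lfc = de_table.set_index("feature_id")["log2fc"]
    rows = []
    for gene, peak_ids in gene_motif_peaks.items():
        if not peak_ids or gene not in lfc.index:
            continue
        gene_lfc = float(lfc[gene])
        if gene_lfc <= log2fc_cutoff:
            continue
        best = max(hit_scores.get(pid, float("-inf")) for pid in peak_ids)
        rows.append((gene, len(peak_ids), best, gene_lfc))
    table = pd.DataFrame(
        rows, columns=["gene_id", "n_motif_peaks", "best_motif_score", "log2fc"]
    )
    table = table.sort_values(
        ["n_motif_peaks", "best_motif_score", "gene_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


# ---------------------------------------------------------------------------
# Wilcoxon matched pairs (exact for small n)
# ---------------------------------------------------------------------------

def _signed_rank_distribution(n: int) -> np.ndarray:
    """Null pmf of W+ over ranks 1..n (all 2^n sign assignments), by DP."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r]
        counts = counts + shifted
    return counts / 2.0**n


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """One-sided (or two-sided) Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped.  For n <= ``exact_max_n`` without tied
    absolute differences the p-value is exact (distribution of W+ over all
    sign assignments); otherwise a continuity-corrected normal
    approximation with tie correction is used.  Returns (W+, p).
    ``alternative='greater'`` tests whether x tends to exceed y.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= exact_max_n and not has_ties:
        pmf = _signed_rank_distribution(n)
        w = int(round(w_plus))
        p_greater = float(pmf[w:].sum())
        p_less = float(pmf[: w + 1].sum())
    else:
        mean = n * (n + 1) / 4.0
        tie_term = sum(
            t**3 - t for t in pd.Series(ranks).value_counts() if t > 1
        )
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
        sd = np.sqrt(var)
        p_greater = float(stats.norm.sf((w_plus - 0.5 - mean) / sd))
        p_less = float(stats.norm.cdf((w_plus + 0.5 - mean) / sd))
    if alternative == "greater":
        return w_plus, min(p_greater, 1.0)
    if alternative == "less":
        return w_plus, min(p_less, 1.0)
    return w_plus, min(1.0, 2.0 * min(p_greater, p_less))


def family_expression_ordering(
    expression: pd.DataFrame, family_genes: Sequence[str]
) -> pd.DataFrame:
    """Pairwise one-sided Wilcoxon matched-pairs tests within a gene family.

    ``expression`` is genes x samples; samples are the matched pairs.  For
    each ordered pair (a, b) the test asks whether a is expressed above b.
    Self-comparisons and all-zero-difference pairs report p = 1 with a
    warning flag.
    """
    if len(family_genes) < 2:
        raise ValidationError("family ordering needs >= 2 members")
    missing = [g for g in family_genes if g not in expression.index]
    if missing:
        raise ValidationError(f"family genes missing from expression: {missing}")
    rows = []
    for a in family_genes:
        for b in family_genes:
            if a == b:
                continue
            xa = expression.loc[a].to_numpy()
            xb = expression.loc[b].to_numpy()
            degenerate = bool(np.all(xa == xb))
            if degenerate:
                w, p = 0.0, 1.0
            else:
                w, p = wilcoxon_signed_rank(xa, xb, alternative="greater")
            rows.append((a, b, w, p, degenerate))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "w_plus", "p_greater", "degenerate"]
    )


# ---------------------------------------------------------------------------
# Coexpression and gene-set enrichment
# ---------------------------------------------------------------------------

def coexpression_selection(
    expression: pd.DataFrame,
    anchor_gene: str,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Genes positively coexpressed with an anchor gene.

    Spearman's rho per gene against the anchor (average ranks), two-sided
    p from the t approximation, BH across genes; kept iff rho > 0 and
    q < cutoff.  Requires >= 10 samples and a non-constant anchor.
    """
    if anchor_gene not in expression.index:
        raise ValidationError(f"anchor gene {anchor_gene!r} not in expression")
    n = expression.shape[1]
    if n < 10:
        raise ValidationError("coexpression selection requires >= 10 samples")
    anchor = expression.loc[anchor_gene].to_numpy(dtype=float)
    if np.allclose(anchor.std(), 0.0):
        raise ValidationError("anchor gene has zero variance")
    others = expression.drop(index=anchor_gene)
    ranks = np.apply_along_axis(stats.rankdata, 1, others.to_numpy(dtype=float))
    anchor_rank = stats.rankdata(anchor)
    ar = anchor_rank - anchor_rank.mean()
    mat = ranks - ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((mat**2).sum(axis=1) * (ar**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (mat @ ar) / denom, 0.0)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, 0.0, 1.0)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"gene_id": others.index, "rho": rho, "p": p, "q": q}
    )
    table["selected"] = (table["rho"] > 0) & (table["q"] < q_cutoff)
    return table.reset_index(drop=True)


def fisher_gene_set(
    selected: set[str] | Sequence[str],
    gene_set: set[str] | Sequence[str],
    universe: set[str] | Sequence[str],
) -> tuple[float, float]:
    """One-tailed Fisher enrichment of ``gene_set`` within ``selected``.

    Upper-tail hypergeometric p on the 2x2 (in-selected x in-set) table
    over ``universe``; returns (odds ratio, p).
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("universe must be non-empty")
    selected = set(selected) & universe
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValidationError("gene_set must be contained in the universe")
    a = len(selected & gene_set)
    b = len(selected - gene_set)
    c = len(gene_set - selected)
    d = len(universe - selected - gene_set)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def fisher_gene_sets(
    selected: set[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Fisher enrichment across several gene sets, BH-adjusted."""
    rows = [
        (name, *fisher_gene_set(selected, genes, universe))
        for name, genes in gene_sets.items()
    ]
    table = pd.DataFrame(rows, columns=["set_name", "odds_ratio", "p"])
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table


# ---------------------------------------------------------------------------
# Expression-matrix preprocessing (TCGA-style)
# ---------------------------------------------------------------------------

def log2_quantile_normalize(expression: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) then quantile normalization across samples.

    Each sample's sorted values are replaced by the mean sorted profile;
    ties within a sample receive the mean of their reference quantiles.
    """
    logged = np.log2(expression.to_numpy(dtype=float) + 1.0)
    order = np.argsort(logged, axis=0, kind="mergesort")
    sorted_vals = np.take_along_axis(logged, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(logged)
    for j in range(logged.shape[1]):
        ranks = stats.rankdata(logged[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, logged.shape[0] + 1), reference)
    return pd.DataFrame(out, index=expression.index, columns=expression.columns)


def residualize_covariates(
    expression: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Remove linear covariate effects (per gene) by least squares.

    ``covariates`` is samples x covariates (numeric); an intercept is
    added, and its contribution (the gene mean) is retained.
    """
    X = np.column_stack(
        [np.ones(len(covariates)), covariates.to_numpy(dtype=float)]
    )
    Y = expression.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted_cov = X[:, 1:] @ beta[1:]
    resid = (Y - fitted_cov).T
    return pd.DataFrame(resid, index=expression.index, columns=expression.columns)


def drop_degenerate_genes(expression: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with missing values or zero variance."""
    mat = expression.to_numpy(dtype=float)
    keep = np.isfinite(mat).all(axis=1) & (np.nanstd(mat, axis=1) > 0)
    return expression.loc[keep]


__all__ = [
    "expression_percentile_gate",
    "overexpression_gate",
    "select_candidates",
    "nominate_targets",
    "wilcoxon_signed_rank",
    "family_expression_ordering",
    "coexpression_selection",
    "fisher_gene_set",
    "fisher_gene_sets",
    "log2_quantile_normalize",
    "residualize_covariates",
    "drop_degenerate_genes",
]
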