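"""End-to-end orchestration: discovery and knockout-integration runs.

``discover`` and ``integrate_ko`` are pure in-memory pipelines over domain
objects; ``run_discovery``/``run_ko_integration`` wrap them with file I/O,
a YAML-driven configuration, per-stage logging, and a reproducibility
manifest (package/library versions, seed, config hash -- deliberately no
wall-clock timestamp, so identical re-runs are byte-identical).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import assign_basal_extension_fast, build_regulatory_domains
from .core import CountMatrix, GeneModel, Peak, merge_close_peaks, merge_members
from .ko import KoGeneSets, intersect_with_motif_genes, ko_de_sets, venn_membership
from .motifs import HitPolicy, exclusivity_filter, motif_set_enrichment, scan_sequences
from .nbglm import ContrastSpec, normalized_log_expression, run_contrast
from .prioritize import (
    expression_percentile_gate,
    nominate_targets,
    overexpression_gate,
    select_candidates,
)
from .pwm import Pwm

log = logging.getLogger("accessprior")

DEFAULT_CONTRASTS = {
    "tumor_specific": {
        "group_a": ["E+GSC"],
        "group_b": ["E-GBM", "E+NSPC"],
        "q_cutoff": 0.05,
        "direction": "greater",
    },
    "developmentally_shared": {
        "group_a": ["E+GSC", "E+NSPC"],
        "group_b": ["E-GBM"],
        "q_cutoff": 0.05,
        "direction": "greater",
    },
    "e_plus_vs_e_minus": {
        "group_a": ["E+"],
        "group_b": ["E-"],
        "q_cutoff": 0.05,
        "direction": "any",
    },
    "ko_overall": {
        "group_a": ["KO"],
        "group_b": ["sham"],
        "q_cutoff": 0.05,
        "direction": "any",
    },
    "ko_migratory": {
        "group_a": ["KO"],
        "group_b": ["sham"],
        "q_cutoff": 0.05,
        "direction": "any",
        "lfc_cutoff": 1.0,
    },
}

DEFAULT_THRESHOLDS = {
    "merge_gap": 150,
    "hit_pvalue": 1e-4,
    "motif_q": 0.05,
    "expr_percentile": 75.0,
    "overexpression_alpha": 0.05,
    "log2fc_cutoff": 3.0,
    "min_motif_score": None,
    "downregulated_in": "both",
}


def contrast_from_dict(name: str, d: Mapping) -> ContrastSpec:
    return ContrastSpec(
        name=name,
        group_a=tuple(d["group_a"]),
        group_b=tuple(d["group_b"]),
        q_cutoff=float(d.get("q_cutoff", 0.05)),
        lfc_cutoff=(None if d.get("lfc_cutoff") is None else float(d["lfc_cutoff"])),
        direction=d.get("direction", "greater"),
    )


@dataclass
class PipelineConfig:
    """File paths, contrast definitions, and thresholds for a run."""

    paths: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=lambda: dict(DEFAULT_CONTRASTS))
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        contrasts = dict(DEFAULT_CONTRASTS)
        contrasts.update(raw.get("contrasts", {}))
        thresholds = dict(DEFAULT_THRESHOLDS)
        thresholds.update(raw.get("thresholds", {}))
        return cls(
            paths=raw.get("paths", {}),
            contrasts=contrasts,
            thresholds=thresholds,
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "results")),
        )

    def to_dict(self) -> dict:
        return {
            "paths": self.paths,
            "contrasts": self.contrasts,
            "thresholds": self.thresholds,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class DiscoveryResult:
    merged_peaks: list[Peak]
    tumor_significant: set[str]
    shared_significant: set[str]
    tumor_table: pd.DataFrame
    shared_table: pd.DataFrame
    hits: pd.DataFrame
    enrichment_tumor: pd.DataFrame
    enrichment_shared: pd.DataFrame
    verdicts: pd.DataFrame
    candidates: pd.DataFrame
    nominated: pd.DataFrame
    expression_table: pd.DataFrame
    motif_annotated: dict[str, list[str]]
    selected_motifs: list[str]


def _peak_sequences(
    genome: Mapping[str, str], peaks: Sequence[Peak]
) -> dict[str, str]:
    seqs = {}
    for p in peaks:
        contig = genome[p.chrom]
        if p.end > len(contig):
            raise ValueError(
                f"peak {p.peak_id} extends past the end of {p.chrom}"
            )
        seqs[p.peak_id] = contig[p.start : p.end]
    return seqs


def discover(
    peaks: Sequence[Peak],
    atac_counts: CountMatrix,
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    pwms: Sequence[Pwm],
    motif_gene_map: Mapping[str, str],
    expression: CountMatrix,
    contrasts: Mapping[str, Mapping] | None = None,
    thresholds: Mapping | None = None,
) -> DiscoveryResult:
    """The discovery pipeline: merge -> contrasts -> scan -> enrichment ->
    exclusivity -> expression gates -> candidate selection -> nomination.

    The "developmentally shared" significant set excludes peaks
    independently called tumor-specific, so the two peak sets partition
    rather than nest (see the methods note).
    """
    cdict = dict(DEFAULT_CONTRASTS)
    if contrasts:
        cdict.update(contrasts)
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    # -- merge close peaks, aggregating member counts ------------------------
    merged = merge_close_peaks(peaks, int(th["merge_gap"]))
    groups = merge_members(peaks, int(th["merge_gap"]))
    if len(merged) != len(peaks):
        frame = atac_counts.to_frame()
        agg = pd.DataFrame(
            {mid: frame.loc[members].sum(axis=0) for mid, members in groups.items()}
        ).T
        agg = agg.loc[[p.peak_id for p in merged]]
        atac_counts = CountMatrix(
            agg, conditions=atac_counts.conditions
        )
    log.info("merge: %d peaks -> %d", len(peaks), len(merged))

    # -- differential accessibility ------------------------------------------
    tumor_spec = contrast_from_dict("tumor_specific", cdict["tumor_specific"])
    shared_spec = contrast_from_dict(
        "developmentally_shared", cdict["developmentally_shared"]
    )
    sig_tumor, tab_tumor = run_contrast(atac_counts, tumor_spec)
    sig_shared_raw, tab_shared = run_contrast(atac_counts, shared_spec)
    sig_shared = sig_shared_raw - sig_tumor
    log.info(
        "contrasts: %d tumor-specific, %d developmentally shared "
        "(%d union-significant before partition)",
        len(sig_tumor), len(sig_shared), len(sig_shared_raw),
    )

    # -- motif scanning and enrichment ---------------------------------------
    policy = HitPolicy(score_pvalue=float(th["hit_pvalue"]))
    hits = scan_sequences(_peak_sequences(genome, merged), pwms, policy)
    universe = [p.peak_id for p in merged]
    enr_tumor = motif_set_enrichment(hits, sorted(sig_tumor), universe, "tumor_specific")
    enr_shared = motif_set_enrichment(
        hits, sorted(sig_shared), universe, "developmentally_shared"
    )
    verdicts = exclusivity_filter(enr_tumor, enr_shared, float(th["motif_q"]))
    log.info("scan: %d hits across %d motifs", len(hits), len(pwms))

    # -- expression gates and candidate selection -----------------------------
    expr_norm = normalized_log_expression(expression)
    cond_a = cdict["e_plus_vs_e_minus"]["group_a"]
    a_samples = expression.samples_for(cond_a)
    means = expr_norm[a_samples].mean(axis=1)
    tf_genes = [motif_gene_map[m] for m in motif_gene_map]
    pct = expression_percentile_gate(means, tf_genes, float(th["expr_percentile"]))
    oe = overexpression_gate(
        expression,
        tf_genes,
        condition_a=cdict["e_plus_vs_e_minus"]["group_a"][0],
        condition_b=cdict["e_plus_vs_e_minus"]["group_b"][0],
        alpha=float(th["overexpression_alpha"]),
    )
    candidates = select_candidates(
        verdicts, enr_tumor, pct, oe, motif_gene_map, "tumor_specific"
    )
    selected = list(candidates.loc[candidates["selected"], "motif_id"])
    log.info("selection: %s", selected or "no candidate passed all gates")

    # -- target nomination -----------------------------------------------------
    expr_spec = contrast_from_dict("e_plus_vs_e_minus", cdict["e_plus_vs_e_minus"])
    _, expr_table = run_contrast(expression, expr_spec)
    domains = build_regulatory_domains(genes, chrom_sizes)
    motif_annotated: dict[str, list[str]] = {}
    nominated = pd.DataFrame(
        columns=["gene_id", "n_motif_peaks", "best_motif_score", "log2fc", "rank"]
    )
    if selected:
        motif_id = selected[0]
        sel_hits = hits[hits["motif_id"] == motif_id]
        if th["min_motif_score"] is not None:
            sel_hits = sel_hits[sel_hits["logodds_score"] >= float(th["min_motif_score"])]
        hit_peaks = set(sel_hits["peak_id"]) & sig_tumor
        carriers = [p for p in merged if p.peak_id in hit_peaks]
        gene_peaks = assign_basal_extension_fast(carriers, domains)
        motif_annotated = {g: sorted(ps) for g, ps in gene_peaks.items() if ps}
        hit_scores = sel_hits.groupby("peak_id")["logodds_score"].max().to_dict()
        nominated = nominate_targets(
            expr_table, motif_annotated, hit_scores, float(th["log2fc_cutoff"])
        )
        log.info(
            "nomination: %d genes with motif-bearing peaks, %d nominated",
            len(motif_annotated), len(nominated),
        )

    return DiscoveryResult(
        merged_peaks=merged,
        tumor_significant=sig_tumor,
        shared_significant=sig_shared,
        tumor_table=tab_tumor,
        shared_table=tab_shared,
        hits=hits,
        enrichment_tumor=enr_tumor,
        enrichment_shared=enr_shared,
        verdicts=verdicts,
        candidates=candidates,
        nominated=nominated,
        expression_table=expr_table,
        motif_annotated=motif_annotated,
        selected_motifs=selected,
    )


def integrate_ko(
    ko_overall: CountMatrix,
    ko_migratory: CountMatrix,
    motif_annotated_genes: set[str],
    contrasts: Mapping[str, Mapping] | None = None,
    thresholds: Mapping | None = None,
) -> tuple[KoGeneSets, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Knockout integration: DE on both datasets, Venn set construction,
    intersection with motif-annotated genes."""
    cdict = dict(DEFAULT_CONTRASTS)
    if contrasts:
        cdict.update(contrasts)
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    overall_spec = contrast_from_dict("ko_overall", cdict["ko_overall"])
    migratory_spec = contrast_from_dict("ko_migratory", cdict["ko_migratory"])
    _, overall_tab = run_contrast(ko_overall, overall_spec)
    _, migratory_tab = run_contrast(ko_migratory, migratory_spec)
    sets = ko_de_sets(
        overall_tab,
        migratory_tab,
        q_cutoff=overall_spec.q_cutoff,
        migratory_lfc_cutoff=migratory_spec.lfc_cutoff or 1.0,
        downregulated_in=th["downregulated_in"],
    )
    sets = intersect_with_motif_genes(sets, motif_annotated_genes)
    log.info(
        "ko integration: overall %d, migratory %d, downregulated overlap %d, final %d",
        len(sets.overall_de), len(sets.migratory_de),
        len(sets.downregulated_overlap), len(sets.final or ()),
    )
    return sets, overall_tab, migratory_tab, venn_membership(sets)


# ---------------------------------------------------------------------------
# File-based entry points
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path: Path, stage: str, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage}\n# config: {cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _manifest(config: PipelineConfig, counts: Mapping[str, int]) -> dict:
    return {
        "accessprior_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "record_counts": dict(counts),
    }


def _load_inputs(config: PipelineConfig):
    from . import io as aio

    paths = config.paths
    peaks = aio.read_peaks(paths["peaks"], paths.get("peaks_dialect", "bed6"))
    counts = aio.read_count_matrix(paths["atac_counts"], paths["atac_conditions"])
    genes = aio.read_gene_models(paths["genes"], paths.get("genes_dialect", "bed6"))
    chrom_sizes = aio.read_chrom_sizes(paths["chrom_sizes"])
    pwm_path = Path(paths["pwms"])
    if pwm_path.suffix in (".meme", ".txt"):
        pwms = aio.read_pwms_meme(pwm_path)
    else:
        pwms = aio.read_pwms_jaspar(pwm_path)
    fasta = aio.open_fasta(paths["genome"])
    genome = {name: str(fasta[name][:]) for name in fasta.keys()}
    expression = aio.read_count_matrix(
        paths["expression_counts"], paths["expression_conditions"]
    )
    mg = pd.read_csv(paths["motif_gene_map"])
    motif_gene_map = dict(zip(mg["motif_id"], mg["gene_id"]))
    return peaks, counts, genome, genes, chrom_sizes, pwms, motif_gene_map, expression


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """File-based discovery run: read inputs, execute, write every
    intermediate table plus a run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = _load_inputs(config)
    result = discover(
        *inputs, contrasts=config.contrasts, thresholds=config.thresholds
    )
    h = config.config_hash()
    _write_table(result.tumor_table, outdir / "differential_tumor_specific.tsv",
                 "differential:tumor_specific", h)
    _write_table(result.shared_table, outdir / "differential_developmentally_shared.tsv",
                 "differential:developmentally_shared", h)
    _write_table(result.hits, outdir / "motif_hits.tsv", "scan", h)
    _write_table(result.enrichment_tumor, outdir / "enrichment_tumor_specific.tsv",
                 "enrichment:tumor_specific", h)
    _write_table(result.enrichment_shared, outdir / "enrichment_developmentally_shared.tsv",
                 "enrichment:developmentally_shared", h)
    _write_table(result.verdicts, outdir / "exclusivity_verdicts.tsv", "exclusivity", h)
    _write_table(result.candidates, outdir / "candidates.tsv", "selection", h)
    _write_table(result.nominated, outdir / "nominated_targets.tsv", "nomination", h)
    _write_table(result.expression_table, outdir / "differential_expression.tsv",
                 "differential:expression", h)
    annot = pd.DataFrame(
        [
            (g, pid)
            for g, pids in sorted(result.motif_annotated.items())
            for pid in pids
        ],
        columns=["gene_id", "peak_id"],
    )
    _write_table(annot, outdir / "motif_annotated_genes.tsv", "annotation", h)
    manifest = _manifest(
        config,
        {
            "peaks": len(result.merged_peaks),
            "tumor_significant": len(result.tumor_significant),
            "shared_significant": len(result.shared_significant),
            "hits": len(result.hits),
            "candidates_selected": int(result.candidates["selected"].sum()),
            "nominated": len(result.nominated),
        },
    )
    (outdir / "manifest_discovery.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return result


def run_ko_integration(config: PipelineConfig) -> KoGeneSets:
    """File-based knockout integration run."""
    from . import io as aio

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = config.paths
    for key in ("ko_overall_counts", "ko_migratory_counts", "motif_annotated"):
        if key not in paths:
            raise FileNotFoundError(f"config paths missing required input {key!r}")
    ko_overall = aio.read_count_matrix(
        paths["ko_overall_counts"], paths["ko_overall_conditions"]
    )
    ko_migratory = aio.read_count_matrix(
        paths["ko_migratory_counts"], paths["ko_migratory_conditions"]
    )
    annot = pd.read_csv(paths["motif_annotated"], sep="\t", comment="#")
    motif_genes = set(annot["gene_id"]) if len(annot) else set()
    sets, overall_tab, migratory_tab, venn = integrate_ko(
        ko_overall, ko_migratory, motif_genes,
        contrasts=config.contrasts, thresholds=config.thresholds,
    )
    h = config.config_hash()
    _write_table(overall_tab, outdir / "differential_ko_overall.tsv",
                 "differential:ko_overall", h)
    _write_table(migratory_tab, outdir / "differential_ko_migratory.tsv",
                 "differential:ko_migratory", h)
    _write_table(venn, outdir / "ko_venn_membership.tsv", "ko_integration", h)
    manifest = _manifest(
        config,
        {
            "overall_de": len(sets.overall_de),
            "migratory_de": len(sets.migratory_de),
            "downregulated_overlap": len(sets.downregulated_overlap),
            "final": len(sets.final or ()),
        },
    )
    (outdir / "manifest_ko.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return sets


__all__ = [
    "PipelineConfig",
    "DiscoveryResult",
    "discover",
    "integrate_ko",
    "run_discovery",
    "run_ko_integration",
    "DEFAULT_CONTRASTS",
    "DEFAULT_THRESHOLDS",
    "contrast_from_dict",
]
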