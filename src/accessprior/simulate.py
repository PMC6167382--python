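"""Seeded generator of a miniature regulatory-genomics study.

The generator emulates the statistical structure the discovery pipeline
assumes, so that every downstream stage can be exercised against known
ground truth without any external download:

* a random 0-order genome over two chromosomes with regularly spaced gene
  models,
* three peak classes -- *developmentally shared* (accessible in both
  stem-cell conditions), *tumor specific* (accessible only in the tumor
  stem-cell condition), and *background* (exchangeable) -- with NB counts
  across three conditions (E+GSC, E+NSPC, E-GBM),
* motif instances of a designated "tumor" PWM planted preferentially into
  tumor-specific peaks and of a "shared" PWM into shared peaks, plus
  unplanted decoy PWMs,
* a gene expression matrix (E+ vs E-) in which exactly one gene -- the
  cognate TF of the tumor PWM -- is both highly expressed and
  differentially overexpressed,
* two knockout-vs-sham expression datasets with a planted downregulated
  target set, a known subset of which carries motif-bearing peaks,
* a ChIP-qPCR Ct table generated from a known true enrichment and primer
  efficiency.

All randomness flows from one root seed through named ``SeedSequence``
spawns, so a fixed configuration reproduces every byte.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CountMatrix, GeneModel, GenomicInterval, Peak
from .pwm import ALPHABET, Pwm, encode_sequence, logodds_matrix, threshold_for_pvalue

CONDITIONS = ("E+GSC", "E+NSPC", "E-GBM")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 8_000_000
    n_peaks_shared: int = 300
    n_peaks_tumor_specific: int = 300
    n_peaks_background: int = 1_400
    peak_length: int = 200
    samples_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"E+GSC": 4, "E+NSPC": 3, "E-GBM": 3}
    )
    nb_dispersion: float = 0.05
    accessibility_log2fc: float = 2.0
    atac_baseline_mean: float = 100.0
    atac_baseline_sigma: float = 0.5
    depth_sigma: float = 0.25
    motif_plant_rate_target: float = 0.65
    motif_plant_rate_background: float = 0.05
    n_decoy_motifs: int = 4
    motif_length: int = 8
    hit_pvalue: float = 1e-4
    n_genes: int = 1_000
    expr_samples_per_condition: int = 3
    expr_dispersion: float = 0.05
    expr_baseline_mean: float = 100.0
    expr_baseline_sigma: float = 1.0
    expr_log2fc_tf: float = 1.5
    n_nominated_genes: int = 10
    nominated_log2fc_min: float = 3.5
    nominated_log2fc_max: float = 5.0
    ko_target_set_size: int = 40
    ko_motif_target_count: int = 12
    ko_log2fc: float = 2.0
    ko_overall_samples: int = 4
    ko_migratory_samples: int = 3
    chip_true_enrichment: float = 8.0
    primer_efficiency: float = 2.0
    chip_noise_sd: float = 0.15
    chip_replicates: int = 6
    chip_igg_percent_input: float = 0.005
    chip_input_ct: float = 24.0

    def __post_init__(self) -> None:
        for rate in (self.motif_plant_rate_target, self.motif_plant_rate_background):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("plant rates must lie in [0, 1]")
        if self.nb_dispersion <= 0 or self.expr_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if not (1.0 < self.primer_efficiency <= 3.0):
            raise ValueError("primer efficiency must exceed 1")


class CapacityError(RuntimeError):
    """Peak or gene demand exceeds what the genome can hold."""


@dataclass
class Truth:
    """Everything the generator planted, for downstream verification."""

    peak_class: dict[str, str]
    peak_owner_gene: dict[str, str]
    planted_instances: list[dict]
    motif_gene_map: dict[str, str]
    tumor_motif: str
    shared_motif: str
    tf_tumor_gene: str
    tf_shared_gene: str
    decoy_genes: dict[str, str]
    nominated_genes: dict[str, int]
    ko_targets: list[str]
    ko_motif_targets: list[str]
    expected_final_intersection: list[str]
    true_size_factors: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class AccessibilityDataset:
    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    peaks: list[Peak]
    counts: CountMatrix
    pwms: list[Pwm]
    truth: Truth


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sharp_pwm(motif_id: str, consensus_idx: np.ndarray, strength: float = 0.85) -> Pwm:
    L = consensus_idx.size
    probs = np.full((L, 4), (1.0 - strength) / 3.0)
    probs[np.arange(L), consensus_idx] = strength
    return Pwm(motif_id=motif_id, probs=probs)


def _make_pwms(config: SimulationConfig, rng: np.random.Generator) -> list[Pwm]:
    L = config.motif_length
    consensi = [rng.integers(0, 4, size=L)]
    # ensure pairwise-distinct consensus sequences so enrichment signals
    # cannot alias between motifs
    while len(consensi) < 2 + config.n_decoy_motifs:
        cand = rng.integers(0, 4, size=L)
        if all(np.sum(cand != c) >= max(3, L // 2) for c in consensi):
            consensi.append(cand)
    names = ["motif_tumor", "motif_shared"] + [
        f"motif_decoy{i + 1}" for i in range(config.n_decoy_motifs)
    ]
    return [_sharp_pwm(n, c) for n, c in zip(names, consensi)]


def _sample_instance(
    pwm: Pwm,
    rng: np.random.Generator,
    threshold: int,
    matrix: np.ndarray | None = None,
    max_tries: int = 50,
) -> np.ndarray:
    """Draw a motif occurrence column-wise from the PWM, conditioned on
    being a genuine match (log-odds score >= the calling threshold)."""
    if matrix is None:
        matrix = logodds_matrix(pwm)
    cum = np.cumsum(pwm.probs, axis=1)
    L = pwm.length
    cols = np.arange(L)
    for _ in range(max_tries):
        u = rng.random(L)
        idx = (u[:, None] > cum).sum(axis=1)
        if int(matrix[cols, idx].sum()) >= threshold:
            return idx
    return np.argmax(pwm.probs, axis=1)  # consensus fallback


def _revcomp_idx(idx: np.ndarray) -> np.ndarray:
    return (3 - idx)[::-1]


def generate_accessibility_dataset(config: SimulationConfig) -> AccessibilityDataset:
    """Genome, gene models, classed peaks, NB counts, PWMs, and truth."""
    (
        rng_genome,
        rng_layout,
        rng_motifs,
        rng_counts,
        rng_plant,
    ) = _streams(config.seed, 5)

    n_peaks = (
        config.n_peaks_shared + config.n_peaks_tumor_specific + config.n_peaks_background
    )
    genes_per_chrom = config.n_genes // config.n_chroms
    spacing = config.chrom_length_bp // (genes_per_chrom + 1)
    if spacing < 8_000:
        raise CapacityError(
            f"gene spacing {spacing} bp too small for basal domains; enlarge "
            "chrom_length_bp or reduce n_genes"
        )
    if n_peaks * (config.peak_length + 800) > config.n_chroms * config.chrom_length_bp:
        raise CapacityError("peak demand exceeds genome capacity")

    # --- genome ------------------------------------------------------------
    genome_idx: dict[str, np.ndarray] = {}
    chrom_sizes: dict[str, int] = {}
    for c in range(config.n_chroms):
        name = f"chr{c + 1}"
        genome_idx[name] = rng_genome.integers(0, 4, size=config.chrom_length_bp).astype(
            np.int8
        )
        chrom_sizes[name] = config.chrom_length_bp

    # --- gene models --------------------------------------------------------
    genes: list[GeneModel] = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for i in range(genes_per_chrom):
            gid = len(genes)
            tss = (i + 1) * spacing + int(rng_layout.integers(-1_000, 1_001))
            strand = "+" if rng_layout.random() < 0.5 else "-"
            # the gene body is 5'-anchored at the TSS so BED round-trips
            # (TSS = start on '+', end-1 on '-') are exact
            if strand == "+":
                span = GenomicInterval(chrom, tss, tss + 2_000, strand)
            else:
                span = GenomicInterval(chrom, tss - 1_999, tss + 1, strand)
            genes.append(
                GeneModel(
                    gene_id=f"g{gid:04d}",
                    symbol=f"G{gid:04d}",
                    chrom=chrom,
                    tss=tss,
                    strand=strand,
                    span=span,
                )
            )

    # --- gene role assignment ------------------------------------------------
    order = rng_layout.permutation(len(genes))
    cursor = 0

    def take(k: int) -> list[GeneModel]:
        nonlocal cursor
        sel = [genes[i] for i in order[cursor : cursor + k]]
        cursor += k
        if len(sel) < k:
            raise CapacityError("not enough genes for the requested roles")
        return sel

    nominated = take(config.n_nominated_genes)
    ko_motif = take(config.ko_motif_target_count)
    n_tumor_extra_owners = max(
        1,
        (config.n_peaks_tumor_specific
         - config.n_nominated_genes * 4
         - config.ko_motif_target_count * 2) // 2,
    )
    tumor_extra = take(n_tumor_extra_owners)
    shared_owners = take(max(1, config.n_peaks_shared // 2))
    tf_tumor, tf_shared = take(2)
    decoy_tf_genes = take(config.n_decoy_motifs)
    ko_plain = take(config.ko_target_set_size - config.ko_motif_target_count)

    # peaks-per-owner for nominated genes follow a skewed profile so target
    # ranking by peak count is non-trivial (one gene far ahead, then a tail)
    nominated_counts = [8, 6, 5, 4, 3, 3, 2, 2, 1, 1]
    if config.n_nominated_genes != len(nominated_counts):
        base = [max(1, 8 - i) for i in range(config.n_nominated_genes)]
        nominated_counts = base

    # --- peak placement -------------------------------------------------------
    peaks: list[Peak] = []
    peak_class: dict[str, str] = {}
    peak_owner: dict[str, str] = {}
    peak_id_iter = iter(f"peak{i:05d}" for i in range(10 * n_peaks))

    def basal_slots(g: GeneModel) -> list[int]:
        if g.strand == "+":
            lo, hi = g.tss - 5_000, g.tss + 1_000
        else:
            lo, hi = g.tss - 1_000, g.tss + 5_000
        lo = max(0, lo) + 150
        hi = min(chrom_sizes[g.chrom], hi) - config.peak_length - 150
        step = config.peak_length + 400
        return list(range(lo, hi, step))

    used_slots: dict[str, set[int]] = {}

    def place_owned(owner: GeneModel, k: int, cls: str) -> None:
        slots = basal_slots(owner)
        free = [s for s in range(len(slots)) if s not in used_slots.setdefault(owner.gene_id, set())]
        if k > len(free):
            raise CapacityError(
                f"gene {owner.gene_id}: cannot hold {k} more peaks in its basal domain"
            )
        chosen = sorted(rng_layout.choice(free, size=k, replace=False))
        used_slots[owner.gene_id].update(chosen)
        for s in chosen:
            pid = next(peak_id_iter)
            iv = GenomicInterval(owner.chrom, slots[s], slots[s] + config.peak_length)
            peaks.append(Peak(iv, pid, 0.0))
            peak_class[pid] = cls
            peak_owner[pid] = owner.gene_id

    # tumor-specific peaks: nominated genes, KO motif targets, then extras
    remaining_tumor = config.n_peaks_tumor_specific
    for g, k in zip(nominated, nominated_counts):
        k = min(k, remaining_tumor)
        place_owned(g, k, "tumor_specific")
        remaining_tumor -= k
    for g in ko_motif:
        k = min(2, remaining_tumor)
        place_owned(g, k, "tumor_specific")
        remaining_tumor -= k
    i = 0
    while remaining_tumor > 0:
        g = tumor_extra[i % len(tumor_extra)]
        place_owned(g, 1, "tumor_specific")
        remaining_tumor -= 1
        i += 1
    # shared peaks: two per owner gene
    remaining_shared = config.n_peaks_shared
    i = 0
    while remaining_shared > 0:
        g = shared_owners[i % len(shared_owners)]
        place_owned(g, 1, "developmentally_shared")
        remaining_shared -= 1
        i += 1
    # background peaks: intergenic slots far from any basal domain, and
    # entirely outside the regulatory reach of knockout-target genes so
    # the planted knockout/motif intersection is well-defined (no
    # background peak can annotate a knockout target by chance)
    bg_needed = config.n_peaks_background
    slot_step = 2_000
    candidates = []
    basal_zones: dict[str, list[tuple[int, int]]] = {}
    ko_ids = {g.gene_id for g in ko_motif} | {g.gene_id for g in ko_plain}
    for g in genes:
        reach = spacing + 2_000 if g.gene_id in ko_ids else 6_000
        basal_zones.setdefault(g.chrom, []).append((g.tss - reach, g.tss + reach))
    for chrom in chrom_sizes:
        zones = sorted(basal_zones.get(chrom, []))
        pos = 1_000
        zi = 0
        while pos + config.peak_length < chrom_sizes[chrom] - 1_000:
            while zi < len(zones) and zones[zi][1] < pos:
                zi += 1
            inside = zi < len(zones) and zones[zi][0] <= pos + config.peak_length
            if not inside:
                candidates.append((chrom, pos))
            pos += slot_step
    if bg_needed > len(candidates):
        raise CapacityError("peak demand exceeds genome capacity")
    chosen = rng_layout.choice(len(candidates), size=bg_needed, replace=False)
    for ci in sorted(chosen):
        chrom, pos = candidates[ci]
        pid = next(peak_id_iter)
        peaks.append(Peak(GenomicInterval(chrom, pos, pos + config.peak_length), pid))
        peak_class[pid] = "background"
    peaks.sort(key=lambda p: (p.chrom, p.start))

    # --- PWMs and motif planting ---------------------------------------------
    pwms = _make_pwms(config, rng_motifs)
    thresholds = {p.motif_id: threshold_for_pvalue(p, config.hit_pvalue) for p in pwms}
    lod_matrices = {p.motif_id: logodds_matrix(p) for p in pwms}
    planted: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    target_class = {"motif_tumor": "tumor_specific", "motif_shared": "developmentally_shared"}

    def free_offset(peak: Peak, L: int) -> int | None:
        # keep planted instances disjoint so one cannot overwrite another
        taken = occupied.setdefault(peak.peak_id, [])
        for _ in range(20):
            off = int(rng_plant.integers(0, len(peak.interval) - L + 1))
            if all(off + L <= s or off >= s + w for s, w in taken):
                taken.append((off, L))
                return off
        return None

    ko_motif_ids = {g.gene_id for g in ko_motif}
    for pwm in pwms:
        for peak in peaks:
            cls = peak_class[peak.peak_id]
            rate = (
                config.motif_plant_rate_target
                if target_class.get(pwm.motif_id) == cls
                else config.motif_plant_rate_background
            )
            if (
                pwm.motif_id == "motif_tumor"
                and peak_owner.get(peak.peak_id) in ko_motif_ids
            ):
                # the designated knockout targets carry the motif by design:
                # the knockout/motif intersection is a planted, known subset
                rate = 1.0
            if rng_plant.random() >= rate:
                continue
            inst = _sample_instance(pwm, rng_plant, thresholds[pwm.motif_id], lod_matrices[pwm.motif_id])
            strand = "+" if rng_plant.random() < 0.5 else "-"
            inst_seq = _revcomp_idx(inst) if strand == "-" else inst
            off = free_offset(peak, pwm.length)
            if off is None:
                continue
            genome_idx[peak.chrom][peak.start + off : peak.start + off + pwm.length] = (
                inst_seq.astype(np.int8)
            )
            planted.append(
                {
                    "motif_id": pwm.motif_id,
                    "peak_id": peak.peak_id,
                    "offset": off,
                    "strand": strand,
                }
            )

    # --- counts ----------------------------------------------------------------
    sample_ids: list[str] = []
    conditions: dict[str, str] = {}
    for cond in CONDITIONS:
        for r in range(config.samples_per_condition[cond]):
            sid = f"{cond}_{r + 1}"
            sample_ids.append(sid)
            conditions[sid] = cond
    n_samples = len(sample_ids)
    base_mean = rng_counts.lognormal(
        np.log(config.atac_baseline_mean), config.atac_baseline_sigma, size=len(peaks)
    )
    fold = np.ones((len(peaks), n_samples))
    mult = 2.0**config.accessibility_log2fc
    cond_of = np.array([conditions[s] for s in sample_ids])
    for i, p in enumerate(peaks):
        cls = peak_class[p.peak_id]
        if cls == "tumor_specific":
            fold[i, cond_of == "E+GSC"] = mult
        elif cls == "developmentally_shared":
            fold[i, np.isin(cond_of, ["E+GSC", "E+NSPC"])] = mult
    depth = rng_counts.lognormal(0.0, config.depth_sigma, size=n_samples)
    mu = base_mean[:, None] * fold * depth[None, :]
    lam = rng_counts.gamma(
        1.0 / config.nb_dispersion, config.nb_dispersion * mu
    )
    counts = rng_counts.poisson(lam)
    cm = CountMatrix(counts, [p.peak_id for p in peaks], sample_ids, conditions)

    # peak scores mimic a caller's enrichment measure: mean accessibility in
    # the most accessible condition
    score_of = (base_mean[:, None] * fold).max(axis=1)
    peaks = [
        Peak(p.interval, p.peak_id, float(np.round(score_of[i], 3)))
        for i, p in enumerate(peaks)
    ]

    base_bytes = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)
    genome = {
        chrom: base_bytes[arr.astype(np.intp)].tobytes().decode("ascii")
        for chrom, arr in genome_idx.items()
    }

    instances_by_gene: dict[str, int] = {}
    for rec in planted:
        if rec["motif_id"] != "motif_tumor":
            continue
        owner = peak_owner.get(rec["peak_id"])
        if owner:
            instances_by_gene[owner] = instances_by_gene.get(owner, 0) + 1
    expected_final = sorted(
        g for g in ko_motif_ids if instances_by_gene.get(g, 0) > 0
    )

    motif_gene_map = {
        "motif_tumor": tf_tumor.gene_id,
        "motif_shared": tf_shared.gene_id,
    }
    for pwm, g in zip(pwms[2:], decoy_tf_genes):
        motif_gene_map[pwm.motif_id] = g.gene_id

    truth = Truth(
        peak_class=peak_class,
        peak_owner_gene=peak_owner,
        planted_instances=planted,
        motif_gene_map=motif_gene_map,
        tumor_motif="motif_tumor",
        shared_motif="motif_shared",
        tf_tumor_gene=tf_tumor.gene_id,
        tf_shared_gene=tf_shared.gene_id,
        decoy_genes={p.motif_id: g.gene_id for p, g in zip(pwms[2:], decoy_tf_genes)},
        nominated_genes={
            g.gene_id: k for g, k in zip(nominated, nominated_counts)
        },
        ko_targets=sorted(g.gene_id for g in ko_motif + ko_plain),
        ko_motif_targets=sorted(ko_motif_ids),
        expected_final_intersection=expected_final,
        true_size_factors=dict(zip(sample_ids, map(float, depth))),
    )
    return AccessibilityDataset(
        genome=genome,
        chrom_sizes=chrom_sizes,
        genes=genes,
        peaks=peaks,
        counts=cm,
        pwms=pwms,
        truth=truth,
    )


def generate_expression_dataset(
    config: SimulationConfig, truth: Truth
) -> CountMatrix:
    """Gene expression counts, conditions E+ vs E-.

    Exactly one gene -- the tumor PWM's cognate TF -- combines a
    top-quartile baseline with positive differential expression toward E+.
    The shared TF and half the decoys are highly expressed but flat; the
    other decoys are differential but lowly expressed.  Nominated target
    genes carry strong (log2FC > 3) overexpression so target nomination has
    something to find.
    """
    rng = _streams(config.seed, 7)[5]
    n = config.n_genes
    gene_ids = [f"g{i:04d}" for i in range(n)]
    base = rng.lognormal(
        np.log(config.expr_baseline_mean), config.expr_baseline_sigma, size=n
    )
    idx = {g: i for i, g in enumerate(gene_ids)}
    hi = float(np.quantile(base, 0.92))
    lo = float(np.quantile(base, 0.15))
    mid = float(np.quantile(base, 0.60))
    lfc = np.zeros(n)
    base[idx[truth.tf_tumor_gene]] = hi
    lfc[idx[truth.tf_tumor_gene]] = config.expr_log2fc_tf
    base[idx[truth.tf_shared_gene]] = hi
    for k, g in enumerate(truth.decoy_genes.values()):
        if k % 2 == 0:
            base[idx[g]] = lo
            lfc[idx[g]] = config.expr_log2fc_tf  # differential but low
        else:
            base[idx[g]] = hi  # high but flat
    span = config.nominated_log2fc_max - config.nominated_log2fc_min
    for j, g in enumerate(sorted(truth.nominated_genes)):
        base[idx[g]] = mid
        lfc[idx[g]] = config.nominated_log2fc_min + span * rng.random()
    # accessibility/expression correspondence: peak-owning genes trend higher
    for g in set(truth.peak_owner_gene.values()):
        if lfc[idx[g]] == 0.0 and base[idx[g]] not in (hi, lo):
            base[idx[g]] *= 2.0
    reps = config.expr_samples_per_condition
    sample_ids = [f"E+_{r + 1}" for r in range(reps)] + [
        f"E-_{r + 1}" for r in range(reps)
    ]
    conditions = {s: ("E+" if s.startswith("E+") else "E-") for s in sample_ids}
    fold = np.ones((n, 2 * reps))
    fold[:, :reps] = 2.0 ** lfc[:, None]
    depth = rng.lognormal(0.0, config.depth_sigma, size=2 * reps)
    mu = base[:, None] * fold * depth[None, :]
    lam = rng.gamma(1.0 / config.expr_dispersion, config.expr_dispersion * mu)
    counts = rng.poisson(lam)
    return CountMatrix(counts, gene_ids, sample_ids, conditions)


def generate_ko_dataset(
    config: SimulationConfig, truth: Truth
) -> tuple[CountMatrix, CountMatrix]:
    """Two knockout-vs-sham count matrices (overall lines; migratory
    spheroids) with the planted target set downregulated in both."""
    rng = _streams(config.seed, 7)[6]
    n = config.n_genes
    gene_ids = [f"g{i:04d}" for i in range(n)]
    idx = {g: i for i, g in enumerate(gene_ids)}
    target_idx = np.array([idx[g] for g in truth.ko_targets])

    def one(reps: int, label: str) -> CountMatrix:
        base = rng.lognormal(
            np.log(config.expr_baseline_mean), config.expr_baseline_sigma, size=n
        )
        base[target_idx] = np.maximum(base[target_idx], config.expr_baseline_mean)
        fold = np.ones((n, 2 * reps))
        fold[target_idx, :reps] = 2.0**-config.ko_log2fc
        sample_ids = [f"{label}_KO_{r + 1}" for r in range(reps)] + [
            f"{label}_sham_{r + 1}" for r in range(reps)
        ]
        conditions = {
            s: ("KO" if "_KO_" in s else "sham") for s in sample_ids
        }
        depth = rng.lognormal(0.0, config.depth_sigma, size=2 * reps)
        mu = base[:, None] * fold * depth[None, :]
        lam = rng.gamma(1.0 / config.expr_dispersion, config.expr_dispersion * mu)
        return CountMatrix(rng.poisson(lam), gene_ids, sample_ids, conditions)

    overall = one(config.ko_overall_samples, "overall")
    migratory = one(config.ko_migratory_samples, "spheroid")
    return overall, migratory


def generate_chip_table(config: SimulationConfig) -> pd.DataFrame:
    """Replicate-level ChIP-qPCR Ct table with known true enrichment.

    Ct values follow Ct = Ct0 - log_E(material): the IgG pulldown recovers
    ``chip_igg_percent_input`` of the input chromatin, the specific
    antibody recovers ``chip_true_enrichment`` times that, and a negative
    control locus has enrichment 1.  Gaussian noise of sd
    ``chip_noise_sd`` cycles is added to every measured Ct.
    """
    rng = _streams(config.seed, 8)[7]
    E = config.primer_efficiency
    log_e = np.log(E)
    rows = []
    loci = {
        "target_locus_1": config.chip_true_enrichment,
        "target_locus_2": config.chip_true_enrichment,
        "negative_control": 1.0,
    }
    for locus, enrichment in loci.items():
        for rep in range(1, config.chip_replicates + 1):
            input_ct = config.chip_input_ct + rng.normal(0.0, config.chip_noise_sd)
            ia_true = config.chip_input_ct - np.log(1.0 / 0.10) / log_e
            s_igg = ia_true - np.log(config.chip_igg_percent_input) / log_e
            s_tf = ia_true - np.log(config.chip_igg_percent_input * enrichment) / log_e
            rows.append(
                {
                    "locus_id": locus,
                    "antibody": "TF",
                    "replicate": rep,
                    "E": E,
                    "Ct_sample": s_tf + rng.normal(0.0, config.chip_noise_sd),
                    "Ct_input": input_ct,
                    "input_fraction": 0.10,
                }
            )
            rows.append(
                {
                    "locus_id": locus,
                    "antibody": "IgG",
                    "replicate": rep,
                    "E": E,
                    "Ct_sample": s_igg + rng.normal(0.0, config.chip_noise_sd),
                    "Ct_input": input_ct,
                    "input_fraction": 0.10,
                }
            )
    return pd.DataFrame(rows)


def write_dataset(dataset: AccessibilityDataset, outdir) -> dict[str, Path]:
    """Write a generated dataset to standard on-disk formats."""
    from . import io as aio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "peaks": outdir / "peaks.bed",
        "genes": outdir / "genes.bed",
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "counts": outdir / "atac_counts.tsv",
        "conditions": outdir / "atac_conditions.csv",
        "pwms": outdir / "motifs.meme",
        "truth": outdir / "truth.json",
    }
    aio.write_fasta(dataset.genome, paths["genome"])
    aio.write_peaks(dataset.peaks, paths["peaks"], dialect="bed6")
    aio.write_gene_models(dataset.genes, paths["genes"])
    aio.write_chrom_sizes(dataset.chrom_sizes, paths["chrom_sizes"])
    aio.write_count_matrix(dataset.counts, paths["counts"], paths["conditions"])
    aio.write_pwms_meme(dataset.pwms, paths["pwms"])
    paths["truth"].write_text(dataset.truth.to_json())
    return paths


__all__ = [
    "SimulationConfig",
    "Truth",
    "AccessibilityDataset",
    "CapacityError",
    "generate_accessibility_dataset",
    "generate_expression_dataset",
    "generate_ko_dataset",
    "generate_chip_table",
    "write_dataset",
    "CONDITIONS",
]
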