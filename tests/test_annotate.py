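"""Regulatory domains, peak-to-gene assignment, and region enrichment."""
import math

import numpy as np
import pandas as pd
import pytest

from accessprior.annotate import (
    BASAL_DOWNSTREAM,
    BASAL_UPSTREAM,
    MAX_EXTENSION,
    assign_basal_extension_fast,
    assign_peaks_to_genes,
    build_regulatory_domains,
    correspondence_table,
    promoter_window,
    region_binomial_enrichment,
)
from accessprior.core import GeneModel, GenomicInterval, Peak, ValidationError


def gene(gid, tss, strand="+", chrom="chr1"):
    return GeneModel(
        gene_id=gid, symbol=gid, chrom=chrom, tss=tss, strand=strand,
        span=GenomicInterval(chrom, max(0, tss - 100), tss + 101, strand),
    )


def peak(start, end, pid=None, chrom="chr1", score=0.0):
    return Peak(GenomicInterval(chrom, start, end), pid or f"p{start}", score)


class TestRegulatoryDomains:
    def test_single_gene_basal_and_capped_extension(self):
        sizes = {"chr1": 2_000_000}
        (dom,) = build_regulatory_domains([gene("g", 10_000)], sizes).values()
        assert (dom.basal.start, dom.basal.end) == (5_000, 11_000)
        assert (dom.extended.start, dom.extended.end) == (0, 1_011_000)

    def test_basal_clipped_at_chromosome_start(self):
        sizes = {"chr1": 100_000}
        (dom,) = build_regulatory_domains([gene("g", 500)], sizes).values()
        assert (dom.basal.start, dom.basal.end) == (0, 1_500)

    def test_minus_strand_basal_is_mirrored(self):
        sizes = {"chr1": 1_000_000}
        (dom,) = build_regulatory_domains([gene("g", 50_000, "-")], sizes).values()
        assert (dom.basal.start, dom.basal.end) == (49_000, 55_000)

    def test_two_close_genes_stop_at_each_others_basal(self):
        sizes = {"chr1": 10_000_000}
        genes = [gene("a", 100_000), gene("b", 120_000)]
        doms = build_regulatory_domains(genes, sizes)
        assert doms["a"].extended.end == doms["b"].basal.start == 115_000
        assert doms["b"].extended.start == doms["a"].basal.end == 101_000

    def test_tss_outside_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            build_regulatory_domains([gene("g", 5_000)], {"chr1": 1_000})

    def test_no_extension_crosses_a_neighbor_basal(self, rng):
        sizes = {"chr1": 5_000_000}
        tsss = np.sort(rng.choice(np.arange(10_000, 4_990_000, 9_000), 40, replace=False))
        genes = [gene(f"g{i}", int(t), rng.choice(["+", "-"])) for i, t in enumerate(tsss)]
        doms = build_regulatory_domains(genes, sizes)
        # structural check: extension bounded by the nearest disjoint basal
        # on each side and by the 1000 kb cap
        for g in genes:
            dom = doms[g.gene_id]
            left = [doms[o.gene_id].basal.end for o in genes
                    if doms[o.gene_id].basal.end <= dom.basal.start]
            right = [doms[o.gene_id].basal.start for o in genes
                     if doms[o.gene_id].basal.start >= dom.basal.end]
            if left:
                assert dom.extended.start >= max(left)
            if right:
                assert dom.extended.end <= min(right)
            assert dom.extended.start >= max(0, dom.basal.start - MAX_EXTENSION)
            assert dom.extended.end <= dom.basal.end + MAX_EXTENSION


class TestAssignment:
    def test_promoter_window_minus_strand_mirroring(self):
        win = promoter_window(gene("g", 100_000, "-"))
        assert (win.start, win.end) == (97_000, 105_000)

    def test_peak_in_basal_assigned_under_both_window_rules(self):
        g = gene("g", 10_000)
        p = peak(6_000, 6_100)
        sizes = {"chr1": 1_000_000}
        for rule in ("basal_extension", "promoter_window"):
            out = assign_peaks_to_genes([p], [g], rule, chrom_sizes=sizes)
            assert list(out["gene_id"]) == ["g"]
        assert out["distance_to_tss"].iloc[0] == 6_050 - 10_000

    @pytest.mark.parametrize("rule", ["basal_extension", "nearest_tss", "promoter_window"])
    def test_rules_match_brute_force_oracle(self, rng, rule):
        sizes = {"chr1": 2_000_000, "chr2": 2_000_000}
        genes = []
        for chrom in sizes:
            tsss = np.sort(rng.choice(np.arange(20_000, 1_980_000, 12_000), 25, replace=False))
            genes += [
                gene(f"{chrom}_g{i}", int(t), rng.choice(["+", "-"]), chrom)
                for i, t in enumerate(tsss)
            ]
        peaks = [
            peak(int(s), int(s) + int(rng.integers(50, 500)), f"pk{i}",
                 chrom=rng.choice(["chr1", "chr2"]))
            for i, s in enumerate(rng.integers(0, 1_990_000, size=500))
        ]
        out = assign_peaks_to_genes(peaks, genes, rule, chrom_sizes=sizes)
        got = set(zip(out["peak_id"], out["gene_id"]))
        doms = build_regulatory_domains(genes, sizes)
        expected = set()
        for p in peaks:
            if rule == "nearest_tss":
                cands = [g for g in genes if g.chrom == p.chrom]
                if cands:
                    best = min(cands, key=lambda g: (abs(p.interval.midpoint - g.tss), g.gene_id))
                    expected.add((p.peak_id, best.gene_id))
            elif rule == "promoter_window":
                for g in genes:
                    if p.interval.overlaps(promoter_window(g)):
                        expected.add((p.peak_id, g.gene_id))
            else:
                for g in genes:
                    if p.interval.overlaps(doms[g.gene_id].extended):
                        expected.add((p.peak_id, g.gene_id))
        assert got == expected

    def test_fast_basal_extension_agrees_with_reference(self, rng):
        sizes = {"chr1": 2_000_000}
        tsss = np.sort(rng.choice(np.arange(20_000, 1_980_000, 15_000), 20, replace=False))
        genes = [gene(f"g{i}", int(t)) for i, t in enumerate(tsss)]
        peaks = [peak(int(s), int(s) + 200, f"pk{i}")
                 for i, s in enumerate(rng.integers(0, 1_990_000, size=300))]
        doms = build_regulatory_domains(genes, sizes)
        ref = assign_peaks_to_genes(peaks, genes, "basal_extension", domains=doms)
        ref_map = {
            g: set(grp["peak_id"]) for g, grp in ref.groupby("gene_id")
        }
        fast = assign_basal_extension_fast(peaks, doms)
        fast = {g: s for g, s in fast.items() if s}
        assert fast == ref_map

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            assign_peaks_to_genes([], [], "closest_enhancer")


class TestCorrespondence:
    def test_max_score_retained_and_side_list_complete(self):
        g1, g2 = gene("g1", 10_000), gene("g2", 500_000)
        peaks = [
            peak(9_000, 9_200, "a", score=5.0),
            peak(10_500, 10_700, "b", score=9.0),
        ]
        table, side = correspondence_table(peaks, [g1, g2], {"g1": 3.3})
        assert list(table["gene_id"]) == ["g1"]
        assert table["max_peak_score"].iloc[0] == 9.0
        assert side == ["g2"]
        assert len(table) + len(side) == 2

    def test_joint_planting_yields_positive_correlation(self, dataset, expression):
        from accessprior.nbglm import normalized_log_expression
        from scipy import stats

        expr = normalized_log_expression(expression)
        means = expr.mean(axis=1).to_dict()
        table, _ = correspondence_table(dataset.peaks, dataset.genes, means)
        rho = stats.spearmanr(table["max_peak_score"], table["mean_expression"]).statistic
        assert rho > 0


class TestRegionBinomial:
    def test_exact_binomial_tail_example(self):
        # engineered layout: one gene whose extended domain covers 1/4 of
        # the genome; 5 of 10 peaks inside
        sizes = {"chr1": 4_044_000}
        doms = build_regulatory_domains([gene("g", 10_000)], sizes)
        dom = doms["g"].extended  # [0, 1_011_000): a quarter of the genome
        assert (dom.end - dom.start) / sizes["chr1"] == pytest.approx(0.25)
        inside = [peak(500_000 + 1_000 * i, 500_000 + 1_000 * i + 200, f"i{i}")
                  for i in range(5)]
        outside = [peak(3_000_000 + 1_000 * i, 3_000_000 + 1_000 * i + 200, f"o{i}")
                   for i in range(5)]
        fold, p = region_binomial_enrichment(inside + outside, doms, ["g"], sizes["chr1"])
        exact = sum(
            math.comb(10, k) * 0.25**k * 0.75 ** (10 - k) for k in range(5, 11)
        )
        assert p == pytest.approx(exact, abs=1e-12)
        assert p == pytest.approx(0.0781, abs=5e-4)
        assert fold == pytest.approx(5 / (10 * 0.25))

    def test_zero_hits_give_p_one(self):
        sizes = {"chr1": 4_044_000}
        doms = build_regulatory_domains([gene("g", 1_011_000)], sizes)
        out = [peak(3_500_000, 3_500_200)]
        _, p = region_binomial_enrichment(out, doms, ["g"], sizes["chr1"])
        assert p == 1.0

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValidationError):
            region_binomial_enrichment([], {}, [], 1000)
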