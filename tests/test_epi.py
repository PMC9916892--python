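"""Hi-C interaction filtering, replicate merging, promoter windows, EPI
calling, and condition-specific EPI sets."""

import pytest

from varlink.core import GenomicInterval
from varlink.epi import (
    Epi,
    Interaction,
    PromoterRegion,
    annotate_anchor_genes,
    call_epis,
    condition_specific_epis,
    filter_interactions,
    merge_replicates,
    promoter_regions,
)
from varlink.genes import GeneRecord


def binp(chrom, start, width=5000):
    return GenomicInterval(chrom, start, start + width)


def inter(c1, s1, c2, s2, reads=20, p=1e-4, width=5000):
    return Interaction(binp(c1, s1, width), binp(c2, s2, width), reads, p)


class TestInteraction:
    def test_anchor_normalization(self):
        it = inter("chr1", 500_000, "chr1", 100_000)
        assert it.anchor1.start == 100_000
        assert it.distance == 400_000

    def test_bin_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Interaction(binp("chr1", 0, 5000), binp("chr1", 50_000, 10_000), 5, 0.5)


class TestFiltering:
    def test_empty(self):
        assert filter_interactions([]) == []

    def test_adjacent_bins_dropped_strict(self):
        assert filter_interactions([inter("chr1", 0, "chr1", 5000)]) == []

    def test_toy_table_hand_enumerated(self):
        rows = [
            inter("chr1", 0, "chr1", 100_000),              # passes all four
            inter("chr1", 0, "chr1", 5_000),                # distance == 5 kb
            inter("chr1", 0, "chr1", 100_000, reads=9),     # too few reads
            inter("chr1", 0, "chr1", 100_000, p=0.02),      # weak p
            inter("chr1", 0, "chr2", 100_000),              # trans
            inter("chr1", 0, "chr1", 11_000_000),           # too far
        ]
        kept = filter_interactions(rows)
        assert kept == [rows[0]]

    def test_idempotent(self):
        rows = [inter("chr1", 0, "chr1", i * 10_000) for i in range(1, 8)]
        once = filter_interactions(rows)
        assert filter_interactions(once) == once


class TestMergeReplicates:
    def test_disjoint_concatenation(self):
        r1 = [inter("chr1", 0, "chr1", 100_000)]
        r2 = [inter("chr1", 0, "chr1", 200_000)]
        merged = merge_replicates(r1, r2)
        assert len(merged) == 2
        assert not any(m.replicate_merged for m in merged)

    def test_shared_pair_counts_sum_p_min(self):
        r1 = [inter("chr1", 0, "chr1", 100_000, reads=6, p=1e-3)]
        r2 = [inter("chr1", 0, "chr1", 100_000, reads=7, p=1e-5)]
        (m,) = merge_replicates(r1, r2)
        assert m.read_count == 13
        assert m.p_value == 1e-5
        assert m.replicate_merged

    def test_width_mismatch(self):
        with pytest.raises(ValueError):
            merge_replicates(
                [inter("chr1", 0, "chr1", 100_000)],
                [inter("chr1", 0, "chr1", 100_000, width=10_000)],
            )


class TestAnchorGenes:
    def _gene(self, symbol, start, end, biotype="protein_coding"):
        return GeneRecord(symbol, GenomicInterval("chr1", start, end), "+", biotype, "fantom5")

    def test_gene_inside_anchor(self):
        it = inter("chr1", 100_000, "chr1", 200_000)
        genes = [self._gene("G", 101_000, 102_000)]
        out = annotate_anchor_genes([it], genes)
        assert out[("chr1", 100_000, 105_000)] == {"G"}

    def test_ten_percent_boundary_long_gene(self):
        it = inter("chr1", 100_000, "chr1", 200_000)
        # 50 kb gene overlapping the 5 kb anchor by 400 bp: 400 < 500 fails
        fail = [self._gene("G", 104_600, 154_600)]
        ok = [self._gene("G", 104_500, 154_500)]  # 500 bp = 10% of the anchor
        assert annotate_anchor_genes([it], fail)[("chr1", 100_000, 105_000)] == set()
        assert annotate_anchor_genes([it], ok)[("chr1", 100_000, 105_000)] == {"G"}

    def test_ten_percent_boundary_short_gene(self):
        it = inter("chr1", 100_000, "chr1", 200_000)
        # 1 kb gene overlapping by exactly 100 bp = 10% of the gene: passes
        genes = [self._gene("G", 104_900, 105_900)]
        assert annotate_anchor_genes([it], genes)[("chr1", 100_000, 105_000)] == {"G"}


class TestPromoters:
    def _gene(self, strand, start=10_000, end=20_000, biotype="protein_coding"):
        return GeneRecord("G", GenomicInterval("chr1", start, end), strand, biotype, "fantom5")

    def test_plus_strand_window(self):
        (p,) = promoter_regions([self._gene("+")])
        assert (p.span.start, p.span.end) == (8_000, 12_000)

    def test_minus_strand_window(self):
        (p,) = promoter_regions([self._gene("-")])
        # tss = 19999; symmetric window covering tss-2000 .. tss+2000
        assert (p.span.start, p.span.end) == (17_999, 22_000)

    def test_clipping(self):
        g = self._gene("+", start=500, end=5_000)
        (p,) = promoter_regions([g], chrom_sizes={"chr1": 2_200})
        assert (p.span.start, p.span.end) == (0, 2_200)

    def test_noncoding_genes_excluded(self):
        assert promoter_regions([self._gene("+", biotype="lncRNA")]) == []


class TestCallEpis:
    peak = GenomicInterval("chr1", 101_000, 102_000)
    prom = PromoterRegion(GenomicInterval("chr1", 201_000, 203_000), "G")

    def test_single_orientation(self):
        it = inter("chr1", 100_000, "chr1", 200_000)
        (e,) = call_epis([it], [self.peak], [self.prom])
        assert e.enhancer_side == 1 and e.promoter_side == 2
        assert e.target_genes == {"G"}

    def test_both_orientations_emitted(self):
        it = inter("chr1", 100_000, "chr1", 200_000)
        peaks = [self.peak, GenomicInterval("chr1", 201_500, 202_000)]
        proms = [self.prom, PromoterRegion(GenomicInterval("chr1", 101_000, 103_000), "H")]
        epis = call_epis([it], peaks, proms)
        assert {(e.enhancer_side, e.promoter_side) for e in epis} == {(1, 2), (2, 1)}

    def test_no_promoter_no_epi(self):
        it = inter("chr1", 100_000, "chr1", 200_000)
        assert call_epis([it], [self.peak], []) == []

    def test_emitted_epis_recheck(self, scenario):
        from varlink.epi import filter_interactions as filt

        epis = call_epis(filt(scenario.interactions["cancer"]), scenario.peaks, scenario.promoters)
        for e in epis:
            assert any(e.enhancer_anchor.overlap_bp(p) >= 1 for p in scenario.peaks)
            assert any(
                e.promoter_anchor.overlap_bp(pr.span) >= 1 for pr in scenario.promoters
            )

    def test_brute_force_oracle(self, scenario):
        """Every (interaction, orientation) pair is checked independently."""
        from varlink.epi import filter_interactions as filt

        kept = filt(scenario.interactions["cancer"])
        epis = call_epis(kept, scenario.peaks, scenario.promoters)
        got = {(e.interaction.bin_pair(), e.enhancer_side) for e in epis}
        expected = set()
        for it in kept:
            for enh, prom in ((1, 2), (2, 1)):
                enh_a = it.anchor1 if enh == 1 else it.anchor2
                prom_a = it.anchor1 if prom == 1 else it.anchor2
                if any(enh_a.overlap_bp(p) >= 1 for p in scenario.peaks) and any(
                    prom_a.overlap_bp(pr.span) >= 1 for pr in scenario.promoters
                ):
                    expected.add((it.bin_pair(), enh))
        assert got == expected


class TestConditionSpecific:
    def _epi(self, it):
        return Epi(it, 1, 2, frozenset({"G"}), (GenomicInterval("chr1", 0, 10),))

    def test_identical_sets_empty(self):
        a = self._epi(inter("chr1", 0, "chr1", 100_000))
        b = self._epi(inter("chr1", 0, "chr1", 100_000))
        assert condition_specific_epis([a], [b]) == []

    def test_extra_pair_returned(self):
        shared = self._epi(inter("chr1", 0, "chr1", 100_000))
        extra = self._epi(inter("chr1", 0, "chr1", 300_000))
        assert condition_specific_epis([shared, extra], [shared]) == [extra]

    def test_identity_is_bin_pair_not_targets(self):
        a = self._epi(inter("chr1", 0, "chr1", 100_000))
        b = Epi(inter("chr1", 0, "chr1", 100_000), 1, 2, frozenset({"OTHER"}),
                (GenomicInterval("chr1", 0, 10),))
        assert condition_specific_epis([a], [b]) == []

    def test_partition_identity(self, scenario):
        from varlink.epi import filter_interactions as filt

        cancer = call_epis(filt(scenario.interactions["cancer"]), scenario.peaks, scenario.promoters)
        normal = call_epis(filt(scenario.interactions["normal"]), scenario.peaks, scenario.promoters)
        specific = condition_specific_epis(cancer, normal)
        cancer_pairs = {e.interaction.bin_pair() for e in cancer}
        normal_pairs = {e.interaction.bin_pair() for e in normal}
        specific_pairs = {e.interaction.bin_pair() for e in specific}
        assert len(specific_pairs) + len(cancer_pairs & normal_pairs) == len(cancer_pairs)
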