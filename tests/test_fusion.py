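"""Fusion filters, breakpoint placement, chimeric products, RNA normalization."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from oncopanel import fusion
from oncopanel import synthetic as syn
from oncopanel.core_io import (
    AssayConfig,
    DomainAnnotation,
    GenomicInterval,
    SvCandidate,
    TranscriptModel,
)
from oncopanel.errors import PlacementError, ProductError


def make_candidate(split=10, disc=10, start_a=100, start_b=5000):
    return SvCandidate(
        end_a=GenomicInterval("1", start_a, start_a + 1, "+"),
        end_b=GenomicInterval("1", start_b, start_b + 1, "+"),
        name="F",
        split_reads=split,
        discordant_reads=disc,
        sv_class="deletion",
    )


class TestReportableRange:
    REGIONS = [("ALK_intron19", GenomicInterval("1", 1000, 2000))]

    def test_end_inside_region(self):
        assert fusion.in_dna_reportable_range(
            make_candidate(start_a=1500), self.REGIONS
        )

    def test_both_ends_outside(self):
        assert not fusion.in_dna_reportable_range(
            make_candidate(start_a=100, start_b=5000), self.REGIONS
        )

    def test_half_open_boundary_abutting(self):
        # end interval [2000, 2001) abuts region [1000, 2000): no overlap
        assert not fusion.in_dna_reportable_range(
            make_candidate(start_a=2000, start_b=5000), self.REGIONS
        )


class TestEvidenceFilter:
    def test_strong_support_passes(self):
        assert fusion.evidence_filter(make_candidate(10, 10))

    def test_no_split_reads_fails(self):
        assert not fusion.evidence_filter(make_candidate(0, 3))

    def test_exact_threshold_inclusive(self):
        config = AssayConfig()
        total = config.fusion_min_support
        assert fusion.evidence_filter(make_candidate(1, total - 1))
        assert not fusion.evidence_filter(make_candidate(1, total - 2))

    def test_monotone_in_support(self):
        for split in range(0, 6):
            for disc in range(0, 6):
                if fusion.evidence_filter(make_candidate(split, disc)):
                    assert fusion.evidence_filter(make_candidate(split + 1, disc))
                    assert fusion.evidence_filter(make_candidate(split, disc + 1))


class TestPlacement:
    def test_intron_breakpoint_five_prime(self, two_exon_plus):
        p = fusion.place_breakpoint(two_exon_plus, 250, fusion.FIVE_PRIME)
        assert p.retained_exons == frozenset({1})
        assert (p.anchor_exon, p.side) == (1, "after_exon")
        assert not p.promoter_retained

    def test_inversion_reverses_walk(self, two_exon_plus):
        p = fusion.place_breakpoint(
            two_exon_plus, 250, fusion.FIVE_PRIME, inverted=True
        )
        assert p.retained_exons == frozenset({2})
        assert (p.anchor_exon, p.side) == (2, "before_exon")

    def test_upstream_breakpoint_retains_promoter_only(self, two_exon_plus):
        p = fusion.place_breakpoint(two_exon_plus, 50, fusion.FIVE_PRIME)
        assert p.promoter_retained
        assert p.retained_exons == frozenset()

    def test_three_prime_retains_suffix(self, two_exon_plus):
        p = fusion.place_breakpoint(two_exon_plus, 250, fusion.THREE_PRIME)
        assert p.retained_exons == frozenset({2})
        assert (p.anchor_exon, p.side) == (2, "before_exon")

    def test_exon_boundary_snaps_to_intron_side(self, two_exon_plus):
        # breakpoint exactly at exon 1 end (200): exon 1 is fully upstream
        p = fusion.place_breakpoint(two_exon_plus, 200, fusion.FIVE_PRIME)
        assert p.retained_exons == frozenset({1})
        # exactly at exon 2 start (300): still only exon 1 upstream
        p2 = fusion.place_breakpoint(two_exon_plus, 300, fusion.FIVE_PRIME)
        assert p2.retained_exons == frozenset({1})

    def test_three_prime_past_transcript_is_placement_error(self, two_exon_plus):
        with pytest.raises(PlacementError):
            fusion.place_breakpoint(two_exon_plus, 450, fusion.THREE_PRIME)

    def test_minus_strand_mirror_symmetry(self):
        """Reflecting coordinates and flipping strand mirrors the placement."""
        plus = syn.toy_transcript("P", strand="+", n_exons=3, offset=1000, seed=4)
        span_hi = 10_000
        minus_exons = tuple(
            GenomicInterval("1", span_hi - e.end, span_hi - e.start)
            for e in reversed(plus.exons)
        )
        minus = TranscriptModel(
            gene_id="M", transcript_id="M-201", strand="-",
            exons=minus_exons,
            cds_start=minus_exons[0].start, cds_end=minus_exons[-1].end,
        )
        bp = 1000 + 90 + 50  # inside intron 1 of the plus-strand gene
        p_plus = fusion.place_breakpoint(plus, bp, fusion.FIVE_PRIME)
        p_minus = fusion.place_breakpoint(minus, span_hi - bp, fusion.FIVE_PRIME)
        # retained exon sets map onto each other under the reflection
        n = len(plus.exons)
        mirrored = frozenset(n + 1 - i for i in p_plus.retained_exons)
        assert p_minus.retained_exons == mirrored

    def test_placement_matches_generator_truth_100_cases(self):
        rng = np.random.default_rng(12)
        matches = 0
        for case in range(100):
            t5 = syn.toy_transcript("G5", n_exons=4, offset=1_000, seed=case)
            t3 = syn.toy_transcript("G3", n_exons=4, offset=100_000, seed=case + 1)
            inversion = bool(rng.integers(2))
            intron5 = int(rng.integers(0, 3))
            intron3 = int(rng.integers(0, 3))
            bp5 = t5.exons[intron5].end + 50
            bp3 = t3.exons[intron3].end + 50
            sim = syn.simulate_fusion_case(t5, t3, bp5, bp3, inversion=inversion)
            p5 = fusion.place_breakpoint(t5, bp5, fusion.FIVE_PRIME)
            p3 = fusion.place_breakpoint(
                t3, bp3, fusion.THREE_PRIME, inverted=inversion
            )
            if (
                p5.retained_exons == sim.truth_5p.retained_exons
                and p5.anchor_exon == sim.truth_5p.anchor_exon
                and p3.retained_exons == sim.truth_3p.retained_exons
                and p3.anchor_exon == sim.truth_3p.anchor_exon
            ):
                matches += 1
        assert matches == 100


def _toy_gene(gene_id, cds, offset, n_utr5=0):
    """Single-exon gene whose CDS is ``cds`` with optional 5' UTR pad."""
    seq = "T" * n_utr5 + cds
    return TranscriptModel(
        gene_id=gene_id, transcript_id=f"{gene_id}-201", strand="+",
        exons=(GenomicInterval("1", offset, offset + len(seq)),),
        cds_start=offset + n_utr5, cds_end=offset + len(seq),
        promoter=GenomicInterval("1", offset - 100, offset),
        protein_id=f"{gene_id}-P", exon_sequences=(seq,),
    )


class TestChimericProduct:
    def test_in_frame_manual_translation(self):
        # 5' donates codons for "MA"; 3' donates codons for "KR" then stop
        t5 = TranscriptModel(
            gene_id="A", transcript_id="A-1", strand="+",
            exons=(GenomicInterval("1", 100, 106), GenomicInterval("1", 200, 206)),
            cds_start=100, cds_end=206,
            promoter=GenomicInterval("1", 0, 100),
            exon_sequences=("ATGGCC", "AAAAAA"),
        )
        t3 = TranscriptModel(
            gene_id="B", transcript_id="B-1", strand="+",
            exons=(GenomicInterval("1", 5000, 5006), GenomicInterval("1", 5100, 5109)),
            cds_start=5000, cds_end=5109,
            exon_sequences=("ATGCCC", "AAACGTTAA"),
        )
        p5 = fusion.place_breakpoint(t5, 150, fusion.FIVE_PRIME)
        p3 = fusion.place_breakpoint(t3, 5050, fusion.THREE_PRIME)
        product = fusion.build_chimeric_product(p5, p3)
        assert product.frame_status == "in_frame"
        assert product.fused_cds == "ATGGCC" + "AAACGTTAA"
        assert product.fused_protein == "MAKR"
        assert product.junction_aa_position == 2
        assert product.three_prime_first_aa == 3

    def test_out_of_frame_shifted_translation(self):
        # 5' contributes 4 nt of CDS -> frame shift into the 3' suffix
        t5 = _toy_gene("A", "ATGG", 100)
        t3 = _toy_gene("B", "ATGCCC" + "AAACGTTAA", 5000)
        p5 = fusion.place_breakpoint(t5, 104, fusion.FIVE_PRIME)
        p3 = fusion.place_breakpoint(t3, 5000, fusion.THREE_PRIME)
        product = fusion.build_chimeric_product(p5, p3)
        assert product.frame_status == "out_of_frame"
        expected = str(Seq(("ATGG" + "ATGCCCAAACGTTAA")[:18]).translate(to_stop=True))
        assert product.fused_protein == expected

    def test_promoter_swap_yields_native_3prime_orf(self, two_exon_plus):
        t3 = _toy_gene("ERGlike", "ATGAAACGTGGGTAA", 50_000)
        p5 = fusion.place_breakpoint(two_exon_plus, 50, fusion.FIVE_PRIME)
        p3 = fusion.place_breakpoint(t3, 50_000, fusion.THREE_PRIME)
        product = fusion.build_chimeric_product(p5, p3)
        assert product.frame_status == "promoter_swap"
        assert product.fused_protein == "MKRG"

    def test_no_coding_either_side_is_product_error(self):
        t5 = _toy_gene("A", "ATGGCA", 100, n_utr5=0)
        t3 = _toy_gene("B", "ATGTTTTAA", 5000)
        # 3' placement retains the single exon; force a 5'-only-UTR case by
        # taking a 5' breakpoint inside the exon (nothing fully upstream)
        p5 = fusion.BreakpointPlacement(
            transcript=t5, role=fusion.FIVE_PRIME,
            retained_exons=frozenset(), anchor_exon=None, side=None,
            promoter_retained=False,
        )
        p3 = fusion.BreakpointPlacement(
            transcript=t3, role=fusion.THREE_PRIME,
            retained_exons=frozenset(), anchor_exon=None, side=None,
        )
        with pytest.raises(ProductError):
            fusion.build_chimeric_product(p5, p3)

    def test_in_frame_protein_length_identity(self):
        """For in-frame products: len(protein) = 5' codons + 3' codons to stop."""
        rng = np.random.default_rng(3)
        for case in range(20):
            t5 = syn.toy_transcript("G5", n_exons=3, offset=1000, seed=case + 50)
            t3 = syn.toy_transcript("G3", n_exons=3, offset=90_000, seed=case + 90)
            intron5 = int(rng.integers(0, 2))
            intron3 = int(rng.integers(0, 2))
            p5 = fusion.place_breakpoint(
                t5, t5.exons[intron5].end + 10, fusion.FIVE_PRIME
            )
            p3 = fusion.place_breakpoint(
                t3, t3.exons[intron3].end + 10, fusion.THREE_PRIME
            )
            product = fusion.build_chimeric_product(p5, p3)
            if product.frame_status != "in_frame":
                continue
            cds5 = fusion._coding_contribution(p5)
            cds3 = fusion._coding_contribution(p3)
            native_tail = str(Seq(cds3).translate(to_stop=True))
            assert len(product.fused_protein) == len(cds5) // 3 + len(native_tail)


class TestRetainedDomains:
    def _product(self, frame_status, junction=20, first3=30):
        return fusion.ChimericProduct(
            fused_cds="", fused_protein="", frame_status=frame_status,
            junction_aa_position=junction, three_prime_first_aa=first3,
        )

    def test_domain_within_prefix_retained(self):
        d5 = [DomainAnnotation("P5", "kinase", 1, 20)]
        kept5, _ = fusion.retained_domains(self._product("in_frame"), d5, [])
        assert [d.name for d in kept5] == ["kinase"]

    def test_domain_straddling_junction_dropped(self):
        d5 = [DomainAnnotation("P5", "straddle", 15, 25)]
        kept5, _ = fusion.retained_domains(self._product("in_frame"), d5, [])
        assert kept5 == []

    def test_promoter_swap_keeps_all_3prime_domains_only(self):
        d5 = [DomainAnnotation("P5", "x", 1, 5)]
        d3 = [DomainAnnotation("P3", "ets", 10, 50)]
        kept5, kept3 = fusion.retained_domains(
            self._product("promoter_swap"), d5, d3
        )
        assert kept5 == [] and [d.name for d in kept3] == ["ets"]

    def test_out_of_frame_drops_3prime_domains(self):
        d3 = [DomainAnnotation("P3", "late", 40, 60)]
        _, kept3 = fusion.retained_domains(self._product("out_of_frame"), [], d3)
        assert kept3 == []


class TestNormalizeRnaCounts:
    def _frame(self, n_genes=200, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        gc = pd.Series(rng.uniform(0.3, 0.7, n_genes), index=genes)
        length = pd.Series(rng.integers(500, 5000, n_genes), index=genes)
        base = rng.lognormal(5, 1, n_genes)
        return genes, gc, length, base

    def test_doubled_sample_normalizes_to_equal(self):
        genes, gc, length, base = self._frame()
        counts = pd.DataFrame({"s1": base, "s2": 2 * base}, index=genes)
        out = fusion.normalize_rna_counts(counts, gc, length)
        assert np.allclose(out["s1"], out["s2"], rtol=1e-6)
        # median-of-ratios oracle: log size factors are +/- log(sqrt 2)
        logs = np.log(counts.values)
        geomean = logs.mean(axis=1)
        oracle = np.exp(np.median(logs - geomean[:, None], axis=0))
        assert np.allclose(oracle, [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample_single_bin_quantile_identity(self):
        genes = [f"g{i}" for i in range(50)]
        rng = np.random.default_rng(1)
        vals = rng.lognormal(4, 1, 50)
        counts = pd.DataFrame({"s": vals}, index=genes)
        gc = pd.Series(0.5, index=genes)
        length = pd.Series(1000, index=genes)
        out = fusion.normalize_rna_counts(counts, gc, length)
        # constant gc/length -> one bin -> quantile step is the identity;
        # single sample -> size factor 1
        assert np.allclose(out["s"].values, vals)

    def test_monotone_gc_trend_removed(self):
        rng = np.random.default_rng(2)
        n = 500
        genes = [f"g{i}" for i in range(n)]
        gc = pd.Series(np.linspace(0.3, 0.7, n), index=genes)
        length = pd.Series(1000, index=genes)
        base = rng.lognormal(5, 0.3, n)
        biased = base * (1 + 3 * (gc.values - 0.3))  # strong monotone GC trend
        counts = pd.DataFrame({"s": biased}, index=genes)
        out = fusion.normalize_rna_counts(counts, gc, length)
        deciles = pd.qcut(gc, 10, labels=False)
        bin_means = out["s"].groupby(deciles).mean()
        assert bin_means.max() / bin_means.min() < 1.01

    def test_zero_length_gene_rejected(self):
        genes = ["a", "b"]
        counts = pd.DataFrame({"s": [1.0, 2.0]}, index=genes)
        with pytest.raises(Exception):
            fusion.normalize_rna_counts(
                counts,
                pd.Series([0.5, 0.5], index=genes),
                pd.Series([0, 100], index=genes),
            )
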