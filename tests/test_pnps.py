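"""Nei–Gojobori site counting, variant classification, per-gene pN/pS."""

import dataclasses
from fractions import Fraction
from itertools import product

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from viralrp import (
    GeneCall,
    PipelineConfig,
    SnpRecord,
    ValidationError,
    aggregate_selection,
    call_usable_snps,
    classify_variant,
    codon_site_counts,
    compute_pnps,
)

BASES = "ACGT"
SENSE_CODONS = sorted(
    c for c in ("".join(p) for p in product(BASES, repeat=3))
    if str(Seq(c).translate()) != "*"
)


def oracle_site_counts(codon):
    """Independent brute force: classify all 9 single-nucleotide changes."""
    aa = str(Seq(codon).translate())
    syn = 0
    for pos, b in product(range(3), BASES):
        if b == codon[pos]:
            continue
        mutant = codon[:pos] + b + codon[pos + 1:]
        if str(Seq(mutant).translate()) == aa:
            syn += 1
    return Fraction(9 - syn, 3), Fraction(syn, 3)  # (N, S)


class TestCodonSiteCounts:
    @pytest.mark.parametrize("codon, n, s", [
        ("TTT", Fraction(8, 3), Fraction(1, 3)),
        ("ATG", Fraction(3), Fraction(0)),
        ("GGG", Fraction(2), Fraction(1)),
    ])
    def test_frozen_hand_checked_codons(self, codon, n, s):
        counts = codon_site_counts(codon)
        assert (counts.n_sites, counts.s_sites) == (n, s)

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_all_sense_codons_match_brute_force(self, codon):
        counts = codon_site_counts(codon)
        n, s = oracle_site_counts(codon)
        assert (counts.n_sites, counts.s_sites) == (n, s)
        assert counts.n_sites + counts.s_sites == 3

    def test_terminal_stop_excluded(self):
        with_stop = codon_site_counts("ATGTTTGGGTAA")
        without = codon_site_counts("ATGTTTGGG")
        assert (with_stop.n_sites, with_stop.s_sites) == \
               (without.n_sites, without.s_sites)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValidationError, match="internal stop"):
            codon_site_counts("ATGTAAGGG")

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValidationError):
            codon_site_counts("ATGTNTGGG")

    @given(st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=40))
    @settings(max_examples=40, deadline=None)
    def test_conservation_n_plus_s(self, codons):
        counts = codon_site_counts("".join(codons))
        assert counts.n_sites + counts.s_sites == 3 * len(codons)


class TestClassifyVariant:
    @pytest.mark.parametrize("pos, alt, expected", [
        (5, "C", "synonymous"),      # TTT -> TTC, Phe
        (3, "C", "nonsynonymous"),   # TTT -> CTT, Phe -> Leu
        (8, "A", "synonymous"),      # GGG -> GGA, Gly
    ])
    def test_worked_codon_changes(self, pos, alt, expected):
        assert classify_variant("ATGTTTGGG", pos, alt) == expected

    def test_stop_gain_is_nonsynonymous(self):
        # TGG (Trp) -> TGA (stop)
        assert classify_variant("ATGTGG", 5, "A") == "nonsynonymous"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_variant("ATGTTT", 6, "A")

    def test_alt_equal_ref_rejected(self):
        with pytest.raises(ValidationError):
            classify_variant("ATGTTT", 0, "A")


def _gene(contig_seq, start, end, strand="+", gid="g1"):
    return GeneCall(gid, "c1", start, end, strand)


class TestCallUsableSnps:
    CONTIG = "AAAA" + "ATGTTTGGGCCCTAA" + "TTTT"

    def _snp(self, pos, alt=None, coverage=50, alt_count=10):
        ref = self.CONTIG[pos]
        alt = alt or {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        return SnpRecord("c1", pos, ref, alt, coverage, alt_count)

    def test_outside_gene_dropped(self, config):
        gene = _gene(self.CONTIG, 4, 19)
        assert call_usable_snps([self._snp(1)], gene, self.CONTIG, config) == []

    def test_low_alt_reads_dropped(self, config):
        gene = _gene(self.CONTIG, 4, 19)
        assert call_usable_snps([self._snp(7, alt_count=3)], gene,
                                self.CONTIG, config) == []

    def test_multiallelic_keeps_largest_alt_count(self, config):
        gene = _gene(self.CONTIG, 4, 19)
        a = self._snp(7, alt="A", alt_count=6)
        b = self._snp(7, alt="C", alt_count=9)
        kept = call_usable_snps([a, b], gene, self.CONTIG, config)
        assert kept == [b]

    def test_ref_mismatch_is_error(self, config):
        gene = _gene(self.CONTIG, 4, 19)
        bad = SnpRecord("c1", 7, "C", "G", 50, 10)  # contig has T at 7
        with pytest.raises(ValidationError, match="7"):
            call_usable_snps([bad], gene, self.CONTIG, config)

    def test_planted_pass_fail_mix(self, config):
        gene = _gene(self.CONTIG, 4, 19)
        passing = [self._snp(p) for p in (5, 7, 10, 13)]
        failing = [self._snp(8, alt_count=1), self._snp(11, alt_count=2)]
        kept = call_usable_snps(passing + failing, gene, self.CONTIG, config)
        assert kept == sorted(passing, key=lambda s: s.pos)


class TestComputePnps:
    def test_worked_example_exact_rational(self, config):
        # gene ATGTTTGGG: N = 23/3, S = 4/3; one syn + one nonsyn SNP
        contig = "ATGTTTGGGTAA"
        gene = _gene(contig, 0, 12)
        snps = [
            SnpRecord("c1", 5, "T", "C", 50, 10),  # TTT->TTC syn
            SnpRecord("c1", 3, "T", "C", 50, 10),  # TTT->CTT nonsyn
        ]
        result = compute_pnps(gene, snps, contig, config)
        # terminal stop excluded: sites are those of ATGTTTGGG only
        assert result.n_sites == Fraction(23, 3)
        assert result.s_sites == Fraction(4, 3)
        assert (result.n_obs, result.s_obs) == (1, 1)
        assert result.pn == Fraction(3, 23)
        assert result.ps == Fraction(3, 4)
        assert result.ratio == Fraction(4, 23)
        assert float(result.ratio) == pytest.approx(0.1739, abs=1e-4)
        assert result.included and result.exclusion_reason == "none"

    def test_two_synonymous_only_gives_zero_ratio(self, config):
        contig = "ATGTTTGGGTAA"
        gene = _gene(contig, 0, 12)
        snps = [SnpRecord("c1", 5, "T", "C", 50, 10),
                SnpRecord("c1", 8, "G", "A", 50, 10)]
        result = compute_pnps(gene, snps, contig, config)
        assert result.ratio == 0
        assert result.included

    def test_no_snps_excluded(self, config):
        contig = "ATGTTTGGGTAA"
        gene = _gene(contig, 0, 12)
        result = compute_pnps(gene, [], contig, config)
        assert not result.included
        assert result.exclusion_reason == "no_snps"

    def test_low_coverage_excluded(self, config):
        contig = "ATGTTTGGGTAA"
        gene = _gene(contig, 0, 12)
        snps = [SnpRecord("c1", 5, "T", "C", 5, 4)]
        result = compute_pnps(gene, snps, contig, config)
        assert not result.included
        assert result.exclusion_reason == "low_coverage"

    def test_zero_ps_undefined_ratio(self, config):
        contig = "ATGTTTGGGTAA"
        gene = _gene(contig, 0, 12)
        snps = [SnpRecord("c1", 3, "T", "C", 50, 10)]  # nonsyn only
        result = compute_pnps(gene, snps, contig, config)
        assert result.ratio is None
        assert result.exclusion_reason == "zero_ps"

    def test_minus_strand_mirrors_plus_strand(self, config):
        from viralrp.simulate import _revcomp

        plus_contig = "AAGG" + "ATGTTTGGGCCCAGATAA" + "CCTT"
        minus_contig = _revcomp(plus_contig)
        plus_gene = GeneCall("gp", "c1", 4, 22, "+")
        minus_gene = GeneCall("gm", "c1", 4, 22, "-")
        plus_snps = [SnpRecord("c1", 9, "T", "C", 40, 8),   # syn
                     SnpRecord("c1", 10, "G", "T", 40, 8)]  # GGG->TGG nonsyn
        minus_snps = [
            SnpRecord("c1", len(plus_contig) - 1 - s.pos,
                      _revcomp(s.ref_base), _revcomp(s.alt_base),
                      s.coverage, s.alt_count)
            for s in plus_snps
        ]
        rp = compute_pnps(plus_gene, plus_snps, plus_contig, config)
        rm = compute_pnps(minus_gene, minus_snps, minus_contig, config)
        assert (rp.n_obs, rp.s_obs) == (rm.n_obs, rm.s_obs)
        assert (rp.n_sites, rp.s_sites) == (rm.n_sites, rm.s_sites)
        assert rp.ratio == rm.ratio


class TestAggregateSelection:
    def test_arithmetic(self, config):
        results = []
        for i, ratio in enumerate([0.0, 0.1, 0.2, 0.5]):
            results.append(dataclasses.replace(
                _dummy_result(f"g{i}"), ratio=Fraction(ratio).limit_denominator(),
            ))
        summary = aggregate_selection(results)
        assert summary.mean_ratio == pytest.approx(0.2)
        assert summary.frac_le_threshold == pytest.approx(0.75)
        assert summary.n_ratio_defined == 4

    def test_empty_included_set(self):
        summary = aggregate_selection([])
        assert summary.n_genes == 0
        assert summary.mean_ratio is None
        assert summary.frac_le_threshold is None

    def test_undefined_ratios_not_averaged(self):
        defined = dataclasses.replace(_dummy_result("g1"),
                                      ratio=Fraction(1, 2))
        undefined = dataclasses.replace(_dummy_result("g2"), ratio=None,
                                        exclusion_reason="zero_ps")
        summary = aggregate_selection([defined, undefined])
        assert summary.mean_ratio == pytest.approx(0.5)
        assert summary.n_ratio_defined == 1
        assert summary.exclusion_counts["zero_ps"] == 1


def _dummy_result(gene_id):
    from viralrp.pnps import PnpsResult

    return PnpsResult(
        gene_id=gene_id, n_obs=1, s_obs=1, n_sites=Fraction(23, 3),
        s_sites=Fraction(4, 3), mean_coverage=50.0, pn=None, ps=None,
        ratio=None, included=True, exclusion_reason="none",
    )
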