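"""Temperate flagging, spacer matching, k-mer host models."""

import dataclasses
from fractions import Fraction

import numpy as np
import pytest

from viralrp import (
    DomainHit,
    ValidationError,
    ViralContig,
    flag_temperate,
    match_spacers,
    predict_host_kmer,
    predict_hosts,
    score_contig,
    train_kmer_model,
)
from viralrp.hostpred import reverse_complement


def _hit(domain, bit, contig="ctg1"):
    return DomainHit(f"{contig}_1", contig, domain, "PF00589", 1e-10, bit, 1, 80)


class TestFlagTemperate:
    def test_integrase_above_threshold(self, config):
        calls = flag_temperate([_hit("Phage_integrase", 35.0)], config)
        assert calls["ctg1"].temperate
        assert len(calls["ctg1"].evidence) == 1

    def test_integrase_below_threshold(self, config):
        calls = flag_temperate([_hit("Phage_integrase", 25.0)], config)
        assert not calls["ctg1"].temperate

    def test_rp_hits_are_not_lifestyle_evidence(self, config):
        calls = flag_temperate([_hit("Ribosomal_S21", 90.0)], config)
        assert not calls["ctg1"].temperate
        assert calls["ctg1"].evidence == []

    def test_absent_contigs_called_lytic_presumed(self, config):
        calls = flag_temperate([], config, contig_ids=["a", "b"])
        assert set(calls) == {"a", "b"}
        assert not any(c.temperate for c in calls.values())

    def test_monotone_in_bitscore_threshold(self, config):
        hits = [_hit("Phage_integrase", b, contig=f"c{i}")
                for i, b in enumerate([10, 20, 29, 30, 31, 45, 80])]
        counts = []
        for thr in (10, 25, 30, 50, 100):
            cfg = dataclasses.replace(config, lifestyle_bitscore_min=thr)
            calls = flag_temperate(hits, cfg)
            counts.append(sum(c.temperate for c in calls.values()))
        assert counts == sorted(counts, reverse=True)


def _brute_force_matches(spacer, contig_seq, max_mismatch):
    """Independent oracle: scan every placement on both strands."""
    found = []
    for strand, sp in (("+", spacer), ("-", reverse_complement(spacer))):
        for pos in range(len(contig_seq) - len(sp) + 1):
            window = contig_seq[pos:pos + len(sp)]
            mm = sum(a != b or a == "N" for a, b in zip(window, sp))
            if mm <= max_mismatch:
                found.append((pos, strand, mm))
    return sorted(found)


class TestMatchSpacers:
    @pytest.fixture
    def contig(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        return ViralContig("ctg", seq)

    def test_planted_exact_forward_match(self, contig):
        spacer = contig.sequence[100:130]
        (m,) = match_spacers([("h1", spacer)], contig, max_mismatch=0)
        assert (m.host_id, m.position, m.strand, m.mismatches) == \
               ("h1", 100, "+", 0)

    def test_planted_reverse_complement_match(self, contig):
        spacer = reverse_complement(contig.sequence[40:70])
        matches = match_spacers([("h1", spacer)], contig, max_mismatch=0)
        assert any(m.position == 40 and m.strand == "-" for m in matches)

    def test_two_mismatches_exceed_budget(self, contig):
        spacer = list(contig.sequence[200:230])
        spacer[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[spacer[3]]
        spacer[17] = {"A": "C", "C": "A", "G": "T", "T": "G"}[spacer[17]]
        assert match_spacers([("h1", "".join(spacer))], contig,
                             max_mismatch=1) == []

    def test_short_spacer_skipped(self, contig):
        assert match_spacers([("h1", contig.sequence[0:15])], contig,
                             min_len=20) == []

    @pytest.mark.parametrize("max_mismatch", [0, 1, 2])
    def test_equals_brute_force_oracle(self, contig, max_mismatch):
        rng = np.random.default_rng(17)
        spacers = []
        for i in range(5):
            start = int(rng.integers(len(contig.sequence) - 30))
            sp = list(contig.sequence[start:start + 30])
            for _ in range(int(rng.integers(0, 3))):
                j = int(rng.integers(30))
                sp[j] = "ACGT"[int(rng.integers(4))]
            spacers.append(("h", "".join(sp)))
        for _, sp in spacers:
            got = sorted((m.position, m.strand, m.mismatches)
                         for m in match_spacers([("h", sp)], contig,
                                                max_mismatch=max_mismatch))
            assert got == _brute_force_matches(sp, contig.sequence,
                                               max_mismatch)


class TestKmerModel:
    def test_order0_uniform_composition(self):
        model = train_kmer_model("h", "ACGT" * 100, order=0, pseudocount=1.0)
        probs = np.exp(model.log_p[0])
        assert probs == pytest.approx([0.25] * 4, abs=1e-9)

    def test_order0_all_a_both_strand_counts(self):
        # 100 A's forward + 100 T's on the reverse strand, +1 pseudocount each
        model = train_kmer_model("h", "A" * 100, order=0, pseudocount=1.0)
        probs = np.exp(model.log_p[0])
        assert probs[0] == pytest.approx(float(Fraction(101, 204)), abs=1e-12)
        assert probs[3] == pytest.approx(float(Fraction(101, 204)), abs=1e-12)
        assert probs[1] == probs[2] == pytest.approx(float(Fraction(1, 204)),
                                                     abs=1e-12)

    def test_rows_normalized(self):
        rng = np.random.default_rng(0)
        genome = "".join(rng.choice(list("ACGT"), 5000))
        model = train_kmer_model("h", genome, order=3, pseudocount=0.5)
        sums = np.exp(model.log_p).sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_unseen_context_uniform(self):
        model = train_kmer_model("h", "A" * 200, order=4)
        # CCCC never occurs on either strand
        idx = int("".join("1" for _ in range(4)), 4)
        assert np.exp(model.log_p[idx]) == pytest.approx([0.25] * 4, abs=1e-9)

    def test_negative_order_rejected(self):
        with pytest.raises(ValidationError):
            train_kmer_model("h", "ACGT", order=-1)


class TestPredictHostKmer:
    def test_all_n_contig_no_call(self, small_dataset, config):
        models = [train_kmer_model(h, g, 4) for h, g in small_dataset.hosts]
        decoys = [train_kmer_model(h, g, 4)
                  for h, g in small_dataset.decoy_hosts]
        contig = ViralContig("nn", "N" * 500)
        assert score_contig(contig.sequence, models[0]) is None
        assert predict_host_kmer(contig, models, decoys, config) is None

    def test_too_few_decoys_no_call(self, small_dataset, config):
        models = [train_kmer_model(h, g, 4) for h, g in small_dataset.hosts]
        contig = small_dataset.contigs[0]
        assert predict_host_kmer(contig, models, models[:3], config) is None

    def test_true_host_recovered(self, small_dataset, config):
        preds = predict_hosts(
            small_dataset.contigs, small_dataset.hosts, [], config,
            decoy_genomes=small_dataset.decoy_hosts,
        )
        truth = dict(zip(small_dataset.truth_contigs.contig_id,
                         small_dataset.truth_contigs.host_id))
        correct = sum(p.host_id == truth[cid] for cid, p in preds.items())
        assert len(preds) >= 0.8 * len(small_dataset.contigs)
        assert correct >= 0.9 * len(preds)

    def test_spacer_precedence_over_kmer(self, small_dataset, config):
        preds = predict_hosts(
            small_dataset.contigs, small_dataset.hosts,
            small_dataset.spacers, config,
            decoy_genomes=small_dataset.decoy_hosts,
        )
        planted = small_dataset.truth_contigs.query("spacer_planted")
        truth = dict(zip(planted.contig_id, planted.host_id))
        for cid, host in truth.items():
            assert preds[cid].method == "spacer"
            assert preds[cid].host_id == host

    def test_temperate_fraction_recovered(self, small_dataset, config):
        calls = flag_temperate(
            small_dataset.domain_hits, config,
            contig_ids=[c.contig_id for c in small_dataset.contigs],
        )
        truth = dict(zip(small_dataset.truth_contigs.contig_id,
                         small_dataset.truth_contigs.temperate))
        assert all(calls[c].temperate == bool(t) for c, t in truth.items())
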