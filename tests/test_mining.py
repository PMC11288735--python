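"""Seed-and-extend mining and element classification against planted truth."""

import numpy as np
import pytest
from Bio import Align

import centeline as C
from centeline.mining import copy_number
from centeline.seqio import GenomeAssembly, GenomicInterval, revcomp
from centeline.simulate import _random_seq


def _plant(background: str, pos0: int, insert: str) -> GenomeAssembly:
    return GenomeAssembly([("chr1", background[:pos0] + insert + background[pos0:])])


@pytest.fixture(scope="module")
def background():
    rng = np.random.default_rng(42)
    return _random_seq(rng, 60_000, 0.338)


class TestFindCopies:
    def test_single_exact_copy_found_with_exact_boundaries(self, master, background):
        genome = _plant(background, 20_000, master.sequence)
        hits = C.find_element_copies(genome, master.sequence)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (20_001, 20_000 + master.length)
        assert hits[0].strand == "+"

    def test_minus_strand_copy_found(self, master, background):
        genome = _plant(background, 30_000, revcomp(master.sequence))
        hits = C.find_element_copies(genome, master.sequence)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (30_001, 30_000 + master.length)

    def test_diverged_copy_boundaries_within_5bp_of_sw_oracle(self, master, background):
        """A 95%-identity copy is located to within 5 bp of a Smith-Waterman oracle."""
        rng = np.random.default_rng(9)
        copy = list(master.sequence)
        for p in rng.choice(len(copy), size=len(copy) // 20, replace=False):
            copy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[p]]
        copy = "".join(copy)
        genome = _plant(background, 25_000, copy)
        hits = C.find_element_copies(genome, master.sequence)
        assert len(hits) == 1
        # independent local-alignment oracle over the widened region
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score, aligner.mismatch_score = 1, -2
        aligner.open_gap_score, aligner.extend_gap_score = -4, -2
        region = genome.sequence("chr1")[24_000 : 32_000 + master.length]
        aln = aligner.align(region, master.sequence)[0]
        oracle_start = 24_000 + int(aln.aligned[0][0][0]) + 1
        oracle_end = 24_000 + int(aln.aligned[0][-1][1])
        assert abs(hits[0].start - oracle_start) <= 5
        assert abs(hits[0].end - oracle_end) <= 5

    def test_no_hits_in_random_sequence(self, master):
        """Seeded random genomes yield zero hits at default thresholds."""
        anchor = master.sequence[:2816]
        for seed in (101, 102, 103):
            rng = np.random.default_rng(seed)
            genome = GenomeAssembly([("chr1", _random_seq(rng, 300_000, 0.338))])
            assert C.find_element_copies(genome, anchor) == []

    def test_anchor_shorter_than_seed_rejected(self, background):
        genome = GenomeAssembly([("chr1", background)])
        with pytest.raises(ValueError):
            C.find_element_copies(genome, "ACGT", min_seed=13)

    def test_recall_and_precision_on_simulation(self, default_sim, mined):
        """>=95% recall of planted copies and no hits outside the truth set."""
        hits, _ = mined
        truth = default_sim.truth
        recalled = sum(
            1
            for r in truth
            if any(
                h.chrom == r.interval.chrom
                and min(h.end, r.interval.end) - max(h.start, r.interval.start) + 1
                >= 0.5 * r.interval.span
                for h in hits
            )
        )
        assert recalled / len(truth) >= 0.95
        false_hits = [
            h
            for h in hits
            if not any(
                h.chrom == r.interval.chrom
                and min(h.end, r.interval.end) >= max(h.start, r.interval.start)
                for r in truth
            )
        ]
        assert false_hits == []


class TestClassification:
    def test_small_5prime_truncation_is_full_length(self, master, background):
        genome = _plant(background, 20_000, master.sequence[80:])
        hit = GenomicInterval("chr1", 20_001, 20_000 + master.length - 80, "+")
        ann = C.classify_element(hit, genome, master)
        assert ann.element_class == "full_length"
        assert ann.truncation5 == 80

    def test_large_internal_deletion_is_truncated(self, master, background):
        mutant = master.sequence[:2000] + master.sequence[2600:]  # 600 bp removed
        genome = _plant(background, 20_000, mutant)
        hit = GenomicInterval("chr1", 20_001, 20_000 + len(mutant), "+")
        ann = C.classify_element(hit, genome, master)
        assert ann.element_class == "truncated"
        assert ann.internal_deletion >= 500

    def test_piece_without_either_end_is_fragment(self, master, background):
        piece = master.sequence[2500:3500]
        genome = _plant(background, 20_000, piece)
        hit = GenomicInterval("chr1", 20_001, 21_000, "+")
        ann = C.classify_element(hit, genome, master)
        assert ann.element_class == "fragment"

    def test_copy_number_excludes_fragments(self, master, background):
        anns = []
        for piece, start in [
            (master.sequence, 10_000),
            (master.sequence[3000:], 30_000),
            (master.sequence[2500:3500], 50_000),
        ]:
            genome = _plant(background, start, piece)
            hit = GenomicInterval("chr1", start + 1, start + len(piece), "+")
            anns.append(C.classify_element(hit, genome, master))
        assert [a.element_class for a in anns] == ["full_length", "truncated", "fragment"]
        assert copy_number(anns) == 2

    def test_classification_matches_truth_on_simulation(self, default_sim, mined):
        """Mined truncation labels agree with the planted values."""
        hits, anns = mined
        truth_by_pos = {
            (r.interval.chrom, r.interval.start, r.interval.end): r
            for r in default_sim.truth
        }
        checked = 0
        for h, a in zip(hits, anns):
            r = truth_by_pos.get((h.chrom, h.start, h.end))
            if r is None:
                continue
            checked += 1
            expected = "full_length" if r.truncation5 < 100 else "truncated"
            assert a.element_class == expected
            assert abs(a.truncation5 - r.truncation5) <= 5
        assert checked >= 30


class TestOrfIntactness:
    def test_reference_is_intact(self, master):
        assert C.assess_orf_intactness(master.sequence, master) == "intact_both"

    def test_premature_stop_disrupts(self, master):
        s, e = master.orf2
        seq = list(master.sequence)
        # force a TAA at an in-frame codon in the middle of ORF2
        codon_start = s - 1 + 3 * (((e - s + 1) // 3) // 2)
        seq[codon_start : codon_start + 3] = "TAA"
        assert C.assess_orf_intactness("".join(seq), master) == "disrupted"

    def test_frameshift_deletion_disrupts(self, master):
        s, _ = master.orf1
        seq = master.sequence[: s + 50] + master.sequence[s + 51 :]  # 1-bp deletion
        assert C.assess_orf_intactness(seq, master) == "disrupted"

    def test_lost_start_codon_disrupts(self, master):
        s, _ = master.orf1
        seq = list(master.sequence)
        seq[s - 1] = "C"  # ATG -> CTG
        assert C.assess_orf_intactness("".join(seq), master) == "disrupted"

    def test_intact_flags_agree_with_truth(self, default_sim, mined):
        hits, anns = mined
        truth_by_pos = {
            (r.interval.chrom, r.interval.start, r.interval.end): r
            for r in default_sim.truth
        }
        for h, a in zip(hits, anns):
            r = truth_by_pos.get((h.chrom, h.start, h.end))
            if r is not None:
                assert (a.orf_status == "intact_both") == r.intact_orfs
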