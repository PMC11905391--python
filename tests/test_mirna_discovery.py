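"""Folding engine, duplex evaluation, novel calling and re-classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_hairpin
from oracles import max_pairs_by_enumeration
from srnakit.io_formats import reverse_complement
from srnakit.mirna_discovery import (
    DiscoveryParams,
    call_novel_mirnas,
    evaluate_duplex,
    fold_hairpin,
    reclassify_reported_mirna,
)
from srnakit.tag_annotation import map_to_genome

dna = st.text(alphabet="ACGT", min_size=1, max_size=14)


class TestFoldHairpin:
    def test_small_stem(self):
        fold = fold_hairpin("GGGAAAACCC", 3)
        assert fold.score == 3
        assert fold.structure == "(((....)))"

    def test_no_complementarity(self):
        assert fold_hairpin("AAAAAAAAAA", 3).score == 0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fold_hairpin("")
        with pytest.raises(ValueError):
            fold_hairpin("ACGU")
        with pytest.raises(ValueError):
            fold_hairpin("A" * 500)

    def test_matches_enumeration_oracle_on_random_corpus(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(4, 15))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            assert fold_hairpin(seq, 3).score == \
                max_pairs_by_enumeration(seq, 3)

    @settings(deadline=None, max_examples=150)
    @given(dna)
    def test_structure_is_balanced_and_consistent(self, seq):
        fold = fold_hairpin(seq, 3)
        assert len(fold.structure) == len(seq)
        depth = 0
        for ch in fold.structure:
            depth += {"(": 1, ")": -1, ".": 0}[ch]
            assert depth >= 0
        assert depth == 0
        for i, p in enumerate(fold.pairs):
            if p >= 0:
                assert fold.pairs[p] == i and abs(p - i) > 3

    def test_deterministic(self):
        seq = "GCGCAAAUACGCGC".replace("U", "T")
        assert fold_hairpin(seq).structure == fold_hairpin(seq).structure


class TestEvaluateDuplex:
    MATURE = "TACGCATCCTAAGTCGAGTCG"  # 21 nt

    def fold_hairpin_with(self, n_mismatches, seed=5):
        rng = np.random.default_rng(seed)
        prec, off = make_hairpin(rng, self.MATURE, loop_len=14,
                                 n_mismatches=n_mismatches)
        fold = fold_hairpin(prec, 8)
        return fold, off

    def test_perfect_stem(self):
        fold, off = self.fold_hairpin_with(0)
        duplex, reason = evaluate_duplex(fold, off, off + len(self.MATURE))
        assert reason is None
        assert duplex.duplex_mismatches == 0
        assert duplex.duplex_bulges == 0
        assert duplex.pairing_fraction == 1.0
        assert duplex.arm == "5p"
        assert duplex.star_span == len(self.MATURE)

    def test_star_is_offset_reverse_complement(self):
        """On a perfect stem the star is the mature's reverse complement
        shifted by the 2-nt 3' overhangs."""
        fold, off = self.fold_hairpin_with(0)
        duplex, _ = evaluate_duplex(fold, off, off + len(self.MATURE))
        rc = reverse_complement(self.MATURE)
        # star pairs mature[:-2]; its last two bases are the 3' overhang
        assert duplex.star_seq[:-2] == rc[2:]

    def test_planted_mismatches_are_counted(self):
        """Mismatch count equals the unpaired mature positions of the optimal
        fold; three planted substitutions cannot vanish entirely, though the
        folder may absorb one as a slipped (bulged) pairing."""
        fold, off = self.fold_hairpin_with(3)
        duplex, reason = evaluate_duplex(fold, off, off + len(self.MATURE))
        assert reason is None
        unpaired = sum(
            1 for p in range(off, off + len(self.MATURE))
            if fold.pairs[p] < 0)
        assert duplex.duplex_mismatches == unpaired
        assert 1 <= duplex.duplex_mismatches <= 3
        assert duplex.duplex_mismatches + duplex.duplex_bulges >= 3

    def test_mature_spanning_loop_rejected(self):
        fold, off = self.fold_hairpin_with(0)
        n = len(fold.seq)
        duplex, reason = evaluate_duplex(fold, 20, 20 + 30)
        assert duplex is None and reason is not None

    def test_mismatch_monotonicity(self):
        """Planting more stem mismatches never increases pairing_fraction."""
        for seed in (3, 9, 21):
            fractions = []
            for n_mis in (0, 1, 2, 3):
                rng = np.random.default_rng(seed)
                prec, off = make_hairpin(rng, self.MATURE, loop_len=12,
                                         n_mismatches=n_mis)
                fold = fold_hairpin(prec, 8)
                duplex, _ = evaluate_duplex(fold, off, off + len(self.MATURE))
                assert duplex is not None
                fractions.append(duplex.pairing_fraction)
            assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_offsets_validated(self):
        fold, _ = self.fold_hairpin_with(0)
        with pytest.raises(ValueError):
            evaluate_duplex(fold, -1, 10)


class TestCandidateWindows:
    def test_two_windows_per_hit_with_flank(self):
        from srnakit.io_formats import GenomicInterval
        from srnakit.mirna_discovery import extract_candidate_windows
        rng = np.random.default_rng(2)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=3000))}
        tag = genome["chr1"][999:1020]
        hit = GenomicInterval("chr1", 1000, 1020, "+")
        windows = extract_candidate_windows(tag, [hit], genome, flank=100)
        assert len(windows) == 2
        assert {w.arm_hint for w in windows} == {"5p", "3p"}
        for w in windows:
            assert w.seq[w.tag_offset:w.tag_offset + len(tag)] == tag
            assert len(w.seq) <= len(tag) + 100 + 20

    def test_window_clipped_at_chromosome_start(self):
        from srnakit.io_formats import GenomicInterval
        from srnakit.mirna_discovery import extract_candidate_windows
        rng = np.random.default_rng(2)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=500))}
        tag = genome["chr1"][9:30]
        hit = GenomicInterval("chr1", 10, 30, "+")
        windows = extract_candidate_windows(tag, [hit], genome, flank=100)
        assert all(w.interval.start >= 1 for w in windows)

    def test_minus_strand_window_is_reverse_complemented(self):
        from srnakit.io_formats import GenomicInterval
        from srnakit.mirna_discovery import extract_candidate_windows
        rng = np.random.default_rng(2)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=2000))}
        tag = reverse_complement(genome["chr1"][999:1020])
        hit = GenomicInterval("chr1", 1000, 1020, "-")
        for w in extract_candidate_windows(tag, [hit], genome, flank=60):
            assert w.seq[w.tag_offset:w.tag_offset + len(tag)] == tag
            assert w.seq == reverse_complement(
                genome["chr1"][w.interval.start - 1:w.interval.end])


def plant_in_genome(rng, precursor, genome_len=3000):
    background = "".join(rng.choice(list("ACGT"),
                                    p=[0.3, 0.2, 0.2, 0.3], size=genome_len))
    pos = genome_len // 2
    genome = background[:pos] + precursor + background[pos + len(precursor):]
    return {"chr1": genome}


class TestCallNovel:
    MATURE = "TACGCATCCTAAGTCGAGTCG"

    def _call(self, genome, counts, params=DiscoveryParams()):
        hits = {self.MATURE: map_to_genome(self.MATURE, genome)}
        return call_novel_mirnas(hits, {self.MATURE: counts}, genome, [],
                                 params)

    def test_planted_hairpin_called(self):
        rng = np.random.default_rng(8)
        prec, _ = make_hairpin(rng, self.MATURE, loop_len=14, n_mismatches=1)
        genome = plant_in_genome(rng, prec)
        records = self._call(genome, counts=50)
        assert len(records) == 1
        rec = records[0]
        assert rec.name == "novel-miR01"
        assert rec.mature_seq == self.MATURE
        start = genome["chr1"].find(prec) + 1
        assert rec.interval.start <= start + 5
        assert rec.interval.end >= start + len(prec) - 6

    def test_count_below_threshold_not_called(self):
        rng = np.random.default_rng(8)
        prec, _ = make_hairpin(rng, self.MATURE, loop_len=14, n_mismatches=1)
        genome = plant_in_genome(rng, prec)
        assert self._call(genome, counts=1) == []

    def test_shuffled_precursor_not_called(self):
        """Dinucleotide shuffling destroys the stem; the locus must vanish."""
        rng = np.random.default_rng(8)
        prec, off = make_hairpin(rng, self.MATURE, loop_len=14, n_mismatches=1)
        # shuffle everything except the mature itself, preserving dinucleotide
        # content of the shuffled part
        rest = prec[:off] + prec[off + len(self.MATURE):]
        pairs = [rest[i:i + 2] for i in range(0, len(rest) - 1, 2)]
        rng.shuffle(pairs)
        shuffled = "".join(pairs)[:len(rest)]
        prec_shuffled = shuffled[:off] + self.MATURE + shuffled[off:]
        genome = plant_in_genome(rng, prec_shuffled)
        fold_orig = fold_hairpin(prec, 8)
        fold_shuf = fold_hairpin(prec_shuffled[:len(prec)], 8)
        assert fold_shuf.score <= fold_orig.score
        assert self._call(genome, counts=50) == []


class TestReclassification:
    MATURE = "TACGCATCCTAAGTCGAGTCG"

    def test_unmappable_mature_is_group_one(self):
        rng = np.random.default_rng(4)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=2000))}
        group, rec = reclassify_reported_mirna(self.MATURE, None, genome, [])
        assert group == "I" and rec is None

    def test_perfect_stem_is_group_three(self):
        rng = np.random.default_rng(4)
        prec, _ = make_hairpin(rng, self.MATURE, loop_len=14, n_mismatches=0)
        genome = plant_in_genome(rng, prec)
        group, rec = reclassify_reported_mirna(self.MATURE, None, genome, [])
        assert group == "III"
        assert rec.stem_loop_group == "III"
        assert rec.duplex_mismatches == 0

    def test_imperfect_stem_is_group_two(self):
        rng = np.random.default_rng(4)
        prec, _ = make_hairpin(rng, self.MATURE, loop_len=14, n_mismatches=3)
        genome = plant_in_genome(rng, prec)
        group, rec = reclassify_reported_mirna(self.MATURE, None, genome, [])
        assert group == "II"
        assert rec.duplex_mismatches == 3

    def test_recorded_precursor_that_maps_keeps_record(self):
        rng = np.random.default_rng(4)
        prec, _ = make_hairpin(rng, self.MATURE, loop_len=14, n_mismatches=0)
        genome = plant_in_genome(rng, prec)
        group, rec = reclassify_reported_mirna(self.MATURE, prec, genome, [])
        assert group is None and rec is None

    def test_groups_are_mutually_exclusive(self):
        """Across the three fixture types each mature lands in exactly one
        group, in rule order."""
        rng = np.random.default_rng(12)
        seen = []
        for n_mis, expect in ((0, "III"), (2, "II")):
            prec, _ = make_hairpin(rng, self.MATURE, loop_len=14,
                                   n_mismatches=n_mis)
            genome = plant_in_genome(rng, prec)
            group, _ = reclassify_reported_mirna(self.MATURE, None, genome, [])
            seen.append(group)
            assert group == expect
        assert len(set(seen)) == len(seen)

    def test_bad_mature_length_rejected(self):
        with pytest.raises(ValueError):
            reclassify_reported_mirna("ACGT", None, {"chr1": "ACGT" * 100}, [])
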