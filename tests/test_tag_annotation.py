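"""Annotation cascade: reference matching, genome mapping, location classes."""

import numpy as np
import pytest

from oracles import hamming_substring_match, naive_genome_hits
from srnakit.io_formats import GenomeFeature, GenomicInterval, SequenceRecord, \
    reverse_complement
from srnakit.read_cleaning import collapse_tags
from srnakit.tag_annotation import (
    GenomeIndex,
    ReferenceSet,
    annotate_tags,
    classify_location,
    map_to_genome,
    match_reference,
)


def rand_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(97)


class TestMatchReference:
    def test_exact_substring(self, rng):
        ref = rand_seq(rng, 200)
        tag = ref[50:71]
        refs = ReferenceSet("r", (SequenceRecord("x", ref),))
        assert match_reference(tag, refs) == "x"

    def test_mismatch_rejected_at_zero_tolerance(self, rng):
        ref = rand_seq(rng, 200)
        tag = ref[50:71]
        tag = tag[:10] + ("A" if tag[10] != "A" else "C") + tag[11:]
        refs = ReferenceSet("r", (SequenceRecord("x", ref),))
        assert match_reference(tag, refs, 0) is None
        assert match_reference(tag, refs, 2) == "x"

    def test_reverse_orientation_matches(self, rng):
        ref = rand_seq(rng, 100)
        tag = reverse_complement(ref[10:31])
        refs = ReferenceSet("r", (SequenceRecord("x", ref),))
        assert match_reference(tag, refs) == "x"

    def test_empty_reference(self):
        assert match_reference("ACGTACGTACGTACGTAC",
                               ReferenceSet("r", ()), 2) is None

    def test_agrees_with_bruteforce_hamming(self, rng):
        """Mismatch matching equals an explicit Hamming scan of every offset."""
        for _ in range(50):
            ref = rand_seq(rng, 80)
            tag = rand_seq(rng, 18)
            refs = ReferenceSet("r", (SequenceRecord("x", ref),))
            for mm in (0, 1, 2, 3):
                expected = (hamming_substring_match(tag, ref, mm)
                            or hamming_substring_match(
                                reverse_complement(tag), ref, mm))
                assert (match_reference(tag, refs, mm) is not None) == expected


class TestMapToGenome:
    def test_planted_tag_found(self, rng):
        genome = {"chr1": rand_seq(rng, 2000)}
        tag = genome["chr1"][500:521]
        hits = map_to_genome(tag, genome)
        assert GenomicInterval("chr1", 501, 521, "+") in hits

    def test_reverse_strand_hit(self, rng):
        genome = {"chr1": rand_seq(rng, 2000)}
        tag = reverse_complement(genome["chr1"][700:721])
        hits = map_to_genome(tag, genome)
        assert GenomicInterval("chr1", 701, 721, "-") in hits

    def test_absent_tag(self, rng):
        genome = {"chr1": rand_seq(rng, 500, "AC")}
        assert map_to_genome("G" * 20, genome) == []

    def test_index_and_scan_agree_with_naive_oracle(self, rng):
        """Indexed and scanning paths both equal an all-offsets enumeration."""
        genome = {"chr1": rand_seq(rng, 3000, "ACGT"),
                  "chr2": rand_seq(rng, 1000, "ACG")}
        index = GenomeIndex(genome)
        tags = [genome["chr1"][i:i + 19] for i in range(0, 2900, 97)]
        tags += [reverse_complement(t) for t in tags[:5]]
        tags += [rand_seq(rng, 19) for _ in range(10)]
        for tag in tags:
            expected = naive_genome_hits(tag, genome, reverse_complement(tag))
            for hits in (map_to_genome(tag, genome), index.find(tag)):
                got = sorted((h.chrom, h.start, h.end, h.strand) for h in hits)
                assert got == expected


FEATURES = [
    GenomeFeature("chr1", 1001, 1400, "+", "exon", "tx1"),
    GenomeFeature("chr1", 1401, 1800, "+", "intron", "tx1"),
    GenomeFeature("chr1", 1801, 2200, "+", "exon", "tx1"),
    GenomeFeature("chr1", 2201, 2400, "+", "three_prime_UTR", "tx1"),
    GenomeFeature("chr1", 1001, 2400, "+", "gene", "tx1"),
]


class TestClassifyLocation:
    @pytest.mark.parametrize("start,end,expected", [
        (1500, 1520, "intron"),
        (5000, 5020, "intergenic"),
        (1390, 1410, "exon"),        # exon/intron junction: exon wins
        (2190, 2210, "exon"),        # exon/3'UTR junction: exon wins
        (2250, 2270, "three_prime_UTR"),
    ])
    def test_priority(self, start, end, expected):
        iv = GenomicInterval("chr1", start, end, "+")
        assert classify_location(iv, FEATURES) == expected

    def test_junction_agrees_with_all_overlap_enumeration(self):
        """The declared priority must match a full overlap enumeration."""
        iv = GenomicInterval("chr1", 1390, 1410, "+")
        overlapping = {
            f.kind for f in FEATURES
            if f.kind != "gene" and f.start <= iv.end and iv.start <= f.end
        }
        assert overlapping == {"exon", "intron"}
        assert classify_location(iv, FEATURES) == "exon"

    def test_strand_agnostic(self):
        iv = GenomicInterval("chr1", 1500, 1520, "-")
        assert classify_location(iv, FEATURES) == "intron"


@pytest.fixture(scope="module")
def cascade(rng):
    genome = {"chr1": rand_seq(rng, 4000)}
    contaminant = SequenceRecord("rRNA_1", rand_seq(rng, 300))
    known = SequenceRecord("cre-miR-x", genome["chr1"][1500:1521])
    tag_seqs = {
        "contaminant": contaminant.seq[100:121],
        "known": known.seq,
        "mapped": genome["chr1"][3000:3021],
        "unmapped": "TTTTAAAATTTTAAAATTTT",
    }
    tags = collapse_tags({"A": list(tag_seqs.values())}, ["A"])
    anns = annotate_tags(
        tags,
        ReferenceSet("cont", (contaminant,)),
        ReferenceSet("known", (known,)),
        genome, FEATURES)
    return tag_seqs, {a.tag.seq: a for a in anns}


class TestAnnotateCascade:
    def test_every_tag_gets_exactly_one_tier(self, cascade):
        tag_seqs, by_seq = cascade
        assert by_seq[tag_seqs["contaminant"]].tier == "contaminant"
        assert by_seq[tag_seqs["known"]].tier == "known_miRNA"
        assert by_seq[tag_seqs["mapped"]].tier == "genome_mapped"
        assert by_seq[tag_seqs["unmapped"]].tier == "unmapped"

    def test_contaminant_dominates_genome(self, rng):
        genome = {"chr1": rand_seq(rng, 1000)}
        shared = genome["chr1"][100:121]
        tags = collapse_tags({"A": [shared]}, ["A"])
        anns = annotate_tags(
            tags,
            ReferenceSet("cont", (SequenceRecord("rRNA_1", shared),)),
            ReferenceSet("known", ()),
            genome, [])
        assert anns[0].tier == "contaminant"

    def test_genome_mapped_has_location_per_hit(self, cascade):
        tag_seqs, by_seq = cascade
        ann = by_seq[tag_seqs["mapped"]]
        assert len(ann.hits) == len(ann.location_classes) >= 1
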