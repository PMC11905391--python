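"""Annotation cascade for clean tags.

Each tag is assigned exactly one tier, in order: contaminant ncRNA
(rRNA/snoRNA/snRNA/tRNA reference, exact match), known miRNA (mature
reference, up to a configurable number of substitutions), genome-mapped
(exact full-length hits on either strand, with genomic location classes),
or unmapped. Location classes follow the priority exon > 3'UTR > intron,
with no overlap meaning intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import (
    GenomeFeature,
    GenomicInterval,
    SequenceRecord,
    as_genome_dict,
    reverse_complement,
)
from .read_cleaning import CleanTag

LOCATION_CLASSES = ("exon", "three_prime_UTR", "intron", "intergenic")

#: feature kinds that mark a tag as a potential mRNA-degradation fragment
EXONIC_CLASSES = frozenset({"exon", "three_prime_UTR"})


@dataclass(frozen=True)
class ReferenceSet:
    """A named FASTA-backed reference (contaminant ncRNAs, known matures)."""

    name: str
    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate ids in reference set {self.name!r}")


@dataclass
class TagAnnotation:
    tag: CleanTag
    tier: str                       # contaminant | known_miRNA | genome_mapped | unmapped
    matched_id: str | None = None
    hits: list[GenomicInterval] = field(default_factory=list)
    location_classes: list[str] = field(default_factory=list)  # one per hit

    def __post_init__(self) -> None:
        if self.tier in ("contaminant", "known_miRNA") and not self.matched_id:
            raise ValueError(f"tier {self.tier} requires a matched id")
        if self.tier == "genome_mapped" and not self.hits:
            raise ValueError("genome_mapped tier requires hits")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def match_reference(tag_seq: str, reference: ReferenceSet,
                    max_mismatches: int = 0) -> str | None:
    """Substring-match a tag against every reference record.

    Both orientations are tried, allowing up to ``max_mismatches``
    substitutions (no indels). The first match in reference order wins.
    """
    queries = (tag_seq, reverse_complement(tag_seq))
    m = len(tag_seq)
    for rec in reference.records:
        if len(rec.seq) < m:
            continue
        if max_mismatches == 0:
            if tag_seq in rec.seq or queries[1] in rec.seq:
                return rec.id
            continue
        ref = _encode(rec.seq)
        windows = np.lib.stride_tricks.sliding_window_view(ref, m)
        for q in queries:
            mm = (windows != _encode(q)).sum(axis=1)
            if mm.min() <= max_mismatches:
                return rec.id
    return None


class GenomeIndex:
    """Exact-match index of genome k-mer anchors for fast full-length lookup.

    Every forward-strand k-mer start is recorded; a query is anchored by its
    first k bases (or its reverse complement's) and verified over its full
    length. Queries shorter than k fall back to a linear scan.
    """

    def __init__(self, genome: Mapping[str, str] | Sequence[SequenceRecord],
                 k: int = 18):
        self.seqs = as_genome_dict(genome)
        self.k = k
        self._anchors: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.seqs.items():
            for i in range(len(seq) - k + 1):
                self._anchors.setdefault(seq[i:i + k], []).append((chrom, i))

    def find(self, tag_seq: str) -> list[GenomicInterval]:
        m = len(tag_seq)
        if m < self.k:
            return _scan_genome(tag_seq, self.seqs)
        hits: list[GenomicInterval] = []
        rc = reverse_complement(tag_seq)
        for query, strand in ((tag_seq, "+"), (rc, "-")):
            if strand == "-" and rc == tag_seq:
                continue
            for chrom, i in self._anchors.get(query[: self.k], ()):
                if self.seqs[chrom][i:i + m] == query:
                    hits.append(GenomicInterval(chrom, i + 1, i + m, strand))
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits


def _scan_genome(tag_seq: str, seqs: Mapping[str, str]) -> list[GenomicInterval]:
    hits: list[GenomicInterval] = []
    rc = reverse_complement(tag_seq)
    m = len(tag_seq)
    for chrom in seqs:
        seq = seqs[chrom]
        for query, strand in ((tag_seq, "+"), (rc, "-")):
            if strand == "-" and rc == tag_seq:
                continue  # palindromic tag: forward hits already cover it
            start = seq.find(query)
            while start >= 0:
                hits.append(GenomicInterval(chrom, start + 1, start + m, strand))
                start = seq.find(query, start + 1)
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def map_to_genome(tag_seq: str,
                  genome: Mapping[str, str] | Sequence[SequenceRecord] | GenomeIndex
                  ) -> list[GenomicInterval]:
    """All exact full-length occurrences of the tag on both genome strands.

    Intervals are 1-based inclusive; a "-"-strand hit reports the coordinates
    of the matching forward-strand segment whose reverse complement equals
    the tag. Pass a prebuilt :class:`GenomeIndex` when mapping many tags.
    """
    if isinstance(genome, GenomeIndex):
        return genome.find(tag_seq)
    return _scan_genome(tag_seq, as_genome_dict(genome))


class FeatureIndex:
    """Interval-tree lookup of genome features for location classification."""

    def __init__(self, features: Sequence[GenomeFeature]):
        self._trees: dict[str, IntervalTree] = {}
        for feat in features:
            if feat.kind == "gene":
                continue  # gene spans would shadow intergenic space
            tree = self._trees.setdefault(feat.chrom, IntervalTree())
            # tree uses half-open coordinates
            tree.addi(feat.start, feat.end + 1, feat.kind)

    def overlapping_kinds(self, interval: GenomicInterval) -> set[str]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(interval.start, interval.end + 1)}


#: classification priority when an interval overlaps several feature kinds
_PRIORITY = ("exon", "three_prime_UTR", "five_prime_UTR", "intron")
_PRIORITY_CLASS = {"five_prime_UTR": "exon"}  # reported classes exclude 5'UTR


def classify_location(interval: GenomicInterval,
                      features: Sequence[GenomeFeature] | FeatureIndex) -> str:
    """Label an interval by the highest-priority overlapping feature kind.

    Overlap needs >= 1 shared base and is strand-agnostic. Priority is
    exon > 3'UTR > intron; no overlap yields "intergenic".
    """
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    kinds = index.overlapping_kinds(interval)
    for kind in _PRIORITY:
        if kind in kinds:
            return _PRIORITY_CLASS.get(kind, kind)
    return "intergenic"


def annotate_tags(tags: Sequence[CleanTag],
                  contaminant_set: ReferenceSet,
                  known_mirna_set: ReferenceSet,
                  genome: Mapping[str, str] | Sequence[SequenceRecord],
                  features: Sequence[GenomeFeature],
                  contaminant_mismatches: int = 0,
                  known_mismatches: int = 2) -> list[TagAnnotation]:
    """Apply the annotation cascade; every tag receives exactly one tier."""
    index = FeatureIndex(features)
    gindex = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    out: list[TagAnnotation] = []
    for tag in tags:
        hit_id = match_reference(tag.seq, contaminant_set, contaminant_mismatches)
        if hit_id is not None:
            out.append(TagAnnotation(tag, "contaminant", matched_id=hit_id))
            continue
        hit_id = match_reference(tag.seq, known_mirna_set, known_mismatches)
        if hit_id is not None:
            out.append(TagAnnotation(tag, "known_miRNA", matched_id=hit_id))
            continue
        hits = map_to_genome(tag.seq, gindex)
        if hits:
            classes = [classify_location(h, index) for h in hits]
            out.append(TagAnnotation(tag, "genome_mapped", hits=hits,
                                     location_classes=classes))
        else:
            out.append(TagAnnotation(tag, "unmapped"))
    return out
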