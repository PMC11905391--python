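"""Readers/writers for FASTA, FASTQ and GFF3 plus shared sequence conventions.

All coordinates are 1-based inclusive throughout the package (conversion to
0-based slicing happens only inside this module). RNA input is normalized to
the DNA alphabet (U -> T) on ingest; reports may render U for mature miRNAs.
FASTQ quality is Phred+33, the modern Illumina default.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class RangeError(ValueError):
    """A genomic interval falls outside its chromosome."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (genome contig, reference ncRNA, mature miRNA...)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-DNA characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Read:
    """One raw sequencing read with per-base Phred scores."""

    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"bad interval {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


FEATURE_KINDS = ("exon", "intron", "five_prime_UTR", "three_prime_UTR", "gene")


@dataclass(frozen=True)
class GenomeFeature:
    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    parent: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"bad feature coordinates {self.start}..{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def normalize_seq(seq: str) -> str:
    """Upper-case and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement on the DNA alphabet; N maps to N."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Parse a FASTA file into normalized SequenceRecords.

    U is mapped to T and case folded to upper. Duplicate ids, empty sequences
    and malformed headers raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(os.fspath(path), "fasta"):
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate record id {rec.id!r}")
            seen.add(rec.id)
            desc = rec.description[len(rec.id):].strip()
            records.append(
                SequenceRecord(rec.id, normalize_seq(str(rec.seq)), desc)
            )
    except FormatError:
        raise
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[SequenceRecord],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path: str | os.PathLike) -> Iterator[Read]:
    """Stream 4-line Phred+33 FASTQ records as :class:`Read` objects."""
    try:
        for rec in SeqIO.parse(os.fspath(path), "fastq"):
            yield Read(
                rec.id,
                normalize_seq(str(rec.seq)),
                tuple(rec.letter_annotations["phred_quality"]),
            )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(path: str | os.PathLike, reads: Iterable[Read]) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qual)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


_GFF3_KIND_MAP = {
    "exon": "exon",
    "intron": "intron",
    "five_prime_UTR": "five_prime_UTR",
    "three_prime_UTR": "three_prime_UTR",
    "gene": "gene",
}


def _parse_gff3_attributes(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | os.PathLike) -> list[GenomeFeature]:
    """Read GFF3 features, deriving introns from consecutive exons.

    Only feature kinds relevant to location classification are kept (exon,
    intron, UTRs, gene); other types (mRNA lines etc.) are used solely to
    group exons by their Parent attribute. When a transcript's exons leave
    gaps and no explicit intron features are present for it, introns are
    emitted as the gaps between consecutive exons.
    """
    features: list[GenomeFeature] = []
    exons_by_parent: dict[str, list[GenomeFeature]] = {}
    parents_with_introns: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates "
                    f"{start_s!r}..{end_s!r}"
                ) from exc
            kind = _GFF3_KIND_MAP.get(ftype)
            if kind is None:
                continue
            parent = _parse_gff3_attributes(attrs).get("Parent", "")
            feat = GenomeFeature(chrom, start, end, strand, kind, parent)
            features.append(feat)
            if kind == "exon" and parent:
                exons_by_parent.setdefault(parent, []).append(feat)
            if kind == "intron" and parent:
                parents_with_introns.add(parent)
    for parent, exons in exons_by_parent.items():
        if parent in parents_with_introns:
            continue
        exons = sorted(exons, key=lambda f: f.start)
        for left, right in zip(exons, exons[1:]):
            if right.start > left.end + 1:
                features.append(
                    GenomeFeature(left.chrom, left.end + 1, right.start - 1,
                                  left.strand, "intron", parent)
                )
    return features


def write_gff3(path: str | os.PathLike, features: Iterable[GenomeFeature],
               source: str = "srnakit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, feat in enumerate(features):
            attrs = f"ID={feat.kind}{i}"
            if feat.parent:
                attrs += f";Parent={feat.parent}"
            fh.write(
                "\t".join(
                    [feat.chrom, source, feat.kind, str(feat.start),
                     str(feat.end), ".", feat.strand, ".", attrs]
                ) + "\n"
            )


def extract_window(genome: dict[str, str] | list[SequenceRecord],
                   interval: GenomicInterval) -> str:
    """Extract a 1-based inclusive window; "-" strand returns the reverse
    complement."""
    seqs = as_genome_dict(genome)
    if interval.chrom not in seqs:
        raise RangeError(f"unknown chromosome {interval.chrom!r}")
    chrom_seq = seqs[interval.chrom]
    if interval.end > len(chrom_seq):
        raise RangeError(
            f"{interval.chrom}:{interval.start}..{interval.end} outside "
            f"chromosome of length {len(chrom_seq)}"
        )
    sub = chrom_seq[interval.start - 1:interval.end]
    return reverse_complement(sub) if interval.strand == "-" else sub


def as_genome_dict(genome: dict[str, str] | list[SequenceRecord]) -> dict[str, str]:
    if isinstance(genome, dict):
        return genome
    return {rec.id: rec.seq for rec in genome}


def to_rna(seq: str) -> str:
    """Render a DNA-alphabet sequence with U, for mature miRNA reports."""
    return seq.replace("T", "U")
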