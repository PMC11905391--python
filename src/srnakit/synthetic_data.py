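"""Synthetic genome, annotation and small-RNA library generator.

The generator emulates the data a DCL-knockout small RNA-seq study consumes:
a GC-rich genome (*Chlamydomonas*-like, ~64% GC) with planted stem-loop
miRNA loci assigned to intergenic/intron/exon/3'UTR locations, gene models
to back those locations, a contaminant ncRNA reference, a known-miRNA
reference covering a subset of planted matures, and two groups (control vs.
knockout) of three replicate libraries. Replicate counts are
negative-binomial; knockout libraries scale each locus by its configured
fold-reduction. Reads carry a ligated 3' adapter and Phred+33 qualities, and
a small planted fraction of defective reads exercises every cleaning filter.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeFeature,
    GenomicInterval,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_gff3,
)

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"   # fixed 21-nt non-genomic 3' adapter
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCG"     # fixed 20-nt 5' adapter

#: defect classes planted to exercise each cleaning filter, with the
#: rejection reason the cleaner is expected to report
DEFECT_REASONS = {
    "low_quality": "low_quality",
    "contains_N": "contains_N",
    "no_3p_adapter": "no_3p_adapter",
    "has_5p_adapter": "has_5p_adapter",
    "short": "short",
    "polyA": "polyA",
}


class GenerationError(RuntimeError):
    """Raised when loci cannot be placed in the configured genome."""


def default_knockout_effects(n_loci: int) -> dict[str, float]:
    """Locus-id -> multiplicative fold-reduction in the knockout group.

    The cycle mixes strong reductions (0.05-0.25, i.e. log2 fc around -2 to
    -4.3), moderate ones, and unaffected loci (1.0), mirroring the spread of
    down-regulation the knockout comparison is meant to detect.
    """
    cycle = (0.09, 0.25, 1.0, 0.15, 0.5, 1.0, 0.05, 0.2, 1.0, 0.12)
    return {f"locus{i + 1:02d}": cycle[i % len(cycle)] for i in range(n_loci)}


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    genome_length: int = 300_000
    n_hairpin_loci: int = 20
    n_genes: int = 25
    n_contaminants: int = 8
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    read_count_per_library: int = 200_000
    mature_star_ratio: float = 10.0
    contaminant_fraction: float = 0.25
    degradation_fraction: float = 0.40
    defect_fraction: float = 0.012     # split evenly over the defect classes
    knockout_effect: dict[str, float] | None = None  # None -> defaults
    replicates_per_group: int = 3
    dispersion: float = 0.1            # NB overdispersion (var = mu + a*mu^2)
    gc_content: float = 0.64
    jitter_fraction: float = 0.10      # mature reads with +-1 nt ragged ends
    known_fraction: float = 0.25       # planted loci listed in the known set
    first_u_bias: float = 0.75         # P(mature starts with U)
    location_mix: tuple[float, ...] = (0.5, 0.25, 0.15, 0.10)
    # order: intergenic, intron, exon, three_prime_UTR

    def __post_init__(self) -> None:
        total = (self.contaminant_fraction + self.degradation_fraction
                 + self.defect_fraction)
        if total >= 1.0:
            raise ValueError("read fractions must leave room for miRNA reads")
        if self.n_hairpin_loci < 1 or self.read_count_per_library < 1:
            raise ValueError("counts must be positive")
        if self.knockout_effect is not None:
            if any(v <= 0 for v in self.knockout_effect.values()):
                raise ValueError("knockout effects must be > 0")

    def effects(self) -> dict[str, float]:
        if self.knockout_effect is not None:
            return dict(self.knockout_effect)
        return default_knockout_effects(self.n_hairpin_loci)


@dataclass
class TruthRecord:
    locus_id: str
    precursor: GenomicInterval
    mature_seq: str
    arm: str
    star_seq: str
    location_class: str
    n_mismatches: int
    baseline_weight: float
    knockout_effect: float
    expected_tpm_control: float
    expected_tpm_knockout: float
    is_known: bool


LOCATION_CLASSES = ("intergenic", "intron", "exon", "three_prime_UTR")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)
    return arr.tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    if n_mut == 0:
        return seq
    out = bytearray(seq.encode())
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    for pos in positions:
        choices = [b for b in b"ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return out.decode()


def build_genome(config: SimConfig) -> tuple[
        list[SequenceRecord], list[GenomeFeature], list[TruthRecord]]:
    """Construct the synthetic chromosome, gene models and planted hairpins.

    Each precursor is left-arm + loop (>= 8 nt) + reverse complement of the
    left arm with 0-3 planted stem mismatches, so it folds into a stem-loop.
    Zero-mismatch loci are siRNA-like (class-III-style) by construction.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    genome = bytearray(_random_seq(rng, config.genome_length, config.gc_content).encode())

    # gene models: exon1 - intron - exon2 - 3'UTR; exon space is sized so
    # degradation fragments spread at a realistic per-nucleotide density
    # relative to miRNA locus expression
    exon1, intron_len, exon2, utr = 400, 400, 400, 200
    gene_len = exon1 + intron_len + exon2 + utr
    spacing = config.genome_length // (config.n_genes + 1)
    if spacing < gene_len + 400:
        raise GenerationError("genome too short for the requested gene count")
    features: list[GenomeFeature] = []
    gene_slots: list[dict] = []
    for g in range(config.n_genes):
        start = spacing * (g + 1) - gene_len // 2
        strand = "+" if rng.random() < 0.5 else "-"
        tx = f"tx{g + 1:02d}"
        b = start
        parts = {
            "exon1": (b, b + exon1 - 1),
            "intron": (b + exon1, b + exon1 + intron_len - 1),
            "exon2": (b + exon1 + intron_len, b + exon1 + intron_len + exon2 - 1),
            "utr": (b + exon1 + intron_len + exon2, b + gene_len - 1),
        }
        features.append(GenomeFeature(chrom, start, start + gene_len - 1,
                                      strand, "gene", tx))
        for key, kind in (("exon1", "exon"), ("intron", "intron"),
                          ("exon2", "exon"), ("utr", "three_prime_UTR")):
            s, e = parts[key]
            features.append(GenomeFeature(chrom, s, e, strand, kind, tx))
        gene_slots.append({"strand": strand, "parts": parts, "used": set()})

    effects = config.effects()
    n = config.n_hairpin_loci
    class_counts = np.floor(np.array(config.location_mix) * n).astype(int)
    while class_counts.sum() < n:
        class_counts[0] += 1
    class_list = [c for c, k in zip(LOCATION_CLASSES, class_counts)
                  for _ in range(int(k))]

    occupied: list[tuple[int, int]] = [
        (slot["parts"]["exon1"][0] - 200, slot["parts"]["utr"][1] + 200)
        for slot in gene_slots
    ]
    weights = np.exp(rng.uniform(np.log(30), np.log(3000), size=n))
    truth: list[TruthRecord] = []
    n_known = int(round(config.known_fraction * n))

    for i in range(n):
        locus_id = f"locus{i + 1:02d}"
        loc_class = class_list[i]
        mature_len = int(rng.choice([20, 21, 22, 23], p=[0.2, 0.5, 0.2, 0.1]))
        # stem mismatches: every 5th locus is a perfect (siRNA-like) stem
        n_mis = 0 if i % 5 == 4 else int(rng.integers(1, 4))
        arm = "5p" if rng.random() < 0.5 else "3p"
        loop_len = int(rng.integers(8, 21))
        arm_len = mature_len + int(rng.integers(6, 13))
        left = _random_seq(rng, arm_len, config.gc_content)
        mature_off = int(rng.integers(2, arm_len - mature_len - 1))
        if rng.random() < config.first_u_bias:
            # 5' U bias of the mature read
            if arm == "5p":
                left = left[:mature_off] + "T" + left[mature_off + 1:]
            else:
                # mature comes from the right arm: rc of left
                pos = arm_len - 1 - (mature_off + mature_len - 1)
                left = left[:pos] + "A" + left[pos + 1:]
        right = _mutate(rng, reverse_complement(left), n_mis)
        precursor = left + _random_seq(rng, loop_len, config.gc_content) + right
        prec_len = len(precursor)

        placed = False
        for _attempt in range(200):
            if loc_class == "intergenic":
                start = int(rng.integers(300, config.genome_length - prec_len - 300))
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                slot = gene_slots[int(rng.integers(len(gene_slots)))]
                part = {"intron": "intron", "exon": "exon1",
                        "three_prime_UTR": "utr"}[loc_class]
                if part in slot["used"]:
                    continue
                s, e = slot["parts"][part]
                if e - s + 1 < prec_len + 10:
                    continue
                start = s + ((e - s + 1) - prec_len) // 2
                strand = slot["strand"]
            end = start + prec_len - 1
            if loc_class == "intergenic":
                if any(start - 60 <= oe and os_ <= end + 60
                       for os_, oe in occupied):
                    continue
            else:
                slot["used"].add(part)
            occupied.append((start, end))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place {locus_id} ({loc_class}) without overlap")

        planted = precursor if strand == "+" else reverse_complement(precursor)
        genome[start - 1:end] = planted.encode()

        if arm == "5p":
            m_start, m_end = mature_off, mature_off + mature_len
        else:
            r_off = arm_len - 1 - (mature_off + mature_len - 1)
            m_start = arm_len + loop_len + r_off
            m_end = m_start + mature_len
        mature_seq = precursor[m_start:m_end]
        # star: positions pairing the mature (i pairs prec_len-1-i), shifted
        # for the 2-nt 3' overhangs on both duplex strands
        s_start = max(0, prec_len - m_end + 2)
        s_end = min(prec_len, prec_len - m_start + 2)
        star_seq = precursor[s_start:s_end]

        truth.append(TruthRecord(
            locus_id=locus_id,
            precursor=GenomicInterval(chrom, start, end, strand),
            mature_seq=mature_seq,
            arm=arm,
            star_seq=star_seq,
            location_class=loc_class,
            n_mismatches=n_mis,
            baseline_weight=float(weights[i]),
            knockout_effect=float(effects.get(locus_id, 1.0)),
            expected_tpm_control=0.0,
            expected_tpm_knockout=0.0,
            is_known=i < n_known,
        ))

    # fill in expected TPM from the generative model
    mirna_share = 1.0 - (config.contaminant_fraction + config.degradation_fraction
                         + config.defect_fraction)
    total_w = float(weights.sum())
    mature_frac = config.mature_star_ratio / (1.0 + config.mature_star_ratio)
    exp_clean = config.read_count_per_library * (1.0 - config.defect_fraction)
    for rec in truth:
        base = (config.read_count_per_library * mirna_share
                * rec.baseline_weight / total_w * mature_frac)
        rec.expected_tpm_control = base / exp_clean * 1e6
        rec.expected_tpm_knockout = (base * rec.knockout_effect) / exp_clean * 1e6

    genome_rec = SequenceRecord(chrom, genome.decode(), "synthetic chromosome")
    return [genome_rec], features, truth


def build_contaminants(config: SimConfig) -> list[SequenceRecord]:
    """Synthetic rRNA/snoRNA/snRNA/tRNA reference records."""
    rng = np.random.default_rng(config.seed + 7_001)
    kinds = ("rRNA", "snoRNA", "snRNA", "tRNA")
    lengths = {"rRNA": (1200, 2500), "snoRNA": (120, 250),
               "snRNA": (120, 200), "tRNA": (70, 90)}
    out = []
    for i in range(config.n_contaminants):
        kind = kinds[i % len(kinds)]
        lo, hi = lengths[kind]
        n = int(rng.integers(lo, hi + 1))
        out.append(SequenceRecord(f"{kind}_{i + 1}",
                                  _random_seq(rng, n, 0.55),
                                  f"synthetic {kind}"))
    return out


def known_mirna_reference(truth: list[TruthRecord]) -> list[SequenceRecord]:
    return [
        SequenceRecord(f"cre-miR-sim{int(rec.locus_id[5:]):02d}",
                       rec.mature_seq, f"synthetic known mature ({rec.locus_id})")
        for rec in truth if rec.is_known
    ]


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return int(rng.poisson(lam))


def _jitter_variant(rng: np.random.Generator, genome_seq: str,
                    iv: GenomicInterval) -> str:
    """A +-1 nt ragged-end variant of a mature read, taken from the genome."""
    which = int(rng.integers(4))
    s, e = iv.start, iv.end
    if which == 0:
        s = max(1, s - 1)
    elif which == 1:
        s += 1
    elif which == 2:
        e = max(s + 1, e - 1)
    else:
        e = min(len(genome_seq), e + 1)
    sub = genome_seq[s - 1:e]
    return sub if iv.strand == "+" else reverse_complement(sub)


def simulate_libraries(genome: list[SequenceRecord],
                       truth: list[TruthRecord],
                       config: SimConfig,
                       outdir: str | os.PathLike,
                       contaminants: list[SequenceRecord] | None = None,
                       features: list[GenomeFeature] | None = None,
                       ) -> pd.DataFrame:
    """Write per-replicate FASTQ files and the sample sheet; returns the sheet.

    Read ids encode their provenance; planted defective reads carry a
    ``defect=<class>`` token used by the cleaning conservation checks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 9_001)
    if contaminants is None:
        contaminants = build_contaminants(config)
    genome_seq = genome[0].seq
    chrom_len = len(genome_seq)

    exonic_spans: list[tuple[int, int, str]] = []
    if features is not None:
        for feat in features:
            if feat.kind in ("exon", "three_prime_UTR"):
                exonic_spans.append((feat.start, feat.end, feat.strand))
    if not exonic_spans:
        exonic_spans = [(1, chrom_len, "+")]

    n_total = config.read_count_per_library
    n_cont = int(round(config.contaminant_fraction * n_total))
    n_deg = int(round(config.degradation_fraction * n_total))
    defect_classes = list(DEFECT_REASONS)
    n_defect_each = int(round(config.defect_fraction * n_total / len(defect_classes)))
    mirna_share = 1.0 - (config.contaminant_fraction + config.degradation_fraction
                         + config.defect_fraction)
    n_mirna = int(round(mirna_share * n_total))
    weights = np.array([t.baseline_weight for t in truth])
    weights = weights / weights.sum()
    mature_frac = config.mature_star_ratio / (1.0 + config.mature_star_ratio)

    mature_ivs = [_find_offset(genome_seq, t, t.mature_seq) for t in truth]

    rows = []
    serial = 0
    for group in ("control", "knockout"):
        for rep in range(1, config.replicates_per_group + 1):
            lib = f"{group}_{rep}"
            path = outdir / f"{lib}.fastq"
            with open(path, "w", buffering=1 << 20) as fh:
                def emit(seq: str, qual_char: str, tokens: str) -> None:
                    nonlocal serial
                    serial += 1
                    fh.write(f"@r{serial}|{tokens}\n{seq}\n+\n"
                             f"{qual_char * len(seq)}\n")

                for t_idx, (t, m_iv) in enumerate(zip(truth, mature_ivs)):
                    eff = t.knockout_effect if group == "knockout" else 1.0
                    mu = n_mirna * weights[t_idx] * eff
                    n_mat = _nb_draw(rng, mu * mature_frac, config.dispersion)
                    n_star = _nb_draw(rng, mu * (1 - mature_frac), config.dispersion)
                    n_jit = int(round(config.jitter_fraction * n_mat))
                    for _ in range(n_mat - n_jit):
                        emit(t.mature_seq + config.adapter3, "I", f"src={t.locus_id}")
                    for _ in range(n_jit):
                        var = _jitter_variant(rng, genome_seq, m_iv)
                        emit(var + config.adapter3, "I", f"src={t.locus_id}|jit=1")
                    for _ in range(n_star):
                        emit(t.star_seq + config.adapter3, "I",
                             f"src={t.locus_id}|star=1")

                for _ in range(n_cont):
                    rec = contaminants[int(rng.integers(len(contaminants)))]
                    ln = int(rng.integers(18, 29))
                    if len(rec.seq) <= ln:
                        frag = rec.seq
                    else:
                        s = int(rng.integers(0, len(rec.seq) - ln))
                        frag = rec.seq[s:s + ln]
                    emit(frag + config.adapter3, "I", f"src=contaminant|{rec.id}")

                for _ in range(n_deg):
                    s, e, strand = exonic_spans[int(rng.integers(len(exonic_spans)))]
                    ln = int(rng.integers(18, 29))
                    if e - s + 1 <= ln:
                        continue
                    p0 = int(rng.integers(s, e - ln + 1))
                    frag = genome_seq[p0 - 1:p0 - 1 + ln]
                    if strand == "-":
                        frag = reverse_complement(frag)
                    emit(frag + config.adapter3, "I", "src=degradation")

                for cls in defect_classes:
                    for _ in range(n_defect_each):
                        _emit_defect(emit, rng, cls, config, genome_seq)
            rows.append({"sample_id": lib, "group": group,
                         "replicate": rep, "path": str(path)})
    sheet = pd.DataFrame(rows)
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return sheet


def _find_offset(genome_seq: str, t: TruthRecord, sub: str) -> GenomicInterval:
    """Genomic interval of a strand-oriented subsequence of the precursor."""
    p = t.precursor
    prec = genome_seq[p.start - 1:p.end]
    if p.strand == "-":
        prec = reverse_complement(prec)
    off = prec.find(sub)
    if off < 0:  # pragma: no cover - construction guarantees presence
        raise GenerationError(f"{t.locus_id}: subsequence lost from precursor")
    if p.strand == "+":
        return GenomicInterval(p.chrom, p.start + off,
                               p.start + off + len(sub) - 1, "+")
    return GenomicInterval(p.chrom, p.end - off - len(sub) + 1,
                           p.end - off, "-")


def _emit_defect(emit, rng: np.random.Generator, cls: str, config: SimConfig,
                 genome_seq: str) -> None:
    insert_start = int(rng.integers(1, len(genome_seq) - 40))
    insert = genome_seq[insert_start - 1:insert_start + 20]
    tokens = f"defect={cls}"
    if cls == "low_quality":
        emit(insert + config.adapter3, "#", tokens)
    elif cls == "contains_N":
        broken = insert[:10] + "N" + insert[11:]
        emit(broken + config.adapter3, "I", tokens)
    elif cls == "no_3p_adapter":
        emit(insert + insert, "I", tokens)
    elif cls == "has_5p_adapter":
        emit(insert[:3] + config.adapter5 + insert[3:6] + config.adapter3,
             "I", tokens)
    elif cls == "short":
        emit(insert[:10] + config.adapter3, "I", tokens)
    elif cls == "polyA":
        emit("A" * 22 + config.adapter3, "I", tokens)


def write_reference_files(outdir: str | os.PathLike,
                          genome: list[SequenceRecord],
                          features: list[GenomeFeature],
                          truth: list[TruthRecord],
                          contaminants: list[SequenceRecord]) -> dict[str, Path]:
    """Write genome FASTA, GFF3, contaminant & known-miRNA FASTA, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "gff3": outdir / "annotation.gff3",
        "contaminants": outdir / "contaminants.fasta",
        "known_mirnas": outdir / "known_mirnas.fasta",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(paths["genome"], genome)
    write_gff3(paths["gff3"], features)
    write_fasta(paths["contaminants"], contaminants)
    write_fasta(paths["known_mirnas"], known_mirna_reference(truth))
    truth_frame(truth).to_csv(paths["truth"], sep="\t", index=False)
    return paths


def truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "locus_id": t.locus_id,
            "chrom": t.precursor.chrom,
            "start": t.precursor.start,
            "end": t.precursor.end,
            "strand": t.precursor.strand,
            "mature_seq": t.mature_seq,
            "arm": t.arm,
            "star_seq": t.star_seq,
            "location_class": t.location_class,
            "n_mismatches": t.n_mismatches,
            "baseline_weight": t.baseline_weight,
            "knockout_effect": t.knockout_effect,
            "expected_tpm_control": t.expected_tpm_control,
            "expected_tpm_knockout": t.expected_tpm_knockout,
            "is_known": t.is_known,
        }
        for t in truth
    ])


def simulate_locus_counts(config: SimConfig, null: bool = False
                          ) -> pd.DataFrame:
    """Replicate count table straight from the generative count model.

    Bypasses read synthesis: draws the per-locus negative-binomial mature
    counts for every replicate of both groups (the same model
    :func:`simulate_libraries` uses). With ``null=True`` every knockout
    effect is forced to 1.0, making the two groups exchangeable.
    """
    rng = np.random.default_rng(config.seed + 13_001)
    effects = config.effects()
    mirna_share = 1.0 - (config.contaminant_fraction + config.degradation_fraction
                         + config.defect_fraction)
    n_mirna = mirna_share * config.read_count_per_library
    weights = np.exp(rng.uniform(np.log(30), np.log(3000),
                                 size=config.n_hairpin_loci))
    weights = weights / weights.sum()
    mature_frac = config.mature_star_ratio / (1.0 + config.mature_star_ratio)
    rows = []
    for i in range(config.n_hairpin_loci):
        locus = f"locus{i + 1:02d}"
        eff = 1.0 if null else effects.get(locus, 1.0)
        row: dict[str, object] = {"locus_id": locus, "knockout_effect": eff}
        for group, scale in (("control", 1.0), ("knockout", eff)):
            mu = n_mirna * weights[i] * scale * mature_frac
            for rep in range(1, config.replicates_per_group + 1):
                row[f"{group}_{rep}"] = _nb_draw(rng, mu, config.dispersion)
        rows.append(row)
    return pd.DataFrame(rows)
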