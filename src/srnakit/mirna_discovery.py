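"""Hairpin folding, miRNA/miRNA* duplex evaluation and novel-miRNA calling.

The folding engine is deterministic base-pair maximization (Nussinov dynamic
programming) over the canonical pairs A·U, G·C and the G·U wobble, with a
minimum hairpin-loop size. It stands in for a full nearest-neighbour
thermodynamic model: the pair count normalized by length (``score_per_base``)
acts as the free-energy proxy, and the algorithm is exactly checkable against
exhaustive enumeration of non-crossing structures on short sequences.

A candidate precursor passes when its mature tag sits on one stem arm, the
star segment implied by the 2-nt 3' overhang geometry of Dicer/DCL cleavage
is compact, and the mature/star duplex satisfies mismatch, bulge and pairing
thresholds. Because pure pair maximization pairs long random flanks
promiscuously, candidate evaluation scans a grid of precursor extents around
the mature tag instead of folding the full flanked window at once.

Previously reported miRNAs whose recorded precursor no longer matches the
genome are re-classified: group I (no precursor recoverable anywhere the
mature maps — not a miRNA), group III (mature perfectly complementary to its
star — siRNA-like), group II (a valid imperfect precursor — miRNA candidate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .io_formats import (
    GenomicInterval,
    SequenceRecord,
    as_genome_dict,
    extract_window,
    reverse_complement,
)
from .tag_annotation import FeatureIndex, classify_location, map_to_genome

# ---------------------------------------------------------------------------
# folding

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

_PAIRABLE = np.zeros((5, 5), dtype=np.bool_)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)):
    _PAIRABLE[_a, _b] = True

MAX_FOLD_LENGTH = 400


@dataclass(frozen=True)
class FoldResult:
    seq: str
    structure: str
    pairs: tuple[int, ...]   # partner index per position, -1 if unpaired
    score: int               # number of base pairs

    @property
    def score_per_base(self) -> float:
        return self.score / len(self.seq)


@njit(cache=False)
def _nussinov(codes, pairable, min_loop):  # pragma: no cover - jit kernel
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int16)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pairable[codes[i], codes[k]]:
                    v = dp[i + 1, k - 1] + 1
                    if k < j:
                        v += dp[k + 1, j]
                    if v > best:
                        best = v
            dp[i, j] = best
    partner = np.full(n, -1, dtype=np.int16)
    stack = np.empty((n + 1, 2), dtype=np.int32)
    top = 0
    stack[top, 0] = 0
    stack[top, 1] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack[top, 0]
        j = stack[top, 1]
        while j - i > min_loop and dp[i, j] > 0:
            target = dp[i, j]
            k_found = -1
            for k in range(i + min_loop + 1, j + 1):
                if pairable[codes[i], codes[k]]:
                    v = dp[i + 1, k - 1] + 1
                    if k < j:
                        v += dp[k + 1, j]
                    if v == target:
                        k_found = k
                        break
            if k_found < 0:
                i += 1
                continue
            partner[i] = k_found
            partner[k_found] = i
            if k_found < j:
                stack[top, 0] = k_found + 1
                stack[top, 1] = j
                top += 1
            j = k_found - 1
            i += 1
    return partner


def fold_hairpin(seq: str, min_loop: int = 3) -> FoldResult:
    """Fold a sequence by deterministic base-pair maximization.

    Ties during traceback are resolved by pairing the current 5' base with
    the smallest admissible partner index, so the structure is reproducible.
    """
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) > MAX_FOLD_LENGTH:
        raise ValueError(f"sequence longer than {MAX_FOLD_LENGTH} nt")
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    try:
        codes = np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-DNA character {exc.args[0]!r}") from exc
    partner = _nussinov(codes, _PAIRABLE, min_loop)
    structure = "".join(
        "." if p < 0 else ("(" if p > i else ")") for i, p in enumerate(partner)
    )
    score = int((partner >= 0).sum()) // 2
    return FoldResult(seq, structure, tuple(int(p) for p in partner), score)


# ---------------------------------------------------------------------------
# duplex evaluation

@dataclass(frozen=True)
class DuplexResult:
    star_start: int          # 0-based offsets within the folded sequence
    star_end: int            # exclusive
    arm: str                 # 5p | 3p
    duplex_mismatches: int
    duplex_bulges: int
    pairing_fraction: float
    gu_pairs: int
    star_seq: str

    @property
    def star_span(self) -> int:
        return self.star_end - self.star_start


def evaluate_duplex(fold: FoldResult, mature_start: int, mature_end: int
                    ) -> tuple[DuplexResult | None, str | None]:
    """Evaluate the mature/star duplex implied by a fold.

    ``mature_start``/``mature_end`` are 0-based, end-exclusive offsets of the
    mature within the folded sequence. The star segment is taken as the
    positions pairing with the mature, shifted so the duplex carries the 2-nt
    3' overhangs characteristic of Dicer/DCL cleavage. Returns the metrics or
    ``(None, reason)`` when the mature does not sit cleanly on one arm.
    """
    n = len(fold.seq)
    if not (0 <= mature_start < mature_end <= n):
        raise ValueError("mature offsets outside the folded sequence")
    mature_len = mature_end - mature_start
    paired = [
        (p, fold.pairs[p])
        for p in range(mature_start, mature_end)
        if fold.pairs[p] >= 0
    ]
    if not paired:
        return None, "mature_unpaired"
    partners = [q for _, q in paired]
    if any(mature_start <= q < mature_end for q in partners):
        return None, "mature_self_pairing"
    if min(partners) < mature_start and max(partners) >= mature_end:
        return None, "mature_spans_loop"
    arm = "5p" if min(partners) >= mature_end else "3p"

    def partner_at(pos: int) -> int:
        # anti-parallel extrapolation from the nearest paired mature base
        nearest_p, nearest_q = min(paired, key=lambda pq: abs(pq[0] - pos))
        return nearest_q - (pos - nearest_p)

    lo_anchor = partner_at(mature_end - 1 - 2)       # pairs star 5'-most zone
    hi_anchor = partner_at(mature_start) + 2         # star 3' 2-nt overhang
    star_start = max(0, min(lo_anchor, hi_anchor))
    star_end = min(n, max(lo_anchor, hi_anchor) + 1)
    if star_end <= star_start:
        return None, "degenerate_star"
    if not (star_end <= mature_start or star_start >= mature_end):
        return None, "star_overlaps_mature"

    # mismatches: mature bases without a partner on the opposite arm.
    # bulges: asymmetric gaps in the duplex — between consecutive paired
    # mature bases, more star bases than mature bases are skipped (symmetric
    # gaps are internal loops/mismatches, not bulges).
    mismatches = mature_len - len(paired)
    bulges = 0
    for (m1, q1), (m2, q2) in zip(paired, paired[1:]):
        gap_m = m2 - m1 - 1
        gap_q = abs(q1 - q2) - 1
        if gap_q > gap_m:
            bulges += 1
    gu = 0
    for p, q in paired:
        duo = {fold.seq[p], fold.seq[q]}
        if duo == {"G", "T"}:
            gu += 1
    return DuplexResult(
        star_start=star_start,
        star_end=star_end,
        arm=arm,
        duplex_mismatches=mismatches,
        duplex_bulges=bulges,
        pairing_fraction=len(paired) / mature_len,
        gu_pairs=gu,
        star_seq=fold.seq[star_start:star_end],
    ), None


# ---------------------------------------------------------------------------
# candidate windows

@dataclass(frozen=True)
class PrecursorWindow:
    interval: GenomicInterval    # genomic span of the window, 1-based inclusive
    seq: str                     # strand-oriented window sequence
    tag_offset: int              # 0-based offset of the tag within seq
    tag_length: int
    arm_hint: str                # 5p | 3p


def extract_candidate_windows(tag_seq: str, hits: Sequence[GenomicInterval],
                              genome: Mapping[str, str] | Sequence[SequenceRecord],
                              flank: int = 180, pad: int = 20
                              ) -> list[PrecursorWindow]:
    """Precursor windows placing the tag on the 5' and the 3' arm of each hit.

    The long flank extends toward where the loop and star arm would lie; the
    short pad leaves room for ragged mature ends. Windows are clipped at
    chromosome boundaries.
    """
    seqs = as_genome_dict(genome)
    out: list[PrecursorWindow] = []
    m = len(tag_seq)
    for hit in hits:
        chrom_len = len(seqs[hit.chrom])
        for arm in ("5p", "3p"):
            if (hit.strand == "+") == (arm == "5p"):
                gstart = max(1, hit.start - pad)
                gend = min(chrom_len, hit.end + flank)
            else:
                gstart = max(1, hit.start - flank)
                gend = min(chrom_len, hit.end + pad)
            window = GenomicInterval(hit.chrom, gstart, gend, hit.strand)
            seq = extract_window(seqs, window)
            if hit.strand == "+":
                off = hit.start - gstart
            else:
                off = gend - hit.end
            out.append(PrecursorWindow(window, seq, off, m, arm))
    return out


def window_offsets_to_genome(window: PrecursorWindow, start: int, end: int
                             ) -> GenomicInterval:
    """Map 0-based end-exclusive offsets in the window sequence back to a
    genomic interval."""
    iv = window.interval
    if iv.strand == "+":
        return GenomicInterval(iv.chrom, iv.start + start, iv.start + end - 1, "+")
    return GenomicInterval(iv.chrom, iv.end - end + 1, iv.end - start, "-")


# ---------------------------------------------------------------------------
# novel-miRNA calling

@dataclass(frozen=True)
class DiscoveryParams:
    flank: int = 180
    # minimum hairpin loop during precursor evaluation: pre-miRNA terminal
    # loops are sizeable, and a larger floor keeps base-pair maximization
    # from building tight sub-hairpins between the mature and its star
    min_loop: int = 8
    max_duplex_mismatches: int = 4
    max_duplex_bulges: int = 2
    min_pairing_fraction: float = 0.6
    min_score_per_base: float = 0.25
    mature_min: int = 18
    mature_max: int = 24
    min_total_count: int = 3
    max_genome_hits: int = 10
    max_star_slack: int = 6          # star span may exceed mature by this many nt
    wc_only_class3: bool = True      # G·U disqualifies "perfect complementarity"
    upstream_pads: tuple[int, ...] = (2, 6, 10)
    loopward_extents: tuple[int, ...] = (30, 40, 50, 60, 75, 90, 110, 130, 150)
    min_precursor: int = 50
    # DCL-cut positional precision: the candidate mature's own 5'-end stack
    # must account for this fraction of read 5' ends in its neighbourhood
    min_stack_fraction: float = 0.3
    stack_window: int = 60
    end_tolerance: int = 2


@dataclass
class PrecursorCandidate:
    tag_seq: str
    total_count: int
    window: PrecursorWindow
    precursor_interval: GenomicInterval
    precursor_seq: str
    fold: FoldResult
    mature_offset: int               # within the precursor subwindow
    duplex: DuplexResult
    overhang_ok: bool

    @property
    def rank_key(self) -> tuple:
        return (
            -self.total_count,
            -self.duplex.pairing_fraction,
            self.duplex.duplex_mismatches + self.duplex.duplex_bulges,
            -int(self.overhang_ok),
            -self.fold.score_per_base,
            self.precursor_interval.chrom,
            self.precursor_interval.start,
        )


@dataclass
class MiRNARecord:
    name: str
    mature_seq: str
    arm: str
    interval: GenomicInterval        # precursor span
    strand: str
    location_classes: list[str]
    origin: str                      # known | novel
    star_seq: str = ""
    mature_interval: GenomicInterval | None = None
    stem_loop_group: str | None = None
    duplex_mismatches: int = 0
    duplex_bulges: int = 0
    pairing_fraction: float = 0.0
    precursor_seq: str = ""
    structure: str = ""

    @property
    def length(self) -> int:
        return len(self.mature_seq)


def _evaluate_window(window: PrecursorWindow, params: DiscoveryParams
                     ) -> PrecursorCandidate | None:
    """Scan precursor extents within one window; return the best passing
    candidate (mature fixed at the tag position)."""
    best: PrecursorCandidate | None = None
    m = window.tag_length
    for pad in params.upstream_pads:
        for ext in params.loopward_extents:
            if window.arm_hint == "5p":
                start = max(0, window.tag_offset - pad)
                end = min(len(window.seq), window.tag_offset + m + ext)
            else:
                start = max(0, window.tag_offset - ext)
                end = min(len(window.seq), window.tag_offset + m + pad)
            if end - start < max(params.min_precursor, m + params.min_loop + 2):
                continue
            sub = window.seq[start:end]
            fold = fold_hairpin(sub, params.min_loop)
            if fold.score_per_base < params.min_score_per_base:
                continue
            duplex, _reason = evaluate_duplex(
                fold, window.tag_offset - start, window.tag_offset - start + m)
            if duplex is None:
                continue
            if duplex.duplex_mismatches > params.max_duplex_mismatches:
                continue
            if duplex.duplex_bulges > params.max_duplex_bulges:
                continue
            if duplex.pairing_fraction < params.min_pairing_fraction:
                continue
            if duplex.star_span > m + params.max_star_slack:
                continue
            if duplex.arm != window.arm_hint:
                continue
            overhang_ok = (
                0 <= duplex.star_start and duplex.star_end <= len(sub)
                and duplex.star_span >= m - 2
            )
            cand = PrecursorCandidate(
                tag_seq=window.seq[window.tag_offset:window.tag_offset + m],
                total_count=0,
                window=window,
                precursor_interval=window_offsets_to_genome(window, start, end),
                precursor_seq=sub,
                fold=fold,
                mature_offset=window.tag_offset - start,
                duplex=duplex,
                overhang_ok=overhang_ok,
            )
            if best is None or _candidate_quality(cand) > _candidate_quality(best):
                best = cand
    return best


def _candidate_quality(cand: PrecursorCandidate) -> tuple:
    return (
        cand.duplex.pairing_fraction,
        int(cand.overhang_ok),
        -(cand.duplex.duplex_mismatches + cand.duplex.duplex_bulges),
        cand.fold.score_per_base,
    )


class StackIndex:
    """Per-(chrom, strand) index of read 5'-end positions with counts.

    Supports the DCL-cut precision filter: how many read 5' ends fall in a
    window, and how many coincide (within a tolerance) with a given end.
    """

    def __init__(self, tag_hits: Mapping[str, Sequence[GenomicInterval]],
                 tag_counts: Mapping[str, int]):
        acc: dict[tuple[str, str], dict[int, int]] = {}
        for seq, hits in tag_hits.items():
            count = tag_counts.get(seq, 0)
            if count <= 0:
                continue
            for hit in hits:
                five = hit.start if hit.strand == "+" else hit.end
                key = (hit.chrom, hit.strand)
                acc.setdefault(key, {}).setdefault(five, 0)
                acc[key][five] += count
        self._pos: dict[tuple[str, str], np.ndarray] = {}
        self._cum: dict[tuple[str, str], np.ndarray] = {}
        for key, stacks in acc.items():
            pos = np.array(sorted(stacks), dtype=np.int64)
            counts = np.array([stacks[p] for p in pos], dtype=np.int64)
            self._pos[key] = pos
            self._cum[key] = np.concatenate([[0], np.cumsum(counts)])

    def reads_between(self, chrom: str, strand: str, lo: int, hi: int) -> int:
        key = (chrom, strand)
        if key not in self._pos:
            return 0
        pos = self._pos[key]
        i = np.searchsorted(pos, lo, side="left")
        j = np.searchsorted(pos, hi, side="right")
        return int(self._cum[key][j] - self._cum[key][i])

    def stack_fraction(self, hit: GenomicInterval, window: int,
                       tolerance: int) -> float:
        """Fraction of neighbourhood read 5' ends at this hit's own 5' end."""
        five = hit.start if hit.strand == "+" else hit.end
        total = self.reads_between(hit.chrom, hit.strand,
                                   five - window, five + window)
        if total == 0:
            return 0.0
        own = self.reads_between(hit.chrom, hit.strand,
                                 five - tolerance, five + tolerance)
        return own / total


def call_novel_mirnas(tag_hits: Mapping[str, Sequence[GenomicInterval]],
                      tag_counts: Mapping[str, int],
                      genome: Mapping[str, str] | Sequence[SequenceRecord],
                      features: Sequence | FeatureIndex,
                      params: DiscoveryParams = DiscoveryParams(),
                      name_prefix: str = "novel-miR") -> list[MiRNARecord]:
    """Call novel miRNAs from unannotated genome-mapped tags.

    ``tag_hits`` maps tag sequences to their genomic hits; ``tag_counts``
    carries each tag's total read count across libraries. Candidates must
    pass the read-stack precision filter (DCL products pile at precise 5'
    ends) before the hairpin scan. Overlapping passing precursors collapse to
    the best-ranked one; records are named ``novel-miRNN`` in rank order of
    total count.
    """
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    stacks = StackIndex(tag_hits, tag_counts)
    candidates: list[PrecursorCandidate] = []
    for tag_seq, hits in tag_hits.items():
        total = tag_counts.get(tag_seq, 0)
        if total < params.min_total_count:
            continue
        if not (params.mature_min <= len(tag_seq) <= params.mature_max):
            continue
        if len(hits) > params.max_genome_hits:
            continue
        sharp_hits = [
            h for h in hits
            if stacks.stack_fraction(h, params.stack_window,
                                     params.end_tolerance)
            >= params.min_stack_fraction
        ]
        for window in extract_candidate_windows(tag_seq, sharp_hits, genome,
                                                params.flank):
            cand = _evaluate_window(window, params)
            if cand is not None:
                cand.total_count = total
                candidates.append(cand)
    candidates.sort(key=lambda c: c.rank_key)
    accepted: list[PrecursorCandidate] = []
    for cand in candidates:
        clash = any(
            _strandless(cand.precursor_interval).overlaps(
                _strandless(acc.precursor_interval))
            for acc in accepted
        )
        if not clash:
            accepted.append(cand)
    records = []
    for i, cand in enumerate(accepted, 1):
        iv = cand.precursor_interval
        w = cand.window
        records.append(MiRNARecord(
            name=f"{name_prefix}{i:02d}",
            mature_seq=cand.tag_seq,
            arm=cand.duplex.arm,
            interval=iv,
            strand=iv.strand,
            location_classes=[classify_location(iv, index)],
            origin="novel",
            star_seq=cand.duplex.star_seq,
            mature_interval=window_offsets_to_genome(
                w, w.tag_offset, w.tag_offset + w.tag_length),
            duplex_mismatches=cand.duplex.duplex_mismatches,
            duplex_bulges=cand.duplex.duplex_bulges,
            pairing_fraction=cand.duplex.pairing_fraction,
            precursor_seq=cand.precursor_seq,
            structure=cand.fold.structure,
        ))
    return records


def _strandless(iv: GenomicInterval) -> GenomicInterval:
    return GenomicInterval(iv.chrom, iv.start, iv.end, "+")


# ---------------------------------------------------------------------------
# re-classification of previously reported miRNAs

def reclassify_reported_mirna(mature_seq: str,
                              recorded_precursor: str | None,
                              genome: Mapping[str, str] | Sequence[SequenceRecord],
                              features: Sequence | FeatureIndex,
                              params: DiscoveryParams = DiscoveryParams(),
                              name: str = "reported-miR"
                              ) -> tuple[str | None, MiRNARecord | None]:
    """Re-classify a previously reported miRNA against the current genome.

    Returns ``(group, record)``: group ``None`` when the recorded precursor
    still maps exactly (record kept as-is), else "I" (no precursor
    recoverable), "III" (mature perfectly complementary to its star:
    siRNA-like) or "II" (valid imperfect precursor) with the re-predicted
    record.
    """
    if not (params.mature_min <= len(mature_seq) <= params.mature_max):
        raise ValueError("mature length outside 18-24 nt")
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    if recorded_precursor:
        if map_to_genome(recorded_precursor, genome):
            return None, None
    hits = map_to_genome(mature_seq, genome)
    if not hits:
        return "I", None
    best: PrecursorCandidate | None = None
    for window in extract_candidate_windows(mature_seq, hits, genome, params.flank):
        cand = _evaluate_window(window, params)
        if cand is not None and (
            best is None or _candidate_quality(cand) > _candidate_quality(best)
        ):
            best = cand
    if best is None:
        return "I", None
    d = best.duplex
    perfect = (
        d.duplex_mismatches == 0
        and d.duplex_bulges == 0
        and d.pairing_fraction == 1.0
        and (d.gu_pairs == 0 or not params.wc_only_class3)
    )
    group = "III" if perfect else "II"
    iv = best.precursor_interval
    record = MiRNARecord(
        name=name,
        mature_seq=mature_seq,
        arm=d.arm,
        interval=iv,
        strand=iv.strand,
        location_classes=[classify_location(iv, index)],
        origin="known",
        star_seq=d.star_seq,
        mature_interval=window_offsets_to_genome(
            best.window, best.window.tag_offset,
            best.window.tag_offset + best.window.tag_length),
        stem_loop_group=group,
        duplex_mismatches=d.duplex_mismatches,
        duplex_bulges=d.duplex_bulges,
        pairing_fraction=d.pairing_fraction,
        precursor_seq=best.precursor_seq,
        structure=best.fold.structure,
    )
    return group, record
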