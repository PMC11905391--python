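# Methods

`srnakit` re-implements, as a tested library, the small RNA-seq analysis
route used to identify Dicer-like (DCL)-dependent miRNAs in *Chlamydomonas
reinhardtii*: raw-read cleaning into counted clean tags, a tiered annotation
cascade, hairpin-based novel-miRNA prediction, re-classification of
previously reported miRNAs against an updated genome, and TPM-based
differential expression between a wild-type and a knockout group. Because
the original deposited libraries and the full genome are not inputs here,
the pipeline ships with a synthetic-data generator whose planted ground
truth makes every stage testable end to end.

## Read cleaning

Reads are rejected, in fixed order, for: mean Phred quality <= 20; any `N`;
no 3' adapter; an embedded 5' adapter; an insert shorter than 18 nt; polyA
inserts; inserts longer than 30 nt (the size-selection window applied in
software). Interpretation choices where the protocol is under-specified:

* *Quality.* "Q <= 20" is read as the mean Phred score of the read rather
  than a per-base rule; the threshold is a config key.
* *Adapter matching.* The 3' adapter is located by an exact match of its
  first 8 bases anywhere in the read, and everything from the match onward
  is trimmed. Reads without a match whose total length is already below the
  minimum insert are reported `short` rather than `no_3p_adapter`, so an
  empty or truncated read carries the more informative reason.
* *polyA.* An insert is polyA when >= 80% of its bases are A or it contains
  a run of >= 10 consecutive A; both clauses are configurable.

Survivors are collapsed into unique clean tags with per-library counts,
ordered by descending total count then lexicographically, so the tag table
is invariant to read order. Tallies are conserved: rejections plus
survivors equal input reads per library.

## Annotation cascade

Each tag receives exactly one tier, in order: contaminant (exact substring
match, either orientation, against the rRNA/snoRNA/snRNA/tRNA reference),
known miRNA (substring match with up to 2 substitutions against the mature
reference), genome-mapped (exact full-length hits on both strands, found
through a k-mer-anchored index and verified base by base), else unmapped.
Genomic hits are classified by overlapping annotation with priority
exon > 3'UTR > intron; no overlap means intergenic. Overlap is
strand-agnostic and needs one shared base. Multi-mapping tags (> 10 hits)
are kept for quantification but excluded from novel-candidate input.

## Hairpin folding

The folding engine is Nussinov-style base-pair maximization over A·U, G·C
and the G·U wobble, with a minimum hairpin-loop size and a deterministic
traceback (ties resolve to the smallest admissible 5' partner). The
normalized pair count (`score_per_base`) serves as the free-energy proxy.
The DP is exactly checkable: on sequences of length <= 14 its pair count is
asserted equal to exhaustive enumeration of every non-crossing structure.
The kernel is numba-compiled; sequences up to 400 nt fold in milliseconds.

During precursor evaluation the minimum loop is raised to 8 nt (config
`min_loop`). Pre-miRNA terminal loops are sizeable, and the larger floor
keeps pure pair maximization from building tight sub-hairpins between a
mature and its star out of random sequence — the Mireap family of tools
imposes an equivalent minimum mature/star spacing.

## miRNA/miRNA* duplex and novel calling

For a candidate mature at a known position in a folded precursor, the star
segment is the set of positions pairing the mature, shifted so the duplex
carries the 2-nt 3' overhangs characteristic of DCL cleavage. Metrics:
mismatches are mature bases without a partner on the opposite arm; bulges
are asymmetric inter-pair gaps (more star bases skipped than mature bases);
`pairing_fraction` is the paired share of the mature. Candidates whose
mature pairs across the loop, into itself, or into an overlong star span
are rejected.

A tag becomes a novel miRNA when all of the following hold (defaults in
parentheses, all configurable): total count (>= 3), mature length (18–24),
genomic hits (<= 10), duplex mismatches (<= 4), bulges (<= 2), pairing
fraction (>= 0.6), precursor score per base (>= 0.25 pairs/nt), star span
at most mature length + 6. Because global pair maximization pairs long
random flanks promiscuously, each 180-nt-flank window is scanned over a
grid of precursor extents around the tag (pads 2/6/10 nt outward, loopward
extents 30–150 nt) and the best-scoring passing extent is kept.

Two further signals matter:

* *DCL-cut positional precision.* A candidate's own 5'-end stack must
  account for >= 30% of read 5' ends within ±60 nt on its strand. DCL
  products pile at precise ends; mRNA degradation tiles uniformly. This is
  the read-stack signal miRDeep/Mireap-family tools rely on; without it,
  dense degradation stacks in GC-rich exons yield false hairpin calls.
* *Overhang agreement* is a ranking bonus, not a hard filter, since ragged
  ends (isomiRs) are real.

Overlapping passing precursors collapse to the best-ranked one (total
count, then pairing fraction, penalty count, overhang, score). Records are
named `novel-miRNN` in rank order.

## Re-classification of previously reported miRNAs

For a reported mature with (optionally) a recorded precursor: if the
recorded precursor still maps exactly to the genome the record is kept
unchanged. Otherwise the mature is mapped and precursor re-prediction is
attempted at every hit. No passing precursor anywhere → group I (not a
miRNA). A passing precursor whose duplex is perfect — zero mismatches,
zero bulges, full mature pairing, and (by default) no G·U pairs, since
"perfect complementarity" is taken as Watson–Crick only (`wc_only_class3`)
— → group III (siRNA-like). Anything else → group II (miRNA candidate)
with updated coordinates, strand and location. The rule order makes the
groups mutually exclusive and exhaustive.

## Quantification and differential expression

A miRNA's count in a library is the count of tags matching its mature
sequence plus tags mapping inside the mature interval padded by the isomiR
window (±2 nt; captures ragged-end variants; star reads are not counted).
TPM = count / total clean tags of the library × 10^6 — the denominator is
all clean tags, not miRNA-mapped tags only, matching the stated formula.
Group means over the three replicates give fc = mean TPM(knockout) / mean
TPM(control) and log2(fc); a 0.01-TPM pseudocount substitutes for a zero
mean, and records at zero in both groups are excluded as undefined.

Significance is Welch's t on log2(TPM + 1), two-sided. The source analysis
does not name its test; Welch on log-transformed TPM is the honest
unmoderated choice for an n = 3 two-group design, and an exact permutation
test is provided as a cross-check (with n = 3 + 3 its two-sided floor is
p = 0.1, so it cannot replace the t-test at α = 0.05). The 1-TPM offset in
the test (distinct from the 0.01 fold-change guard) stabilizes the log
variance of low-expression records. No multiple-testing correction is
applied — the stated thresholds are raw p < 0.05 with fold change >= 1.5.
Down-regulated records with log2(fc) <= −1 are "high-differential", the
rest "medium-differential"; the boundary value −1 is assigned to high.
Under the generator's null, the test's type-I error sits slightly below
the nominal 0.05 (Welch on log counts with n = 3 is mildly conservative)
but within the binomial 95% band.

Stem-loop RT-qPCR quantification is the standard 2^−ΔΔCt:
ΔΔCt = (Ct_target − Ct_reference)_treated − (Ct_target − Ct_reference)_control.

## Synthetic data

The generator emulates the study design: one GC-rich chromosome (64% GC,
matching the organism; 300 kb), 25 two-exon gene models with intron and
3'UTR, 20 planted stem-loop loci assigned 50/25/15/10% to
intergenic/intron/exon/3'UTR, and two groups (control, knockout) × 3
replicate libraries of 200k reads. Each precursor is left arm + loop
(8–20 nt) + reverse complement of the left arm with 0–3 planted stem
mismatches; every fifth locus is mismatch-free (siRNA-like by
construction). Matures are 20–23 nt (mode 21) with a 75% 5'-U bias.
Reads carry a fixed 21-nt non-genomic 3' adapter and Phred+33 qualities.

Library composition: 25% contaminant fragments, 40% mRNA-degradation
fragments from exonic space, ~1.2% planted defective reads (one class per
cleaning filter, labelled in the read id), the rest miRNA reads split
mature:star at 10:1 with 10% of mature reads carrying ±1-nt ragged ends.
miRNAs are deliberately a minority of the library, as in real sRNA-seq;
an early draft that made them ~75% both misrepresented real libraries and
biased every log2(fc) by ~+0.8 through knockout-group shrinkage of the TPM
denominator. Similarly, the gene space is sized so degradation fragments
tile at a realistic per-nucleotide density relative to locus expression —
a miniature exome concentrates degradation ~100-fold and buries genuinely
expressed exonic loci, an artifact of the toy scale rather than a property
of the method.

Replicate counts are negative-binomial (dispersion 0.1, gamma–Poisson
mixture); knockout libraries scale each locus mean by its configured
fold-reduction (default cycle 0.09–1.0, i.e. log2 fc ≈ −3.5 to 0).
Baseline locus weights are log-uniform over 30–3000. Everything derives
from a single seed; identical configs yield byte-identical files.

What the generator does not emulate: sequencing errors beyond quality
strings, PCR duplicates, the DNA-level 140–160 bp size selection, genuine
siRNA populations, multi-chromosome genomes, and the real length spectrum
beyond making 21 nt the mode. Passing the synthetic recovery and power
checks therefore shows the pipeline's logic is sound at realistic densities
and depths, not that its thresholds are tuned for any particular real
library.

## Problem sizes used in the checks

The end-to-end benchmark runs the default study (20 loci, 6 × 200k reads,
~1–2 minutes on one core). Null calibration uses the count model directly
(200 loci, no read synthesis). The folding oracle compares 500 random
sequences of length <= 14 against exhaustive enumeration. The cleaning
conservation check uses a 6-locus, 5k-read library so every defect class
appears dozens of times.

## Known limitations

* Base-pair maximization is not a thermodynamic model; a stacking-aware
  energy (e.g. ViennaRNA) can be slotted in behind `fold_hairpin` but the
  shipped engine is the one the oracle verifies.
* The annotation cascade matches contaminants exactly; a divergent rRNA
  fragment with sequencing errors would fall through to the genome tier.
* Known-miRNA quantification is by reference matching, so reads from two
  identical mature sequences at different loci are not disambiguated.
* With n = 3 and an unmoderated test, power for effects near the 1.5-fold
  threshold is intrinsically modest; the detection guarantee in the checks
  applies to effects of 4-fold and stronger at TPM >= 50.
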