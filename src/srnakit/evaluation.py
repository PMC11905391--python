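"""Benchmark helpers: score a pipeline run against the generator's truth.

Only meaningful for synthetic studies, where every planted locus and its
knockout effect are known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_stats import de_test, tpm_normalize
from .io_formats import GenomicInterval
from .pipeline import PipelineResult
from .synthetic_data import SimConfig, simulate_locus_counts


@dataclass(frozen=True)
class RecoveryReport:
    n_loci: int
    n_recovered: int
    n_false: int
    locus_to_record: dict[str, str]

    @property
    def recovery_rate(self) -> float:
        return self.n_recovered / self.n_loci


def score_recovery(result: PipelineResult, truth: pd.DataFrame
                   ) -> RecoveryReport:
    """Match called miRNAs against planted loci.

    A locus counts as recovered when its mature was identified as a known
    miRNA or a called precursor overlaps the planted precursor interval; a
    novel call overlapping no planted locus is a false locus.
    """
    truth_ivs = [
        (row.locus_id, GenomicInterval(row.chrom, int(row.start), int(row.end)))
        for row in truth.itertuples()
    ]
    locus_to_record: dict[str, str] = {}
    known_found = {a.matched_id for a in result.annotations
                   if a.tier == "known_miRNA"}
    for row in truth.itertuples():
        ref_id = f"cre-miR-sim{int(row.locus_id[5:]):02d}"
        if row.is_known and ref_id in known_found:
            locus_to_record[row.locus_id] = ref_id
    n_false = 0
    for rec in result.novel:
        iv = GenomicInterval(rec.interval.chrom, rec.interval.start,
                             rec.interval.end)
        matched = [lid for lid, tiv in truth_ivs if iv.overlaps(tiv)]
        if matched:
            for lid in matched:
                locus_to_record.setdefault(lid, rec.name)
        else:
            n_false += 1
    return RecoveryReport(
        n_loci=len(truth_ivs),
        n_recovered=len(locus_to_record),
        n_false=n_false,
        locus_to_record=locus_to_record,
    )


def score_knockout_detection(result: PipelineResult, truth: pd.DataFrame,
                             recovery: RecoveryReport,
                             max_effect: float = 0.25,
                             min_tpm: float = 50.0) -> tuple[int, int]:
    """(flagged, eligible): how many strongly knocked-down planted loci the
    DE stage flagged as significantly down-regulated."""
    by_name = {r.name: r for r in result.expression}
    flagged = eligible = 0
    for row in truth.itertuples():
        if row.knockout_effect > max_effect:
            continue
        if row.expected_tpm_control < min_tpm:
            continue
        eligible += 1
        name = recovery.locus_to_record.get(row.locus_id)
        rec = by_name.get(name) if name else None
        if rec is not None and rec.status == "down":
            flagged += 1
    return flagged, eligible


def null_type1_error(sim: SimConfig, alpha: float = 0.05) -> float:
    """Fraction of null loci called significant by the DE test.

    Draws replicate counts from the generator's count model with every
    knockout effect forced to 1.0, normalizes to TPM and applies the test.
    """
    counts = simulate_locus_counts(sim, null=True)
    libs = [f"{g}_{i}" for g in ("control", "knockout")
            for i in range(1, sim.replicates_per_group + 1)]
    totals = {lib: int(counts[lib].sum()) for lib in libs}
    n_sig = 0
    for row in counts.itertuples():
        k = [tpm_normalize(getattr(row, f"knockout_{i}"), totals[f"knockout_{i}"])
             for i in range(1, sim.replicates_per_group + 1)]
        c = [tpm_normalize(getattr(row, f"control_{i}"), totals[f"control_{i}"])
             for i in range(1, sim.replicates_per_group + 1)]
        if de_test(k, c) < alpha:
            n_sig += 1
    return n_sig / len(counts)


def binomial_interval(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation 95% band for an observed proportion under p."""
    half = z * np.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), p + half
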