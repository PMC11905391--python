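"""TPM normalization, fold change, significance and DE tiers; 2^-ddCt qPCR.

Expression of a miRNA in one library is TPM = miRNA read count / total clean
tags x 10^6. The knockout/control comparison uses fold change
fc = mean TPM(knockout) / mean TPM(control) and log2(fc); a miRNA is
down-regulated when log2(fc) <= -log2(1.5) with p < 0.05, and among the
down-regulated ones, "high-differential" when log2(fc) <= -1, else
"medium-differential". The significance test is Welch's t on
log2(TPM + pseudocount) — the honest choice for an n = 3 two-group design;
a permutation alternative is available for cross-checking. No
multiple-testing correction is applied (raw p < 0.05).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LOG2_1_5 = math.log2(1.5)

#: Published quantification of the 22 miRNAs significantly down-regulated in
#: the C. reinhardtii dcl1 knockout (group-mean TPM over three replicate
#: libraries per group, and the published log2 fold change). Used as worked
#: examples for the fold-change and tier arithmetic.
DCL1_DOWNREGULATED = pd.DataFrame(
    [
        ("novel-miR01", 3.5, 0.15, -4.523),
        ("novel-miR02", 1.37, 0.08, -4.169),
        ("novel-miR03", 1.18, 0.08, -3.956),
        ("novel-miR04", 375.57, 32.48, -3.531),
        ("novel-miR05", 3.11, 0.32, -3.289),
        ("novel-miR06", 55.04, 6.52, -3.078),
        ("cre-miR1166.1", 14.93, 1.83, -3.028),
        ("novel-miR07", 2.62, 0.67, -1.976),
        ("novel-miR08", 3.22, 0.85, -1.92),
        ("novel-miR09", 4.13, 1.24, -1.737),
        ("novel-miR10", 61.72, 19.9, -1.633),
        ("novel-miR11", 5.14, 1.98, -1.376),
        ("novel-miR12", 31.24, 12.49, -1.322),
        ("novel-miR13", 9.78, 4.3, -1.184),
        ("cre-miR1165-5p", 2745.53, 1478.23, -0.893),
        ("novel-miR14", 11.19, 6.12, -0.87),
        ("cre-miR1165-3p", 3202.79, 1831.38, -0.806),
        ("novel-miR15", 19.31, 11.05, -0.806),
        ("cre-miR918", 221.83, 130.13, -0.769),
        ("cre-miR910", 40883.05, 24703.94, -0.727),
        ("novel-miR16", 16175.43, 9927.71, -0.704),
        ("miR_t20*", 98402.4, 62535.6, -0.654),
    ],
    columns=["name", "control_mean_tpm", "knockout_mean_tpm", "log2fc"],
)


@dataclass
class ExpressionRecord:
    name: str
    tpm: dict[str, float]            # per-library TPM
    group_means: dict[str, float]    # group -> mean TPM
    fc: float
    log2fc: float
    p_value: float
    status: str                      # up | down | ns
    tier: str                        # high | medium | none


@dataclass(frozen=True)
class QpcrMeasurement:
    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float
    ddct: float
    relative_expression: float


def tpm_normalize(count: float, total_clean_tags: int) -> float:
    """count / total clean tags x 10^6."""
    if total_clean_tags <= 0:
        raise ValueError("total clean tags must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total_clean_tags * 1e6


def fold_change(mean_knockout_tpm: float, mean_control_tpm: float,
                pseudocount: float = 0.01) -> tuple[float, float]:
    """(fc, log2fc) of knockout over control group-mean TPM.

    The pseudocount replaces a zero mean only; both means zero is undefined
    and raises so the caller can flag and exclude the record.
    """
    if mean_knockout_tpm < 0 or mean_control_tpm < 0:
        raise ValueError("group means must be non-negative")
    if mean_knockout_tpm == 0 and mean_control_tpm == 0:
        raise ValueError("fold change undefined: both group means are zero")
    num = mean_knockout_tpm or pseudocount
    den = mean_control_tpm or pseudocount
    fc = num / den
    return fc, math.log2(fc)


def de_test(knockout_tpm: np.ndarray | list[float],
            control_tpm: np.ndarray | list[float],
            pseudocount: float = 1.0) -> float:
    """Two-sided Welch's t p-value on log2(TPM + pseudocount).

    The default offset of 1 TPM stabilizes the log variance of
    low-expression records (a replicate with zero reads would otherwise
    dominate the test). Returns 1.0 for the degenerate case of zero variance
    in both groups with equal means.
    """
    a = np.log2(np.asarray(knockout_tpm, dtype=float) + pseudocount)
    b = np.log2(np.asarray(control_tpm, dtype=float) + pseudocount)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def de_test_permutation(knockout_tpm, control_tpm, pseudocount: float = 1.0
                        ) -> float:
    """Exact permutation p-value on the difference of log2 group means.

    Independent cross-check for :func:`de_test`; enumerates all group
    relabelings (exact for n = 3 + 3).
    """
    a = np.log2(np.asarray(knockout_tpm, dtype=float) + pseudocount)
    b = np.log2(np.asarray(control_tpm, dtype=float) + pseudocount)
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = abs(a.mean() - b.mean())
    hits = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(combo)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        if diff >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def classify_de(log2fc: float, p_value: float) -> tuple[str, str]:
    """(status, tier) under the fc >= 1.5, p < 0.05 thresholds.

    Down-regulated records are "high" when log2fc <= -1 (the boundary value
    -1 counts as high), otherwise "medium".
    """
    if not (math.isfinite(log2fc) and math.isfinite(p_value)):
        raise ValueError("inputs must be finite")
    if p_value < 0.05 and log2fc <= -LOG2_1_5:
        return "down", "high" if log2fc <= -1 else "medium"
    if p_value < 0.05 and log2fc >= LOG2_1_5:
        return "up", "none"
    return "ns", "none"


def ddct(ct_target_treated: float, ct_ref_treated: float,
         ct_target_control: float, ct_ref_control: float) -> QpcrMeasurement:
    """Relative expression by the 2^-ddCt method."""
    delta = ((ct_target_treated - ct_ref_treated)
             - (ct_target_control - ct_ref_control))
    return QpcrMeasurement(ct_target_treated, ct_ref_treated,
                           ct_target_control, ct_ref_control,
                           ddct=delta, relative_expression=2.0 ** -delta)


def quantify(counts: pd.DataFrame, totals: dict[str, int],
             groups: dict[str, str], pseudocount: float = 0.01,
             test_pseudocount: float = 1.0) -> list[ExpressionRecord]:
    """Build expression records from a miRNA x library count table.

    ``counts`` is indexed by miRNA name with one column per library;
    ``totals`` gives each library's total clean tags (the TPM denominator);
    ``groups`` maps library -> group name ("control"/"knockout"). Records
    with zero TPM in every library are excluded (fold change undefined).
    """
    libs = list(counts.columns)
    out: list[ExpressionRecord] = []
    control_libs = [l for l in libs if groups[l] == "control"]
    knockout_libs = [l for l in libs if groups[l] == "knockout"]
    for name, row in counts.iterrows():
        tpm = {lib: tpm_normalize(float(row[lib]), totals[lib]) for lib in libs}
        mean_c = float(np.mean([tpm[l] for l in control_libs]))
        mean_k = float(np.mean([tpm[l] for l in knockout_libs]))
        if mean_c == 0 and mean_k == 0:
            continue
        fc, log2fc = fold_change(mean_k, mean_c, pseudocount)
        p = de_test([tpm[l] for l in knockout_libs],
                    [tpm[l] for l in control_libs], test_pseudocount)
        status, tier = classify_de(log2fc, p)
        out.append(ExpressionRecord(
            name=str(name), tpm=tpm,
            group_means={"control": mean_c, "knockout": mean_k},
            fc=fc, log2fc=log2fc, p_value=p, status=status, tier=tier,
        ))
    return out


def expression_frame(records: list[ExpressionRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({
            "name": rec.name,
            **{f"tpm_{lib}": v for lib, v in rec.tpm.items()},
            "control_mean_tpm": rec.group_means["control"],
            "knockout_mean_tpm": rec.group_means["knockout"],
            "fc": rec.fc,
            "log2fc": rec.log2fc,
            "p_value": rec.p_value,
            "status": rec.status,
            "tier": rec.tier,
        })
    return pd.DataFrame(rows)
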