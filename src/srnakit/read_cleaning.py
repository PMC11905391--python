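"""Raw-read filtering, 3' adapter trimming and clean-tag collapsing.

Raw small-RNA reads are rejected for: low mean quality (Q <= 20), unknown
bases (N), missing 3' adapter, embedded 5' adapter, insert shorter than
18 nt, polyA inserts, and inserts longer than the 18-30 nt size-selection
window. Survivors are trimmed to the insert and collapsed into unique clean
tags with per-library counts — the unit of all downstream annotation and
quantification.

Interpretation choices (the source protocol leaves these open):

* "Q value <= 20" is read as the mean Phred score of the read; the threshold
  is configurable.
* The 3' adapter is located by an exact match of its first ``adapter_seed``
  bases anywhere in the read; everything from the match onward is trimmed.
  Reads without a match are rejected as ``no_3p_adapter`` unless the whole
  read is already shorter than the minimum insert, in which case the more
  informative ``short`` reason is reported.
* "polyA" inserts are those with >= 80% A or a run of >= 10 consecutive A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import Read

#: rejection reasons, in the order the filters are applied
REASONS = (
    "low_quality",
    "contains_N",
    "no_3p_adapter",
    "has_5p_adapter",
    "short",
    "polyA",
    "long",
)


@dataclass(frozen=True)
class CleaningParams:
    quality_threshold: float = 20.0   # reject when mean Phred <= this
    min_length: int = 18
    max_length: int = 30
    adapter_seed: int = 8             # leading adapter bases used for matching
    polya_fraction: float = 0.8
    polya_run: int = 10


@dataclass
class CleanTag:
    """A unique trimmed insert with per-library read counts."""

    seq: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class LibraryTally:
    """Per-library cleaning bookkeeping; tallies sum to input reads."""

    input_reads: int = 0
    rejected: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASONS})
    surviving_reads: int = 0
    unique_tags: int = 0

    def check(self) -> bool:
        return self.input_reads == self.surviving_reads + sum(
            self.rejected.values())


def clean_read(read: Read, adapter3: str, adapter5: str,
               params: CleaningParams = CleaningParams()
               ) -> tuple[str | None, str | None]:
    """Apply the cleaning filters to one read.

    Returns ``(insert, None)`` for a surviving read, or ``(None, reason)``
    with the first failing filter's reason otherwise.
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    seq = read.seq
    if not seq:
        return None, "short"
    if sum(read.qual) / len(read.qual) <= params.quality_threshold:
        return None, "low_quality"
    if "N" in seq:
        return None, "contains_N"
    seed = adapter3[: params.adapter_seed]
    pos = seq.find(seed)
    if pos < 0:
        if len(seq) < params.min_length:
            return None, "short"
        return None, "no_3p_adapter"
    insert = seq[:pos]
    if adapter5 in insert:
        return None, "has_5p_adapter"
    if len(insert) < params.min_length:
        return None, "short"
    if _is_polya(insert, params):
        return None, "polyA"
    if len(insert) > params.max_length:
        return None, "long"
    return insert, None


def _is_polya(insert: str, params: CleaningParams) -> bool:
    if insert.count("A") >= params.polya_fraction * len(insert):
        return True
    return "A" * params.polya_run in insert


def clean_library(reads: Iterable[Read], adapter3: str, adapter5: str,
                  params: CleaningParams = CleaningParams()
                  ) -> tuple[list[str], LibraryTally]:
    """Clean one library; returns surviving inserts and the tally."""
    tally = LibraryTally()
    inserts: list[str] = []
    for read in reads:
        tally.input_reads += 1
        insert, reason = clean_read(read, adapter3, adapter5, params)
        if insert is None:
            tally.rejected[reason] += 1
        else:
            tally.surviving_reads += 1
            inserts.append(insert)
    return inserts, tally


def collapse_tags(inserts_by_library: Mapping[str, Sequence[str]],
                  libraries: Sequence[str]) -> list[CleanTag]:
    """Collapse inserts into unique tags with per-library counts.

    Tags are ordered by descending total count, then lexicographically, so
    output is invariant to input read order.
    """
    for name in inserts_by_library:
        if name not in libraries:
            raise KeyError(f"library {name!r} absent from sample sheet")
    counts: dict[str, dict[str, int]] = {}
    for lib, inserts in inserts_by_library.items():
        for seq in inserts:
            per = counts.setdefault(seq, dict.fromkeys(libraries, 0))
            per[lib] += 1
    tags = [CleanTag(seq, per) for seq, per in counts.items()]
    tags.sort(key=lambda t: (-t.total, t.seq))
    return tags


def length_distribution(tags: Sequence[CleanTag],
                        libraries: Sequence[str]) -> pd.DataFrame:
    """Read-count-weighted insert length proportions per library.

    Rows are lengths, columns libraries; each column sums to 1.
    """
    if not tags:
        raise ValueError("no tags")
    rows: dict[int, dict[str, int]] = {}
    for tag in tags:
        per = rows.setdefault(len(tag.seq), dict.fromkeys(libraries, 0))
        for lib in libraries:
            per[lib] += tag.counts.get(lib, 0)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return df / df.sum(axis=0)


def tags_to_frame(tags: Sequence[CleanTag],
                  libraries: Sequence[str]) -> pd.DataFrame:
    rows = [
        {"sequence": t.seq, **{lib: t.counts.get(lib, 0) for lib in libraries}}
        for t in tags
    ]
    return pd.DataFrame(rows, columns=["sequence", *libraries])


def tally_frame(tallies: Mapping[str, LibraryTally]) -> pd.DataFrame:
    rows = []
    for lib, t in tallies.items():
        rows.append({
            "library": lib,
            "input_reads": t.input_reads,
            **{f"rejected_{r}": t.rejected[r] for r in REASONS},
            "surviving_reads": t.surviving_reads,
            "unique_tags": t.unique_tags,
        })
    return pd.DataFrame(rows)
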