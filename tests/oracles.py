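"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

from typing import Iterator

CANONICAL = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"),
             ("G", "T"), ("T", "G")}


def enumerate_structures(seq: str, min_loop: int = 3
                         ) -> Iterator[frozenset[tuple[int, int]]]:
    """Yield every non-crossing structure over canonical pairs (incl. G·U).

    Explicit exhaustive enumeration — exponential, usable for len(seq) <= ~16.
    """
    n = len(seq)

    def rec(i: int, j: int) -> list[frozenset]:
        if j - i <= min_loop:
            return [frozenset()]
        out = list(rec(i + 1, j))
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in CANONICAL:
                for left in rec(i + 1, k - 1):
                    right = rec(k + 1, j) if k < j else [frozenset()]
                    for rgt in right:
                        out.append(left | rgt | {(i, k)})
        return out

    seen = set()
    for s in rec(0, n - 1):
        if s not in seen:
            seen.add(s)
            yield s


def max_pairs_by_enumeration(seq: str, min_loop: int = 3) -> int:
    """Maximum base-pair count over all enumerated non-crossing structures."""
    return max(len(s) for s in enumerate_structures(seq, min_loop))


def hamming_substring_match(query: str, reference: str, max_mismatches: int
                            ) -> bool:
    """Brute-force Hamming scan of the query against every reference offset."""
    m = len(query)
    for start in range(len(reference) - m + 1):
        window = reference[start:start + m]
        if sum(a != b for a, b in zip(query, window)) <= max_mismatches:
            return True
    return False


def naive_genome_hits(tag: str, seqs: dict[str, str], rc: str
                      ) -> list[tuple[str, int, int, str]]:
    """Every exact occurrence of tag (and its reverse complement) by scanning
    each offset explicitly."""
    m = len(tag)
    out = []
    for chrom, seq in seqs.items():
        for i in range(len(seq) - m + 1):
            window = seq[i:i + m]
            if window == tag:
                out.append((chrom, i + 1, i + m, "+"))
            if window == rc and rc != tag:
                out.append((chrom, i + 1, i + m, "-"))
    return sorted(out)
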