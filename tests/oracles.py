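"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's numpy code paths: plain Python
tallies, Counter, statistics.fmean, and a literal transcription of the
greedy merge procedure. They are imported by the test suite and by
scripts/acceptance.py, and must stay independent of src/umidedup internals
beyond the public data containers they score.
"""

from __future__ import annotations

from collections import Counter
from statistics import fmean


def brute_consensus(reads: list[tuple[str, list[int]]]) -> tuple[str, list[int]]:
    """Per-base consensus of equal-length (sequence, qualities) reads.

    At each column: tally base frequencies and mean qualities; score each
    base by the mean of its percentage frequency and its mean Phred quality;
    pick the top score, break ties by higher mean quality, then by the
    alphabetically smallest base; emit the winner's mean quality rounded
    half-up.
    """
    length = len(reads[0][0])
    out_seq, out_qual = [], []
    for pos in range(length):
        column = [(seq[pos], quals[pos]) for seq, quals in reads]
        counts = Counter(base for base, _ in column)
        best = None
        for base, count in counts.items():
            freq_pct = 100.0 * count / len(column)
            meanq = fmean(q for b, q in column if b == base)
            score = (freq_pct + meanq) / 2.0
            cand = (score, meanq, _reverse_lex(base))
            if best is None or cand > best[0]:
                best = (cand, base, meanq)
        assert best is not None
        out_seq.append(best[1])
        q = best[2]
        out_qual.append(min(max(int(q + 0.5) if q >= 0 else 0, 0), 41))
    return "".join(out_seq), out_qual


def _reverse_lex(base: str) -> int:
    # larger is better in the max(); later letters must lose ties
    return -"ACGNT".index(base)


def brute_hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return len([1 for x, y in zip(a, b) if x != y])


def brute_merge(
    groups: list[tuple[str, int, str, str | None]],
    umi_distance: int,
    seq_distance: int,
) -> list[tuple[str, list[str]]]:
    """Literal transcription of the greedy merge loop.

    ``groups`` holds (umi, read_count, consensus_r1, consensus_r2-or-None).
    Returns (representative_umi, absorbed_umis) per cluster, in creation
    order: repeatedly take the unassigned UMI with the most reads (ties to
    the smallest UMI string), absorb every other unassigned UMI within
    ``umi_distance`` of it whose consensus read(s) are within
    ``seq_distance``, remove them all, repeat.
    """
    remaining = list(groups)
    clusters = []
    while remaining:
        seed = min(remaining, key=lambda g: (-g[1], g[0]))
        absorbed = []
        for g in remaining:
            if g is seed:
                continue
            if brute_hamming(seed[0], g[0]) > umi_distance:
                continue
            if brute_hamming(seed[2], g[2]) > seq_distance:
                continue
            if seed[3] is not None and brute_hamming(seed[3], g[3]) > seq_distance:
                continue
            absorbed.append(g)
        clusters.append((seed[0], sorted(a[0] for a in absorbed)))
        dropped = {id(seed)} | {id(a) for a in absorbed}
        remaining = [g for g in remaining if id(g) not in dropped]
    return clusters
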