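"""Per-base consensus calling over a group of equal-length reads.

For every read position the base counts and the arithmetic mean Phred
quality of each observed base are tabulated. A base's selection criterion is
the mean of its frequency (as a percentage of the group, 0-100) and its mean
quality (raw Phred scale, 0-41) — two quantities of comparable magnitude.
The base with the highest criterion wins; a criterion tie goes to the base
with the higher mean quality, and a remaining tie to the alphabetically
smallest base (A < C < G < N < T). The consensus quality at that position is
the winner's mean quality, rounded half-up and clipped to [0, 41].

``N`` participates as a fifth base symbol: it can win a position only by the
same criterion as any other base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fastq_io import MAX_PHRED, ReadRecord

ALPHABET = "ACGNT"  # lexicographic; doubles as the tie-break order
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_LOOKUP = np.full(256, -1, dtype=np.int8)
for _b, _i in _CODE.items():
    _LOOKUP[ord(_b)] = _i


@dataclass(frozen=True)
class PositionProfile:
    """Base counts and per-base mean Phred quality at one read position."""

    position: int
    counts: dict[str, int]
    mean_quality: dict[str, float]  # defined only for bases with count > 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ConsensusRead:
    """A collapsed group: one sequence + quality string and its read support."""

    sequence: str
    qualities: tuple[int, ...]
    support: int

    def to_record(self, read_id: str) -> ReadRecord:
        return ReadRecord(read_id, self.sequence, self.qualities)


def _encode(members: Sequence[ReadRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not members:
        raise ValueError("cannot build a profile from an empty group")
    length = len(members[0])
    seqs = np.frombuffer(
        "".join(m.sequence for m in members).encode("ascii"), dtype=np.uint8
    )
    if seqs.size != len(members) * length:
        raise ValueError("ragged read lengths in group")
    codes = _LOOKUP[seqs].reshape(len(members), length)
    if (codes < 0).any():
        bad = chr(seqs[(_LOOKUP[seqs] < 0).argmax()])
        raise ValueError(f"unsupported base symbol {bad!r}; alphabet is {ALPHABET}")
    quals = np.array([m.qualities for m in members], dtype=np.float64)
    return codes, quals


def build_profile(members: Sequence[ReadRecord]) -> list[PositionProfile]:
    """Tabulate counts and mean qualities at every position of the group."""
    codes, quals = _encode(members)
    n_reads, length = codes.shape
    counts = np.zeros((length, len(ALPHABET)), dtype=np.int64)
    qual_sums = np.zeros((length, len(ALPHABET)), dtype=np.float64)
    pos_idx = np.broadcast_to(np.arange(length), codes.shape)
    np.add.at(counts, (pos_idx, codes), 1)
    np.add.at(qual_sums, (pos_idx, codes), quals)

    profiles = []
    for pos in range(length):
        cnt = {b: int(counts[pos, i]) for b, i in _CODE.items() if counts[pos, i]}
        meanq = {
            b: float(qual_sums[pos, _CODE[b]] / c) for b, c in cnt.items()
        }
        profiles.append(PositionProfile(pos, cnt, meanq))
    return profiles


def consensus_base(profile: PositionProfile) -> tuple[str, int]:
    """Pick the winning base and its integer consensus quality at one position."""
    total = profile.total
    if total < 1:
        raise ValueError(f"position {profile.position}: empty profile")
    best_base = None
    best_key: tuple[float, float, str] | None = None
    for base, count in profile.counts.items():
        freq_pct = 100.0 * count / total
        meanq = profile.mean_quality[base]
        criterion = (freq_pct + meanq) / 2.0
        # Maximize criterion, then mean quality; final tie -> smallest base.
        key = (-criterion, -meanq, base)
        if best_key is None or key < best_key:
            best_key = key
            best_base = base
    assert best_base is not None
    quality = int(math.floor(profile.mean_quality[best_base] + 0.5))
    return best_base, min(max(quality, 0), MAX_PHRED)


def consensus_read(members: Sequence[ReadRecord]) -> ConsensusRead:
    """Collapse a group of equal-length reads into one consensus read."""
    calls = [consensus_base(p) for p in build_profile(members)]
    return ConsensusRead(
        sequence="".join(base for base, _ in calls),
        qualities=tuple(q for _, q in calls),
        support=len(members),
    )
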