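"""FASTQ input/output with Phred+33 qualities.

Readers are streaming generators: memory use is bounded per record, never
per file. Files ending in ``.gz`` are transparently (de)compressed. Only the
Sanger/Illumina-1.8 Phred+33 encoding is supported, with scores clipped to
the contractual range [0, 41].
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
MAX_PHRED = 41

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ record: header (without ``@``), bases, integer Phred scores."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"record {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        for q in self.qualities:
            if not 0 <= q <= MAX_PHRED:
                raise ValueError(
                    f"record {self.read_id!r}: Phred score {q} outside [0, {MAX_PHRED}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadPair:
    """A synchronized forward/reverse read pair (R1/R2)."""

    r1: ReadRecord
    r2: ReadRecord

    def __post_init__(self) -> None:
        if mate_root(self.r1.read_id) != mate_root(self.r2.read_id):
            raise ValueError(
                f"mate identifiers disagree: {self.r1.read_id!r} vs {self.r2.read_id!r}"
            )


def mate_root(read_id: str) -> str:
    """Read identity shared by both mates.

    Strips the space-delimited Illumina mate field ("... 1:N:0:..."), or a
    trailing "/1" / "/2" (old Casava dialect).
    """
    root = read_id.split(None, 1)[0] if read_id else read_id
    if root.endswith(("/1", "/2")):
        root = root[:-2]
    return root


def decode_qualities(quality_string: str) -> tuple[int, ...]:
    """Phred+33 characters -> integer scores, clipped to [0, 41]."""
    scores = []
    for ch in quality_string:
        q = ord(ch) - PHRED_OFFSET
        if q < 0:
            raise ValueError(f"quality character {ch!r} below Phred+33 range")
        scores.append(min(q, MAX_PHRED))
    return tuple(scores)


def encode_qualities(qualities: Iterable[int]) -> str:
    """Integer scores -> Phred+33 string; scores must lie in [0, 41]."""
    chars = []
    for q in qualities:
        if not 0 <= q <= MAX_PHRED:
            raise ValueError(f"Phred score {q} outside [0, {MAX_PHRED}]")
        chars.append(chr(q + PHRED_OFFSET))
    return "".join(chars)


def _open_text(path: Path, mode: str) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream records from a (possibly gzipped) 4-line FASTQ file.

    Malformed records (truncated block, missing ``+`` line, sequence/quality
    length mismatch) raise ValueError naming the 0-based record index.
    """
    path = Path(path)
    index = 0
    with _open_text(path, "r") as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise ValueError("sequence/quality length mismatch")
                yield ReadRecord(title, seq.upper(), decode_qualities(qual))
                index += 1
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ at record {index}: {exc}") from exc


def read_fastq_paired(
    path_r1: str | Path, path_r2: str | Path
) -> Iterator[ReadPair]:
    """Stream synchronized pairs from two FASTQ files.

    Unequal record counts or a per-pair identifier mismatch raise ValueError
    with the offending position.
    """
    it1, it2 = read_fastq(path_r1), read_fastq(path_r2)
    index = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            return
        if rec1 is None or rec2 is None:
            longer = path_r2 if rec1 is None else path_r1
            raise ValueError(
                f"unequal record counts: {longer} has extra records from pair {index}"
            )
        try:
            yield ReadPair(rec1, rec2)
        except ValueError as exc:
            raise ValueError(f"pair {index}: {exc}") from exc
        index += 1


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as Phred+33 FASTQ (gzipped if path ends in .gz).

    Returns the number of records written.
    """
    path = Path(path)
    count = 0
    with _open_text(path, "w") as handle:
        for rec in records:
            handle.write(
                f"@{rec.read_id}\n{rec.sequence}\n+\n{encode_qualities(rec.qualities)}\n"
            )
            count += 1
    return count


def corrected_name(input_path: str | Path) -> str:
    """Output file name: input root + "_corrected" + original extension(s).

    ``sampleA_R1.fastq`` -> ``sampleA_R1_corrected.fastq``;
    ``x.fastq.gz`` -> ``x_corrected.fastq.gz``.
    """
    name = Path(input_path).name
    suffixes = ""
    while True:
        stem, dot, ext = name.rpartition(".")
        if dot and ext.lower() in {"fastq", "fq", "gz"}:
            suffixes = "." + ext + suffixes
            name = stem
        else:
            break
    return name + "_corrected" + suffixes
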