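"""UMI extraction, exact grouping, and count-based cleaning.

The molecular barcode (UMI) sits at the 5' start of the read. Three library
layouts are supported:

* single-end, UMI on R1;
* paired-end, UMI on R1 only;
* paired-end, UMIs on both R1 and R2 (the two barcodes are concatenated
  into a single 2k key that identifies the molecule).

Reads sharing an identical key form a :class:`UmiGroup`; groups below the
``countsCutoff`` read-count floor are dropped before any correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from .fastq_io import ReadPair, ReadRecord

UMI_LOCATION_R1 = "R1"
UMI_LOCATION_R1R2 = "R1andR2"


@dataclass
class RunConfig:
    """User-facing run parameters plus I/O paths.

    Field names mirror the tool's documented options: ``pairedData`` selects
    paired-end input, ``UMIlocation`` is "R1" or "R1andR2", ``UMIlength`` is
    the barcode length k, ``sequenceLength`` the insert length n,
    ``countsCutoff`` the minimum reads per UMI kept by data cleaning, and
    ``UMIdistance`` / ``sequenceDistance`` the Hamming-distance ceilings used
    when merging near-identical barcodes.
    """

    pairedData: bool = False
    UMIlocation: str = UMI_LOCATION_R1
    UMIlength: int = 12
    sequenceLength: int = 50
    countsCutoff: int = 1
    UMIdistance: int = 1
    sequenceDistance: int = 3
    input_dir: Path = Path(".")
    output_dir: Path = Path("corrected")

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if self.UMIlength < 1:
            raise ValueError("UMIlength must be >= 1")
        if self.sequenceLength < 1:
            raise ValueError("sequenceLength must be >= 1")
        if self.countsCutoff < 0:
            raise ValueError("countsCutoff must be >= 0")
        if self.UMIdistance < 0 or self.sequenceDistance < 0:
            raise ValueError("distance thresholds must be >= 0")
        if self.UMIlocation not in (UMI_LOCATION_R1, UMI_LOCATION_R1R2):
            raise ValueError(
                f"UMIlocation must be {UMI_LOCATION_R1!r} or {UMI_LOCATION_R1R2!r}"
            )
        if self.UMIlocation == UMI_LOCATION_R1R2 and not self.pairedData:
            raise ValueError("UMIlocation=R1andR2 requires pairedData=True")


Insert = Union[ReadRecord, ReadPair]


@dataclass
class UmiGroup:
    """All insert reads (and mates, when paired) carrying one UMI key."""

    umi: str
    members: list[ReadRecord] = field(default_factory=list)
    mates: list[ReadRecord] | None = None

    @property
    def count(self) -> int:
        return len(self.members)


def _split_prefix(read: ReadRecord, k: int) -> tuple[str, ReadRecord]:
    if len(read) < k + 1:
        raise ValueError(
            f"read {read.read_id!r} has length {len(read)} < UMIlength+1 = {k + 1}"
        )
    return read.sequence[:k], ReadRecord(
        read.read_id, read.sequence[k:], read.qualities[k:]
    )


def extract_umi(read: Insert, config: RunConfig) -> tuple[str, Insert]:
    """Split off the 5' UMI(s); the barcode's quality scores are discarded.

    Returns ``(umi_key, insert)`` where the insert keeps the read identifier
    and the remaining bases/qualities. For dual-barcode libraries the key is
    the R1 barcode concatenated with the R2 barcode and both mates are
    trimmed.
    """
    k = config.UMIlength
    if isinstance(read, ReadPair):
        if config.UMIlocation == UMI_LOCATION_R1R2:
            umi1, insert1 = _split_prefix(read.r1, k)
            umi2, insert2 = _split_prefix(read.r2, k)
            return umi1 + umi2, ReadPair(insert1, insert2)
        umi, insert1 = _split_prefix(read.r1, k)
        return umi, ReadPair(insert1, read.r2)
    if config.pairedData:
        raise TypeError("pairedData=True but a single ReadRecord was given")
    umi, insert = _split_prefix(read, k)
    return umi, insert


def group_by_umi(extracted: Iterable[tuple[str, Insert]]) -> list[UmiGroup]:
    """Collect inserts by exact UMI key.

    Returns groups in deterministic order: descending read count, ties broken
    by lexicographic UMI. All inserts must share one length (hard error
    otherwise — the method is strictly columnar).
    """
    table: dict[str, UmiGroup] = {}
    insert_len: int | None = None
    mate_len: int | None = None
    for key, insert in extracted:
        if isinstance(insert, ReadPair):
            r1, r2 = insert.r1, insert.r2
        else:
            r1, r2 = insert, None
        if insert_len is None:
            insert_len = len(r1)
            mate_len = len(r2) if r2 is not None else None
        if len(r1) != insert_len or (r2 is not None and len(r2) != mate_len):
            raise ValueError(
                f"mixed insert lengths: read {r1.read_id!r} breaks the "
                f"single-length contract ({insert_len} bp)"
            )
        group = table.get(key)
        if group is None:
            group = table[key] = UmiGroup(key, [], [] if r2 is not None else None)
        group.members.append(r1)
        if r2 is not None:
            assert group.mates is not None
            group.mates.append(r2)
    return sorted(table.values(), key=lambda g: (-g.count, g.umi))


def clean_groups(groups: Sequence[UmiGroup], countsCutoff: int) -> list[UmiGroup]:
    """Keep groups with at least ``countsCutoff`` reads (inclusive floor)."""
    return [g for g in groups if g.count >= countsCutoff]
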