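"""Adapter trimming and UMI-based duplicate collapsing.

The library structure places the captured RNA 3' end immediately before a
6-nt random hexamer (the UMI) and the constant 3' adapter:

    read = insert + UMI(6) + AGATCGGAAGAGCACACGTCT + downstream primer bases

Locating the adapter therefore recovers the RNA 3' end exactly.  Matching is
substitution-only, leftmost acceptable match, with a mismatch budget of
``floor(max_error_rate * aligned_length)`` and a minimum terminal overlap —
the usual 3'-adapter semantics.  Reads without a detectable adapter are
discarded: without the adapter position, neither the RNA 3' end nor the UMI
can be identified.

Collapsing groups reads by the exact (insert + UMI) string; every distinct
string is taken to be one original RNA molecule, and the group size records
its PCR duplication multiplicity.  No UMI error correction is attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from crrnaseq.formats_io import PathLike, SequencingRead, write_fastq

#: Constant portion of the pre-adenylated 3' adapter oligo (after the UMI).
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

UMI_LENGTH = 6
#: Minimum trimmed length: at least 1 insert base + the 6-nt UMI.
MIN_TRIMMED_LENGTH = UMI_LENGTH + 1


@dataclass(frozen=True)
class TrimmedRead:
    """A read with its 3' adapter located and removed.

    ``insert_plus_umi`` is the read prefix up to the adapter start
    (``adapter_offset``); ``quality`` is the original quality string
    truncated to the same length (carried for output, never interpreted).
    """

    identifier: str
    insert_plus_umi: str
    adapter_offset: int
    quality: str = ""

    def __post_init__(self) -> None:
        if len(self.insert_plus_umi) != self.adapter_offset:
            raise ValueError("insert_plus_umi length must equal adapter_offset")
        if len(self.insert_plus_umi) < MIN_TRIMMED_LENGTH:
            raise ValueError(
                f"trimmed read shorter than {MIN_TRIMMED_LENGTH} nt; "
                "callers must discard such reads"
            )


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct trimmed sequence after UMI removal.

    ``insert`` is the sense strand of the original RNA (first base = RNA 5'
    end, last base = RNA 3' end); ``count`` is the number of raw reads
    collapsed into this record.
    """

    identifier: str
    insert: str
    umi: str
    count: int
    quality: str = ""

    def __post_init__(self) -> None:
        if len(self.umi) != UMI_LENGTH:
            raise ValueError(f"UMI must be {UMI_LENGTH} nt, got {len(self.umi)}")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def locate_adapter(
    sequence: str,
    adapter: str = DEFAULT_ADAPTER,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> Optional[int]:
    """Return the 0-based start of the leftmost acceptable adapter match.

    A match at position p aligns ``adapter[:k]`` with the read, where
    ``k = min(len(adapter), len(sequence) - p)``.  It is acceptable when
    ``k >= min_overlap`` and the number of substitutions is at most
    ``floor(max_error_rate * k)``; a partial match (k < len(adapter)) must
    reach the read's 3' end, which it does by construction.  Returns None if
    no position is acceptable.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, m = len(sequence), len(adapter)
    if m < min_overlap:
        return None
    for p in range(0, n - min_overlap + 1):
        k = min(m, n - p)
        # small epsilon guards the floor against binary-float fuzz (0.1*k)
        budget = int(max_error_rate * k + 1e-9)
        mismatches = 0
        for a, b in zip(sequence[p : p + k], adapter[:k]):
            if a != b:
                mismatches += 1
                if mismatches > budget:
                    break
        else:
            return p
    return None


def trim_read(
    read: SequencingRead,
    adapter: str = DEFAULT_ADAPTER,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> Optional[TrimmedRead]:
    """Trim the 3' adapter off one read; None if the read must be discarded.

    Discarded reads are those with no acceptable adapter match and those
    whose adapter starts before position 7 (leaving no room for 1 insert
    base + the 6-nt UMI).
    """
    p = locate_adapter(read.sequence, adapter, max_error_rate, min_overlap)
    if p is None or p < MIN_TRIMMED_LENGTH:
        return None
    return TrimmedRead(
        identifier=read.identifier,
        insert_plus_umi=read.sequence[:p],
        adapter_offset=p,
        quality=read.quality[:p],
    )


def strip_umi(insert_plus_umi: str) -> tuple[str, str]:
    """Split a trimmed sequence into (insert, UMI): the UMI is the last 6 nt."""
    if len(insert_plus_umi) < MIN_TRIMMED_LENGTH:
        raise ValueError(
            f"need at least {MIN_TRIMMED_LENGTH} nt to strip a {UMI_LENGTH}-nt UMI "
            f"(got {len(insert_plus_umi)})"
        )
    return insert_plus_umi[:-UMI_LENGTH], insert_plus_umi[-UMI_LENGTH:]


def collapse_reads(trimmed: Iterable[TrimmedRead]) -> list[CollapsedRead]:
    """Collapse exact duplicate (insert + UMI) strings into one record each.

    Output order is first occurrence; each record's count is its group size
    and its identifier/quality come from the group's first read.  Count
    conservation: sum of counts equals the number of input reads.
    """
    groups: dict[str, CollapsedRead] = {}
    counts: dict[str, int] = {}
    for t in trimmed:
        s = t.insert_plus_umi
        if s in counts:
            counts[s] += 1
        else:
            counts[s] = 1
            insert, umi = strip_umi(s)
            groups[s] = CollapsedRead(
                identifier=t.identifier,
                insert=insert,
                umi=umi,
                count=1,
                quality=t.quality[: len(insert)],
            )
    return [
        CollapsedRead(
            identifier=g.identifier,
            insert=g.insert,
            umi=g.umi,
            count=counts[s],
            quality=g.quality,
        )
        for s, g in groups.items()
    ]


@dataclass
class TrimCollapseLog:
    """Per-sample counters for the trim/collapse stage."""

    n_input: int = 0
    n_adapter_found: int = 0
    n_discarded_no_adapter: int = 0
    n_discarded_short: int = 0
    n_distinct_after_collapse: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


def trim_and_collapse(
    reads: Iterable[SequencingRead],
    adapter: str = DEFAULT_ADAPTER,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
    max_read_length: Optional[int] = None,
) -> tuple[list[CollapsedRead], TrimCollapseLog]:
    """Run trimming then collapsing over one sample's reads, with counters.

    ``max_read_length`` only validates inputs: a read longer than it is a
    hard error (it indicates the wrong file or run configuration).
    """
    log = TrimCollapseLog()

    def _trimmed() -> Iterator[TrimmedRead]:
        for read in reads:
            log.n_input += 1
            if max_read_length is not None and len(read.sequence) > max_read_length:
                raise ValueError(
                    f"read {read.identifier!r} is {len(read.sequence)} nt, "
                    f"longer than the declared maximum {max_read_length}"
                )
            p = locate_adapter(read.sequence, adapter, max_error_rate, min_overlap)
            if p is None:
                log.n_discarded_no_adapter += 1
                continue
            log.n_adapter_found += 1
            if p < MIN_TRIMMED_LENGTH:
                log.n_discarded_short += 1
                continue
            yield TrimmedRead(read.identifier, read.sequence[:p], p, read.quality[:p])

    collapsed = collapse_reads(_trimmed())
    log.n_distinct_after_collapse = len(collapsed)
    return collapsed, log


def collapsed_header(read: CollapsedRead) -> str:
    """FASTQ/FASTA header encoding the duplicate count and UMI."""
    return f"{read.identifier}_x{read.count}_umi:{read.umi}"


def parse_collapsed_header(header: str) -> tuple[str, int, Optional[str]]:
    """Invert :func:`collapsed_header`: (identifier, count, umi).

    Headers without the suffix parse as count 1, UMI None, so plain FASTA
    files remain consumable downstream.
    """
    umi: Optional[str] = None
    count = 1
    rest = header
    if "_umi:" in rest:
        rest, umi = rest.rsplit("_umi:", 1)
    if "_x" in rest:
        maybe_id, maybe_count = rest.rsplit("_x", 1)
        if maybe_count.isdigit():
            rest, count = maybe_id, int(maybe_count)
    return rest, count, umi


def write_collapsed_fastq(collapsed: Iterable[CollapsedRead], path: PathLike) -> None:
    """Write collapsed reads as FASTQ: UMI-stripped insert, truncated quality."""
    write_fastq(
        (
            SequencingRead(
                collapsed_header(c),
                c.insert,
                c.quality if len(c.quality) == len(c.insert) else "I" * len(c.insert),
            )
            for c in collapsed
        ),
        path,
    )
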