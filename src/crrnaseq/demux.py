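"""Demultiplexing: segregate reads by comparing index reads against a key.

Sample reads and index reads are positionally paired (read i of R1 goes with
read i of I1, as produced by Illumina bcl conversion).  Assignment compares
the first ``len(index)`` bases of each index read to every key entry:
exact match by default, or Hamming distance with a unique best match when
``max_mismatches > 0``.  Reads matching no entry (or matching ambiguously)
are counted as unassigned and dropped; downstream stages consume only the
per-sample files.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Iterable

from crrnaseq.formats_io import DemuxKey, PathLike, SequencingRead, write_fastq


@dataclass
class DemuxResult:
    """Partition of a run into per-sample read lists.

    Invariant: sum of per-sample list lengths + unassigned_count == total_count.
    """

    per_sample: dict[str, list[SequencingRead]] = field(default_factory=dict)
    unassigned_count: int = 0
    total_count: int = 0

    def counts(self) -> dict[str, int]:
        return {name: len(reads) for name, reads in self.per_sample.items()}

    def check_conservation(self) -> None:
        assigned = sum(len(v) for v in self.per_sample.values())
        if assigned + self.unassigned_count != self.total_count:
            raise AssertionError(
                f"demux conservation violated: {assigned} assigned + "
                f"{self.unassigned_count} unassigned != {self.total_count} total"
            )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[SequencingRead],
    index_reads: Iterable[SequencingRead],
    key: DemuxKey,
    max_mismatches: int = 0,
) -> DemuxResult:
    """Assign each read to the sample whose key index matches its index read.

    The comparison uses the first ``key.index_length`` bases of the index
    read (index reads may carry an extra sequencing cycle).  With
    ``max_mismatches > 0`` a read is assigned only if exactly one key entry
    is within the tolerance at the minimal distance; ties count as
    unassigned.  Raises if the two streams have different lengths.
    """
    result = DemuxResult(per_sample={name: [] for name, _ in key.entries})
    k = key.index_length
    sentinel = object()
    for read, index_read in itertools.zip_longest(reads, index_reads, fillvalue=sentinel):
        if read is sentinel or index_read is sentinel:
            raise ValueError("read stream and index-read stream have different lengths")
        result.total_count += 1
        observed = index_read.sequence[:k]
        assigned: str | None = None
        if max_mismatches == 0:
            for name, index in key.entries:
                if observed == index:
                    assigned = name
                    break
        else:
            best_d, best_name, ties = max_mismatches + 1, None, 0
            for name, index in key.entries:
                d = _hamming(observed, index)
                if d < best_d:
                    best_d, best_name, ties = d, name, 1
                elif d == best_d:
                    ties += 1
            if best_name is not None and best_d <= max_mismatches and ties == 1:
                assigned = best_name
        if assigned is None:
            result.unassigned_count += 1
        else:
            result.per_sample[assigned].append(read)
    result.check_conservation()
    return result


def write_demux_result(result: DemuxResult, key: DemuxKey, out_dir: PathLike) -> dict[str, str]:
    """Write one ``<sample_name>.fastq`` per key entry (empty files included).

    Returns a map from sample name to output path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    for name, _ in key.entries:
        path = os.path.join(os.fspath(out_dir), f"{name}.fastq")
        write_fastq(result.per_sample.get(name, []), path)
        paths[name] = path
    return paths
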