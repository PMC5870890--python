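"""Readers/writers for the formats the pipeline touches, plus sequence utilities.

Standard formats (4-line FASTQ, FASTA) are parsed with Biopython's low-level
iterators; the pipeline's own small text formats (demultiplexing key, 3-line
parameters file, spacer-endings list) have parsers defined here.

All sequences are normalized at entry: uppercase, U -> T.  RNA-derived reads
must compare equal to DNA-space references, so normalization happens in every
reader rather than at comparison sites.  Quality strings are carried through
but never interpreted; the pipeline performs no quality filtering.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Union

from Bio.Seq import reverse_complement as _bio_revcomp
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PathLike = Union[str, os.PathLike]

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated the format contract (malformed record, bad field)."""


def normalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and map U -> T.

    Raises :class:`FormatError` if the result contains characters outside
    {A, C, G, T, N}.
    """
    norm = seq.upper().replace("U", "T")
    if not _VALID_BASES.issuperset(norm):
        bad = sorted(set(norm) - _VALID_BASES)
        raise FormatError(f"invalid nucleotide characters {bad!r} in sequence")
    return norm


@dataclass(frozen=True)
class SequencingRead:
    """One FASTQ record: identifier (header without '@'), sequence, quality.

    Invariant: ``len(quality) == len(sequence)``; sequence is over {A,C,G,T,N}.
    """

    identifier: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.identifier!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class DemuxKey:
    """Ordered demultiplexing key: (sample_name, index_sequence) pairs.

    The index column holds the sequence expected in the index read, i.e. the
    reverse complement of the TruSeq LT index as spelled in the indexing
    primer.  Sample names and index sequences must each be distinct; all
    indexes must have equal length (6 for TruSeq LT).
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        indexes = [i for _, i in self.entries]
        if any(not n for n in names):
            raise FormatError("demux key contains an empty sample name")
        if len(set(names)) != len(names):
            raise FormatError("demux key contains duplicate sample names")
        if len(set(indexes)) != len(indexes):
            raise FormatError("demux key contains duplicate index sequences")
        if len({len(i) for i in indexes}) > 1:
            raise FormatError("demux key index sequences have unequal lengths")

    @property
    def index_length(self) -> int:
        return len(self.entries[0][1]) if self.entries else 0


@dataclass(frozen=True)
class PipelineParams:
    """The 3-line parameters file: CRISPR repeat, reference gene, Y-axis scale.

    The repeat must be at least 12 nt (the minimum processed-repeat length the
    filter retains) and the reference at least 25 nt (the substring length
    used for reference-read counting); shorter values would make those rules
    unsatisfiable.
    """

    repeat: str
    reference: str
    y_scale: float

    def __post_init__(self) -> None:
        if len(self.repeat) < 12:
            raise FormatError(
                f"CRISPR repeat must be >= 12 nt (got {len(self.repeat)}): "
                "no read could qualify via the repeat-length route"
            )
        if len(self.reference) < 25:
            raise FormatError(
                f"reference gene must be >= 25 nt (got {len(self.reference)}): "
                "no read could ever match a 25-nt reference substring"
            )
        if not self.y_scale > 0:
            raise FormatError(f"y_scale must be positive (got {self.y_scale})")


@dataclass(frozen=True)
class SpacerEndSet:
    """The set of all possible native spacer endings (5-mers).

    A crRNA 3' read that retains fewer than 12 repeat bases is rescued only
    if the 5 bases immediately upstream of the repeat match one of these.
    """

    endings: frozenset[str]

    def __post_init__(self) -> None:
        for e in self.endings:
            if len(e) != 5:
                raise FormatError(f"spacer ending {e!r} is not 5 nt")

    def __contains__(self, item: str) -> bool:
        return item in self.endings

    def __len__(self) -> int:
        return len(self.endings)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------


def read_fastq(path: PathLike) -> Iterator[SequencingRead]:
    """Yield :class:`SequencingRead` records from a 4-line FASTQ file.

    Sequences are normalized (uppercase, U->T).  Malformed records raise
    :class:`FormatError` naming the record index.
    """
    with open(path) as handle:
        i = -1
        try:
            for i, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                yield SequencingRead(title, normalize_sequence(seq), qual)
        except ValueError as exc:  # Biopython signals malformed records
            raise FormatError(f"malformed FASTQ record at index {i + 1}: {exc}") from exc


def write_fastq(reads: Iterable[SequencingRead], path: PathLike) -> None:
    """Write records as 4-line FASTQ."""
    with open(path, "w") as handle:
        for r in reads:
            handle.write(f"@{r.identifier}\n{r.sequence}\n+\n{r.quality}\n")


def read_fasta(path: PathLike) -> Iterator[tuple[str, str]]:
    """Yield (identifier, normalized sequence) pairs from a FASTA file."""
    with open(path) as handle:
        first = handle.read(1)
        if first and first != ">":
            raise FormatError(f"{path}: malformed FASTA header (expected '>')")
        handle.seek(0)
        for title, seq in SimpleFastaParser(handle):
            yield title, normalize_sequence(seq)


def write_fasta(records: Iterable[tuple[str, str]], path: PathLike) -> None:
    """Write (identifier, sequence) pairs as FASTA, one line per sequence."""
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n{seq}\n")


def fastq_to_fasta(fastq_path: PathLike, fasta_path: PathLike) -> int:
    """Convert one FASTQ file to one FASTA file, dropping qualities only.

    Returns the number of records converted.
    """
    n = 0
    with open(fasta_path, "w") as out:
        for read in read_fastq(fastq_path):
            out.write(f">{read.identifier}\n{read.sequence}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Pipeline text formats
# ---------------------------------------------------------------------------


def _read_lines(path: PathLike) -> list[str]:
    with open(path, newline=None) as handle:
        return handle.read().splitlines()


def parse_demux_key(path: PathLike) -> DemuxKey:
    """Parse a tab-separated demultiplexing key.

    Two columns per non-empty line: sample name, then the index sequence
    expected in the index read (the reverse complement of the TruSeq index).
    """
    entries: list[tuple[str, str]] = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"{path}, line {lineno}: expected 2 tab-separated columns, "
                f"got {len(fields)}"
            )
        name, index = fields[0].strip(), fields[1].strip()
        entries.append((name, normalize_sequence(index)))
    return DemuxKey(tuple(entries))


def parse_params(path: PathLike) -> PipelineParams:
    """Parse the 3-line parameters file: repeat, reference gene, Y scale."""
    lines = [ln.strip() for ln in _read_lines(path) if ln.strip()]
    if len(lines) < 3:
        raise FormatError(
            f"{path}: parameters file needs 3 non-empty lines "
            f"(repeat, reference, scale); found {len(lines)}"
        )
    repeat = normalize_sequence(lines[0])
    reference = normalize_sequence(lines[1])
    try:
        y_scale = float(lines[2])
    except ValueError as exc:
        raise FormatError(f"{path}: Y-axis scale {lines[2]!r} is not a number") from exc
    return PipelineParams(repeat=repeat, reference=reference, y_scale=y_scale)


def parse_spacer_ends(path: PathLike) -> SpacerEndSet:
    """Parse a spacer-endings file: one 5-mer per line, '#' comments allowed."""
    endings: set[str] = set()
    for lineno, raw in enumerate(_read_lines(path), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        seq = normalize_sequence(line)
        if len(seq) != 5:
            raise FormatError(
                f"{path}, line {lineno}: spacer ending {line!r} has length "
                f"{len(seq)}, expected 5"
            )
        endings.add(seq)
    return SpacerEndSet(frozenset(endings))


def write_params(params: PipelineParams, path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write(f"{params.repeat}\n{params.reference}\n{params.y_scale}\n")


def write_spacer_ends(spacer_ends: SpacerEndSet, path: PathLike) -> None:
    with open(path, "w") as handle:
        for e in sorted(spacer_ends.endings):
            handle.write(e + "\n")


def write_demux_key(key: DemuxKey, path: PathLike) -> None:
    with open(path, "w") as handle:
        for name, index in key.entries:
            handle.write(f"{name}\t{index}\n")


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    if not _VALID_BASES.issuperset(seq):
        bad = sorted(set(seq) - _VALID_BASES)
        raise FormatError(f"invalid characters {bad!r} for reverse complement")
    return _bio_revcomp(seq)


def library_molarity(concentration_ng_per_ul: float, mean_length_bp: float) -> float:
    """Approximate dsDNA library molarity in nM.

    nM = (ng/ul) / (660 g/mol/bp * mean length in bp) * 10^6, the standard
    dsDNA conversion (660 g/mol per base pair).
    """
    if concentration_ng_per_ul < 0:
        raise ValueError("concentration must be non-negative")
    if not mean_length_bp > 0:
        raise ValueError("mean library length must be positive")
    return concentration_ng_per_ul / (660.0 * mean_length_bp) * 1e6
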