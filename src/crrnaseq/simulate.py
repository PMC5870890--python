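"""Synthetic multiplexed sequencing runs with the protocol's read structure.

Each simulated molecule is a small RNA whose 3' end was captured by ligation
of the pre-adenylated adapter, so every read has the layout

    insert + UMI(6 random nt) + AGATCGGAAGAGCACACGTCT + downstream primer bases

truncated to the read length (80 cycles by default).  Three molecule classes
are generated:

* ``crrna`` — a native spacer suffix (5-20 nt, so the spacer-repeat junction
  is present) followed by the first ``l`` bases of the CRISPR repeat, with
  ``l`` drawn from a configurable 3'-end distribution;
* ``reference`` — a random 25-40-nt window of the reference gene;
* ``background`` — random sequence.

Each molecule is replicated with a PCR-duplication multiplicity drawn from a
configurable distribution, all duplicates sharing one UMI; matching index
reads carry the sample's barcode.  A ground-truth table records every
emitted read's sample, class, insert, UMI, true 3'-end position and
duplicate provenance, so every pipeline stage can be validated exactly.

The default repeat, spacers and reference gene are synthetic stand-ins
written for this simulator (realistic lengths for a type III CRISPR locus
and a tRNA-sized reference); they are not genomic sequences.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from crrnaseq.formats_io import (
    DemuxKey,
    PipelineParams,
    SequencingRead,
    SpacerEndSet,
    reverse_complement,
    write_demux_key,
    write_fastq,
    write_params,
    write_spacer_ends,
)
from crrnaseq.trim_collapse import DEFAULT_ADAPTER, UMI_LENGTH

#: Fixed bases downstream of the adapter (PCR-primer region); only the first
#: 13 are contractual, the rest exist so truncation at any read length is
#: well defined.
DOWNSTREAM_FILLER = "GAACTCCAGTCAC" + "ATCTCGTATGCCGTCTTCTGCTTG" * 4

#: Illumina TruSeq LT indexes AD001-AD008 as spelled in the indexing primers.
TRUSEQ_LT_INDEXES = (
    "ATCACG", "CGATGT", "TTAGGC", "TGACCA",
    "ACAGTG", "GCCAAT", "CAGATC", "ACTTGA",
)

#: Synthetic 37-nt direct repeat (realistic length for a type III locus).
DEFAULT_REPEAT = "GTTCACTGCCGTATAGGCAGCTAAGAAAGTCGGCAAC"

#: Synthetic 35-nt spacers; their last 5 nt define the native spacer endings.
DEFAULT_SPACERS = (
    "TTAATGAGGGACGTGATTAGGGCTTTTCTATCTGA",
    "TTTCCCGCATTCGAATGAATCGCCGAACTTTTCGT",
    "GGATTTCAGTTCCTAGGTTAGAATAGACTATGTTA",
    "AAAGCAAAGTGGGTTGGAGTGACGTCTCGGCGTCA",
    "GGTAGCGACTTTGGGGTCGTTACTACTGCGTTAGC",
    "CTATGGTGCGGCCTGGAAGGATAGTGCACAAAACC",
)

#: Synthetic 95-nt reference gene (tRNA-sized highly expressed species).
DEFAULT_REFERENCE = (
    "TAGAACATGGTAACCTTCACAATGCATCGAACCAGTGTCTCCGGAAGCC"
    "GGATTCCTCTGCAGAATCAAAACAAAATATCTAGCGGTGCACTTAT"
)

#: Dominant Cas6 cleavage site at repeat position 20 with minor heterogeneity
#: and a small read-through fraction reaching the full repeat.
DEFAULT_END_DISTRIBUTION = {20: 0.60, 21: 0.25, 22: 0.10, 37: 0.05}

#: Library-PCR duplicate multiplicities (most molecules seen once or twice).
DEFAULT_PCR_DUPLICATION = {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.03}


def default_samples() -> tuple[tuple[str, str], ...]:
    """sample1..sample8 with the index-read sequence (revcomp of the index)."""
    return tuple(
        (f"sample{i + 1}", reverse_complement(idx))
        for i, idx in enumerate(TRUSEQ_LT_INDEXES)
    )


@dataclass
class SimConfig:
    """Parameters of one simulated multiplexed run."""

    seed: int = 0
    read_length: int = 80
    samples: Sequence[tuple[str, str]] = field(default_factory=default_samples)
    repeat: str = DEFAULT_REPEAT
    spacers: Sequence[str] = DEFAULT_SPACERS
    reference: str = DEFAULT_REFERENCE
    end_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_END_DISTRIBUTION)
    )
    n_crrna: int = 2000
    n_reference: int = 500
    n_background: int = 500
    pcr_duplication: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PCR_DUPLICATION)
    )
    substitution_rate: float = 0.001
    y_scale: float = 1.0
    #: Upstream (spacer-suffix) length range for crRNA inserts, inclusive.
    crrna_upstream_range: tuple[int, int] = (5, 20)

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("at least one sample is required")
        if abs(sum(self.end_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("end_distribution probabilities must sum to 1")
        if abs(sum(self.pcr_duplication.values()) - 1.0) > 1e-9:
            raise ValueError("pcr_duplication probabilities must sum to 1")
        if any(m < 1 for m in self.pcr_duplication):
            raise ValueError("PCR multiplicities must be >= 1")
        for l in self.end_distribution:
            if not 1 <= l <= len(self.repeat):
                raise ValueError(
                    f"3'-end position {l} outside [1, {len(self.repeat)}]"
                )
        for s in self.spacers:
            if len(s) < 30:
                raise ValueError("spacers must be at least 30 nt")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must be in [0, 1)")
        lo, hi = self.crrna_upstream_range
        if not (5 <= lo <= hi and hi <= min(len(s) for s in self.spacers)):
            raise ValueError("invalid crRNA upstream length range")

    def spacer_ends(self) -> SpacerEndSet:
        """Spacer endings implied by the configured spacers (their last 5 nt)."""
        return SpacerEndSet(frozenset(s[-5:] for s in self.spacers))

    def params(self) -> PipelineParams:
        return PipelineParams(self.repeat, self.reference, self.y_scale)

    def demux_key(self) -> DemuxKey:
        return DemuxKey(tuple(self.samples))


@dataclass(frozen=True)
class GroundTruthRow:
    """Provenance of one emitted read."""

    read_id: str
    sample_name: str
    klass: str  # crrna | reference | background
    insert: str
    umi: str
    true_end_position: Optional[int]  # repeat position of the 3' end; crRNA only
    duplicate_of: Optional[str]  # read_id of the molecule's first read


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(seq: str, substitution_rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions; a substituted base always changes."""
    if substitution_rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < substitution_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def assemble_read(
    insert: str,
    umi: str,
    read_length: int = 80,
    substitution_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> SequencingRead:
    """Build one sequencing read from a molecule's insert and UMI.

    sequence = (insert + umi + adapter + downstream filler) truncated to
    ``read_length``, with i.i.d. substitutions; quality is uniform 'I'.
    """
    if not insert:
        raise ValueError("insert must be non-empty")
    if len(umi) != UMI_LENGTH:
        raise ValueError(f"UMI must be {UMI_LENGTH} nt")
    full = insert + umi + DEFAULT_ADAPTER + DOWNSTREAM_FILLER
    seq = full[:read_length]
    if substitution_rate > 0:
        if rng is None:
            raise ValueError("an rng is required when substitution_rate > 0")
        seq = _mutate(seq, substitution_rate, rng)
    return SequencingRead("sim", seq, "I" * len(seq))


def _draw(rng: np.random.Generator, dist: dict[int, float]) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=probs / probs.sum()))


def simulate_run(
    config: SimConfig,
) -> tuple[list[SequencingRead], list[SequencingRead], list[GroundTruthRow]]:
    """Simulate one multiplexed run: (R1 reads, I1 index reads, ground truth).

    Deterministic under a fixed config (including its seed): running twice
    yields byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_names = [name for name, _ in config.samples]
    index_by_sample = dict(config.samples)
    lo, hi = config.crrna_upstream_range

    # molecules: (class, insert, true_end_position)
    molecules: list[tuple[str, str, Optional[int]]] = []
    for _ in range(config.n_crrna):
        spacer = config.spacers[rng.integers(len(config.spacers))]
        u = int(rng.integers(lo, hi + 1))
        l = _draw(rng, config.end_distribution)
        molecules.append(("crrna", spacer[-u:] + config.repeat[:l], l))
    ref_len = len(config.reference)
    for _ in range(config.n_reference):
        w = int(rng.integers(25, min(40, ref_len) + 1))
        start = int(rng.integers(0, ref_len - w + 1))
        molecules.append(("reference", config.reference[start : start + w], None))
    for _ in range(config.n_background):
        molecules.append(("background", _random_seq(rng, int(rng.integers(15, 46))), None))

    reads: list[SequencingRead] = []
    index_reads: list[SequencingRead] = []
    truth: list[GroundTruthRow] = []
    entries: list[tuple[str, str, str, str, Optional[int], int]] = []
    for mol_idx, (klass, insert, end_pos) in enumerate(molecules):
        sample = sample_names[int(rng.integers(len(sample_names)))]
        umi = _random_seq(rng, UMI_LENGTH)
        multiplicity = _draw(rng, config.pcr_duplication)
        entries.append((klass, insert, umi, sample, end_pos, multiplicity))

    # expand to reads and shuffle so samples/duplicates are interleaved
    expanded: list[tuple[int, int]] = []  # (molecule index, duplicate index)
    for mol_idx, (_, _, _, _, _, mult) in enumerate(entries):
        expanded.extend((mol_idx, d) for d in range(mult))
    order = rng.permutation(len(expanded))

    first_read_id: dict[int, str] = {}
    for out_idx, exp_idx in enumerate(order):
        mol_idx, dup_idx = expanded[exp_idx]
        klass, insert, umi, sample, end_pos, _ = entries[mol_idx]
        read_id = f"sim:mol{mol_idx}:dup{dup_idx}"
        read = assemble_read(
            insert, umi, config.read_length,
            config.substitution_rate, rng if config.substitution_rate > 0 else None,
        )
        reads.append(SequencingRead(read_id, read.sequence, read.quality))
        index_seq = index_by_sample[sample]
        if config.substitution_rate > 0:
            index_seq = _mutate(index_seq, config.substitution_rate, rng)
        index_reads.append(SequencingRead(read_id, index_seq, "I" * len(index_seq)))
        dup_of = first_read_id.get(mol_idx)
        if dup_of is None:
            first_read_id[mol_idx] = read_id
        truth.append(
            GroundTruthRow(read_id, sample, klass, insert, umi, end_pos, dup_of)
        )
    return reads, index_reads, truth


def write_run(
    config: SimConfig,
    out_dir: str,
) -> dict[str, str]:
    """Simulate and write a complete, runnable fixture set.

    Produces Undetermined_S0_L001_R1_001.fastq / _I1_001.fastq, the ground
    truth TSV, and matching key.tsv, params.txt and spacer_ends.txt.
    Returns a map from artifact name to path.
    """
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    reads, index_reads, truth = simulate_run(config)
    paths = {
        "r1": os.path.join(out_dir, "Undetermined_S0_L001_R1_001.fastq"),
        "i1": os.path.join(out_dir, "Undetermined_S0_L001_I1_001.fastq"),
        "ground_truth": os.path.join(out_dir, "ground_truth.tsv"),
        "key": os.path.join(out_dir, "key.tsv"),
        "params": os.path.join(out_dir, "params.txt"),
        "spacer_ends": os.path.join(out_dir, "spacer_ends.txt"),
    }
    write_fastq(reads, paths["r1"])
    write_fastq(index_reads, paths["i1"])
    pd.DataFrame(
        [
            {
                "read_id": t.read_id,
                "sample_name": t.sample_name,
                "class": t.klass,
                "insert": t.insert,
                "umi": t.umi,
                "true_end_position": "" if t.true_end_position is None else t.true_end_position,
                "duplicate_of": "" if t.duplicate_of is None else t.duplicate_of,
            }
            for t in truth
        ]
    ).to_csv(paths["ground_truth"], sep="\t", index=False)
    write_demux_key(config.demux_key(), paths["key"])
    write_params(config.params(), paths["params"])
    write_spacer_ends(config.spacer_ends(), paths["spacer_ends"])
    return paths
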