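# Methods

## Read model

The library chemistry ligates a pre-adenylated DNA adapter
(`/5rApp/NNNNNNAGATCGGAAGAGCACACGTCT/3ddC/`) directly to each small RNA's
3' end, so after reverse transcription, circularization and PCR, a
sequencing read is

```
insert + UMI(6) + AGATCGGAAGAGCACACGTCT + downstream PCR-primer bases
```

truncated at the read length. The first base of the insert is the RNA 5'
end and the last base its 3' end; the 6-nt random hexamer (UMI) tags each
ligation event. Index reads carry the sample barcode (the reverse
complement of the TruSeq LT index as spelled in the indexing primer).
Quality strings are carried through all stages but never interpreted: the
assay uses no quality filtering, and decisions are purely sequence-based.

## Stage contracts

**Demultiplexing.** Exact comparison of the first `len(barcode)` bases of
each index read against the key (index reads may carry an extra cycle).
`max_mismatches` (default 0) optionally allows Hamming-distance assignment,
requiring a unique best entry; ties are unassigned. Unassigned reads are
counted and dropped — downstream stages consume only per-sample files. One
output FASTQ is written per key entry even when empty. The partition
identity (assigned + unassigned = total) is asserted on every run.

**Adapter location.** Substitution-only alignment of the adapter at every
offset, leftmost acceptable match wins. A match aligning `k` adapter bases
(`k = min(|adapter|, |read| − p)`, `k ≥ min_overlap`, partial matches must
reach the read 3' end) is acceptable with at most
`floor(max_error_rate × k)` mismatches. Defaults: error rate 0.1, minimum
overlap 3. Indels are not modeled — substitution errors dominate Illumina
data, and the exhaustive-oracle equivalence test pins the semantics
exactly. A small epsilon inside the floor guards against binary-float
artifacts in `0.1 × k`.

Reads with no acceptable match, or whose adapter starts before position 7
(no room for ≥ 1 insert base + the UMI), are discarded and counted: without
the adapter position neither the RNA 3' end nor the UMI is identifiable, so
keeping the read untrimmed would poison the 3'-end histogram. The
`max_read_length` argument (80 by default) only validates input — longer
reads indicate the wrong file and are a hard error.

**Collapsing.** Exact string grouping on insert + UMI; no UMI-network or
directional error correction. With 4096 possible hexamers and per-sample
molecule counts in the hundreds-to-thousands, occasional (insert, UMI)
collisions between real molecules are expected and slightly undercount
molecules; correcting UMI sequencing errors would equally risk merging real
molecules. The UMI is stripped at collapse time and recorded in the output
header (`<id>_x<count>_umi:<UMI>`) along with the duplicate count.

**Qualification.** Rule order: (a) leftmost exact occurrence of the
repeat's first 5 bases (N never matches) anchors the read; absence rejects
it (`no_seed`); (b) everything upstream of the anchor is removed and the
suffix is the processed repeat; (c) a processed repeat shorter than 12 nt
is rescued only when the 5 bases immediately upstream are a known native
spacer ending — 5 spacer + ≥ 5 repeat bases = ≥ 10 matching bases across
the spacer–repeat junction (`upstream_too_short` when fewer than 5 upstream
bases exist, `too_short_no_junction` when they match no ending); (d) the
processed repeat must be a mismatch-free left-anchored prefix of the repeat
(`fidelity_fail` otherwise). Reads running through the full repeat into the
next spacer fail (d) and are logged under a separate count: an excess of
them flags unprocessed pre-crRNA signal. If the leftmost seed occurrence
fails fidelity the read is rejected without re-scanning later occurrences —
deterministic and simple; with a 5-base seed, second occurrences in real
inserts are rare.

**Reference counting.** A read counts (once) toward the reference tally if
any of its 25-nt windows is an exact sense-strand substring of the
reference gene; the library is strand-specific, so the antisense strand is
never indexed. Reads shorter than 25 nt never count. A read may in
principle count as both reference and crRNA (only if the sequences
overlap); both tallies keep it and the event is logged.

**Profile.** Counting is per collapsed read — collapsing defines the
molecule count, so each molecule contributes 1 regardless of PCR
multiplicity (`--weight-by-count` re-weights by the pre-collapse count for
diagnostics only). `height(ℓ) = count(ℓ) / n_reference × y_scale`; zero
reference reads is an explicit error advising a different reference gene,
not a silent division. Positions are 1-based in every table and plot,
0-based half-open internally. Profiles are always written as TSV beside
the image so downstream checks never parse pixels.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| adapter | `AGATCGGAAGAGCACACGTCT` | nt | constant portion of the ligated 3' adapter oligo |
| max_error_rate | 0.1 | mismatches per aligned base | standard 3'-adapter trimming tolerance |
| min_overlap | 3 | nt | shortest terminal adapter prefix trusted as a match |
| UMI length | 6 | nt | hexamer in the adapter oligo |
| seed length | 5 | nt | shortest repeat prefix anchoring a read |
| min repeat length | 12 | nt | processed-repeat length retained without junction support |
| junction rule | 5 + 5 | nt | spacer-ending bases + repeat seed across the junction |
| reference k-mer | 25 | nt | substring length for reference-read counting |
| read length | 80 | cycles | single-read sequencing configuration |
| y_scale | any > 0 | — | arbitrary plot scaling, third line of the params file |

The spacer-endings file uses a portable dialect — one 5-mer per line, `#`
comments — rather than a language-specific literal; converting an existing
Python-dict-style file is a one-liner (print each key on its own line).

## The simulator

`crrnaseq.simulate` generates complete runs with the read structure above
and a per-read ground-truth table (sample, class, insert, UMI, true 3'-end
position, duplicate provenance). Defaults model the study conditions of a
type III CRISPR locus assay: 8 samples with TruSeq LT barcodes AD001–AD008,
a 37-nt direct repeat, six 35-nt spacers, a 95-nt tRNA-sized reference gene
(all synthetic stand-in sequences — realistic lengths and composition, not
genomic), 2000 crRNA / 500 reference / 500 background molecules, a 3'-end
distribution concentrated at one dominant cleavage position
(0.60/0.25/0.10 at positions 20–22, 0.05 read-through to the full repeat),
PCR multiplicities {1: 0.55, 2: 0.25, 3: 0.12, 4: 0.05, 5: 0.03} (mean
1.76), and an i.i.d. substitution rate of 0.001 applied to sample and index
reads alike. crRNA inserts carry a 5–20-nt native spacer suffix so the
junction route is exercisable; the spacer-endings file it writes is derived
from the configured spacers, keeping simulator and filter consistent by
construction. Output is deterministic given the config (fixed NumPy
generator seed): two runs are byte-identical.

What it does not emulate: ligation and circularization bias, RT drop-off,
quality-score structure, indels, index hopping. Passing tests therefore
demonstrate correctness of the processing logic under the stated read
model, not robustness to every artifact of real libraries.

## Numerical and degenerate-input choices

- Parameters file validation is this package's own: repeat ≥ 12 nt and
  reference ≥ 25 nt (otherwise the corresponding rules are unsatisfiable),
  y_scale > 0, exactly 3 non-empty lines.
- All sequence entry points normalize uppercase and U→T.
- Empty samples produce empty downstream files and are skipped by profiling
  with a logged warning, not an error.
- The molarity helper uses the standard dsDNA conversion
  nM = (ng/µl) ÷ (660 g/mol/bp × length in bp) × 10⁶.
- Test and acceptance problem sizes: conservation identities on a
  ~10,000-read run, adapter-locator oracle equivalence on 10,000 random
  reads (2,000 in the unit test), 25-mer containment oracle on 1,000 reads,
  parameter recovery on 20,000 error-free molecules with a 3-standard-error
  binomial acceptance band per position.

## Known limitations

- Single-end, single-index reads only; no dual indexing or index-hopping
  correction, no undetermined-reads output file.
- Exact-match collapsing undercounts molecules under high sequencing error
  and splits molecules whose UMI acquired an error into two records.
- Only the leftmost seed occurrence is considered; a read whose first seed
  hit is spurious but whose second is genuine is lost.
- Reference counting is exact-match: a reference read with a substitution
  in every 25-nt window escapes the tally, slightly inflating normalized
  heights at high error rates.
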