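# crrnaseq

Processing pipeline for strand-specific small RNA sequencing of bacterial
CRISPR RNAs (crRNAs), from raw multiplexed Illumina reads to a per-base
profile of crRNA 3' ends along the CRISPR direct repeat.

## The problem

In type I and type III CRISPR-Cas systems, the Cas6 endoribonuclease cleaves
the precursor crRNA transcript site-specifically within each direct repeat,
releasing mature crRNAs whose 3' ends fall at a characteristic repeat
position. A 3'-capture small RNA-seq library (pre-adenylated adapter ligated
directly to the RNA 3'-OH) records each molecule's 3' end exactly, so the
distribution of read 3' ends within the repeat is a direct readout of Cas6
activity. This package implements the computational half of that assay for
people running such libraries: demultiplexing, adapter trimming, UMI-based
duplicate collapsing, repeat-anchored read filtering, and the normalized
3'-end histogram — plus a simulator that generates complete synthetic runs
with ground truth, so the whole pipeline is testable end to end without
sequencing data.

## The method

Every read has the molecular structure

```
insert (RNA, 5'→3') + NNNNNN (random hexamer UMI) + AGATCGGAAGAGCACACGTCT (3' adapter) + …
```

truncated at the read length (80 cycles). The stages:

1. **Demultiplex** — read *i* of `R1` is assigned to the sample whose key
   barcode equals the first 6 bases of index read *i* (exact match by
   default).
2. **Trim** — locate the 3' adapter (substitution-only matching, error rate
   ≤ 0.1 per aligned base, minimum terminal overlap 3) and cut the read at
   its start; the base before the cut is the RNA 3' end. Reads without a
   locatable adapter are discarded and counted.
3. **Collapse** — group identical (insert + UMI) strings; each distinct
   string is one RNA molecule, its group size the PCR multiplicity. The UMI
   is then stripped.
4. **Qualify** — a read is CRISPR-derived when it contains the repeat's
   first 5 bases (the seed; leftmost occurrence anchors it), the processed
   repeat (read suffix from the seed) is ≥ 12 nt **or** is shorter but the
   5 bases upstream match a native spacer ending (≥ 10 matching bases across
   the spacer–repeat junction), and the processed repeat is a mismatch-free,
   left-anchored prefix of the repeat.
5. **Normalize** — count reads containing any exact 25-nt substring of a
   highly expressed reference gene (e.g. an isoleucine tRNA); the profile
   height at repeat position ℓ is

   `height(ℓ) = count(3' ends at ℓ) / n_reference × y_scale`

## Worked example

Simulate a multiplexed run (8 samples, TruSeq LT barcodes, 2000 crRNA + 500
reference + 500 background molecules, realistic PCR duplication and a 0.001
substitution rate), then run the whole pipeline:

```sh
crrna simulate --out-dir sim --seed 7
crrna all --r1 sim/Undetermined_S0_L001_R1_001.fastq \
          --i1 sim/Undetermined_S0_L001_I1_001.fastq \
          --key sim/key.tsv --params sim/params.txt \
          --spacer-ends sim/spacer_ends.txt --out-dir run
```

Among the log lines this prints (sample5 shown):

```
demux reads_sample5=637
demux unassigned=22
demux total=5202
trim-collapse[sample5] n_input=637
trim-collapse[sample5] n_distinct_after_collapse=401
profile[sample5] n_seed_found=266
profile[sample5] n_repeat_route=254
profile[sample5] n_reference=67
profile[sample5] n_rejected_fidelity_fail=11
```

637 of 5202 reads carried sample5's barcode; 22 reads run-wide had a
sequencing error in the index and were dropped. Collapsing 637 reads to 401
distinct (insert, UMI) pairs removed PCR duplicates. 254 molecules qualified
as crRNA and 67 matched the reference gene; the 11 fidelity failures are
molecules whose repeat portion picked up a substitution. The per-sample
profile (`run/profiles/sample5.tsv`, with a matching bar chart PNG whose
X-axis spells the repeat sequence) contains one row per repeat position; the
non-zero rows:

```
position  base  raw_count  normalized_height
20        G     161        2.4029850746268657
21        C     57         0.8507462686567164
22        T     25         0.373134328358209
37        C     11         0.16417910447761194
```

A sharp dominant 3' end at repeat position 20 (161/254 ≈ 0.63 of qualified
molecules, matching the simulator's configured 0.60) is exactly the
signature of site-specific Cas6 cleavage; the normalized heights are counts
divided by the 67 reference reads times the y-scale (1.0).

The pooling helper computes library molarity for equimolar mixing:

```sh
$ crrna molarity --ng-per-ul 10 --length-bp 150
101.0101
```

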