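# ecbench

Benchmarking haplotype-aware error correction of long sequencing reads
against a truth assembly.

Modern HiFi assemblers (hifiasm, LJA, Verkko, HiCanu, ...) all start by
error-correcting (EC) the reads, and mistakes made there — especially
collapsing the two parental haplotypes of a diploid sample — propagate into
the assembly. `ecbench` measures how well an EC tool did, for developers and
evaluators of such tools: it aligns nothing itself, but compares, read by
read, the alignment of the raw read and the alignment of the corrected read
against a high-quality assembly of the same sample.

## The metrics

Given a truth assembly, any substitution or gap in a read-to-assembly
alignment is an error in the read. For each read, comparing the raw and the
corrected alignments partitions the errors into

* **CC** (correct corrections): errors in the raw read absent from the
  corrected read — true positives of the corrector;
* **UC** (under-corrections): errors present in both — false negatives;
* **OC** (over-corrections): new errors only in the corrected read — false
  positives;

from which

```
FDR = OC / (CC + OC)        FNR = UC / (CC + UC)
```

Events are extracted from minimap2 `cs` tags (or SAM CIGAR+MD), left-aligned
against the reference so the same indel compares equal in both alignments,
and matched by `(contig, position, type, ref allele, alt allele)`. Reads
whose raw and corrected alignments disagree on contig or interval are
excluded from the rates and classified instead as **haplotype**,
**chromosome** or **position** differences (with a MAPQ filter, since an
ambiguous mapping says little). Metrics can additionally be stratified by
annotation BED files (centromeric satellites, segmental duplications, ...)
or by homopolymer runs derived from the assembly itself, and the whole
evaluation can be run in homopolymer-compressed (HPC) space for EC tools
that only emit HPC reads.

The package also ships a fully ground-truthed simulator: a two-haplotype
genome with heterozygous SNPs/indels, reads with injected errors, and
pseudo-corrected reads whose fixed/missed/introduced errors are recorded in
a per-read ledger — plus truth-derived PAF records, so the entire pipeline
is testable without an aligner.

## Worked example

Simulate a 2 × 200 kb diploid dataset at 20× with 0.2% read error, a
corrector that fixes 90% of errors and introduces 0.2 new errors per read,
then evaluate:

```sh
ecbench simulate --genome-length 200000 --read-length 10000 --coverage 20 \
    --error-rate 0.002 --p-correct 0.9 --q-overcorrect 0.2 \
    --unambiguous --seed 7 -o demo
ecbench eval --raw-paf demo.raw.paf --corr-paf demo.corr.paf \
    --assembly demo.asm.fa -o demo_eval
```

which prints

```
reads counted:       400
reads excluded:      0 (mapping-inconsistent)
CC (correct):        7281
UC (under-corr):     742
OC (over-corr):      86
trimmed raw events:  0
FDR = OC/(CC+OC):    0.011674 (86/7367)
FNR = UC/(CC+UC):    0.092484 (742/8023)
```

The corrector missed 742 of 8023 injected errors, so the measured FNR
(0.092) recovers the simulated miss rate of 1 − 0.9 within sampling error,
and the 86 introduced errors over 7367 attempted corrections give the FDR.
Per-read counts land in `demo_eval.per_read.tsv`, the mapping-difference
classification in `demo_eval.mapdiff*.tsv`, and per-annotation metrics in
`demo_eval.stratified.tsv`.

With real data the PAFs come from minimap2 (the `cs` tag is required):

```sh
minimap2 -c --cs -x map-hifi --secondary=no assembly.fa raw.fq.gz  > raw.paf
minimap2 -c --cs -x map-hifi --secondary=no assembly.fa corr.fa.gz > corr.paf
ecbench eval --raw-paf raw.paf --corr-paf corr.paf --assembly assembly.fa \
    --bed satellite=censat.bed --bed segdup=sd.bed -o sample_eval
```

For HPC-only correctors, compress assembly and raw reads first with
`ecbench hpc` and align in HPC space.

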