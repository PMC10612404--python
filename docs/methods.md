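# Methods

## Evaluation model

The premise: given an assembly of the same sample that is orders of
magnitude more accurate than the reads, every substitution or gap in a
read-to-assembly alignment is a read error. An EC tool is then judged by
comparing, per read, the error set of the raw alignment with the error set
of the corrected alignment. The assembly need not be perfect — assembly
consensus accuracy (Phred ~50–60) is roughly a thousandfold better than HiFi
read accuracy (~Q23), so residual assembly errors inflate both error sets
almost identically and largely cancel in the comparison.

An edit event is `(contig, pos, kind, ref_seq, alt_seq)` with `kind` in
{SUB, INS, DEL}, 0-based half-open reference coordinates (PAF convention).
Granularity follows the short-form `cs` tag: one SUB per substituted base,
one event per maximal indel run. Events come from the `cs` tag directly or
are derived from CIGAR+MD for SAM input; a record with neither is a hard
error rather than silent substitution blindness.

**Event identity includes the alt allele** by default: a raw `A→C` error
"corrected" into `A→G` at the same site counts as one CC (the old error is
gone) plus one OC (a new error exists), because CC/UC/OC are set differences
over errors, and `A→G` is a different error. `--no-match-alt` relaxes the
key to (position, type) for comparability studies.

**Indel left-alignment.** The same biological indel can be written at any
position within a repeat. Before comparison every INS/DEL is shifted to its
smallest equivalent reference position (VCF-style rotation: an insertion of
`S` after `p` equals an insertion of `ref[p] + S[:-1]` after `p−1` whenever
`S` ends with `ref[p]`; a deletion of `ref[p:p+k]` shifts while
`ref[p−1] == ref[p+k−1]`). Without this, identical indels represented
differently by the two alignments would inflate both CC and OC.

**Interval overlap.** Comparison is restricted to the intersection of the
raw and corrected reference intervals. Raw events outside it mean the
corrector trimmed the read; trimming is not correction, so these are
reported in a separate `trimmed_raw_events` counter instead of CC (counting
them as CC would deflate FNR for tools that discard hard read ends).

**Mapping consistency.** A pair is consistent when both alignments share a
contig and their intervals overlap. Inconsistent pairs are still evaluated
(over their full event sets) but excluded from aggregate FDR/FNR and handed
to the mapping-difference classifier. On real human data only ~0.2% of
reads move, so this exclusion barely affects totals.

## Mapping-difference classification

For a diploid truth assembly each contig resolves — via a user regex with
(chromosome, haplotype) capture groups, a per-contig table, or the built-in
`<chrom>_<MAT|PAT|hap1|hap2>` preset — and an inconsistent pair is:

* **haplotype**: same chromosome, different haplotype label;
* **chromosome**: different chromosome, same haplotype label;
* **position**: same chromosome and haplotype, disjoint intervals.

A pair enters the counts when *at least one* of the two alignments has
MAPQ ≥ threshold (default 2; summaries are reported per threshold, typically
2 and 10). Unresolvable contig names get their own category with a warning.
Two open choices, made here and documented as such: any interval overlap on
the same contig counts as consistent (correctors commonly shift endpoints a
few bases, and no distance cutoff is principled without a model of local
repeat structure); and a pair differing in both chromosome and haplotype is
classed as a chromosome difference, the larger-scale event.

## Stratification

Metrics are stratified by *event position*, not whole-read overlap: a 15 kb
read can span several annotation classes, and per-region FNR/FDR is only
meaningful per event. An event belongs to a stratum if its reference
position (any deleted base for DEL, the anchor base for INS) falls in the
stratum's merged intervals. Strata may overlap — an event counts once in
each — and events in no stratum fall into a residual `other` stratum, so
with disjoint exhaustive labels per-stratum totals sum to the global totals
(a tested invariant). The homopolymer stratum can be derived from the
assembly itself (maximal single-base runs, default min length 3, exposed as
a flag since no canonical threshold exists).

## Homopolymer compression

`compress` maps each maximal run of one base to a single base and records
each run's original start, so positions are recoverable; compression is
case-insensitive (soft-masked assemblies must not split runs), N runs
compress like any base, and no run-length cap is applied. FASTQ input
yields FASTA output because per-base qualities are undefined after merging
a run. Evaluation in HPC mode simply runs the normal pipeline on
HPC-compressed assembly and reads, and reports in HPC coordinates; a
consequence used as a cross-module check: homopolymer annotation of an
HPC-compressed assembly at min length 3 is empty.

## The synthetic generator

The generator emulates the *structure* of a diploid HiFi benchmark, not its
sequence realism; its purpose is a known answer.

* Genome: i.i.d. uniform bases per chromosome (default one chromosome,
  100 kb per haplotype); haplotype 2 derives from haplotype 1 by
  heterozygous SNPs (default 10⁻³/bp, human-like) and 1–3 bp indels
  (2×10⁻⁴/bp). Both haplotypes are separate contigs of the truth assembly,
  named `chrN_MAT`/`chrN_PAT`.
* Reads: uniform start positions, haplotype chosen 50/50, fixed read length
  (default 15 kb, HiFi-like), count set by fold coverage (default 30×,
  counting both haplotypes against the haploid length).
* Errors: per-base rate 0.002 (matching published HiFi simulation practice),
  split 70/15/15 into substitutions/insertions/deletions; indel errors are
  1 bp, the dominant HiFi error mode.
* Pseudo-corrector: operates on the truth ledger, not on sequence. Each
  injected error is fixed with probability `p_correct` (default 0.9), new
  errors are introduced at Poisson rate `q_overcorrect` per read (default
  0.1), and with probability `s_hapswitch` (default 0) the corrected read is
  replaced by the homologous substring of the *other* haplotype — emulating
  haplotype collapse, the failure mode this benchmark is designed to expose.
  Defaults describe a good-but-imperfect corrector so that all three of
  CC/UC/OC are exercised.
* Truth alignments: one primary PAF record per read at its true locus with
  a `cs` tag rebuilt from the ledger, MAPQ 60 — so the pipeline runs with no
  aligner.

**Unambiguous placement mode.** Exact ledger recovery is impossible in
general because indel representation is ambiguous (an indel inside a repeat
has many equal alignments, and an insertion/deletion pair placed close
together can tie with a substitution run at equal alignment cost). In
unambiguous mode errors are placed ≥5 bp apart, ≥6 bp from read ends, and
only at sites whose three-base neighbourhood is pairwise distinct (inserted
bases also differ from both neighbours), which makes every event's
left-aligned representation unique. Under these conditions the pipeline is
required — and tested — to reproduce the ledger *exactly*, per read and in
aggregate; this also holds through a real minimap2 alignment at the default
error rate. Default (unrestricted) mode exists for stress testing and makes
no exactness promise.

What passing these tests shows, and what it does not: the comparison logic,
coordinate arithmetic and normalization are exact on errors that are
identifiable in principle; they say nothing about errors in long repeats or
homopolymers, where no alignment-based evaluator can assign a unique
representation, nor about non-uniform HiFi error profiles or chimeric
reads, which the generator does not model.

## Numerical and interface choices

* All randomness flows from a single `numpy` generator seeded by
  `SimParams.seed`; identical seeds give byte-identical output files, and
  evaluation itself is fully deterministic.
* FDR/FNR with zero denominators are reported as `NA`, never 0 — a
  corrector that changes nothing has undefined FDR, not perfect FDR.
* Duplicate event keys within one alignment (only possible from malformed
  input) collapse to one with a warning.
* Events touching an N base (assembly gaps) are kept but flagged;
  `--ignore-n` excludes them so gaps do not inflate UC.
* Primary-alignment selection: PAF `tp:A:P` when present, else first record
  per read name with a warning (keeps hand-made fixtures usable); SAM uses
  the secondary/supplementary flags.
* Test problem sizes: the shared suite uses 40–500 kb genomes and a few
  hundred reads, enough for binomial confidence intervals around the
  simulated rates at a few thousand injected errors while keeping the whole
  suite around fifteen seconds.

## Known limitations

* No liftover between HPC and original coordinates: HPC-mode results are
  reported in HPC space.
* Long-form `cs` tags and BAM output are unsupported; reads and assemblies
  are treated as plain nucleotide sequence (no quality weighting, no QV
  estimate of corrected reads).
* The evaluator never decides which haplotype a read truly came from; it
  measures only agreement between the raw and corrected mappings.
* The simulator does not model structural variants, realistic HiFi
  pass-number quality profiles, or coverage bias.
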