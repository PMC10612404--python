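"""Fully ground-truthed synthetic data for hermetic testing.

Generates a two-haplotype genome with heterozygous SNPs and short indels,
HiFi-like reads with injected base errors, pseudo-corrected reads with a
known per-read ledger of fixed, missed and introduced errors, and alignment
records emitted directly from the ledger — so the whole evaluation pipeline
can be exercised and checked exactly, without an aligner or any downloads.

The pseudo-corrector operates on the truth ledger, not on sequence content:
each injected error is fixed with probability ``p_correct``, a
Poisson(``q_overcorrect``) number of new errors is introduced, and with
probability ``s_hapswitch`` the "corrected" read is rewritten onto the
homologous region of the other haplotype (emulating a corrector collapsing
haplotypes).  The point is a known answer, not realism.

In ``unambiguous`` placement mode errors are kept >=5 bp apart, away from
read ends and outside homopolymer context (the three reference bases around
each error site are pairwise distinct, and inserted bases differ from both
neighbours), so that every injected event has a unique left-aligned
representation and downstream CC/UC/OC counts must match the ledger exactly.
Default mode places errors without restriction, for stress testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alignment_io import EditEvent, EditKind, reconstruct_read, _event_order

log = logging.getLogger("ecbench")

_BASES = np.frombuffer(b"ACGT", dtype="S1")
HAP_LABELS = ("MAT", "PAT")


@dataclass
class SimParams:
    """Simulation parameters.

    ``genome_length`` is the total length per haplotype, split evenly over
    ``n_chromosomes``.  ``coverage`` is the fold coverage of the haploid
    genome, reads drawn evenly from both haplotypes.  ``error_rate`` is the
    per-base error probability split into substitution/insertion/deletion by
    ``error_mix``; indel errors are 1 bp, the dominant HiFi error mode.
    """

    genome_length: int = 100_000
    n_chromosomes: int = 1
    het_snp_rate: float = 0.001
    het_indel_rate: float = 0.0002
    read_length: int = 15_000
    coverage: float = 30.0
    error_rate: float = 0.002
    error_mix: tuple[float, float, float] = (0.70, 0.15, 0.15)  # SUB, INS, DEL
    p_correct: float = 0.9
    q_overcorrect: float = 0.1
    s_hapswitch: float = 0.0
    unambiguous: bool = False
    seed: int = 1

    def validate(self) -> None:
        for name in ("het_snp_rate", "het_indel_rate", "error_rate",
                     "p_correct", "s_hapswitch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.q_overcorrect < 0:
            raise ValueError("q_overcorrect must be >= 0")
        if self.genome_length <= 0 or self.n_chromosomes <= 0 or self.read_length <= 0:
            raise ValueError("lengths must be positive")
        if self.read_length > self.genome_length // self.n_chromosomes:
            raise ValueError("read_length exceeds chromosome length")
        if abs(sum(self.error_mix) - 1.0) > 1e-9:
            raise ValueError("error_mix must sum to 1")


@dataclass
class ReadTruth:
    """Per-read ledger entry: where the read came from and every error."""

    read_id: str
    contig: str            # haplotype contig of origin
    start: int             # 0-based reference start on that contig
    end: int               # exclusive reference end (start + read span)
    injected: list[EditEvent] = field(default_factory=list)
    fixed: list[EditEvent] = field(default_factory=list)      # subset of injected
    introduced: list[EditEvent] = field(default_factory=list)
    switched: bool = False
    corr_contig: str = ""  # where the corrected read lives (differs if switched)
    corr_start: int = -1   # start on corr_contig (== start unless switched)

    @property
    def missed(self) -> list[EditEvent]:
        fixed_keys = {e.key() for e in self.fixed}
        return [e for e in self.injected if e.key() not in fixed_keys]

    # expected evaluation outcome for a non-switched read
    @property
    def cc_true(self) -> int:
        return len(self.fixed)

    @property
    def uc_true(self) -> int:
        return len(self.injected) - len(self.fixed)

    @property
    def oc_true(self) -> int:
        return len(self.introduced)


@dataclass
class Simulation:
    """In-memory result of :func:`simulate`: genome, reads and truth ledger."""

    params: SimParams
    genome: dict[str, str]                 # haplotype contig -> sequence
    reads: list[ReadTruth]
    raw_seqs: dict[str, str]
    corr_seqs: dict[str, str]

    # ---- writers (plain-text standard formats) ----

    def write_assembly(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name} seed={self.params.seed}\n")
                _write_wrapped(fh, seq)

    def write_raw_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rt in self.reads:
                seq = self.raw_seqs[rt.read_id]
                fh.write(f"@{rt.read_id} seed={self.params.seed}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_corrected_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rt in self.reads:
                fh.write(f">{rt.read_id} seed={self.params.seed}\n")
                _write_wrapped(fh, self.corr_seqs[rt.read_id])

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tcontig\tstart\tend\tn_injected\tn_fixed\tn_missed"
                     "\tn_introduced\tswitched\tcorr_contig\n")
            for rt in self.reads:
                fh.write(f"{rt.read_id}\t{rt.contig}\t{rt.start}\t{rt.end}"
                         f"\t{len(rt.injected)}\t{len(rt.fixed)}\t{rt.uc_true}"
                         f"\t{len(rt.introduced)}\t{int(rt.switched)}\t{rt.corr_contig}\n")

    def write(self, prefix) -> dict[str, Path]:
        """Write assembly FASTA, raw FASTQ, corrected FASTA and truth TSV
        under ``prefix`` and return the paths."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "assembly": prefix.with_suffix(".asm.fa"),
            "raw": prefix.with_suffix(".raw.fq"),
            "corrected": prefix.with_suffix(".corr.fa"),
            "truth": prefix.with_suffix(".truth.tsv"),
        }
        self.write_assembly(paths["assembly"])
        self.write_raw_fastq(paths["raw"])
        self.write_corrected_fasta(paths["corrected"])
        self.write_truth_tsv(paths["truth"])
        return paths


def _write_wrapped(fh, seq: str, width: int = 80) -> None:
    for i in range(0, len(seq), width):
        fh.write(seq[i:i + width] + "\n")
    if not seq:
        fh.write("\n")


# ---------------------------------------------------------------------------
# genome and read generation


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _apply_het_variants(rng: np.random.Generator, hap1: np.ndarray,
                        snp_rate: float, indel_rate: float) -> np.ndarray:
    """Derive the second haplotype: SNPs plus 1-3 bp insertions/deletions."""
    n = len(hap1)
    out: list[bytes] = []
    i = 0
    # draw per-site events sparsely
    p_any = snp_rate + indel_rate
    if p_any == 0:
        return hap1.copy()
    sites = np.flatnonzero(rng.random(n) < p_any)
    is_snp = rng.random(len(sites)) < (snp_rate / p_any)
    cursor = 0
    pieces: list[np.ndarray] = []
    for site, snp in zip(sites, is_snp):
        if site < cursor:
            continue
        pieces.append(hap1[cursor:site])
        if snp:
            old = hap1[site]
            choices = _BASES[_BASES != old]
            pieces.append(np.array([rng.choice(choices)]))
            cursor = site + 1
        else:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion in hap2
                pieces.append(np.array([hap1[site]]))
                pieces.append(_BASES[rng.integers(0, 4, size=size)])
                cursor = site + 1
            else:  # deletion in hap2
                pieces.append(np.array([hap1[site]]))
                cursor = min(site + 1 + size, n)
    pieces.append(hap1[cursor:])
    return np.concatenate(pieces)


def _unambiguous_mask(seq: np.ndarray) -> np.ndarray:
    """Positions whose 3-base neighbourhood is pairwise distinct — indels
    placed there cannot shift under left-alignment."""
    n = len(seq)
    ok = np.zeros(n, dtype=bool)
    if n >= 3:
        a, b, c = seq[:-2], seq[1:-1], seq[2:]
        ok[1:-1] = (a != b) & (b != c) & (a != c)
    return ok


def _place_errors(rng: np.random.Generator, hap_seq: str, contig: str,
                  start: int, end: int, n_target: int,
                  mix: Sequence[float], unambiguous: bool,
                  valid_mask: np.ndarray | None,
                  occupied: set[int] | None = None,
                  min_gap: int = 5) -> list[EditEvent]:
    """Draw error events on reference window [start, end).

    In unambiguous mode candidate sites come from ``valid_mask`` with a
    ``min_gap`` spacing (also to ``occupied`` sites); otherwise sites are
    uniform without replacement.
    """
    margin = min_gap + 1
    lo, hi = start + margin, end - margin
    if hi <= lo or n_target <= 0:
        return []
    if unambiguous:
        cand = np.flatnonzero(valid_mask[lo:hi]) + lo
        cand = rng.permutation(cand)
        chosen: list[int] = []
        taken = sorted(occupied) if occupied else []
        for p in cand:
            if len(chosen) >= n_target:
                break
            if all(abs(p - q) >= min_gap for q in chosen) and \
               all(abs(p - q) >= min_gap for q in taken):
                chosen.append(int(p))
    else:
        n_target = min(n_target, hi - lo)
        pool = rng.choice(hi - lo, size=n_target, replace=False) + lo
        chosen = [int(p) for p in pool if not (occupied and int(p) in occupied)]
    events: list[EditEvent] = []
    kinds = rng.choice(3, size=len(chosen), p=list(mix))
    for p, k in zip(sorted(chosen), kinds[np.argsort(chosen)] if chosen else []):
        ref_b = hap_seq[p]
        if k == 0:  # SUB
            alt = _random_other(rng, (ref_b,))
            events.append(EditEvent(contig, p, EditKind.SUB, ref_b, alt))
        elif k == 1:  # INS of one base after p
            if unambiguous:
                alt = _random_other(rng, (hap_seq[p], hap_seq[p + 1]))
            else:
                alt = str(_BASES[rng.integers(0, 4)], "ascii")
            events.append(EditEvent(contig, p, EditKind.INS, "", alt))
        else:  # DEL of the base at p
            events.append(EditEvent(contig, p, EditKind.DEL, ref_b, ""))
    return events


def _random_other(rng: np.random.Generator, exclude: Sequence[str]) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[int(rng.integers(0, len(choices)))]


def simulate(params: SimParams, out_prefix=None) -> Simulation:
    """Run the full generator; deterministic given ``params.seed``.

    Returns the in-memory :class:`Simulation`; when ``out_prefix`` is given
    also writes assembly FASTA, raw FASTQ, corrected FASTA and truth TSV.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    chrom_len = params.genome_length // params.n_chromosomes
    genome: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    chrom_names: list[tuple[str, str]] = []
    for c in range(params.n_chromosomes):
        hap1 = _random_genome(rng, chrom_len)
        hap2 = _apply_het_variants(rng, hap1, params.het_snp_rate, params.het_indel_rate)
        mat = f"chr{c + 1}_{HAP_LABELS[0]}"
        pat = f"chr{c + 1}_{HAP_LABELS[1]}"
        genome[mat] = hap1.tobytes().decode("ascii")
        genome[pat] = hap2.tobytes().decode("ascii")
        chrom_names.append((mat, pat))
        if params.unambiguous:
            masks[mat] = _unambiguous_mask(hap1)
            masks[pat] = _unambiguous_mask(hap2)

    total_hap = sum(len(genome[m]) for m, _ in chrom_names)
    n_reads = max(1, int(round(params.coverage * total_hap / params.read_length)))

    reads: list[ReadTruth] = []
    raw_seqs: dict[str, str] = {}
    corr_seqs: dict[str, str] = {}

    partner = {}
    for mat, pat in chrom_names:
        partner[mat] = pat
        partner[pat] = mat

    for i in range(n_reads):
        rid = f"read{i:06d}"
        c = int(rng.integers(0, params.n_chromosomes))
        contig = chrom_names[c][int(rng.integers(0, 2))]
        hap_seq = genome[contig]
        start = int(rng.integers(0, len(hap_seq) - params.read_length + 1))
        end = start + params.read_length

        n_err = int(rng.binomial(params.read_length, params.error_rate))
        injected = _place_errors(rng, hap_seq, contig, start, end, n_err,
                                 params.error_mix, params.unambiguous,
                                 masks.get(contig))
        raw_seqs[rid] = reconstruct_read(hap_seq, start, end, injected)

        fix_mask = rng.random(len(injected)) < params.p_correct
        fixed = [e for e, f in zip(injected, fix_mask) if f]
        missed = [e for e, f in zip(injected, fix_mask) if not f]

        switched = bool(rng.random() < params.s_hapswitch)
        if switched:
            other = partner[contig]
            oseq = genome[other]
            ostart = max(0, min(start, len(oseq) - params.read_length))
            rt = ReadTruth(rid, contig, start, end, injected, fixed, [], True,
                           other, ostart)
            corr_seqs[rid] = oseq[ostart:ostart + params.read_length]
        else:
            n_new = int(rng.poisson(params.q_overcorrect))
            occupied = {e.pos for e in injected}
            introduced = _place_errors(rng, hap_seq, contig, start, end, n_new,
                                       params.error_mix, params.unambiguous,
                                       masks.get(contig), occupied=occupied)
            remaining = sorted(missed + introduced, key=_event_order)
            rt = ReadTruth(rid, contig, start, end, injected, fixed, introduced,
                           False, contig, start)
            corr_seqs[rid] = reconstruct_read(hap_seq, start, end, remaining)
        reads.append(rt)

    sim = Simulation(params, genome, reads, raw_seqs, corr_seqs)
    if out_prefix is not None:
        sim.write(out_prefix)
    return sim


# ---------------------------------------------------------------------------
# truth-derived alignment records (bypassing any aligner)


def _cs_from_events(ref_seq: str, start: int, end: int,
                    events: Iterable[EditEvent]) -> tuple[str, int, int, int]:
    """Build a short-form cs tag for a perfect truth alignment.

    Returns (cs, n_match, aln_len, query_len)."""
    parts: list[str] = []
    cur = start
    n_match = n_sub = n_ins = n_del = 0
    for ev in sorted(events, key=_event_order):
        if ev.kind is EditKind.INS:
            gap = ev.pos + 1 - cur
            if gap > 0:
                parts.append(f":{gap}")
                n_match += gap
                cur = ev.pos + 1
            parts.append("+" + ev.alt_seq.lower())
            n_ins += len(ev.alt_seq)
        else:
            gap = ev.pos - cur
            if gap > 0:
                parts.append(f":{gap}")
                n_match += gap
            cur = ev.pos
            if ev.kind is EditKind.SUB:
                parts.append(f"*{ev.ref_seq.lower()}{ev.alt_seq.lower()}")
                n_sub += 1
                cur += 1
            else:
                parts.append("-" + ev.ref_seq.lower())
                n_del += len(ev.ref_seq)
                cur += len(ev.ref_seq)
    if end - cur > 0:
        parts.append(f":{end - cur}")
        n_match += end - cur
    qlen = n_match + n_sub + n_ins
    aln_len = n_match + n_sub + n_ins + n_del
    return "".join(parts), n_match, aln_len, qlen


def emit_truth_alignments(sim: Simulation, which: str, path=None) -> list[str]:
    """Emit one primary PAF record (with cs tag, mapq 60) per read, at its
    true locus, reconstructed from the error ledger.  ``which`` selects the
    raw or the corrected read set.  Returns the PAF lines; writes them when
    ``path`` is given."""
    if which not in ("raw", "corrected"):
        raise ValueError("which must be 'raw' or 'corrected'")
    lines: list[str] = []
    for rt in sim.reads:
        if which == "raw":
            contig, start, end = rt.contig, rt.start, rt.end
            events = rt.injected
        elif rt.switched:
            contig = rt.corr_contig
            start = rt.corr_start
            end = start + sim.params.read_length
            events = []
        else:
            contig, start, end = rt.contig, rt.start, rt.end
            events = sorted(rt.missed + rt.introduced, key=_event_order)
        ref_seq = sim.genome[contig]
        cs, n_match, aln_len, qlen = _cs_from_events(ref_seq, start, end, events)
        lines.append("\t".join(map(str, (
            rt.read_id, qlen, 0, qlen, "+", contig, len(ref_seq), start, end,
            n_match, aln_len, 60, "tp:A:P", f"cs:Z:{cs}"))))
    if path is not None:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    return lines
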