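"""Core comparison: match edit events between each read's raw and corrected
alignments and compute CC/UC/OC, FDR and FNR.

For every read the tool compares the edit events of the raw alignment and of
the corrected alignment against the truth assembly:

* correct corrections (CC) — errors in the raw read absent from the
  corrected read (true positives of the corrector);
* under-corrections (UC) — errors present in both (false negatives);
* over-corrections (OC) — new errors only in the corrected read (false
  positives).

The two headline metrics are ``FDR = OC/(CC+OC)`` and ``FNR = UC/(CC+UC)``.
Reads whose raw and corrected alignments land on different contigs or
non-overlapping intervals are flagged mapping-inconsistent; they are still
evaluated but excluded from the aggregate rates by default (they are handed
to the mapping-difference classifier instead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

from .alignment_io import EditEvent, EditKind, ReadAlignment

log = logging.getLogger("ecbench")


@dataclass
class ReadEvaluation:
    """Per-read partition of edit events into CC/UC/OC."""

    read_id: str
    cc: list[EditEvent]
    uc: list[EditEvent]
    oc: list[EditEvent]
    mapping_consistent: bool
    overlap: tuple[str, int, int] | None  # (contig, start, end) compared
    trimmed_raw: int = 0   # raw events outside the overlap (read trimmed by EC)
    trimmed_corr: int = 0  # corrected events outside the overlap
    raw_locus: tuple[str, int, int, int] = None    # (contig, start, end, mapq)
    corr_locus: tuple[str, int, int, int] = None


@dataclass
class EvaluationSummary:
    """Aggregate CC/UC/OC counts and the derived FDR/FNR."""

    n_reads: int = 0
    n_excluded: int = 0  # mapping-inconsistent reads not counted
    cc: int = 0
    uc: int = 0
    oc: int = 0
    trimmed_raw: int = 0
    trimmed_corr: int = 0

    @property
    def fdr(self) -> float | None:
        """OC / (CC + OC), or None when no corrections were attempted."""
        return self.oc / (self.cc + self.oc) if (self.cc + self.oc) > 0 else None

    @property
    def fnr(self) -> float | None:
        """UC / (CC + UC), or None when the raw reads had no errors."""
        return self.uc / (self.cc + self.uc) if (self.cc + self.uc) > 0 else None


def _dedupe(events: Iterable[EditEvent], match_alt: bool, read_id: str) -> dict:
    keyed: dict[tuple, EditEvent] = {}
    for ev in events:
        k = ev.key(match_alt)
        if k in keyed:
            log.warning("%s: duplicate event key %s collapsed", read_id, k)
        else:
            keyed[k] = ev
    return keyed


def evaluate_read(raw: ReadAlignment, corr: ReadAlignment, *,
                  match_alt: bool = True, ignore_n: bool = False) -> ReadEvaluation:
    """Compare a read's raw and corrected alignments.

    Event identity is ``(contig, pos, kind, ref_seq, alt_seq)`` (drop the
    alleles with ``match_alt=False``).  The comparison is restricted to the
    intersection of the two reference intervals; raw events outside it — the
    corrector trimmed the read — are counted separately, not as CC.  With
    ``ignore_n`` events touching an N base (assembly gaps) are dropped first.
    """
    if raw.read_id != corr.read_id:
        raise ValueError(f"read_id mismatch: {raw.read_id!r} vs {corr.read_id!r}")

    raw_events = [e for e in raw.edits if not (ignore_n and e.has_n)]
    corr_events = [e for e in corr.edits if not (ignore_n and e.has_n)]

    consistent = (raw.contig == corr.contig
                  and raw.ref_start < corr.ref_end and corr.ref_start < raw.ref_end)
    if consistent:
        ov = (raw.contig, max(raw.ref_start, corr.ref_start),
              min(raw.ref_end, corr.ref_end))
        in_ov = lambda e: ov[1] <= e.pos < ov[2]
    else:
        # still evaluated (full event sets), but flagged for exclusion
        ov = None
        in_ov = lambda e: True

    raw_keep = _dedupe((e for e in raw_events if in_ov(e)), match_alt, raw.read_id)
    corr_keep = _dedupe((e for e in corr_events if in_ov(e)), match_alt, corr.read_id)

    cc = [ev for k, ev in raw_keep.items() if k not in corr_keep]
    uc = [ev for k, ev in raw_keep.items() if k in corr_keep]
    oc = [ev for k, ev in corr_keep.items() if k not in raw_keep]

    return ReadEvaluation(
        read_id=raw.read_id, cc=cc, uc=uc, oc=oc,
        mapping_consistent=consistent, overlap=ov,
        trimmed_raw=len(raw_events) - len(raw_keep) if ov else 0,
        trimmed_corr=len(corr_events) - len(corr_keep) if ov else 0,
        raw_locus=(raw.contig, raw.ref_start, raw.ref_end, raw.mapq),
        corr_locus=(corr.contig, corr.ref_start, corr.ref_end, corr.mapq),
    )


@dataclass
class PairingResult:
    """Read pairs plus the orphans on either side."""

    pairs: list[tuple[ReadAlignment, ReadAlignment]]
    dropped_raw: list[str]   # raw reads with no corrected counterpart
    orphan_corr: list[str]   # corrected reads with no raw counterpart


def strip_suffix_rule(suffix: str) -> Callable[[str], str]:
    """Name-matching rule mapping a corrected read id back to the raw id by
    stripping a fixed suffix (e.g. ``_corrected``)."""

    def rule(name: str) -> str:
        return name[:-len(suffix)] if suffix and name.endswith(suffix) else name

    return rule


def pair_reads(raw_alignments: Iterable[ReadAlignment],
               corr_alignments: Iterable[ReadAlignment],
               name_rule: Callable[[str], str] | None = None) -> PairingResult:
    """Pair raw and corrected primary alignments by read id.

    ``name_rule`` (applied to corrected ids) accommodates correctors that
    rename reads.  Raw reads without a corrected counterpart are reported as
    dropped by the corrector — some tools discard whole reads — and orphan
    corrected reads are reported and excluded.  Orphans are never fatal.
    """
    raw_by_id: dict[str, ReadAlignment] = {}
    for aln in raw_alignments:
        raw_by_id[aln.read_id] = aln
    pairs: list[tuple[ReadAlignment, ReadAlignment]] = []
    matched: set[str] = set()
    orphan_corr: list[str] = []
    for aln in corr_alignments:
        rid = name_rule(aln.read_id) if name_rule else aln.read_id
        raw = raw_by_id.get(rid)
        if raw is None:
            orphan_corr.append(aln.read_id)
        else:
            pairs.append((raw, aln))
            matched.add(rid)
    dropped = [rid for rid in raw_by_id if rid not in matched]
    if not pairs and (dropped or orphan_corr):
        log.warning("no read ids in common between raw and corrected alignments "
                    "(%d raw, %d corrected)", len(dropped), len(orphan_corr))
    elif dropped:
        log.info("%d raw reads have no corrected counterpart (dropped by the EC tool)",
                 len(dropped))
    return PairingResult(pairs, dropped, orphan_corr)


def summarize(evals: Iterable[ReadEvaluation],
              include_inconsistent: bool = False) -> EvaluationSummary:
    """Total CC/UC/OC over mapping-consistent reads (unless
    ``include_inconsistent``) and the resulting FDR/FNR."""
    s = EvaluationSummary()
    for ev in evals:
        if not ev.mapping_consistent and not include_inconsistent:
            s.n_excluded += 1
            continue
        s.n_reads += 1
        s.cc += len(ev.cc)
        s.uc += len(ev.uc)
        s.oc += len(ev.oc)
        s.trimmed_raw += ev.trimmed_raw
        s.trimmed_corr += ev.trimmed_corr
    return s


# ---------------------------------------------------------------------------
# tabular output

PER_READ_COLUMNS = ["read_id", "contig", "ref_start", "ref_end", "CC", "UC", "OC",
                    "mapping_consistent", "trimmed_raw_events"]


def per_read_rows(evals: Iterable[ReadEvaluation]) -> Iterator[list]:
    for ev in evals:
        contig, start, end, _ = ev.raw_locus
        yield [ev.read_id, contig, start, end, len(ev.cc), len(ev.uc), len(ev.oc),
               int(ev.mapping_consistent), ev.trimmed_raw]


def write_per_read_tsv(evals: Iterable[ReadEvaluation], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PER_READ_COLUMNS) + "\n")
        for row in per_read_rows(evals):
            fh.write("\t".join(str(x) for x in row) + "\n")


def format_summary(s: EvaluationSummary) -> str:
    """Human-readable summary with explicit numerators/denominators."""
    fdr = "NA" if s.fdr is None else f"{s.fdr:.6f} ({s.oc}/{s.cc + s.oc})"
    fnr = "NA" if s.fnr is None else f"{s.fnr:.6f} ({s.uc}/{s.cc + s.uc})"
    return (
        f"reads counted:       {s.n_reads}\n"
        f"reads excluded:      {s.n_excluded} (mapping-inconsistent)\n"
        f"CC (correct):        {s.cc}\n"
        f"UC (under-corr):     {s.uc}\n"
        f"OC (over-corr):      {s.oc}\n"
        f"trimmed raw events:  {s.trimmed_raw}\n"
        f"FDR = OC/(CC+OC):    {fdr}\n"
        f"FNR = UC/(CC+UC):    {fnr}\n"
    )


def write_summary_tsv(s: EvaluationSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("n_reads\tn_excluded\tCC\tUC\tOC\ttrimmed_raw\tFDR\tFNR\n")
        fdr = "NA" if s.fdr is None else f"{s.fdr:.6g}"
        fnr = "NA" if s.fnr is None else f"{s.fnr:.6g}"
        fh.write(f"{s.n_reads}\t{s.n_excluded}\t{s.cc}\t{s.uc}\t{s.oc}"
                 f"\t{s.trimmed_raw}\t{fdr}\t{fnr}\n")
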