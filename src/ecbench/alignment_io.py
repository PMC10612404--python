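"""Alignment ingestion: PAF/SAM records to per-read primary alignments with
reference-anchored edit events.

Every difference between a read and the truth assembly is represented as an
:class:`EditEvent` — a substitution, insertion or deletion anchored on the
reference.  Events are extracted from minimap2 cs tags (short form) or, for
SAM records without a cs tag, derived from CIGAR plus the MD tag.  All
coordinates are 0-based, half-open, in reference space, matching PAF.

Because the same biological indel can be written at several equivalent
positions inside a repeat, :func:`normalize_indels` left-aligns every
insertion and deletion against the reference so that events from the raw and
the corrected alignment of a read compare equal.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Iterator, Mapping

log = logging.getLogger("ecbench")

_VALID_BASES = frozenset("ACGTN")


class AlignmentParseError(ValueError):
    """Unparseable alignment record, malformed cs tag, or missing edit info."""


class EditKind(str, Enum):
    SUB = "SUB"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class EditEvent:
    """One reference-anchored difference between a read and the assembly.

    ``pos`` is the 0-based reference coordinate of the edited base; for an
    insertion it is the coordinate of the reference base immediately *after*
    which the inserted sequence appears (an insertion before the first
    aligned base gets ``pos = ref_start - 1``).
    """

    contig: str
    pos: int
    kind: EditKind
    ref_seq: str = ""
    alt_seq: str = ""

    def __post_init__(self) -> None:
        if self.kind is EditKind.SUB:
            if len(self.ref_seq) != 1 or len(self.alt_seq) != 1:
                raise ValueError(f"SUB must be 1bp->1bp, got {self!r}")
        elif self.kind is EditKind.INS:
            if self.ref_seq or not self.alt_seq:
                raise ValueError(f"INS must have empty ref_seq and non-empty alt_seq: {self!r}")
        elif self.kind is EditKind.DEL:
            if self.alt_seq or not self.ref_seq:
                raise ValueError(f"DEL must have empty alt_seq and non-empty ref_seq: {self!r}")
        bad = (set(self.ref_seq) | set(self.alt_seq)) - _VALID_BASES
        if bad:
            raise ValueError(f"non-ACGTN base(s) {sorted(bad)} in {self!r}")

    @property
    def has_n(self) -> bool:
        """True if the reference or alternate sequence contains an N (e.g. an
        assembly gap); such events can be excluded from counting."""
        return "N" in self.ref_seq or "N" in self.alt_seq

    def key(self, match_alt: bool = True) -> tuple:
        """Identity used when matching events between raw and corrected
        alignments.  With ``match_alt`` (default) the alternate allele is part
        of the identity, so replacing one error with a different error at the
        same position counts as one correction plus one new error."""
        if match_alt:
            return (self.contig, self.pos, self.kind, self.ref_seq, self.alt_seq)
        return (self.contig, self.pos, self.kind)

    def ref_span(self) -> tuple[int, int]:
        """Reference interval touched by the event (anchor base for INS/SUB,
        all deleted bases for DEL)."""
        if self.kind is EditKind.DEL:
            return (self.pos, self.pos + len(self.ref_seq))
        return (self.pos, self.pos + 1)


def _event_order(ev: EditEvent) -> tuple:
    # INS anchored at p sorts after a SUB/DEL consuming base p
    return (ev.contig, ev.pos, 1 if ev.kind is EditKind.INS else 0)


@dataclass
class ReadAlignment:
    """One primary alignment of a read, with its edit events."""

    read_id: str
    contig: str
    ref_start: int
    ref_end: int
    strand: str
    mapq: int
    is_primary: bool = True
    edits: list[EditEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(
                f"{self.read_id}: ref_start {self.ref_start} >= ref_end {self.ref_end}"
            )
        self.edits = sorted(self.edits, key=_event_order)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)


@dataclass
class ParseStats:
    """Counters accumulated while streaming an alignment file."""

    n_primary: int = 0
    n_secondary: int = 0
    n_supplementary: int = 0
    n_unmapped: int = 0
    n_duplicate: int = 0


# ---------------------------------------------------------------------------
# cs-tag extraction


def extract_edits(cs_string: str, contig: str, ref_start: int) -> list[EditEvent]:
    """Parse a short-form cs tag into reference-ordered edit events.

    The reference cursor starts at ``ref_start`` and is advanced by ``:len``
    matches, ``*`` substitutions (1 bp) and ``-`` deletions (run length);
    insertions consume no reference.  Raises :class:`AlignmentParseError` on
    malformed syntax, naming the offending token.
    """
    events: list[EditEvent] = []
    pos = ref_start
    i, n = 0, len(cs_string)
    while i < n:
        c = cs_string[i]
        if c == ":":
            j = i + 1
            while j < n and cs_string[j].isdigit():
                j += 1
            if j == i + 1:
                raise AlignmentParseError(f"malformed cs token {cs_string[i:i + 8]!r}")
            pos += int(cs_string[i + 1:j])
            i = j
        elif c == "*":
            if i + 2 >= n or not (cs_string[i + 1].isalpha() and cs_string[i + 2].isalpha()):
                raise AlignmentParseError(f"malformed cs token {cs_string[i:i + 8]!r}")
            ref_b = cs_string[i + 1].upper()
            alt_b = cs_string[i + 2].upper()
            _check_bases(ref_b + alt_b, cs_string[i:i + 3])
            events.append(EditEvent(contig, pos, EditKind.SUB, ref_b, alt_b))
            pos += 1
            i += 3
        elif c in "+-":
            j = i + 1
            while j < n and cs_string[j].isalpha():
                j += 1
            seq = cs_string[i + 1:j].upper()
            if not seq:
                raise AlignmentParseError(f"malformed cs token {cs_string[i:i + 8]!r}")
            _check_bases(seq, cs_string[i:j])
            if c == "+":
                events.append(EditEvent(contig, pos - 1, EditKind.INS, "", seq))
            else:
                events.append(EditEvent(contig, pos, EditKind.DEL, seq, ""))
                pos += len(seq)
            i = j
        else:
            raise AlignmentParseError(f"unsupported cs token starting at {cs_string[i:i + 8]!r}")
    return events


def _check_bases(seq: str, token: str) -> None:
    if not set(seq) <= _VALID_BASES:
        raise AlignmentParseError(f"non-ACGTN base in cs token {token!r}")


def reconstruct_read(ref_seq: str, ref_start: int, ref_end: int,
                     edits: Iterable[EditEvent]) -> str:
    """Replay edit events onto the reference window ``[ref_start, ref_end)``
    and return the aligned read sequence.  ``ref_seq`` is the full contig."""
    out: list[str] = []
    cur = ref_start
    for ev in sorted(edits, key=_event_order):
        if ev.kind is EditKind.SUB:
            out.append(ref_seq[cur:ev.pos])
            out.append(ev.alt_seq)
            cur = ev.pos + 1
        elif ev.kind is EditKind.DEL:
            out.append(ref_seq[cur:ev.pos])
            cur = ev.pos + len(ev.ref_seq)
        else:  # INS after ev.pos
            stop = ev.pos + 1
            if stop > cur:
                out.append(ref_seq[cur:stop])
                cur = stop
            out.append(ev.alt_seq)
    out.append(ref_seq[cur:ref_end])
    return "".join(out)


# ---------------------------------------------------------------------------
# indel left-alignment

RefAccessor = Callable[[str], str]


class _RefCache:
    """Uppercased per-contig sequence cache over a mapping-like reference
    (dict of str, Bio.Seq objects, or a pyfaidx.Fasta)."""

    def __init__(self, ref: Mapping) -> None:
        self._ref = ref
        self._cache: dict[str, str] = {}

    def __call__(self, contig: str) -> str:
        seq = self._cache.get(contig)
        if seq is None:
            seq = str(self._ref[contig]).upper()
            self._cache[contig] = seq
        return seq


def normalize_indels(edits: Iterable[EditEvent], ref) -> list[EditEvent]:
    """Left-align every insertion and deletion to its smallest equivalent
    reference position; substitutions are position-fixed.  ``ref`` is a
    callable ``contig -> sequence`` or any mapping from contig name to a
    sequence object.  Output is re-sorted in reference order."""
    get: RefAccessor = ref if callable(ref) else _RefCache(ref)
    out: list[EditEvent] = []
    for ev in edits:
        if ev.kind is EditKind.SUB:
            out.append(ev)
            continue
        seq = get(ev.contig)
        if ev.kind is EditKind.DEL:
            k = len(ev.ref_seq)
            pos = ev.pos
            if pos < 0 or pos + k > len(seq):
                raise AlignmentParseError(
                    f"DEL at {ev.contig}:{pos}+{k} outside contig (len {len(seq)})")
            while pos > 0 and seq[pos - 1] == seq[pos + k - 1]:
                pos -= 1
            out.append(replace(ev, pos=pos, ref_seq=seq[pos:pos + k]))
        else:  # INS: rotate left while the base before the anchor matches
            pos = ev.pos
            if pos >= len(seq) or pos < -1:
                raise AlignmentParseError(
                    f"INS anchor {ev.contig}:{pos} outside contig (len {len(seq)})")
            alt = ev.alt_seq
            while pos >= 0 and seq[pos] == alt[-1]:
                alt = seq[pos] + alt[:-1]
                pos -= 1
            out.append(replace(ev, pos=pos, alt_seq=alt))
    return sorted(out, key=_event_order)


# ---------------------------------------------------------------------------
# file parsing


def parse_alignments(path, fmt: str | None = None,
                     stats: ParseStats | None = None) -> Iterator[ReadAlignment]:
    """Stream primary alignments from a PAF (optionally gzipped) or SAM file.

    Yields exactly one :class:`ReadAlignment` per read id: for PAF the record
    tagged ``tp:A:P`` (or, when no tp tags are present, the first record per
    read, with a warning); for SAM the record that is neither secondary nor
    supplementary.  Skipped records are counted in ``stats``.
    """
    path = str(path)
    if fmt is None:
        base = path[:-3] if path.endswith(".gz") else path
        if base.endswith(".paf"):
            fmt = "paf"
        elif base.endswith(".sam") or base.endswith(".bam"):
            fmt = "sam"
        else:
            raise AlignmentParseError(
                f"cannot infer alignment format of {path!r}; pass fmt='paf' or 'sam'")
    if stats is None:
        stats = ParseStats()
    if fmt == "paf":
        yield from _parse_paf(path, stats)
    elif fmt == "sam":
        yield from _parse_sam(path, stats)
    else:
        raise AlignmentParseError(f"unknown alignment format {fmt!r}")


_TAG_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]):([AifZHB]):(.*)$")


def _parse_paf(path: str, stats: ParseStats) -> Iterator[ReadAlignment]:
    opener = gzip.open if path.endswith(".gz") else open
    seen: set[str] = set()
    warned_no_tp = False
    n_lines = 0
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            n_lines += 1
            f = line.split("\t")
            if len(f) < 12:
                raise AlignmentParseError(f"{path} line {lineno}: expected >=12 PAF columns")
            try:
                qname = f[0].split()[0]
                strand = f[4]
                tname = f[5]
                tstart = int(f[7])
                tend = int(f[8])
                mapq = int(f[11])
            except (ValueError, IndexError) as exc:
                raise AlignmentParseError(f"{path} line {lineno}: unparseable PAF record: {exc}")
            tags: dict[str, str] = {}
            for tok in f[12:]:
                m = _TAG_RE.match(tok)
                if not m:
                    raise AlignmentParseError(f"{path} line {lineno}: bad tag {tok!r}")
                tags[m.group(1)] = m.group(3)
            tp = tags.get("tp")
            if tp is not None and tp != "P":
                stats.n_secondary += 1
                continue
            if tp is None and not warned_no_tp:
                log.warning("%s: no tp:A tags; taking the first record per read as primary", path)
                warned_no_tp = True
            if qname in seen:
                stats.n_duplicate += 1
                continue
            if "cs" not in tags:
                raise AlignmentParseError(
                    f"{path} line {lineno}: record for {qname!r} lacks a cs tag; "
                    "rerun minimap2 with --cs")
            try:
                edits = extract_edits(tags["cs"], tname, tstart)
            except AlignmentParseError as exc:
                raise AlignmentParseError(f"{path} line {lineno}: {exc}")
            seen.add(qname)
            stats.n_primary += 1
            yield ReadAlignment(qname, tname, tstart, tend, strand, mapq, True, edits)
    if n_lines == 0:
        log.warning("empty alignment file %s", path)


def _parse_sam(path: str, stats: ParseStats) -> Iterator[ReadAlignment]:
    import pysam

    seen: set[str] = set()
    n_records = 0
    save = pysam.set_verbosity(0)  # silence missing-index chatter
    try:
        afile = pysam.AlignmentFile(path, check_sq=False)
    finally:
        pysam.set_verbosity(save)
    with afile:
        for aln in afile:
            n_records += 1
            if aln.is_unmapped:
                stats.n_unmapped += 1
                continue
            if aln.is_secondary:
                stats.n_secondary += 1
                continue
            if aln.is_supplementary:
                stats.n_supplementary += 1
                continue
            qname = aln.query_name
            if qname in seen:
                stats.n_duplicate += 1
                continue
            contig = aln.reference_name
            if aln.has_tag("cs"):
                edits = extract_edits(aln.get_tag("cs"), contig, aln.reference_start)
            else:
                edits = _edits_from_cigar_md(aln)
            seen.add(qname)
            stats.n_primary += 1
            yield ReadAlignment(qname, contig, aln.reference_start, aln.reference_end,
                                "-" if aln.is_reverse else "+", aln.mapping_quality,
                                True, edits)
    if n_records == 0:
        log.warning("empty alignment file %s", path)


def _edits_from_cigar_md(aln) -> list[EditEvent]:
    """Derive cs-equivalent events from CIGAR + MD for a pysam record."""
    if not aln.has_tag("MD"):
        raise AlignmentParseError(
            f"SAM record for {aln.query_name!r} has neither cs nor MD tag; "
            "substitutions cannot be recovered")
    contig = aln.reference_name
    ref = aln.get_reference_sequence().upper()  # aligned ref span, from MD
    query = aln.query_sequence.upper()
    events: list[EditEvent] = []
    qpos = 0
    rpos = aln.reference_start
    roff = 0  # offset into `ref`
    for op, length in aln.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            for k in range(length):
                rb, qb = ref[roff + k], query[qpos + k]
                if rb != qb:
                    events.append(EditEvent(contig, rpos + k, EditKind.SUB, rb, qb))
            qpos += length
            rpos += length
            roff += length
        elif op == 1:  # I
            events.append(EditEvent(contig, rpos - 1, EditKind.INS, "",
                                    query[qpos:qpos + length]))
            qpos += length
        elif op == 2:  # D
            events.append(EditEvent(contig, rpos, EditKind.DEL,
                                    ref[roff:roff + length], ""))
            rpos += length
            roff += length
        elif op == 4:  # S
            qpos += length
        elif op == 5:  # H
            pass
        else:
            raise AlignmentParseError(
                f"unsupported CIGAR op {op} in record for {aln.query_name!r}")
    return events
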