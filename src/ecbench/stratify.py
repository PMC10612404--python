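"""Stratify correction metrics by genomic annotation.

Error-correction accuracy is not uniform along a genome: centromeric
satellites, segmental duplications and homopolymer runs are harder than
unique sequence.  Each edit event is attributed to every region set whose
intervals contain its reference position (any deleted base for a deletion,
the anchor base for an insertion), and CC/UC/OC and the derived FDR/FNR are
totalled per stratum.  Strata may overlap; events in no stratum fall into a
residual "other" stratum.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .alignment_io import EditEvent
from .eval_core import EvaluationSummary, ReadEvaluation

log = logging.getLogger("ecbench")


@dataclass
class RegionSet:
    """A labelled set of non-overlapping, sorted genomic intervals
    (0-based, half-open), e.g. one annotation track."""

    label: str
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, contig: str, start: int, end: int) -> None:
        self.trees.setdefault(contig, IntervalTree()).addi(start, end)

    def merge(self) -> None:
        for tree in self.trees.values():
            tree.merge_overlaps(strict=False)  # merge adjacent intervals too

    @property
    def n_intervals(self) -> int:
        return sum(len(t) for t in self.trees.values())

    def contains(self, contig: str, start: int, end: int | None = None) -> bool:
        """True if [start, end) (or the single position start) overlaps the set."""
        tree = self.trees.get(contig)
        if tree is None:
            return False
        if end is None or end <= start + 1:
            return bool(tree[start])
        return tree.overlaps(start, end)

    def intervals(self) -> Iterable[tuple[str, int, int]]:
        for contig in sorted(self.trees):
            for iv in sorted(self.trees[contig]):
                yield (contig, iv.begin, iv.end)


def load_bed(path, label: str, known_contigs: Iterable[str] | None = None) -> RegionSet:
    """Load a 3+ column BED file into a merged :class:`RegionSet`.

    Malformed lines (too few columns, non-integer or inverted coordinates)
    are a hard error naming the line number.  Contigs absent from
    ``known_contigs`` (when given) only trigger a warning; the interval is
    kept.
    """
    rs = RegionSet(label)
    known = set(known_contigs) if known_contigs is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path} line {lineno}: expected >=3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ValueError(f"{path} line {lineno}: non-integer coordinates")
            if end <= start:
                raise ValueError(f"{path} line {lineno}: end {end} <= start {start}")
            if known is not None and f[0] not in known:
                log.warning("%s line %d: contig %r not in the assembly", path, lineno, f[0])
            rs.add(f[0], start, end)
    rs.merge()
    return rs


_HOMOPOLYMER_RE = re.compile(r"(.)\1+")


def annotate_homopolymers(assembly: Mapping, min_len: int = 3) -> RegionSet:
    """Derive the homopolymer-run stratum from the assembly itself: one
    interval per maximal single-base run of length >= ``min_len``.

    ``assembly`` is any mapping from contig name to sequence (dict of str,
    Bio.Seq values, or a pyfaidx.Fasta).
    """
    rs = RegionSet("homopolymer")
    for contig in assembly.keys() if hasattr(assembly, "keys") else assembly:
        seq = str(assembly[contig]).upper()
        for m in _HOMOPOLYMER_RE.finditer(seq):
            if m.end() - m.start() >= min_len:
                rs.add(contig, m.start(), m.end())
    rs.merge()
    return rs


def _event_in(rs: RegionSet, ev: EditEvent) -> bool:
    span = ev.ref_span()
    return rs.contains(ev.contig, span[0], span[1])


def stratified_summary(evals: Iterable[ReadEvaluation],
                       regions: list[RegionSet],
                       include_inconsistent: bool = False) -> pd.DataFrame:
    """Per-stratum CC/UC/OC and FDR/FNR table.

    Attribution is by event position, not whole-read overlap — a long read
    can span several annotation classes.  An event may fall in several
    (overlapping) strata and is counted once in each; events in none are
    totalled under "other".  With no region sets, a single "all" stratum
    equals the global summary.
    """
    labels = [rs.label for rs in regions] if regions else ["all"]
    sums = {lab: EvaluationSummary() for lab in labels}
    sums["other"] = EvaluationSummary()

    def tally(ev: EditEvent, attr: str) -> None:
        hit = False
        for rs in regions:
            if _event_in(rs, ev):
                setattr(sums[rs.label], attr, getattr(sums[rs.label], attr) + 1)
                hit = True
        if not regions:
            sums["all"].__dict__[attr] += 1
            hit = True
        if not hit:
            sums["other"].__dict__[attr] += 1

    for rev in evals:
        if not rev.mapping_consistent and not include_inconsistent:
            continue
        for ev in rev.cc:
            tally(ev, "cc")
        for ev in rev.uc:
            tally(ev, "uc")
        for ev in rev.oc:
            tally(ev, "oc")

    rows = []
    for lab in labels + ["other"]:
        s = sums[lab]
        rows.append({"label": lab, "CC": s.cc, "UC": s.uc, "OC": s.oc,
                     "FDR": s.fdr, "FNR": s.fnr})
    return pd.DataFrame(rows)
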