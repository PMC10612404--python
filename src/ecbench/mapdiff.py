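"""Classify reads whose raw and corrected alignments disagree.

On a diploid truth assembly a corrector can move a read between the two
parental haplotypes, between chromosomes, or along the same contig.  Each
mapping-inconsistent pair is classified as a haplotype difference (same
chromosome, opposite haplotype), a chromosome difference (same haplotype
label, different chromosome), or a position difference (same chromosome and
haplotype, non-overlapping intervals).  Pairs where neither alignment
reaches the mapping-quality threshold are too ambiguous to classify and are
filtered out first.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment_io import ReadAlignment

log = logging.getLogger("ecbench")

CATEGORIES = ("consistent", "haplotype", "chromosome", "position", "unresolvable")

#: Locus = (contig, ref_start, ref_end, mapq)
Locus = tuple[str, int, int, int]


@dataclass
class HaplotypeMap:
    """Resolve a contig name to a (chromosome, haplotype) label pair.

    Assembly naming schemes vary, so the rule is user-configured: either a
    regex with two capture groups (chromosome, haplotype — named groups
    ``chrom``/``hap`` or the first two positional groups) or an explicit
    per-contig table.
    """

    pattern: re.Pattern | None = None
    table: Mapping[str, tuple[str, str]] | None = None

    @classmethod
    def from_regex(cls, pattern: str) -> "HaplotypeMap":
        pat = re.compile(pattern)
        if pat.groups < 2:
            raise ValueError("haplotype regex needs two capture groups (chromosome, haplotype)")
        return cls(pattern=pat)

    @classmethod
    def from_table(cls, table: Mapping[str, tuple[str, str]]) -> "HaplotypeMap":
        return cls(table=dict(table))

    def resolve(self, contig: str) -> tuple[str, str] | None:
        """(chromosome, haplotype) labels for a contig, or None if unresolvable."""
        if self.table is not None:
            return self.table.get(contig)
        m = self.pattern.match(contig)
        if not m:
            return None
        gd = m.groupdict()
        if "chrom" in gd and "hap" in gd:
            return (gd["chrom"], gd["hap"])
        return (m.group(1), m.group(2))


#: Preset for "<chrom>_<MAT|PAT>"-style dual assemblies (also hap1/hap2 naming).
MAT_PAT_PRESET = HaplotypeMap.from_regex(
    r"^(?P<chrom>.+?)[_#](?P<hap>MAT|PAT|mat|pat|hap1|hap2|1|2)$")


@dataclass
class MappingDiffRecord:
    read_id: str
    category: str  # one of CATEGORIES, or "filtered" below the MAPQ threshold
    raw_locus: Locus
    corr_locus: Locus

    @property
    def max_mapq(self) -> int:
        return max(self.raw_locus[3], self.corr_locus[3])


def _geometric_category(raw: Locus, corr: Locus, hmap: HaplotypeMap) -> str:
    rc, rs, re_, _ = raw
    cc, cs, ce, _ = corr
    if rc == cc:
        return "consistent" if (rs < ce and cs < re_) else "position"
    r_lab = hmap.resolve(rc)
    c_lab = hmap.resolve(cc)
    if r_lab is None or c_lab is None:
        return "unresolvable"
    if r_lab[0] == c_lab[0]:
        # same chromosome: opposite haplotype, or (odd naming) same labels
        return "haplotype" if r_lab[1] != c_lab[1] else "position"
    # different chromosome dominates even if the haplotype label changed too
    return "chromosome"


def classify(raw: ReadAlignment, corr: ReadAlignment, hmap: HaplotypeMap,
             mapq_min: int = 2) -> MappingDiffRecord:
    """Classify one raw/corrected alignment pair.

    A pair passes the filter when the raw *or* the corrected alignment has
    ``mapq >= mapq_min``; otherwise both mappings are too ambiguous and the
    category is reported as ``filtered``.
    """
    raw_locus: Locus = (raw.contig, raw.ref_start, raw.ref_end, raw.mapq)
    corr_locus: Locus = (corr.contig, corr.ref_start, corr.ref_end, corr.mapq)
    if max(raw.mapq, corr.mapq) < mapq_min:
        cat = "filtered"
    else:
        cat = _geometric_category(raw_locus, corr_locus, hmap)
        if cat == "unresolvable":
            log.warning("%s: contig %r or %r not resolvable by the haplotype map",
                        raw.read_id, raw.contig, corr.contig)
    return MappingDiffRecord(raw.read_id, cat, raw_locus, corr_locus)


def classify_pairs(pairs: Iterable[tuple[ReadAlignment, ReadAlignment]],
                   hmap: HaplotypeMap, mapq_min: int = 0) -> list[MappingDiffRecord]:
    """Classify every pair.  Use ``mapq_min=0`` to keep the geometric category
    for all pairs, so :func:`mapdiff_summary` can re-apply thresholds."""
    return [classify(r, c, hmap, mapq_min) for r, c in pairs]


def mapdiff_summary(records: Iterable[MappingDiffRecord],
                    mapq_thresholds: Sequence[int] = (2, 10)) -> pd.DataFrame:
    """Category counts and percentages at each MAPQ threshold.

    ``records`` should carry geometric categories (classified with
    ``mapq_min=0``); the threshold filter — at least one of the two
    alignments at or above the threshold — is applied here, per threshold.
    Percentages are over the passing pairs; the denominator is reported.
    """
    records = [r for r in records if r.category != "filtered"]
    rows = []
    for t in mapq_thresholds:
        passing = [r for r in records if r.max_mapq >= t]
        row: dict = {"mapq_min": t, "n_pairs": len(passing)}
        for cat in CATEGORIES:
            n = sum(1 for r in passing if r.category == cat)
            row[cat] = n
            row[f"{cat}_pct"] = 100.0 * n / len(passing) if passing else 0.0
        rows.append(row)
    if not records:
        log.warning("mapdiff summary over zero paired reads")
    return pd.DataFrame(rows)


def write_records_tsv(records: Iterable[MappingDiffRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcategory\traw_contig\traw_start\traw_end\traw_mapq"
                 "\tcorr_contig\tcorr_start\tcorr_end\tcorr_mapq\n")
        for r in records:
            fh.write("\t".join(str(x) for x in
                               (r.read_id, r.category, *r.raw_locus, *r.corr_locus)) + "\n")
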