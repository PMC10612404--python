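"""Homopolymer compression (HPC).

HPC collapses each maximal run of identical bases to a single base.  Some
error-correction tools emit only HPC reads, so to compare like with like the
truth assembly and the raw reads must be compressed the same way and the
whole evaluation run in HPC space.  :class:`HpcResult` keeps the coordinate
map (original start of each run) so positions can be related back to the
uncompressed sequence.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

log = logging.getLogger("ecbench")

_ALLOWED = frozenset("ACGTN")


@dataclass
class HpcResult:
    compressed: str
    run_starts: list[int]  # original 0-based start of each compressed position's run

    def expand(self, original_length: int) -> str:
        """Reconstruct the original sequence (up to case) from the run map."""
        bounds = self.run_starts + [original_length]
        return "".join(
            base * (bounds[i + 1] - bounds[i]) for i, base in enumerate(self.compressed)
        )


def compress(seq: str) -> HpcResult:
    """Homopolymer-compress ``seq`` (case-insensitive, uppercase output).

    N runs compress like any base.  Raises ``ValueError`` naming the position
    of the first non-nucleotide character.
    """
    up = seq.upper()
    out: list[str] = []
    starts: list[int] = []
    prev = ""
    for i, c in enumerate(up):
        if c not in _ALLOWED:
            raise ValueError(f"non-nucleotide character {c!r} at position {i}")
        if c != prev:
            out.append(c)
            starts.append(i)
            prev = c
    return HpcResult("".join(out), starts)


def compress_file(in_path, out_path) -> int:
    """Compress every record of a FASTA/FASTQ file (optionally gzipped) into
    a FASTA file; returns the record count.

    Output is always FASTA: per-base qualities are undefined after merging a
    run, so FASTQ qualities are dropped.  Headers are preserved verbatim.
    """
    from Bio import SeqIO

    in_path = str(in_path)
    opener = gzip.open if in_path.endswith(".gz") else open
    n = 0
    with opener(in_path, "rt") as fh, open(out_path, "w") as out:
        fmt = _sniff_format(fh)
        if fmt is None:
            return 0  # empty input -> empty output
        for rec in SeqIO.parse(fh, fmt):
            hpc = compress(str(rec.seq))
            header = rec.description or rec.id
            out.write(f">{header}\n{hpc.compressed}\n")
            n += 1
    return n


def _sniff_format(fh) -> str | None:
    """Peek at the first byte to distinguish FASTA from FASTQ."""
    pos = fh.tell()
    first = fh.read(1)
    fh.seek(pos)
    if first == "":
        log.warning("empty sequence file")
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"unrecognised sequence file (first character {first!r})")
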