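"""Independent oracles for the test suite.

Everything here is deliberately written from first principles, without
reusing the package's parsing or normalization code paths, so that
agreement between the two routes is meaningful:

* a Needleman–Wunsch global aligner (match 0, mismatch 1, gap 2 per base)
  with a deterministic traceback, producing reference-anchored edit events;
* brute-force enumeration oracles for leftmost-equivalent indel placement;
* a self-contained fixture generator that plants edits at unambiguous sites
  (pairwise-distinct 3-base neighbourhood, >=5 bp apart) and builds the
  mutated read and its cs string with local code only.
"""

from __future__ import annotations

import numpy as np

MATCH, MISMATCH, GAP = 0, 1, 2


def nw_events(ref: str, read: str, contig: str = "c", ref_start: int = 0):
    """Global alignment of ``read`` against ``ref``; returns edit events as
    (kind, pos, ref_seq, alt_seq) tuples in reference order.

    Rows are the reference; the linear-gap row recurrence is evaluated with
    a prefix-minimum scan so the DP stays fast at a few hundred bp.
    """
    n, m = len(ref), len(read)
    read_arr = np.frombuffer(read.encode(), dtype="S1")
    scores = np.empty((n + 1, m + 1), dtype=np.int32)
    scores[0] = np.arange(m + 1) * GAP
    jj = np.arange(m + 1, dtype=np.int64) * GAP
    for i in range(1, n + 1):
        prev = scores[i - 1]
        sub = np.where(read_arr == ref[i - 1].encode(), MATCH, MISMATCH)
        base = np.empty(m + 1, dtype=np.int64)
        base[0] = prev[0] + GAP
        np.minimum(prev[:-1] + sub, prev[1:] + GAP, out=base[1:])
        # row[j] = min_{k<=j} base[k] + GAP*(j-k): prefix-min over shifted costs
        scores[i] = np.minimum.accumulate(base - jj) + jj

    # deterministic traceback: diagonal > up (deletion) > left (insertion)
    ops = []  # ('M'|'X'|'D'|'I', ref_index, read_index)
    i, j = n, m
    while i > 0 or j > 0:
        s = scores[i, j]
        if i > 0 and j > 0 and s == scores[i - 1, j - 1] + (
                MATCH if ref[i - 1] == read[j - 1] else MISMATCH):
            ops.append(("M" if ref[i - 1] == read[j - 1] else "X", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and s == scores[i - 1, j] + GAP:
            ops.append(("D", i - 1, j))
            i -= 1
        else:
            assert j > 0 and s == scores[i, j - 1] + GAP
            ops.append(("I", i, j - 1))
            j -= 1
    ops.reverse()

    events = []
    k = 0
    while k < len(ops):
        op, ri, qi = ops[k]
        if op == "M":
            k += 1
        elif op == "X":
            events.append(("SUB", ref_start + ri, ref[ri], read[qi]))
            k += 1
        elif op == "D":
            run = [ri]
            k += 1
            while k < len(ops) and ops[k][0] == "D":
                run.append(ops[k][1])
                k += 1
            events.append(("DEL", ref_start + run[0],
                           ref[run[0]:run[-1] + 1], ""))
        else:  # I: anchored after the previous reference base
            q0 = qi
            k += 1
            while k < len(ops) and ops[k][0] == "I":
                k += 1
            q1 = ops[k - 1][2]
            events.append(("INS", ref_start + ri - 1, "", read[q0:q1 + 1]))
    return events


def nw_score(ref: str, read: str) -> int:
    """Alignment cost only (for cross-checks)."""
    n, m = len(ref), len(read)
    read_arr = np.frombuffer(read.encode(), dtype="S1")
    prev = np.arange(m + 1, dtype=np.int64) * GAP
    jj = np.arange(m + 1, dtype=np.int64) * GAP
    for i in range(1, n + 1):
        sub = np.where(read_arr == ref[i - 1].encode(), MATCH, MISMATCH)
        base = np.empty(m + 1, dtype=np.int64)
        base[0] = prev[0] + GAP
        np.minimum(prev[:-1] + sub, prev[1:] + GAP, out=base[1:])
        prev = np.minimum.accumulate(base - jj) + jj
    return int(prev[m])


# ---------------------------------------------------------------------------
# brute-force leftmost-equivalent indel placement


def leftmost_deletion(seq: str, pos: int, length: int) -> tuple[int, str]:
    """Smallest p such that deleting seq[p:p+length] leaves the same string
    as deleting seq[pos:pos+length]."""
    target = seq[:pos] + seq[pos + length:]
    for p in range(pos + 1):
        if seq[:p] + seq[p + length:] == target:
            return p, seq[p:p + length]
    raise AssertionError("unreachable")


def leftmost_insertion(seq: str, pos: int, alt: str) -> tuple[int, str]:
    """Smallest anchor p (>= -1) such that inserting some string of the same
    length after p reproduces the insertion of ``alt`` after ``pos``."""
    target = seq[:pos + 1] + alt + seq[pos + 1:]
    for p in range(-1, pos + 1):
        cand = target[p + 1:p + 1 + len(alt)]
        if seq[:p + 1] + cand + seq[p + 1:] == target:
            return p, cand
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# self-contained fixture generation


def random_ref(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def plant_edits(rng: np.random.Generator, ref: str, n_edits: int,
                min_gap: int = 5):
    """Plant up to ``n_edits`` edits at unambiguous sites of ``ref``.

    Returns (read, cs_string, events); events as (kind, pos, ref_seq, alt_seq)
    tuples, positions 0-based on ``ref``.
    """
    n = len(ref)
    candidates = [p for p in range(min_gap + 1, n - min_gap - 1)
                  if len({ref[p - 1], ref[p], ref[p + 1]}) == 3]
    rng.shuffle(candidates)
    chosen: list[int] = []
    for p in candidates:
        if len(chosen) >= n_edits:
            break
        if all(abs(p - q) >= min_gap for q in chosen):
            chosen.append(p)
    chosen.sort()

    events = []
    for p in chosen:
        kind = ["SUB", "INS", "DEL"][rng.integers(0, 3)]
        if kind == "SUB":
            alt = rng.choice([b for b in "ACGT" if b != ref[p]])
            events.append(("SUB", p, ref[p], str(alt)))
        elif kind == "INS":
            alt = rng.choice([b for b in "ACGT" if b not in (ref[p], ref[p + 1])])
            events.append(("INS", p, "", str(alt)))
        else:
            events.append(("DEL", p, ref[p], ""))

    # build the read and the cs string directly from the event list
    read_parts: list[str] = []
    cs_parts: list[str] = []
    cur = 0
    for kind, p, ref_seq, alt in events:
        if kind == "INS":
            gap = p + 1 - cur
            read_parts.append(ref[cur:p + 1])
            cs_parts.append(f":{gap}")
            read_parts.append(alt)
            cs_parts.append("+" + alt.lower())
            cur = p + 1
        else:
            if p - cur > 0:
                cs_parts.append(f":{p - cur}")
            read_parts.append(ref[cur:p])
            if kind == "SUB":
                read_parts.append(alt)
                cs_parts.append(f"*{ref_seq.lower()}{alt.lower()}")
                cur = p + 1
            else:
                cs_parts.append("-" + ref_seq.lower())
                cur = p + len(ref_seq)
    if n - cur > 0:
        cs_parts.append(f":{n - cur}")
    read_parts.append(ref[cur:])
    return "".join(read_parts), "".join(cs_parts), events
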