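"""cs-tag extraction, PAF/SAM parsing and indel left-alignment."""

import gzip

import numpy as np
import pytest

import oracles
from ecbench import (
    AlignmentParseError,
    EditEvent,
    EditKind,
    ParseStats,
    extract_edits,
    normalize_indels,
    parse_alignments,
    reconstruct_read,
)


def ev(contig, pos, kind, ref="", alt=""):
    return EditEvent(contig, pos, EditKind[kind], ref, alt)


class TestExtractEdits:
    @pytest.mark.parametrize(
        "cs,start,expected",
        [
            # hand-traced cursor arithmetic: 5 matches, sub, 3 matches, ins,
            # 2 matches, 2bp del, 4 matches
            (":5*ac:3+g:2-tt:4", 100,
             [ev("c1", 105, "SUB", "A", "C"),
              ev("c1", 108, "INS", alt="G"),
              ev("c1", 111, "DEL", ref="TT")]),
            (":150", 0, []),
            # adjacent substitutions stay separate events
            ("*at*cg", 10,
             [ev("c1", 10, "SUB", "A", "T"), ev("c1", 11, "SUB", "C", "G")]),
        ],
    )
    def test_examples(self, cs, start, expected):
        assert extract_edits(cs, "c1", start) == expected

    @pytest.mark.parametrize("bad", ["::5", ":5*a", "=ACGT", ":5~gt10ac", "*xy", "+", ":"])
    def test_malformed_cs_is_hard_error(self, bad):
        with pytest.raises(AlignmentParseError):
            extract_edits(bad, "c1", 0)

    def test_reference_cursor_ignores_insertions(self):
        # insertions consume no reference: following events keep their coords
        evs = extract_edits(":10+acgt:5*ga", "c1", 0)
        assert evs[0] == ev("c1", 9, "INS", alt="ACGT")
        assert evs[1] == ev("c1", 15, "SUB", "G", "A")

    def test_roundtrip_reconstruction(self, rng):
        """Replaying parsed edits onto the reference window reproduces the
        mutated read, on randomly planted unambiguous fixtures."""
        for _ in range(25):
            ref = oracles.random_ref(rng, int(rng.integers(80, 300)))
            read, cs, _ = oracles.plant_edits(rng, ref, int(rng.integers(0, 8)))
            edits = extract_edits(cs, "c1", 0)
            assert reconstruct_read(ref, 0, len(ref), edits) == read


class TestNormalizeIndels:
    def test_deletion_left_aligned_in_homopolymer(self):
        ref = {"c1": "C" * 10 + "AAAA" + "G" * 6}  # A-run spans [10, 14)
        out = normalize_indels([ev("c1", 12, "DEL", ref="A")], ref)
        assert out == [ev("c1", 10, "DEL", ref="A")]

    def test_substitution_unchanged(self):
        ref = {"c1": "A" * 20}
        sub = ev("c1", 7, "SUB", "A", "G")
        assert normalize_indels([sub], ref) == [sub]

    def test_insertion_left_shifted_through_dinucleotide_repeat(self):
        # expected anchor computed with the brute-force enumeration oracle
        ref_seq = "C" * 14 + "ATATAT" + "G" * 5
        want_pos, want_alt = oracles.leftmost_insertion(ref_seq, 19, "AT")
        assert (want_pos, want_alt) == (13, "AT")
        out = normalize_indels([ev("c1", 19, "INS", alt="AT")], {"c1": ref_seq})
        assert out == [ev("c1", want_pos, "INS", alt=want_alt)]

    def test_matches_enumeration_oracle_on_random_indels(self, rng):
        for _ in range(50):
            seq = oracles.random_ref(rng, 60)
            if rng.random() < 0.5:
                k = int(rng.integers(1, 4))
                pos = int(rng.integers(1, 60 - k))
                raw = ev("c1", pos, "DEL", ref=seq[pos:pos + k])
                want = oracles.leftmost_deletion(seq, pos, k)
                got = normalize_indels([raw], {"c1": seq})[0]
                assert (got.pos, got.ref_seq) == want
            else:
                alt = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                pos = int(rng.integers(0, 59))
                raw = ev("c1", pos, "INS", alt=alt)
                want = oracles.leftmost_insertion(seq, pos, alt)
                got = normalize_indels([raw], {"c1": seq})[0]
                assert (got.pos, got.alt_seq) == want

    def test_normalization_preserves_reconstruction(self, rng):
        for _ in range(25):
            ref = oracles.random_ref(rng, int(rng.integers(60, 200)))
            read, cs, _ = oracles.plant_edits(rng, ref, 5)
            edits = extract_edits(cs, "c1", 0)
            shifted = normalize_indels(edits, {"c1": ref})
            assert reconstruct_read(ref, 0, len(ref), shifted) == read

    def test_out_of_contig_position_is_hard_error(self):
        with pytest.raises(AlignmentParseError):
            normalize_indels([ev("c1", 50, "DEL", ref="A")], {"c1": "ACGT"})


PAF_TPL = ("{name}\t{qlen}\t0\t{qlen}\t+\tc1\t1000\t{ts}\t{te}\t{qlen}\t{qlen}"
           "\t{mapq}{tags}\n")


def paf_line(name, ts=0, te=100, mapq=60, cs=":100", tp="P"):
    tags = ""
    if tp:
        tags += f"\ttp:A:{tp}"
    if cs:
        tags += f"\tcs:Z:{cs}"
    return PAF_TPL.format(name=name, qlen=te - ts, ts=ts, te=te, mapq=mapq, tags=tags)


class TestParsePaf:
    def test_perfect_match_has_no_edits(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(paf_line("r1"))
        (aln,) = parse_alignments(p)
        assert aln.read_id == "r1" and aln.edits == [] and aln.mapq == 60
        assert (aln.ref_start, aln.ref_end) == (0, 100)

    def test_primary_selected_by_tp_tag(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(paf_line("r1", ts=500, te=600, tp="S")
                     + paf_line("r1", ts=0, te=100, tp="P"))
        stats = ParseStats()
        (aln,) = parse_alignments(p, stats=stats)
        assert aln.ref_start == 0
        assert stats.n_secondary == 1 and stats.n_primary == 1

    def test_first_record_fallback_without_tp_tags(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(paf_line("r1", ts=0, te=100, tp=None)
                     + paf_line("r1", ts=500, te=600, tp=None))
        (aln,) = parse_alignments(p)
        assert aln.ref_start == 0

    def test_missing_cs_names_line_number(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text(paf_line("r1") + paf_line("r2", cs=None))
        with pytest.raises(AlignmentParseError, match="line 2"):
            list(parse_alignments(p))

    def test_truncated_line_is_hard_error(self, tmp_path):
        p = tmp_path / "a.paf"
        p.write_text("r1\t100\t0\t100\n")
        with pytest.raises(AlignmentParseError, match="line 1"):
            list(parse_alignments(p))

    def test_gzip_input(self, tmp_path):
        p = tmp_path / "a.paf.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(paf_line("r1", cs=":40*ga:59"))
        (aln,) = parse_alignments(p)
        assert len(aln.edits) == 1 and aln.edits[0].pos == 40

    def test_empty_file_yields_empty_stream(self, tmp_path, caplog):
        p = tmp_path / "a.paf"
        p.write_text("")
        with caplog.at_level("WARNING", logger="ecbench"):
            assert list(parse_alignments(p)) == []
        assert "empty" in caplog.text


SAM_HEADER = "@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:c1\tLN:50\n"
# reference c1[0:50]
REF = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTAC"


def sam_record(name, flag, pos1, cigar, seq, md=None, cs=None, mapq=60):
    tags = []
    if md:
        tags.append(f"MD:Z:{md}")
    if cs:
        tags.append(f"cs:Z:{cs}")
    fields = [name, str(flag), "c1", str(pos1), str(mapq), cigar, "*", "0", "0",
              seq, "*"] + tags
    return "\t".join(fields) + "\n"


class TestParseSam:
    def test_cs_tag_preferred(self, tmp_path):
        p = tmp_path / "a.sam"
        # 10bp read at ref pos 5, one substitution at ref pos 8
        seq = REF[5:8] + "G" + REF[9:15]
        p.write_text(SAM_HEADER + sam_record("r1", 0, 6, "10M", seq, cs=":3*ag:6"))
        (aln,) = parse_alignments(p)
        assert aln.edits == [ev("c1", 8, "SUB", "A", "G")]

    def test_cigar_md_derivation(self, tmp_path):
        # 4M at ref 0, 1bp deletion of REF[4], 3M, then 2bp insertion
        seq = REF[0:4] + REF[5:8] + "TT" + REF[8:12]
        cigar = "4M1D3M2I4M"
        md = "4^A7"
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER + sam_record("r1", 0, 1, cigar, seq, md=md))
        (aln,) = parse_alignments(p)
        assert ev("c1", 4, "DEL", ref="A") in aln.edits
        assert ev("c1", 7, "INS", alt="TT") in aln.edits
        assert len(aln.edits) == 2

    def test_md_substitutions_recovered(self, tmp_path):
        seq = "G" + REF[1:10]
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER + sam_record("r1", 0, 1, "10M", seq, md="0A9"))
        (aln,) = parse_alignments(p)
        assert aln.edits == [ev("c1", 0, "SUB", "A", "G")]

    def test_secondary_flag_skipped_and_counted(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER
                     + sam_record("r1", 0, 1, "10M", REF[0:10], md="10")
                     + sam_record("r1", 256, 21, "10M", REF[20:30], md="10"))
        stats = ParseStats()
        alns = list(parse_alignments(p, stats=stats))
        assert len(alns) == 1 and alns[0].ref_start == 0
        assert stats.n_secondary == 1

    def test_no_cs_no_md_is_hard_error(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(SAM_HEADER + sam_record("r1", 0, 1, "10M", REF[0:10]))
        with pytest.raises(AlignmentParseError, match="r1"):
            list(parse_alignments(p))

    def test_sam_and_paf_agree_on_the_same_alignment(self, tmp_path, rng):
        """Format parity: identical edits from a cs-tagged PAF record and the
        CIGAR+MD SAM encoding of the same alignment."""
        ref = oracles.random_ref(rng, 40)
        seq = ref[:10] + "A" if ref[10] != "A" else ref[:10] + "C"
        alt = seq[10]
        seq = seq + ref[11:40]
        cs = f":10*{ref[10].lower()}{alt.lower()}:29"
        paf = tmp_path / "a.paf"
        paf.write_text(f"r1\t40\t0\t40\t+\tc1\t40\t0\t40\t39\t40\t60\ttp:A:P\tcs:Z:{cs}\n")
        sam = tmp_path / "a.sam"
        sam.write_text("@HD\tVN:1.6\n@SQ\tSN:c1\tLN:40\n"
                       + "\t".join(["r1", "0", "c1", "1", "60", "40M", "*", "0", "0",
                                    seq, "*", f"MD:Z:10{ref[10]}29"]) + "\n")
        (a,) = parse_alignments(paf)
        (b,) = parse_alignments(sam)
        assert a.edits == b.edits
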