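"""Transcript validation and C-terminal codon window geometry."""
import random

import pytest

from pts1scan.errors import (
    TranscriptValidationError,
    UnknownChromosomeError,
    UnsupportedTranscriptError,
)
from pts1scan.transcripts import (
    TranscriptRecord,
    cterminal_codon_intervals,
    load_transcripts,
    read_transcript_tsv,
    window_tripeptide,
    write_transcript_tsv,
    write_windows_bed,
)

from conftest import make_genome, random_transcript

# Hand-built single-exon transcript on the plus strand:
# CDS [100,124) = 24 nt = 7 aa + stop.  Protein: MVS SKL L? -> build
# explicitly: ATG GTT TCC AAG CTT GAA TCC TAA  -> M V S K L E S *
_CDS_PLUS = "ATGGTTTCCAAGCTTGAATCCTAA"
_PROT_PLUS = "MVSKLES"


def _plus_transcript():
    genome = make_genome({"1": "N" * 0 + "A" * 100 + _CDS_PLUS + "A" * 100})
    t = TranscriptRecord("T1", "G1", "1", "+", ((100, 124),), _PROT_PLUS)
    return t, genome


def _minus_transcript():
    # same protein on the minus strand: genomic = revcomp(CDS)
    rc = _CDS_PLUS.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    genome = make_genome({"1": "A" * 100 + rc + "A" * 100})
    t = TranscriptRecord("T2", "G2", "1", "-", ((100, 124),), _PROT_PLUS)
    return t, genome


class TestLoadTranscripts:
    def test_withdrawn_records_are_excluded(self):
        t, genome = _plus_transcript()
        withdrawn = TranscriptRecord("TW", "GW", "1", "+", ((100, 124),), _PROT_PLUS, "Withdrawn")
        other = TranscriptRecord("T3", "G3", "1", "+", ((100, 124),), _PROT_PLUS)
        result = load_transcripts([t, withdrawn, other], genome)
        assert [r.transcript_id for r in result.records] == ["T1", "T3"]
        assert result.n_withdrawn == 1

    def test_empty_input_gives_empty_set(self):
        result = load_transcripts([], {"1": "ACGT"})
        assert result.records == [] and result.rejected == []

    def test_protein_cds_disagreement_is_reported_not_kept(self):
        """Oracle: the spliced CDS translates to MVSKLES, so a record
        claiming a different protein must be rejected by name."""
        t, genome = _plus_transcript()
        bad = TranscriptRecord("TBAD", "GB", "1", "+", ((100, 124),), "MVSKLEL")
        result = load_transcripts([t, bad], genome)
        assert [r.transcript_id for r in result.records] == ["T1"]
        assert len(result.rejected) == 1
        assert result.rejected[0][0] == "TBAD"

    def test_unknown_chromosome_is_hard_error_naming_transcript(self):
        t = TranscriptRecord("TX9", "G", "99", "+", ((100, 124),), _PROT_PLUS)
        with pytest.raises(UnknownChromosomeError, match="TX9"):
            load_transcripts([t], {"1": "A" * 300})

    def test_cds_length_not_multiple_of_three_rejected(self):
        t, genome = _plus_transcript()
        bad = TranscriptRecord("TLEN", "G", "1", "+", ((100, 123),), _PROT_PLUS)
        result = load_transcripts([t, bad], genome)
        assert ("TLEN" in dict(result.rejected)) and "divisible by 3" in dict(result.rejected)["TLEN"]

    def test_missing_terminal_stop_rejected_with_distinct_reason(self):
        genome = make_genome({"1": "A" * 100 + "ATGGTTTCCAAGCTTGAATCCGGG" + "A" * 100})
        t = TranscriptRecord("TNOSTOP", "G", "1", "+", ((100, 124),), _PROT_PLUS)
        result = load_transcripts([t], genome)
        assert "stop codon" in dict(result.rejected)["TNOSTOP"]

    def test_short_protein_excluded_and_logged(self):
        genome = make_genome({"1": "A" * 100 + "ATGGTTTAA" + "A" * 100})
        t = TranscriptRecord("TSHORT", "G", "1", "+", ((100, 109),), "MV")
        result = load_transcripts([t], genome)
        assert dict(result.rejected)["TSHORT"] == "protein-too-short"


class TestCterminalWindow:
    def test_plus_strand_single_exon_interval(self):
        t, genome = _plus_transcript()
        w = cterminal_codon_intervals(t, genome)
        assert w.intervals == ((112, 121),)
        assert w.tripeptide == "LES"

    def test_minus_strand_single_exon_interval(self):
        """Oracle: reverse-complement splice puts spliced positions
        12..20 at genomic 103..111 when the CDS spans [100,124)."""
        t, genome = _minus_transcript()
        w = cterminal_codon_intervals(t, genome)
        assert w.intervals == ((103, 112),)

    def test_exon_boundary_inside_window_splits_intervals(self):
        """Two-exon plus-strand transcript with the boundary 4 nt
        before the stop codon: the 9-nt window straddles the intron."""
        # split _CDS_PLUS at spliced position 20 (4 nt before pos 24)
        part1, part2 = _CDS_PLUS[:20], _CDS_PLUS[20:]
        genome = make_genome({"1": "A" * 100 + part1 + "G" * 50 + part2 + "A" * 100})
        t = TranscriptRecord(
            "T2E", "G", "1", "+", ((100, 120), (170, 174)), _PROT_PLUS
        )
        w = cterminal_codon_intervals(t, genome)
        assert len(w.intervals) == 2
        assert sum(e - s for s, e in w.intervals) == 9
        # brute force over the spliced coordinate map
        positions = [p for s, e in t.cds_segments for p in range(s, e)]
        assert sorted(w.codon_map) == positions[12:21]

    def test_window_never_covers_stop_codon(self):
        t, genome = _plus_transcript()
        w = cterminal_codon_intervals(t, genome)
        stop_positions = set(range(121, 124))
        assert not stop_positions & set(w.codon_map)

    def test_protein_shorter_than_three_is_unsupported(self):
        genome = make_genome({"1": "A" * 100 + "ATGGTTTAA" + "A" * 100})
        t = TranscriptRecord("TS", "G", "1", "+", ((100, 109),), "MV")
        with pytest.raises(UnsupportedTranscriptError):
            cterminal_codon_intervals(t, genome)


class TestWindowTripeptide:
    def test_plus_strand_skl(self):
        # window bases TCC AAG CTT -> S K L
        genome = make_genome({"1": "A" * 100 + "ATGTCCAAGCTTTAA" + "A" * 100})
        t = TranscriptRecord("T", "G", "1", "+", ((100, 115),), "MSKL")
        w = cterminal_codon_intervals(t, genome)
        assert window_tripeptide(w, genome) == "SKL"

    def test_minus_strand_skl(self):
        # genomic AAGCTTGGA on minus strand reads TCCAAGCTT -> SKL
        rc = "ATGTCCAAGCTTTAA".translate(str.maketrans("ACGT", "TGCA"))[::-1]
        genome = make_genome({"1": "A" * 100 + rc + "A" * 100})
        t = TranscriptRecord("T", "G", "1", "-", ((100, 115),), "MSKL")
        w = cterminal_codon_intervals(t, genome)
        assert genome["1"][103:112] == "AAGCTTGGA"
        assert window_tripeptide(w, genome) == "SKL"

    def test_translation_mismatch_is_consistency_error(self):
        genome = make_genome({"1": "A" * 100 + "ATGTCCAAGCTTTAA" + "A" * 100})
        t = TranscriptRecord("T", "G", "1", "+", ((100, 115),), "MSKL")
        w = cterminal_codon_intervals(t, genome)
        corrupted = dict(genome)
        corrupted["1"] = corrupted["1"][:104] + "G" + corrupted["1"][105:]
        with pytest.raises(TranscriptValidationError):
            window_tripeptide(w, corrupted)


def test_window_translation_identity_over_random_transcripts():
    """For hundreds of random transcripts on both strands and 1-4
    exons, the translated window equals the protein's last three
    residues, the interval lengths sum to 9, and extraction is
    deterministic."""
    rng = random.Random(20240917)
    for i in range(250):
        for strand in "+-":
            t, genome = random_transcript(rng, strand, tid=f"T{i}{strand}")
            w1 = cterminal_codon_intervals(t, genome)
            w2 = cterminal_codon_intervals(t, genome)
            assert w1 == w2 and w1.codon_map == w2.codon_map
            assert sum(e - s for s, e in w1.intervals) == 9
            assert window_tripeptide(w1, genome) == t.protein_seq[-3:]


def test_tsv_round_trip_and_bed_output(tmp_path):
    t, genome = _plus_transcript()
    path = tmp_path / "tx.tsv"
    write_transcript_tsv([t], path)
    back = read_transcript_tsv(path)
    assert back == [t]

    w = cterminal_codon_intervals(t, genome)
    bed = tmp_path / "w.bed"
    write_windows_bed([w], bed)
    rows = [line.split("\t") for line in bed.read_text().splitlines()]
    assert [(r[0], int(r[1]), int(r[2]), r[4]) for r in rows] == [
        ("1", 112, 115, "1"), ("1", 115, 118, "2"), ("1", 118, 121, "3"),
    ]
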