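"""Transcript models, validation, and C-terminal codon window extraction.

A transcript is a protein-coding record with ordered CDS segments on a
genome (0-based, half-open, ascending genomic order) plus its protein
sequence.  The CDS is expected to *include* the stop codon, so the
spliced CDS length is ``3 * (len(protein) + 1)``; this assumption is
self-checking because every loaded record is spliced and translated
against its stored protein.

The quantity of interest is the genomic footprint of the last three
amino-acid codons preceding the stop codon — the positions where a
single-nucleotide variant can rewrite the C-terminal tripeptide that
acts (or could act) as a type-1 peroxisomal targeting signal.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

from Bio import SeqIO

from .errors import (
    SequenceError,
    TranscriptValidationError,
    UnknownChromosomeError,
    UnsupportedTranscriptError,
)
from .genome import Genome, fetch, normalize_chrom, reverse_complement, translate_cds

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class TranscriptRecord:
    """One protein-coding transcript with CDS geometry and protein sequence."""

    transcript_id: str
    gene: str
    chromosome: str
    strand: str  # "+" or "-"
    cds_segments: Tuple[Interval, ...]  # ascending genomic order, half-open
    protein_seq: str
    status: str = "Public"  # "Public" or "Withdrawn"

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        object.__setattr__(self, "cds_segments", tuple(tuple(s) for s in self.cds_segments))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


@dataclass(frozen=True)
class CterminalWindow:
    """Genomic footprint of the last three codons before the stop codon.

    ``codon_map`` maps every genomic position of the 9-nt window to
    ``(codon_index, offset, coding_base)`` where ``codon_index`` is the
    1-based position of the residue within the C-terminal tripeptide
    (1 = third-from-last residue, 3 = last residue) and ``offset`` is
    the 0-based position of the base within its codon, both counted in
    coding orientation.
    """

    transcript_id: str
    gene: str
    chromosome: str
    strand: str
    intervals: Tuple[Interval, ...]  # ascending genomic order, half-open
    codon_map: Dict[int, Tuple[int, int, str]] = field(compare=False)
    tripeptide: str = ""

    def __contains__(self, genomic_position: int) -> bool:
        return genomic_position in self.codon_map


@dataclass
class LoadResult:
    """Outcome of a batch load: validated records plus a rejection report."""

    records: List[TranscriptRecord]
    rejected: List[Tuple[str, str]]  # (transcript_id, reason)
    n_withdrawn: int = 0


def coding_order_positions(t: TranscriptRecord) -> List[int]:
    """Genomic positions of the spliced CDS in coding (5'→3') order."""
    if t.strand == "+":
        return [p for s, e in t.cds_segments for p in range(s, e)]
    return [p for s, e in reversed(t.cds_segments) for p in range(e - 1, s - 1, -1)]


def spliced_cds(t: TranscriptRecord, genome: Genome) -> str:
    """The spliced, strand-oriented coding sequence including the stop codon."""
    chrom = normalize_chrom(t.chromosome)
    if chrom not in genome:
        raise UnknownChromosomeError(t.transcript_id, t.chromosome)
    parts = [fetch(genome, chrom, s, e) for s, e in t.cds_segments]
    seq = "".join(parts)
    return seq if t.strand == "+" else reverse_complement(seq)


def validate_transcript(t: TranscriptRecord, genome: Genome) -> None:
    """Check every structural invariant; raise on the first violation.

    Raises
    ------
    UnknownChromosomeError
        Chromosome absent from the genome (hard error, not a rejection).
    TranscriptValidationError
        Geometry or translation inconsistency.
    """
    if not t.cds_segments:
        raise TranscriptValidationError(t.transcript_id, "no CDS segments")
    if t.strand not in ("+", "-"):
        raise TranscriptValidationError(t.transcript_id, f"bad strand {t.strand!r}")
    prev_end = None
    for s, e in t.cds_segments:
        if e <= s:
            raise TranscriptValidationError(t.transcript_id, f"empty/inverted segment [{s},{e})")
        if prev_end is not None and s < prev_end:
            raise TranscriptValidationError(
                t.transcript_id, "segments overlap or are not ascending"
            )
        prev_end = e
    if t.cds_length % 3 != 0:
        raise TranscriptValidationError(
            t.transcript_id, f"CDS length {t.cds_length} not divisible by 3"
        )
    if t.cds_length != 3 * (len(t.protein_seq) + 1):
        raise TranscriptValidationError(
            t.transcript_id,
            f"CDS length {t.cds_length} != 3*(protein {len(t.protein_seq)} aa + stop)",
        )
    cds = spliced_cds(t, genome)
    if cds[-3:] not in STOP_CODONS:
        raise TranscriptValidationError(
            t.transcript_id, f"CDS does not end in a stop codon (found {cds[-3:]})"
        )
    translated = translate_cds(cds)
    if translated != t.protein_seq + "*":
        raise TranscriptValidationError(
            t.transcript_id,
            "translated CDS disagrees with stored protein sequence",
        )


def load_transcripts(
    records_source: Union[str, Path, Iterable[TranscriptRecord]],
    genome: Genome,
) -> LoadResult:
    """Load, filter, and validate transcript records against the genome.

    Withdrawn records are excluded up front.  Records failing a
    structural or translation check, and proteins shorter than three
    residues, are reported in ``LoadResult.rejected`` rather than kept
    or silently dropped.  An unknown chromosome aborts the whole load.
    """
    if isinstance(records_source, (str, Path)):
        raw = read_transcript_tsv(records_source)
    else:
        raw = list(records_source)

    result = LoadResult(records=[], rejected=[])
    for t in raw:
        if t.status == "Withdrawn":
            result.n_withdrawn += 1
            continue
        if len(t.protein_seq) < 3:
            logger.info("excluding %s: protein shorter than 3 residues", t.transcript_id)
            result.rejected.append((t.transcript_id, "protein-too-short"))
            continue
        try:
            validate_transcript(t, genome)
        except TranscriptValidationError as exc:
            logger.warning("rejecting %s: %s", t.transcript_id, exc)
            result.rejected.append((t.transcript_id, str(exc)))
            continue
        result.records.append(t)
    return result


def cterminal_codon_intervals(t: TranscriptRecord, genome: Genome) -> CterminalWindow:
    """Genomic intervals of the last three amino-acid codons of ``t``.

    The window covers spliced-CDS positions ``[3*(P-3), 3*P)`` with
    ``P = len(protein_seq)`` — i.e. exactly the 9 nucleotides encoding
    the C-terminal tripeptide, never the stop codon.  Intervals are
    split wherever an exon boundary falls inside the window.
    """
    P = len(t.protein_seq)
    if P < 3:
        raise UnsupportedTranscriptError(
            f"{t.transcript_id}: protein has {P} residues; need at least 3"
        )
    positions = coding_order_positions(t)
    cds = spliced_cds(t, genome)
    lo, hi = 3 * (P - 3), 3 * P
    codon_map: Dict[int, Tuple[int, int, str]] = {}
    for i in range(lo, hi):
        codon_index = (i - lo) // 3 + 1
        offset = (i - lo) % 3
        codon_map[positions[i]] = (codon_index, offset, cds[i])
    intervals = _merge_positions(sorted(codon_map))
    return CterminalWindow(
        transcript_id=t.transcript_id,
        gene=t.gene,
        chromosome=t.chromosome,
        strand=t.strand,
        intervals=tuple(intervals),
        codon_map=codon_map,
        tripeptide=t.protein_seq[-3:],
    )


def window_tripeptide(w: CterminalWindow, genome: Genome) -> str:
    """Translate the window straight off the genome; consistency check.

    The result must equal the owning transcript's stored C-terminal
    tripeptide; a disagreement means the window geometry or the genome
    is wrong and raises ``TranscriptValidationError``.
    """
    bases = []
    for pos in sorted(w.codon_map):
        codon_index, offset, _ = w.codon_map[pos]
        base = fetch(genome, w.chromosome, pos, pos + 1)
        if base not in "ACGT":
            raise SequenceError(
                f"{w.transcript_id}: ambiguous base {base!r} at {w.chromosome}:{pos}"
            )
        bases.append((codon_index, offset, base))
    # order bases in coding orientation
    if w.strand == "+":
        coding = "".join(b for _, _, b in sorted(bases, key=lambda x: (x[0], x[1])))
    else:
        coding = reverse_complement(
            "".join(b for _, _, b in sorted(bases, key=lambda x: (-x[0], -x[1])))
        )
    tri = translate_cds(coding)
    if w.tripeptide and tri != w.tripeptide:
        raise TranscriptValidationError(
            w.transcript_id,
            f"window translates to {tri!r} but protein ends in {w.tripeptide!r}",
        )
    return tri


def _merge_positions(positions: Sequence[int]) -> List[Interval]:
    """Collapse sorted genomic positions into maximal half-open intervals."""
    intervals: List[Interval] = []
    for p in positions:
        if intervals and intervals[-1][1] == p:
            intervals[-1] = (intervals[-1][0], p + 1)
        else:
            intervals.append((p, p + 1))
    return intervals


# ---------------------------------------------------------------------------
# Readers / writers


def read_transcript_tsv(path: Union[str, Path]) -> List[TranscriptRecord]:
    """Read the package's transcript TSV.

    Columns: transcript_id, gene, chromosome, strand, cds_segments
    (``start-end;start-end`` …, 0-based half-open), protein_seq, status.
    """
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            segs = tuple(
                (int(a), int(b))
                for a, b in (part.split("-") for part in row["cds_segments"].split(";"))
            )
            records.append(
                TranscriptRecord(
                    transcript_id=row["transcript_id"],
                    gene=row["gene"],
                    chromosome=row["chromosome"],
                    strand=row["strand"],
                    cds_segments=segs,
                    protein_seq=row["protein_seq"],
                    status=row.get("status", "Public"),
                )
            )
    return records


def write_transcript_tsv(records: Iterable[TranscriptRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["transcript_id", "gene", "chromosome", "strand", "cds_segments", "protein_seq", "status"]
        )
        for t in records:
            writer.writerow(
                [
                    t.transcript_id,
                    t.gene,
                    t.chromosome,
                    t.strand,
                    ";".join(f"{s}-{e}" for s, e in t.cds_segments),
                    t.protein_seq,
                    t.status,
                ]
            )


def read_ccds_records(
    ccds_txt: Union[str, Path], protein_fasta: Union[str, Path]
) -> List[TranscriptRecord]:
    """Reader for the native CCDS tab-delimited dialect.

    ``ccds_txt`` is the CCDS current.txt table (columns include
    chromosome, gene, ccds_id, ccds_status, cds_strand and
    cds_locations as ``[from1-to1, from2-to2, ...]`` with 0-based
    *inclusive* ends); ``protein_fasta`` supplies protein sequences
    keyed by the CCDS accession before the first ``|`` in the FASTA
    header.  Coordinates are converted to half-open on read.
    """
    proteins: Dict[str, str] = {}
    for rec in SeqIO.parse(str(protein_fasta), "fasta"):
        accession = rec.id.split("|")[0]
        proteins[accession] = str(rec.seq)

    records = []
    with open(ccds_txt) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            ccds_id = row["ccds_id"]
            locations = row["cds_locations"].strip("[]")
            if not locations or locations == "-":
                continue
            segs = tuple(
                (int(a), int(b) + 1)
                for a, b in (part.strip().split("-") for part in locations.split(","))
            )
            records.append(
                TranscriptRecord(
                    transcript_id=ccds_id,
                    gene=row["gene"],
                    chromosome=row["#chromosome"],
                    strand=row["cds_strand"],
                    cds_segments=segs,
                    protein_seq=proteins.get(ccds_id, ""),
                    status=row["ccds_status"],
                )
            )
    return records


def write_windows_bed(windows: Iterable[CterminalWindow], path: Union[str, Path]) -> None:
    """BED-like TSV of window intervals, one row per codon-contiguous run.

    Columns: chromosome, start, end, transcript_id, codon_index,
    strand — 0-based half-open.  Rows are sorted by (chromosome,
    start, transcript_id) so identical inputs yield identical bytes.
    """
    rows = []
    for w in windows:
        runs: List[Tuple[int, int, int]] = []  # (start, end, codon_index)
        for pos in sorted(w.codon_map):
            ci = w.codon_map[pos][0]
            if runs and runs[-1][1] == pos and runs[-1][2] == ci:
                runs[-1] = (runs[-1][0], pos + 1, ci)
            else:
                runs.append((pos, pos + 1, ci))
        for s, e, ci in runs:
            rows.append((w.chromosome, s, e, w.transcript_id, ci, w.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[3], r[4]))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for row in rows:
            writer.writerow(row)
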