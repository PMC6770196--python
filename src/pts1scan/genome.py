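"""Genome access helpers.

A *genome* throughout this package is simply a mapping from chromosome
name to an upper-case nucleotide string.  Chromosome names are
normalised by stripping an optional ``chr`` prefix, because transcript
tables and VCFs in the wild disagree on the dialect.  Toy and
per-locus genomes comfortably fit in memory; random access into large
references is out of scope.
"""
from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Union

from Bio import SeqIO
from Bio.Seq import Seq

Genome = Mapping[str, str]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def normalize_chrom(name: str) -> str:
    """Strip an optional ``chr`` prefix: ``chr7`` and ``7`` compare equal."""
    return name[3:] if name.lower().startswith("chr") else name


def load_genome(path: Union[str, Path]) -> Dict[str, str]:
    """Read a FASTA file into a dict keyed by normalised chromosome name."""
    genome: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[normalize_chrom(rec.id)] = str(rec.seq).upper()
    return genome


def fetch(genome: Genome, chromosome: str, start: int, end: int) -> str:
    """Return genome[chromosome][start:end] (0-based half-open).

    Raises ``KeyError`` for an unknown chromosome and ``IndexError``
    when the interval runs off the sequence end.
    """
    chrom = normalize_chrom(chromosome)
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        raise IndexError(
            f"interval [{start},{end}) outside chromosome {chrom} "
            f"of length {len(seq)}"
        )
    return seq[start:end]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard nuclear code.

    The stop codon, if present, is rendered as ``*``.
    """
    return str(Seq(cds).translate())
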