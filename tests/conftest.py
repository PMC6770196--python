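"""Shared fixtures: tiny hand-built genomes, random transcript factories,
and an independent splice-mutate-translate oracle.

The oracle deliberately bypasses the package's window machinery: it
rebuilds the *entire* mutated chromosome, re-splices, re-translates,
and reads off the last three residues, so agreement with the mapped
tripeptide is a genuine cross-check.
"""
from __future__ import annotations

import random
from typing import Dict, List, Tuple

import pytest
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from pts1scan.transcripts import TranscriptRecord

SENSE_CODONS = sorted(standard_dna_table.forward_table)
STOPS = sorted(standard_dna_table.stop_codons)
BASES = "ACGT"


def make_genome(chrom_seqs: Dict[str, str]) -> Dict[str, str]:
    return {k: v.upper() for k, v in chrom_seqs.items()}


def random_transcript(
    rng: random.Random,
    strand: str,
    n_exons: int | None = None,
    protein_len: int | None = None,
    chrom: str = "1",
    tid: str = "TX",
) -> Tuple[TranscriptRecord, Dict[str, str]]:
    """A random valid transcript embedded in a fresh random genome.

    Construction is independent of the package's simulator: codons are
    drawn directly from the standard table, chunks are laid onto the
    chromosome by hand, and minus-strand chunks are reverse
    complemented in reversed order.
    """
    P = protein_len if protein_len is not None else rng.randint(5, 60)
    codons = [rng.choice(SENSE_CODONS) for _ in range(P)]
    cds = "".join(codons) + rng.choice(STOPS)
    protein = str(Seq("".join(codons)).translate())

    k = n_exons if n_exons is not None else rng.randint(1, 4)
    k = min(k, len(cds))
    cuts = sorted(rng.sample(range(1, len(cds)), k - 1)) if k > 1 else []
    bounds = [0] + cuts + [len(cds)]
    chunks = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    genomic_chunks = (
        chunks if strand == "+" else [revcomp(c) for c in reversed(chunks)]
    )

    seq_parts: List[str] = []
    segments: List[Tuple[int, int]] = []
    pos = rng.randint(10, 60)
    seq_parts.append(random_bases(rng, pos))
    for i, chunk in enumerate(genomic_chunks):
        if i > 0:
            gap = rng.randint(5, 40)
            seq_parts.append(random_bases(rng, gap))
            pos += gap
        segments.append((pos, pos + len(chunk)))
        seq_parts.append(chunk)
        pos += len(chunk)
    seq_parts.append(random_bases(rng, rng.randint(10, 60)))

    t = TranscriptRecord(
        transcript_id=tid,
        gene=f"G_{tid}",
        chromosome=chrom,
        strand=strand,
        cds_segments=tuple(segments),
        protein_seq=protein,
    )
    return t, {chrom: "".join(seq_parts)}


def random_bases(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def oracle_mutant_tail(
    t: TranscriptRecord, genome: Dict[str, str], position: int, alt: str
) -> str:
    """Last three residues after mutating the genome and re-translating.

    Stop codons translate to ``*``; a mutated stop codon would change
    the tail length, which callers treat as out of scope here because
    the window never covers the stop codon.
    """
    chrom_seq = genome[t.chromosome]
    mutated = {t.chromosome: chrom_seq[:position] + alt + chrom_seq[position + 1 :]}
    parts = [mutated[t.chromosome][s:e] for s, e in t.cds_segments]
    cds = "".join(parts)
    if t.strand == "-":
        cds = revcomp(cds)
    protein = str(Seq(cds).translate())
    assert protein.endswith("*")
    return protein[-4:-1]


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic dataset, generated once per session."""
    from pts1scan.simulate import SimulationConfig, generate_dataset

    out = tmp_path_factory.mktemp("bundle")
    return generate_dataset(SimulationConfig(seed=1), out)


@pytest.fixture(scope="session")
def matrix():
    from pts1scan.scoring import example_matrix

    return example_matrix()
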