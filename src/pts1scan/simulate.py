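"""Self-contained synthetic dataset with planted LoF/GoF variants.

The generator emits a toy genome (FASTA), a transcript table, a VCF,
localisation and gene-context tables, a curated peroxisomal gene
list, and a truth table — everything the pipeline consumes — so that
every stage is testable offline.  The emulated structure mirrors
population-scale variant mining inputs: multi-exon CDS on both
strands, stop-codon-terminated coding sequences, PASS/fail variant
quality flags, and keyword-style localisation annotations.

Planting strategy
-----------------
* LoF variants sit in exclusively peroxisomal, disease-flagged genes
  whose wild-type tripeptide matches the classical consensus and
  whose mutant tripeptide does not.  The planted tripeptide pairs are
  the six substitution classes selected for loss-of-function testing
  in the underlying affinity study (SKL>STL, AKL>AEL, ...).
* GoF variants sit in exclusively cytosolic genes; the single-base
  change flips the bundled example matrix's category to "Targeted".
* Decoys each violate exactly one pipeline rule: a synonymous
  tripeptide change, a variant upstream of the 9-nt window, or a
  consensus-destroying variant that fails the quality filter.

Codons for planted residues are sampled uniformly among synonymous
codons reachable by a *single* substitution from the target mutant
codon, guaranteeing the planted event is a true SNV.  Separate seeded
random streams drive transcript geometry, coding-sequence choice and
variant bookkeeping, all derived from the one master seed; identical
config and seed give byte-identical files.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .errors import ConfigError
from .genome import reverse_complement
from .stats import table3_fixture  # re-exported: the in-study affinity fixture
from .transcripts import (
    TranscriptRecord,
    coding_order_positions,
    write_transcript_tsv,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "DatasetBundle",
    "generate_dataset",
    "read_truth_tsv",
    "table3_fixture",
    "LOF_TRIPEPTIDE_PAIRS",
    "GOF_TRIPEPTIDE_PAIRS",
]

LOF = "lof"
GOF = "gof"
DECOY_SYNONYMOUS = "decoy_synonymous"
DECOY_OUTSIDE = "decoy_outside"
DECOY_FAILQC = "decoy_failqc"

# Wild-type > mutant tripeptide pairs planted for each class.  LoF
# pairs are the six loss-of-function substitution classes tested in
# the affinity study; GoF pairs are gain classes whose mutant crosses
# the example matrix's "Targeted" threshold while the wild type does
# not.
LOF_TRIPEPTIDE_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("SKL", "STL"),
    ("AKL", "AEL"),
    ("SHL", "FHL"),
    ("SKL", "GKL"),
    ("SKL", "NKL"),
    ("AKL", "PKL"),
)
GOF_TRIPEPTIDE_PAIRS: Tuple[Tuple[str, str], ...] = (
    ("SNP", "SNL"),
    ("ATL", "AKL"),
    ("SGL", "SRL"),
    ("TKL", "SKL"),
)

_CODON_TABLE = standard_dna_table
_CODONS_FOR: Dict[str, List[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()
STOP_CODONS_SORTED = sorted(_CODON_TABLE.stop_codons)

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Defaults mirror the scale of the study's candidate pools: six
# loss-of-function and five gain-of-function variants were selected
# for testing there.
@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_lof_planted: int = 6
    n_gof_planted: int = 5
    n_decoy_synonymous: int = 3
    n_decoy_outside_window: int = 3
    n_decoy_failqc: int = 3
    n_genes: int = 30
    exons_per_transcript: Tuple[int, int] = (1, 4)
    strand_mix: float = 0.5  # fraction of transcripts on the minus strand
    min_protein_length: int = 40
    max_protein_length: int = 200

    def validate(self) -> None:
        counts = (
            self.n_lof_planted, self.n_gof_planted, self.n_decoy_synonymous,
            self.n_decoy_outside_window, self.n_decoy_failqc, self.n_genes,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be non-negative")
        lo, hi = self.exons_per_transcript
        if not 1 <= lo <= hi:
            raise ConfigError(f"bad exon range {self.exons_per_transcript}")
        if not 0.0 <= self.strand_mix <= 1.0:
            raise ConfigError("strand_mix must be a fraction in [0, 1]")
        if self.min_protein_length < 12:
            raise ConfigError("proteins must be at least 12 residues for scoring")
        if self.min_protein_length > self.max_protein_length:
            raise ConfigError("min_protein_length > max_protein_length")


@dataclass(frozen=True)
class TruthRecord:
    """What was planted where, for exact-recovery checks."""

    chromosome: str
    position: int  # 0-based
    ref: str
    alt: str
    planted_class: str
    gene: str
    transcript_id: str
    expected_wt_tri: str
    expected_mt_tri: str

    @property
    def variant_key(self) -> Tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclass
class DatasetBundle:
    """Paths to one generated dataset plus its truth table."""

    root: Path
    genome_fa: Path
    transcripts_tsv: Path
    variants_vcf: Path
    localization_tsv: Path
    gene_context_tsv: Path
    pts1_genes_txt: Path
    truth_tsv: Path
    truth: List[TruthRecord] = field(default_factory=list)


@dataclass
class _PlannedVariant:
    chromosome: str
    position: int
    ref: str
    alt: str
    rsid: str
    filter_status: str  # "PASS" or a failed-filter label
    allele_frequency: float
    planted_class: str
    gene: str
    transcript_id: str
    wt_tri: str
    mt_tri: str


def generate_dataset(cfg: SimulationConfig, out_dir: Union[str, Path]) -> DatasetBundle:
    """Write the full file bundle for ``cfg`` under ``out_dir``."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    master = np.random.SeedSequence(cfg.seed)
    rng_geometry, rng_sequence, rng_variants = (
        np.random.default_rng(s) for s in master.spawn(3)
    )

    plan = _gene_plan(cfg)
    chrom = "1"
    cursor = 0
    genome_parts: List[str] = []
    transcripts: List[TranscriptRecord] = []
    planned: List[_PlannedVariant] = []
    localization: List[Tuple[str, str]] = []  # (protein_id, keywords)
    contexts: List[Tuple[str, bool, int, bool, bool, str]] = []
    peroxisomal_genes: List[str] = []
    rs_counter = 1

    for spec in plan:
        gap = int(rng_geometry.integers(50, 300))
        genome_parts.append(_random_bases(rng_geometry, gap))
        cursor += gap

        transcript, genomic_seq, planted = _build_transcript(
            spec, cfg, cursor, chrom, rng_geometry, rng_sequence
        )
        genome_parts.append(genomic_seq)
        cursor += len(genomic_seq)
        transcripts.append(transcript)
        localization.append((transcript.transcript_id, spec["keywords"]))
        contexts.append(
            (
                spec["gene"],
                spec["omim"],
                len(transcript.protein_seq),
                False,
                False,
                f"{transcript.transcript_id}:{len(transcript.protein_seq)}",
            )
        )
        if spec["in_pts1_list"]:
            peroxisomal_genes.append(spec["gene"])
        if planted is not None:
            position, ref, alt, wt_tri, mt_tri = planted
            af = float(rng_variants.uniform(1e-6, 3e-4))
            planned.append(
                _PlannedVariant(
                    chromosome=chrom,
                    position=position,
                    ref=ref,
                    alt=alt,
                    rsid=f"rs{900000 + rs_counter}",
                    filter_status="RF" if spec["class"] == DECOY_FAILQC else "PASS",
                    allele_frequency=round(af, 8),
                    planted_class=spec["class"],
                    gene=spec["gene"],
                    transcript_id=transcript.transcript_id,
                    wt_tri=wt_tri,
                    mt_tri=mt_tri,
                )
            )
            rs_counter += 1

    tail = int(rng_geometry.integers(50, 300))
    genome_parts.append(_random_bases(rng_geometry, tail))
    genome = "".join(genome_parts)

    bundle = DatasetBundle(
        root=out,
        genome_fa=out / "genome.fa",
        transcripts_tsv=out / "transcripts.tsv",
        variants_vcf=out / "variants.vcf",
        localization_tsv=out / "localization.tsv",
        gene_context_tsv=out / "gene_context.tsv",
        pts1_genes_txt=out / "pts1_genes.txt",
        truth_tsv=out / "truth.tsv",
    )

    _write_fasta(bundle.genome_fa, chrom, genome)
    write_transcript_tsv(transcripts, bundle.transcripts_tsv)
    _write_vcf(bundle.variants_vcf, chrom, len(genome), planned)
    with open(bundle.localization_tsv, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "keywords", "isoform_specific"])
        for protein_id, keywords in localization:
            writer.writerow([protein_id, keywords, "false"])
    with open(bundle.gene_context_tsv, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene", "omim_flag", "length", "tmd_flag", "manual_include", "transcript_lengths"]
        )
        for gene, omim, length, tmd, manual, tx_lengths in contexts:
            writer.writerow(
                [gene, str(omim).lower(), length, str(tmd).lower(), str(manual).lower(), tx_lengths]
            )
    bundle.pts1_genes_txt.write_text("".join(f"{g}\n" for g in peroxisomal_genes))

    bundle.truth = [
        TruthRecord(
            chromosome=pv.chromosome,
            position=pv.position,
            ref=pv.ref,
            alt=pv.alt,
            planted_class=pv.planted_class,
            gene=pv.gene,
            transcript_id=pv.transcript_id,
            expected_wt_tri=pv.wt_tri,
            expected_mt_tri=pv.mt_tri,
        )
        for pv in planned
    ]
    _write_truth_tsv(bundle.truth, bundle.truth_tsv)
    return bundle


def _gene_plan(cfg: SimulationConfig) -> List[dict]:
    """Ordered gene specifications covering planted classes plus filler."""
    plan: List[dict] = []
    for i in range(cfg.n_lof_planted):
        wt, mt = LOF_TRIPEPTIDE_PAIRS[i % len(LOF_TRIPEPTIDE_PAIRS)]
        plan.append(
            dict(gene=f"LOFG{i + 1}", cls_pair=(wt, mt), class_=LOF,
                 keywords="Peroxisome", omim=True, in_pts1_list=True)
        )
    for i in range(cfg.n_gof_planted):
        wt, mt = GOF_TRIPEPTIDE_PAIRS[i % len(GOF_TRIPEPTIDE_PAIRS)]
        plan.append(
            dict(gene=f"GOFG{i + 1}", cls_pair=(wt, mt), class_=GOF,
                 keywords="Cytoplasm", omim=False, in_pts1_list=False)
        )
    for i in range(cfg.n_decoy_synonymous):
        plan.append(
            dict(gene=f"DSYN{i + 1}", cls_pair=("SKL", "SKL"), class_=DECOY_SYNONYMOUS,
                 keywords="Peroxisome", omim=True, in_pts1_list=True)
        )
    for i in range(cfg.n_decoy_outside_window):
        plan.append(
            dict(gene=f"DOUT{i + 1}", cls_pair=("SKL", "SKL"), class_=DECOY_OUTSIDE,
                 keywords="Peroxisome", omim=True, in_pts1_list=True)
        )
    for i in range(cfg.n_decoy_failqc):
        wt, mt = LOF_TRIPEPTIDE_PAIRS[i % len(LOF_TRIPEPTIDE_PAIRS)]
        plan.append(
            dict(gene=f"DQC{i + 1}", cls_pair=(wt, mt), class_=DECOY_FAILQC,
                 keywords="Peroxisome", omim=True, in_pts1_list=True)
        )
    n_filler = max(0, cfg.n_genes - len(plan))
    for i in range(n_filler):
        plan.append(
            dict(gene=f"FILL{i + 1}", cls_pair=None, class_=None,
                 keywords="Nucleus", omim=False, in_pts1_list=False)
        )
    for spec in plan:
        spec["class"] = spec.pop("class_")
    return plan


def _build_transcript(
    spec: dict,
    cfg: SimulationConfig,
    offset: int,
    chrom: str,
    rng_geometry: np.random.Generator,
    rng_sequence: np.random.Generator,
):
    """One transcript starting at genomic ``offset``; returns the record,
    its genomic sequence block, and the planted variant (if any)."""
    P = int(rng_sequence.integers(cfg.min_protein_length, cfg.max_protein_length + 1))
    cls = spec["class"]
    if spec["cls_pair"] is not None:
        wt_tri, mt_tri = spec["cls_pair"]
    else:
        wt_tri = mt_tri = None

    aa_pool = "ACDEFGHIKLMNPQRSTVWY"
    body = "".join(rng_sequence.choice(list(aa_pool), size=P - 3))
    if wt_tri is None:
        # filler: any non-canonical tail so filler genes stay inert
        tail = "DDD"
    else:
        tail = wt_tri
    protein = body + tail

    # choose codons; remember where the planted substitution goes
    codons: List[str] = []
    sub: Optional[Tuple[int, int, str, str]] = None  # (codon idx, offset, wt base, mt base)
    for idx, aa in enumerate(protein):
        tri_pos = idx - (P - 3)  # 0,1,2 inside the tripeptide; negative upstream
        planted_here = False
        if wt_tri is not None and tri_pos >= 0 and cls in (LOF, GOF, DECOY_FAILQC):
            if wt_tri[tri_pos] != mt_tri[tri_pos]:
                planted_here = True
        if cls == DECOY_SYNONYMOUS and tri_pos == 2:
            # synonymous change in the last codon: CTG -> CTA (Leu)
            codons.append("CTG")
            sub = (idx, 2, "G", "A")
            continue
        if planted_here:
            pairs = _snv_codon_pairs(aa, mt_tri[tri_pos])
            if not pairs:
                raise ConfigError(
                    f"no single-substitution codon pair for {aa}>{mt_tri[tri_pos]}"
                )
            wt_codon, mt_codon = pairs[int(rng_sequence.integers(len(pairs)))]
            diff = next(k for k in range(3) if wt_codon[k] != mt_codon[k])
            codons.append(wt_codon)
            sub = (idx, diff, wt_codon[diff], mt_codon[diff])
        else:
            options = _CODONS_FOR[aa]
            codons.append(options[int(rng_sequence.integers(len(options)))])
    if cls == DECOY_OUTSIDE:
        # missense-style substitution ~10 codons upstream of the window
        idx = P - 10
        wt_codon = codons[idx]
        mt_base = next(b for b in _BASES if b != wt_codon[0])
        sub = (idx, 0, wt_codon[0], mt_base)

    codons.append(STOP_CODONS_SORTED[int(rng_sequence.integers(len(STOP_CODONS_SORTED)))])
    cds = "".join(codons)

    strand = "-" if rng_geometry.random() < cfg.strand_mix else "+"
    n_exons = int(
        rng_geometry.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1)
    )
    n_exons = min(n_exons, len(cds) // 3)  # keep exons at least a few nt
    cuts = sorted(
        rng_geometry.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False).tolist()
    ) if n_exons > 1 else []
    bounds = [0] + cuts + [len(cds)]
    chunks = [cds[a:b] for a, b in zip(bounds, bounds[1:])]

    # lay chunks onto the genome with intron gaps; for minus-strand
    # transcripts ascending genomic order carries the reversed,
    # reverse-complemented chunks
    genomic_chunks = chunks if strand == "+" else [
        reverse_complement(c) for c in reversed(chunks)
    ]
    parts: List[str] = []
    segments: List[Tuple[int, int]] = []
    pos = offset
    for i, chunk in enumerate(genomic_chunks):
        if i > 0:
            intron = int(rng_geometry.integers(20, 100))
            parts.append(_random_bases(rng_geometry, intron))
            pos += intron
        segments.append((pos, pos + len(chunk)))
        parts.append(chunk)
        pos += len(chunk)

    transcript = TranscriptRecord(
        transcript_id=f"T_{spec['gene']}",
        gene=spec["gene"],
        chromosome=chrom,
        strand=strand,
        cds_segments=tuple(segments),
        protein_seq=protein,
        status="Public",
    )

    planted = None
    if sub is not None:
        codon_idx, codon_off, wt_base, mt_base = sub
        coding_index = 3 * codon_idx + codon_off
        genomic_pos = coding_order_positions(transcript)[coding_index]
        if strand == "+":
            ref, alt = wt_base, mt_base
        else:
            ref, alt = _COMPLEMENT[wt_base], _COMPLEMENT[mt_base]
        planted = (genomic_pos, ref, alt, protein[-3:], mt_tri or protein[-3:])
    return transcript, "".join(parts), planted


def _snv_codon_pairs(wt_aa: str, mt_aa: str) -> List[Tuple[str, str]]:
    """All (wt_codon, mt_codon) pairs one substitution apart."""
    pairs = []
    for wt_codon in _CODONS_FOR[wt_aa]:
        for mt_codon in _CODONS_FOR[mt_aa]:
            if sum(a != b for a, b in zip(wt_codon, mt_codon)) == 1:
                pairs.append((wt_codon, mt_codon))
    return pairs


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n)) if n else ""


def _write_fasta(path: Path, chrom: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _write_vcf(path: Path, chrom: str, chrom_len: int, planned: Sequence[_PlannedVariant]) -> None:
    rows = sorted(planned, key=lambda pv: pv.position)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={chrom_len}>\n")
        fh.write('##FILTER=<ID=RF,Description="Failed random-forest quality model">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=nhomalt,Number=A,Type=Integer,Description="Homozygote count">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pv in rows:
            info = f"AF={pv.allele_frequency:.8f};nhomalt=0"
            fh.write(
                f"{pv.chromosome}\t{pv.position + 1}\t{pv.rsid}\t{pv.ref}\t"
                f"{pv.alt}\t.\t{pv.filter_status}\t{info}\n"
            )


def _write_truth_tsv(truth: Sequence[TruthRecord], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "chromosome", "position", "ref", "alt", "planted_class",
                "gene", "transcript_id", "expected_wt_tri", "expected_mt_tri",
            ]
        )
        for tr in truth:
            writer.writerow(
                [
                    tr.chromosome, tr.position + 1, tr.ref, tr.alt, tr.planted_class,
                    tr.gene, tr.transcript_id, tr.expected_wt_tri, tr.expected_mt_tri,
                ]
            )


def read_truth_tsv(path: Union[str, Path]) -> List[TruthRecord]:
    truth = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            truth.append(
                TruthRecord(
                    chromosome=row["chromosome"],
                    position=int(row["position"]) - 1,
                    ref=row["ref"],
                    alt=row["alt"],
                    planted_class=row["planted_class"],
                    gene=row["gene"],
                    transcript_id=row["transcript_id"],
                    expected_wt_tri=row["expected_wt_tri"],
                    expected_mt_tri=row["expected_mt_tri"],
                )
            )
    return truth
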