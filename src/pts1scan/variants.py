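"""VCF normalisation and mapping of SNVs onto C-terminal tripeptides.

Variants enter as VCF rows (possibly multi-allelic, possibly from two
call sets — exome and genome — as in gnomAD), are decomposed into one
record per (site, alt allele), restricted to single-nucleotide
substitutions, and then mapped onto the 9-nt C-terminal codon windows
of overlapping transcripts.  The affected codon is rebuilt with the
alternate base substituted on the coding strand, and the mutant
tripeptide is compared with the wild type to classify the consequence.

Coordinates are converted from VCF's 1-based convention to the
package-wide 0-based half-open convention at parse time.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pysam

from .errors import ReferenceMismatchError, VcfParseError
from .genome import Genome, fetch, normalize_chrom, translate_cds
from .transcripts import STOP_CODONS, CterminalWindow

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

MISSENSE = "missense"
SYNONYMOUS = "synonymous"
STOP_GAINED = "stop_gained"


@dataclass(frozen=True)
class VariantRecord:
    """One normalised single-nucleotide allele.

    ``position`` is 0-based.  ``pass_exome`` / ``pass_genome`` record
    the PASS status in the respective call set; a variant absent from
    a call set carries ``False`` there.  Allele frequency and
    homozygote count are ``None`` when unknown.
    """

    chromosome: str
    position: int
    ref: str
    alt: str
    pass_exome: bool = False
    pass_genome: bool = False
    allele_frequency: Optional[float] = None
    homozygote_count: Optional[int] = None
    rsid: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)

    @property
    def quality_passing(self) -> bool:
        """PASS in either the exome or the genome call set."""
        return self.pass_exome or self.pass_genome


@dataclass(frozen=True)
class TripeptideChange:
    """Effect of one SNV on the C-terminal tripeptide of one transcript."""

    transcript_id: str
    gene: str
    variant: VariantRecord
    wt_tripeptide: str
    mt_tripeptide: str
    codon_index: int  # 1 = third-from-last residue, 3 = last residue
    consequence: str


@dataclass
class NormalizeStats:
    n_input_alleles: int = 0
    n_non_snv_dropped: int = 0
    n_merged_duplicates: int = 0


def read_vcf_alleles(
    path: Union[str, Path],
    call_set: str = "exome",
    af_key: str = "AF",
    nhom_key: str = "nhomalt",
) -> List[VariantRecord]:
    """Read a VCF and decompose each row into per-alt ``VariantRecord``s.

    ``call_set`` names the source ("exome" or "genome") and decides
    which PASS flag the FILTER column populates.  Non-SNV alleles are
    kept at this stage (as multi-base records) and dropped later by
    :func:`normalize_variants`, which also counts them.
    """
    if call_set not in ("exome", "genome"):
        raise ValueError(f"call_set must be 'exome' or 'genome', got {call_set!r}")
    records: List[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        # looking up an INFO key that the header does not declare raises
        have_af = af_key in vcf.header.info
        have_nhom = nhom_key in vcf.header.info
        for rec in vcf:
            if rec.alts is None:
                continue
            is_pass = "PASS" in rec.filter or len(rec.filter) == 0
            afs = rec.info.get(af_key, None) if have_af else None
            nhoms = rec.info.get(nhom_key, None) if have_nhom else None
            for i, alt in enumerate(rec.alts):
                af = _nth(afs, i)
                nhom = _nth(nhoms, i)
                records.append(
                    VariantRecord(
                        chromosome=rec.chrom,
                        position=rec.pos - 1,
                        ref=rec.ref or "",
                        alt=alt or "",
                        pass_exome=is_pass and call_set == "exome",
                        pass_genome=is_pass and call_set == "genome",
                        allele_frequency=float(af) if af is not None else None,
                        homozygote_count=int(nhom) if nhom is not None else None,
                        rsid=rec.id or "",
                    )
                )
    return records


def _nth(value, i):
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        return value[i] if i < len(value) else None
    return value if i == 0 else None


def normalize_variants(
    raw_records: Iterable[VariantRecord],
) -> Tuple[List[VariantRecord], NormalizeStats]:
    """Keep SNVs only and merge duplicate alleles across call sets.

    One output record per (chromosome, position, ref, alt).  Records
    for the same allele (typically one from the exome and one from the
    genome call set) are merged by OR-ing the two PASS flags; the
    allele frequency and homozygote count of the first record carrying
    them win.  The operation is idempotent: feeding its output back in
    reproduces it.

    Raises ``VcfParseError`` for malformed ref/alt fields.
    """
    stats = NormalizeStats()
    merged: Dict[Tuple[str, int, str, str], VariantRecord] = {}
    for rec in raw_records:
        stats.n_input_alleles += 1
        if not rec.ref or not rec.alt:
            raise VcfParseError(
                f"empty ref/alt at {rec.chromosome}:{rec.position + 1}"
            )
        if len(rec.ref) != 1 or len(rec.alt) != 1:
            stats.n_non_snv_dropped += 1
            continue
        if rec.ref not in "ACGT" or rec.alt not in "ACGT" or rec.ref == rec.alt:
            raise VcfParseError(
                f"malformed SNV {rec.ref}>{rec.alt} at "
                f"{rec.chromosome}:{rec.position + 1}"
            )
        key = rec.key
        if key in merged:
            stats.n_merged_duplicates += 1
            old = merged[key]
            merged[key] = replace(
                old,
                pass_exome=old.pass_exome or rec.pass_exome,
                pass_genome=old.pass_genome or rec.pass_genome,
                allele_frequency=(
                    old.allele_frequency
                    if old.allele_frequency is not None
                    else rec.allele_frequency
                ),
                homozygote_count=(
                    old.homozygote_count
                    if old.homozygote_count is not None
                    else rec.homozygote_count
                ),
                rsid=old.rsid or rec.rsid,
            )
        else:
            merged[key] = rec
    return sorted(merged.values(), key=lambda r: r.key), stats


def map_variant(
    v: VariantRecord, w: CterminalWindow, genome: Genome
) -> Optional[TripeptideChange]:
    """Apply ``v`` to the tripeptide window ``w``; ``None`` if outside.

    The substitution is applied on the coding strand (the alternate
    base is complemented for minus-strand transcripts), the affected
    codon is rebuilt and translated, and both tripeptides are
    returned.  A REF base that disagrees with the genome is a hard
    ``ReferenceMismatchError`` — silently skipping would corrupt
    downstream counts.
    """
    if normalize_chrom(v.chromosome) != w.chromosome or v.position not in w.codon_map:
        return None
    genome_base = fetch(genome, w.chromosome, v.position, v.position + 1)
    if genome_base != v.ref:
        raise ReferenceMismatchError(
            f"variant {v.chromosome}:{v.position + 1} {v.ref}>{v.alt}: genome has "
            f"{genome_base!r} (transcript {w.transcript_id})"
        )
    codon_index, offset, _ = w.codon_map[v.position]
    coding_alt = v.alt if w.strand == "+" else _COMPLEMENT[v.alt]

    # rebuild the affected codon in coding orientation from the window map
    codon_bases = {
        off: base
        for pos, (ci, off, base) in w.codon_map.items()
        if ci == codon_index
    }
    wt_codon = "".join(codon_bases[o] for o in range(3))
    mt_codon = wt_codon[:offset] + coding_alt + wt_codon[offset + 1 :]

    wt_tri = w.tripeptide
    if mt_codon in STOP_CODONS:
        mt_aa = "*"
    else:
        mt_aa = translate_cds(mt_codon)
    mt_tri = wt_tri[: codon_index - 1] + mt_aa + wt_tri[codon_index:]

    change = TripeptideChange(
        transcript_id=w.transcript_id,
        gene=w.gene,
        variant=v,
        wt_tripeptide=wt_tri,
        mt_tripeptide=mt_tri,
        codon_index=codon_index,
        consequence="",
    )
    return replace(change, consequence=classify_consequence(change))


def classify_consequence(c: TripeptideChange) -> str:
    """``synonymous`` | ``stop_gained`` | ``missense`` for one change."""
    if "*" in c.mt_tripeptide:
        return STOP_GAINED
    if c.mt_tripeptide == c.wt_tripeptide:
        return SYNONYMOUS
    return MISSENSE


def scan_windows(
    variants: Iterable[VariantRecord],
    windows: Iterable[CterminalWindow],
    genome: Genome,
    missense_only: bool = True,
) -> List[TripeptideChange]:
    """Intersect variants with windows and classify every hit.

    Downstream candidate filtering consumes missense changes only
    (the default); set ``missense_only=False`` to keep synonymous and
    stop-gain hits for accounting.
    """
    by_pos: Dict[Tuple[str, int], List[CterminalWindow]] = {}
    for w in windows:
        for pos in w.codon_map:
            by_pos.setdefault((w.chromosome, pos), []).append(w)
    changes: List[TripeptideChange] = []
    for v in variants:
        for w in by_pos.get((v.chromosome, v.position), []):
            c = map_variant(v, w, genome)
            if c is None:
                continue
            if missense_only and c.consequence != MISSENSE:
                continue
            changes.append(c)
    changes.sort(key=lambda c: (c.variant.key, c.transcript_id))
    return changes


def write_changes_tsv(changes: Iterable[TripeptideChange], path: Union[str, Path]) -> None:
    """TSV of tripeptide changes; positions written back as 1-based."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "transcript_id", "gene", "chromosome", "position", "ref", "alt",
                "wt_tripeptide", "mt_tripeptide", "codon_index", "consequence",
                "pass_exome", "pass_genome", "allele_frequency", "rsid",
            ]
        )
        for c in changes:
            v = c.variant
            writer.writerow(
                [
                    c.transcript_id, c.gene, v.chromosome, v.position + 1, v.ref,
                    v.alt, c.wt_tripeptide, c.mt_tripeptide, c.codon_index,
                    c.consequence, v.pass_exome, v.pass_genome,
                    "" if v.allele_frequency is None else v.allele_frequency,
                    v.rsid,
                ]
            )
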