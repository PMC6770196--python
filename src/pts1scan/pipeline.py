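"""End-to-end orchestration: files in, candidate tables out.

This module wires the stages together for callers that hold a file
bundle (whether generated by :mod:`pts1scan.simulate` or assembled
from real resources): load and validate transcripts, extract
C-terminal codon windows, normalise variants, map them onto the
windows, score the 12-residue C-termini, and run both candidate
cascades.  The command-line interface is a thin wrapper around these
functions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .filters import (
    FilterOutcome,
    GeneContext,
    LocalizationAnnotation,
    gof_cascade,
    lof_cascade,
    read_gene_context_tsv,
    read_localization_tsv,
    result_key,
)
from .genome import Genome, load_genome
from .scoring import Pts1Matrix, PTS1Result, score_pair
from .transcripts import (
    CterminalWindow,
    LoadResult,
    TranscriptRecord,
    cterminal_codon_intervals,
    load_transcripts,
)
from .variants import (
    NormalizeStats,
    TripeptideChange,
    VariantRecord,
    normalize_variants,
    read_vcf_alleles,
    scan_windows,
)


@dataclass
class PipelineResult:
    """Everything the pipeline computed, for inspection or writing."""

    transcripts: LoadResult
    windows: List[CterminalWindow]
    variants: List[VariantRecord]
    normalize_stats: NormalizeStats
    changes: List[TripeptideChange]
    pts1_results: Dict[Tuple, PTS1Result]
    lof: Optional[FilterOutcome] = None
    gof: Optional[FilterOutcome] = None
    annotations: Dict[str, LocalizationAnnotation] = field(default_factory=dict)
    contexts: Dict[str, GeneContext] = field(default_factory=dict)


def score_changes(
    changes: Sequence[TripeptideChange],
    transcripts: Sequence[TranscriptRecord],
    matrix: Pts1Matrix,
) -> Dict[Tuple, PTS1Result]:
    """Score the wild-type and mutant 12-residue C-termini per change.

    The mutant window replaces only the C-terminal tripeptide; the
    nine upstream residues are shared with the wild type by
    construction (the variants live in the last three codons).
    Proteins shorter than 12 residues are skipped — they cannot be
    scored without inventing a padding rule.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    results: Dict[Tuple, PTS1Result] = {}
    for c in changes:
        t = by_id.get(c.transcript_id)
        if t is None or len(t.protein_seq) < 12:
            continue
        wt12 = t.protein_seq[-12:]
        mt12 = wt12[:9] + c.mt_tripeptide
        results[result_key(c)] = score_pair(wt12, mt12, matrix)
    return results


def run_pipeline(
    genome_fa: Union[str, Path],
    transcripts_tsv: Union[str, Path],
    vcf_paths: Sequence[Tuple[Union[str, Path], str]],
    localization_tsv: Union[str, Path],
    gene_context_tsv: Union[str, Path],
    matrix: Pts1Matrix,
    peroxisomal_genes: Sequence[str],
) -> PipelineResult:
    """Run every stage over one file bundle.

    ``vcf_paths`` pairs each VCF with its call-set name ("exome" or
    "genome"); alleles appearing in both call sets are merged with
    their respective PASS flags.
    """
    genome = load_genome(genome_fa)
    loaded = load_transcripts(str(transcripts_tsv), genome)
    windows = [cterminal_codon_intervals(t, genome) for t in loaded.records]

    raw: List[VariantRecord] = []
    for path, call_set in vcf_paths:
        raw.extend(read_vcf_alleles(path, call_set=call_set))
    variants, norm_stats = normalize_variants(raw)

    changes = scan_windows(variants, windows, genome)
    pts1_results = score_changes(changes, loaded.records, matrix)

    annotations = read_localization_tsv(localization_tsv)
    contexts = read_gene_context_tsv(gene_context_tsv)

    lof = lof_cascade(changes, annotations, contexts, peroxisomal_genes)
    gof = gof_cascade(changes, annotations, contexts, pts1_results)

    return PipelineResult(
        transcripts=loaded,
        windows=windows,
        variants=variants,
        normalize_stats=norm_stats,
        changes=changes,
        pts1_results=pts1_results,
        lof=lof,
        gof=gof,
        annotations=annotations,
        contexts=contexts,
    )


def run_on_bundle(bundle, matrix: Pts1Matrix) -> PipelineResult:
    """Convenience wrapper for a :class:`~pts1scan.simulate.DatasetBundle`."""
    peroxisomal = [
        line.strip()
        for line in Path(bundle.pts1_genes_txt).read_text().splitlines()
        if line.strip()
    ]
    return run_pipeline(
        genome_fa=bundle.genome_fa,
        transcripts_tsv=bundle.transcripts_tsv,
        vcf_paths=[(bundle.variants_vcf, "exome")],
        localization_tsv=bundle.localization_tsv,
        gene_context_tsv=bundle.gene_context_tsv,
        matrix=matrix,
        peroxisomal_genes=peroxisomal,
    )
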