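"""Loss- and gain-of-function candidate prioritisation cascades.

Starting from missense tripeptide changes, two filter cascades narrow
the pool to experimentally tractable candidates:

* **LoF** — variants that may inactivate an existing PTS1 on a known,
  disease-linked, exclusively peroxisomal protein: the wild-type
  tripeptide matches the classical consensus and the mutant one does
  not.
* **GoF** — variants that may create a *de novo* PTS1 on a normally
  cytosolic protein: the matrix category flips to "Targeted" from
  "Twilight zone" or "Not targeted".

Both cascades are pure conjunctions, so the retained *set* does not
depend on stage order; the order is fixed anyway so that per-stage
in/out counts are reproducible, and every excluded record is logged
with the first stage it failed.  Keyword matching on localisation
annotations is exact-token and case-insensitive — "Cytoplasmic
vesicle" never matches "Cytoplasm".
"""
from __future__ import annotations

import csv
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .scoring import NOT_TARGETED, TARGETED, TWILIGHT, PTS1Result, is_canonical_pts1
from .variants import TripeptideChange

# Keyword sets from the prioritisation procedure: a LoF gene product
# must be exclusively peroxisomal; a GoF product exclusively cytosolic.
LOF_REQUIRED_KEYWORD = "peroxisome"
LOF_EXCLUDED_KEYWORDS = frozenset(
    {"secreted", "nucleus", "mitochondrion", "endosome", "cytoplasm"}
)
GOF_REQUIRED_KEYWORD = "cytoplasm"
GOF_EXCLUDED_KEYWORDS = frozenset(
    {"secreted", "nucleus", "mitochondrion", "endosome", "peroxisome"}
)
MAX_GOF_PROTEIN_LENGTH = 1000

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class LocalizationAnnotation:
    """Subcellular-localisation keywords for one protein (transcript)."""

    protein_id: str
    keywords: frozenset  # lower-cased, trimmed tokens
    is_isoform_specific: bool = False

    @staticmethod
    def make(protein_id: str, keywords: Iterable[str], is_isoform_specific: bool = False):
        return LocalizationAnnotation(
            protein_id=protein_id,
            keywords=frozenset(k.strip().lower() for k in keywords if k.strip()),
            is_isoform_specific=is_isoform_specific,
        )


@dataclass(frozen=True)
class GeneContext:
    """Gene-level facts the cascades consult."""

    gene: str
    has_omim_disease: bool = False
    protein_length: int = 0
    has_tmd: bool = False
    transcript_lengths: Mapping[str, int] = field(default_factory=dict)
    manual_include: bool = False


@dataclass
class FilterOutcome:
    """Cascade result with per-stage accounting.

    ``stage_counts`` maps stage name to ``(n_in, n_out)`` and
    telescopes: the out-count of each stage is the in-count of the
    next.  Every input record lands exactly once in ``retained`` or in
    ``exclusion_log`` (paired with the first stage it failed).
    """

    retained: List[TripeptideChange]
    stage_counts: "OrderedDict[str, Tuple[int, int]]"
    exclusion_log: List[Tuple[TripeptideChange, str]]


def propagate_annotations(
    annotations: Mapping[str, LocalizationAnnotation],
    gene_isoforms: Mapping[str, Sequence[str]],
) -> Tuple[Dict[str, LocalizationAnnotation], List[str]]:
    """Extend each gene's canonical annotation to unannotated isoforms.

    ``gene_isoforms`` lists each gene's transcripts with the canonical
    transcript first.  Isoform-specific annotations are left
    untouched; isoforms without one inherit the canonical
    transcript's.  Genes whose canonical transcript has no annotation
    are returned separately as unannotated (their products will be
    excluded later with reason "unannotated").
    """
    completed = dict(annotations)
    unannotated_genes: List[str] = []
    for gene, isoforms in gene_isoforms.items():
        if not isoforms:
            continue
        canonical = annotations.get(isoforms[0])
        if canonical is None:
            unannotated_genes.append(gene)
            continue
        for iso in isoforms[1:]:
            existing = completed.get(iso)
            if existing is not None and existing.is_isoform_specific:
                continue
            if existing is None:
                completed[iso] = LocalizationAnnotation(
                    protein_id=iso,
                    keywords=canonical.keywords,
                    is_isoform_specific=False,
                )
    return completed, unannotated_genes


# A stage maps the surviving records to (kept, excluded); wrapping
# per-record predicates this way lets group-wise stages (longest
# transcript per gene) share the same plumbing.
Stage = Tuple[str, Callable[[List[TripeptideChange]], Tuple[List[TripeptideChange], List[TripeptideChange]]]]


def _predicate_stage(name: str, pred: Callable[[TripeptideChange], bool]) -> Stage:
    def run(records: List[TripeptideChange]):
        kept, excluded = [], []
        for r in records:
            (kept if pred(r) else excluded).append(r)
        return kept, excluded

    return name, run


def _run_cascade(changes: Iterable[TripeptideChange], stages: Sequence[Stage]) -> FilterOutcome:
    surviving = list(changes)
    counts: "OrderedDict[str, Tuple[int, int]]" = OrderedDict()
    log: List[Tuple[TripeptideChange, str]] = []
    for name, run in stages:
        n_in = len(surviving)
        surviving, excluded = run(surviving)
        counts[name] = (n_in, len(surviving))
        log.extend((r, name) for r in excluded)
    surviving.sort(key=lambda c: (c.variant.key, c.transcript_id))
    return FilterOutcome(retained=surviving, stage_counts=counts, exclusion_log=log)


def lof_cascade(
    changes: Iterable[TripeptideChange],
    annotations: Mapping[str, LocalizationAnnotation],
    contexts: Mapping[str, GeneContext],
    peroxisomal_gene_list: Iterable[str],
    consensus=None,
) -> FilterOutcome:
    """Prioritise variants that may destroy an existing PTS1.

    Stages, in order: curated peroxisomal-gene membership; OMIM
    disease link; exclusive peroxisomal localisation (keyword
    "Peroxisome" present, none of Secreted/Nucleus/Mitochondrion/
    Endosome/Cytoplasm — bypassable per gene via ``manual_include``
    for cases where the mutant, not the native protein, carries a
    second compartment keyword); variant quality PASS in either call
    set; wild-type tripeptide canonical while the mutant one is not.
    """
    gene_list: Set[str] = {g for g in peroxisomal_gene_list}
    kwargs = {} if consensus is None else {"consensus": consensus}

    def localization_ok(c: TripeptideChange) -> bool:
        ctx = contexts.get(c.gene)
        if ctx is not None and ctx.manual_include:
            return True
        ann = annotations.get(c.transcript_id)
        if ann is None:
            return False
        return LOF_REQUIRED_KEYWORD in ann.keywords and not (
            ann.keywords & LOF_EXCLUDED_KEYWORDS
        )

    stages = [
        _predicate_stage("pts1_gene_list", lambda c: c.gene in gene_list),
        _predicate_stage(
            "omim_disease",
            lambda c: c.gene in contexts and contexts[c.gene].has_omim_disease,
        ),
        _predicate_stage("peroxisome_only_localization", localization_ok),
        _predicate_stage("quality_pass", lambda c: c.variant.quality_passing),
        _predicate_stage(
            "consensus_lost",
            lambda c: is_canonical_pts1(c.wt_tripeptide, **kwargs)
            and not is_canonical_pts1(c.mt_tripeptide, **kwargs),
        ),
    ]
    return _run_cascade(changes, stages)


def gof_cascade(
    changes: Iterable[TripeptideChange],
    annotations: Mapping[str, LocalizationAnnotation],
    contexts: Mapping[str, GeneContext],
    pts1_results: Mapping[Tuple, PTS1Result],
    max_protein_length: int = MAX_GOF_PROTEIN_LENGTH,
) -> FilterOutcome:
    """Prioritise variants that may create a *de novo* PTS1.

    Stages, in order: variant quality; exclusively cytosolic
    localisation; matrix category gain (mutant "Targeted" from
    "Twilight zone"/"Not targeted"); longest transcript per gene (ties
    broken by smallest transcript id); protein shorter than
    ``max_protein_length`` residues and free of transmembrane domains.

    ``pts1_results`` is keyed by ``(transcript_id,) + variant.key``.
    """

    def localization_ok(c: TripeptideChange) -> bool:
        ann = annotations.get(c.transcript_id)
        if ann is None:
            return False
        return GOF_REQUIRED_KEYWORD in ann.keywords and not (
            ann.keywords & GOF_EXCLUDED_KEYWORDS
        )

    def category_gain(c: TripeptideChange) -> bool:
        res = pts1_results.get(result_key(c))
        if res is None:
            return False
        return res.mt_category == TARGETED and res.wt_category in (TWILIGHT, NOT_TARGETED)

    def tx_length(c: TripeptideChange) -> Optional[int]:
        ctx = contexts.get(c.gene)
        if ctx is None:
            return None
        length = ctx.transcript_lengths.get(c.transcript_id)
        return length if length is not None else (ctx.protein_length or None)

    def longest_transcript(records: List[TripeptideChange]):
        kept, excluded = [], []
        groups: Dict[Tuple, List[TripeptideChange]] = {}
        for r in records:
            groups.setdefault((r.gene, r.variant.key), []).append(r)
        for group in groups.values():
            if any(tx_length(r) is None for r in group):
                excluded.extend(group)
                continue
            winner = min(group, key=lambda r: (-tx_length(r), r.transcript_id))
            for r in group:
                (kept if r is winner else excluded).append(r)
        return kept, excluded

    def size_and_tmd(c: TripeptideChange) -> bool:
        ctx = contexts.get(c.gene)
        if ctx is None:
            return False
        length = tx_length(c)
        return length is not None and length < max_protein_length and not ctx.has_tmd

    stages = [
        _predicate_stage("quality_pass", lambda c: c.variant.quality_passing),
        _predicate_stage("cytoplasm_only_localization", localization_ok),
        _predicate_stage("category_gain", category_gain),
        ("longest_transcript", longest_transcript),
        _predicate_stage("length_and_no_tmd", size_and_tmd),
    ]
    return _run_cascade(changes, stages)


def result_key(c: TripeptideChange) -> Tuple:
    """Key linking a tripeptide change to its PTS1 scoring result."""
    return (c.transcript_id,) + c.variant.key


# ---------------------------------------------------------------------------
# Readers / writers


def read_localization_tsv(path: Union[str, Path]) -> Dict[str, LocalizationAnnotation]:
    """TSV columns: protein_id, keywords (semicolon-separated), isoform_specific."""
    annotations: Dict[str, LocalizationAnnotation] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            annotations[row["protein_id"]] = LocalizationAnnotation.make(
                row["protein_id"],
                row["keywords"].split(";"),
                row.get("isoform_specific", "false").strip().lower() == "true",
            )
    return annotations


def read_gene_context_tsv(path: Union[str, Path]) -> Dict[str, GeneContext]:
    """TSV columns: gene, omim_flag, length, tmd_flag, manual_include,
    transcript_lengths (optional, ``tx:len;tx:len``)."""
    contexts: Dict[str, GeneContext] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            tx_lengths: Dict[str, int] = {}
            raw = row.get("transcript_lengths", "") or ""
            for part in raw.split(";"):
                if part.strip():
                    tx, ln = part.split(":")
                    tx_lengths[tx] = int(ln)
            contexts[row["gene"]] = GeneContext(
                gene=row["gene"],
                has_omim_disease=_truthy(row.get("omim_flag")),
                protein_length=int(row.get("length", "0") or 0),
                has_tmd=_truthy(row.get("tmd_flag")),
                transcript_lengths=tx_lengths,
                manual_include=_truthy(row.get("manual_include")),
            )
    return contexts


def _truthy(value: Optional[str]) -> bool:
    return (value or "").strip().lower() in ("true", "1", "yes")


def write_candidates_tsv(
    outcome: FilterOutcome,
    path: Union[str, Path],
    annotations: Optional[Mapping[str, LocalizationAnnotation]] = None,
    pts1_results: Optional[Mapping[Tuple, PTS1Result]] = None,
) -> None:
    """Retained candidates with the columns of the selection tables."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "rsid", "gene", "transcript_id", "chromosome", "position",
                "ref", "alt", "wt_tripeptide", "mt_tripeptide",
                "wt_category", "mt_category", "localization",
            ]
        )
        for c in outcome.retained:
            res = (pts1_results or {}).get(result_key(c))
            ann = (annotations or {}).get(c.transcript_id)
            writer.writerow(
                [
                    c.variant.rsid, c.gene, c.transcript_id, c.variant.chromosome,
                    c.variant.position + 1, c.variant.ref, c.variant.alt,
                    c.wt_tripeptide, c.mt_tripeptide,
                    res.wt_category if res else "", res.mt_category if res else "",
                    ";".join(sorted(ann.keywords)) if ann else "",
                ]
            )


def write_stage_counts_tsv(outcome: FilterOutcome, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["stage", "n_in", "n_out"])
        for name, (n_in, n_out) in outcome.stage_counts.items():
            writer.writerow([name, n_in, n_out])
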