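# Methods

## The problem

A type-1 peroxisomal targeting signal (PTS1) is carried by the extreme
C-terminus of a protein: the last tripeptide (canonically SKL, more
generally `[S/A/C]-[K/R/H]-L`) plus a modulating upstream context,
bound by the TPR domain of the receptor PEX5. Because the signal is
encoded by the last three codons before the stop codon, single-
nucleotide variants (SNVs) in a 9-nt genomic window per transcript can
inactivate an existing signal or create a new one. The package mines
variant call sets for such SNVs, scores the predicted targeting
change, prioritises candidates through two filter cascades, and
quantifies how well two predictors agree with experimental affinity
measurements.

## Coordinate model

All internal coordinates are 0-based half-open; VCF positions are
converted on read, and written back 1-based. Chromosome names are
compared after stripping an optional `chr` prefix. CDS segments are
stored in ascending genomic order; the coding order of a minus-strand
transcript is the reverse complement of their concatenation.

A transcript's CDS is assumed to include the stop codon, so its
spliced length must equal `3*(P+1)` for a protein of `P` residues.
The assumption is self-checking: every loaded record is spliced and
translated, and must reproduce its stored protein followed by a stop.
Records without a terminal stop codon are rejected with a distinct
reason rather than silently repaired, since their coordinate
convention is unknowable from the data. Proteins shorter than three
residues are excluded and logged; an unknown chromosome aborts the
load, because it indicates mismatched inputs rather than one bad
record.

The C-terminal window covers spliced-CDS positions `[3(P-3), 3P)` —
exactly the nine nucleotides of the last three amino-acid codons,
never the stop codon (variants in the stop codon are a stop-loss
problem, out of scope). The window records, for each genomic position,
the 1-based codon index within the tripeptide (1 = third-from-last
residue), the offset within the codon, and the coding-strand base, so
a mutant codon can be rebuilt locally. A consistency check translates
the window directly off the genome and requires equality with the
protein's stored tail.

## Variant handling

Variant records are decomposed to one record per (site, alt) pair;
each such pair counts as one SNV. Non-SNV alleles are dropped and
counted. The same allele appearing in two call sets (exome and genome)
is merged into one record carrying both PASS flags; a variant is
quality-passing if it passed in *either* call set. Normalisation is
idempotent. A REF base that disagrees with the genome is a hard error
— a silent skip would corrupt downstream stage counts.

Consequence classification is local to the tripeptide: synonymous if
the mutant tripeptide equals the wild type, stop-gained if the mutant
codon is a stop, missense otherwise. Two SNVs in one codon are treated
independently (no phasing), matching how population catalogues report
them. Correctness of the local codon rebuild is established by a
property test against an independent oracle that rebuilds the entire
mutated chromosome, re-splices, and re-translates.

## PTS1 scoring

Scoring takes the last 12 residues — the tripeptide plus nine upstream
residues that modulate receptor binding — and sums one matrix entry
per position. Categories: score ≥ `t_targeted` → "Targeted";
`t_twilight` ≤ score < `t_targeted` → "Twilight zone"; else "Not
targeted". A score exactly at a threshold joins the higher category (a
deterministic, documented tie-break). Proteins shorter than 12
residues are rejected rather than padded: any padding scheme would be
an unverifiable invention.

The coefficients of the original published predictor are not public.
The matrix is therefore runtime configuration with a strict TSV
format. The package ships an all-zero placeholder and an *example*
matrix (consensus-style rewards at the last three positions,
thresholds 14/8) used by tests, examples and the synthetic-data
defaults. Published score differences are consumed as data in the
concordance statistics and are never claimed to be reproduced by the
example matrix.

## Candidate cascades

Both cascades are pure conjunctions of per-record (and one per-group)
predicates, so the retained set is independent of stage order; the
order is nonetheless fixed so the per-stage in/out counts — which
*are* order-sensitive — are reproducible. Every input record lands
exactly once in the retained list or the exclusion log (first failing
stage), and the counts telescope.

LoF stages: membership in a curated peroxisomal-protein gene list;
disease annotation; exclusively peroxisomal localisation (keyword
"Peroxisome" present and none of Secreted/Nucleus/Mitochondrion/
Endosome/Cytoplasm); variant quality; wild-type tripeptide canonical
while the mutant is not. The localisation stage can be bypassed per
gene via an explicit `manual_include` whitelist — a generalisation of
the one known case where the *mutant* form, not the native protein,
carries a second-compartment keyword — rather than hard-coding a gene
name.

GoF stages: variant quality; exclusively cytosolic localisation
(keyword "Cytoplasm" present, none of Secreted/Nucleus/Mitochondrion/
Endosome/Peroxisome); matrix category gain (mutant "Targeted" from
"Twilight zone" or "Not targeted"); one transcript per gene (the
longest, ties broken by lexicographically smallest transcript id);
protein length < 1000 residues and no transmembrane domain (both read
from annotations, not predicted).

Keyword matching is exact-token and case-insensitive, deliberately
stricter than free-text substring matching: "Cytoplasmic vesicle" must
not trigger the "Cytoplasm" rule. Isoforms without their own
annotation inherit the canonical transcript's; isoform-specific
annotations win. Records whose gene or protein lacks the needed
annotation fail the stage that needs it (reason "unannotated").

## Concordance statistics

The experimental summary is `log10(Ka_app_WT / Ka_app_MT)` from
FRET-derived apparent association strengths; positive = mutant binds
PEX5 more weakly. Ka values are kept on their printed 1e-6 scale
(ratios are scale-invariant). Non-analyzable fits are flagged `None`
and excluded pairwise, never zero-filled.

Pearson r uses the product-moment formula (via `scipy.stats.pearsonr`)
with the two-sided p-value from the t transform on n−2 degrees of
freedom; the 95% CI comes from the Fisher z transform with standard
error `1/sqrt(n-3)`. With only two planned correlations, no
multiple-testing correction is applied. A seeded simulation check
(1000 bivariate-normal draws, ρ = 0.7, n = 11) verifies ~95% CI
coverage.

Energy-change concordance uses a three-way rule with a ±0.5 kcal/mol
significance band: above +band predicts loss, below −band predicts
gain, inside the band predicts no change; a verdict is correct iff it
equals the observed outcome, and per-record verdicts are always
emitted for audit. Categorical predictor concordance ranks the three
categories and predicts the direction of the rank change. In the
packaged table the protein with weak native punctate staining is
labelled `no_change`, following the experimental accounting that
grouped it with the unchanged candidates. One row's printed log ratio
(the glycolipid-transfer protein) differs by ~0.006 from the value
recomputed from the rounded Ka columns — evidently computed from
unrounded inputs — so it is excluded from exact-reproduction checks
(tolerance widened to 0.01 in the round-trip test, and omitted from
the reproduction report).

## Synthetic data

The generator emulates the *structure* of population-scale mining
inputs — multi-exon CDS on both strands (1–4 exons, half the
transcripts on the minus strand), stop-terminated coding sequences,
PASS/fail variant quality flags, keyword localisation annotations —
not their content: allele frequencies are placeholders and no attempt
is made to match real allele-frequency spectra or mutational
signatures. Toy proteins are 40–200 residues on a single toy
chromosome with seeded intergenic and intronic spacers. Default
planted counts (6 LoF, 5 GoF) mirror the candidate pools selected for
experimental testing in the underlying study; three decoys per class
cover the synonymous, outside-window and failed-quality failure
modes, each violating exactly one rule. Codons for planted residues
are drawn uniformly among synonymous codons reachable by a single
substitution from the mutant codon, so every planted event is a true
SNV. Three independent seeded streams (geometry, coding sequence,
variant bookkeeping) derive from the master seed; identical config and
seed give byte-identical files.

Passing the planted-recovery tests therefore demonstrates coordinate,
strand and filter-logic correctness; it does not demonstrate
robustness to real-data messiness (annotation gaps, non-PASS filter
vocabulary, reference-genome mismatches), which the loaders surface as
explicit errors instead.

## Problem sizes

Test and reproduction runs are sized for a laptop-class machine: the
oracle-equivalence and window-identity suites use 500 random
transcripts per strand, the planted-recovery sweep uses 20 seeds with
the default 30-gene bundle, and the CI-coverage check uses 1000
draws. The full suite completes in a few seconds.

## Known limitations

- No selenocysteine recoding, CDS frameshift exceptions, or
  mitochondrial codon tables; only the 20 standard residues.
- Stop-loss variants and upstream-context modelling beyond the
  12-residue window are out of scope.
- The bundled example matrix is a teaching device; analyses of real
  data require a user-supplied matrix and thresholds.
- Pathogenicity annotations (ClinVar, PolyPhen-2, SIFT) are carried as
  pass-through strings only.
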