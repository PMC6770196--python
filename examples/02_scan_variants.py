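"""Map variants from a VCF onto C-terminal tripeptides.

Generates a small synthetic bundle (genome, transcripts, VCF), then
normalises the variants and intersects them with the tripeptide
windows to produce wild-type/mutant tripeptide pairs.
"""
import tempfile

from pts1scan import load_genome, load_transcripts, cterminal_codon_intervals
from pts1scan.simulate import SimulationConfig, generate_dataset
from pts1scan.variants import normalize_variants, read_vcf_alleles, scan_windows

with tempfile.TemporaryDirectory() as tmp:
    bundle = generate_dataset(SimulationConfig(seed=11), tmp)
    genome = load_genome(bundle.genome_fa)
    loaded = load_transcripts(str(bundle.transcripts_tsv), genome)
    windows = [cterminal_codon_intervals(t, genome) for t in loaded.records]

    raw = read_vcf_alleles(bundle.variants_vcf, call_set="exome")
    variants, stats = normalize_variants(raw)
    print(f"{stats.n_input_alleles} alleles read, "
          f"{stats.n_non_snv_dropped} non-SNV dropped")

    changes = scan_windows(variants, windows, genome)
    print(f"{len(changes)} missense tripeptide changes:")
    for c in changes[:8]:
        v = c.variant
        print(f"  {c.gene:6s} {v.chromosome}:{v.position + 1} {v.ref}>{v.alt} "
              f"{c.wt_tripeptide} -> {c.mt_tripeptide} (codon {c.codon_index})")

# Each line is one single-nucleotide variant rewriting one residue of
# a C-terminal tripeptide; codon 1 is the third-from-last residue.
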