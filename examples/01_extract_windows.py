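"""Locate the genomic footprint of a protein's last three codons.

Builds a two-exon transcript by hand, extracts the 9-nt window that
encodes the C-terminal tripeptide, and shows how the window splits
across an exon boundary.
"""
from pts1scan import TranscriptRecord, cterminal_codon_intervals, window_tripeptide

# CDS: ATG TCC AAG CTT TAA -> protein MSKL (+ stop), split into two
# exons with a 50-nt intron 4 nt before the stop codon.
cds = "ATGTCCAAGCTTTAA"
genome = {"1": "A" * 100 + cds[:11] + "G" * 50 + cds[11:] + "A" * 100}
transcript = TranscriptRecord(
    transcript_id="DEMO1", gene="DEMO", chromosome="1", strand="+",
    cds_segments=((100, 111), (161, 165)), protein_seq="MSKL",
)

window = cterminal_codon_intervals(transcript, genome)
print(f"tripeptide window intervals : {window.intervals}")
print(f"window length (nt)          : {sum(e - s for s, e in window.intervals)}")
print(f"translated window           : {window_tripeptide(window, genome)}")

# The intervals jointly cover exactly 9 nucleotides — the last three
# amino-acid codons, never the stop codon — and the translation must
# equal the protein's last three residues (here SKL, the classical
# peroxisomal targeting tripeptide).
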