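"""Score 12-residue C-termini with the example scoring matrix.

Shows consensus matching, matrix scores, category assignment, and the
mutant-minus-wild-type score difference for a gain-of-signal pair.
"""
from pts1scan import example_matrix, is_canonical_pts1, pssm_score, categorize, score_pair

matrix = example_matrix()

for tail in ("SKL", "AKL", "STL", "SNP", "SNL"):
    seq = "AAAAAAAAA" + tail   # 9 neutral upstream residues + tripeptide
    score = pssm_score(seq, matrix)
    print(f"...{tail}: consensus={str(is_canonical_pts1(tail)):5s} "
          f"score={score:5.1f}  category={categorize(score, matrix)}")

# A proline-to-leucine change at the last residue can create a signal:
res = score_pair("AAAAAAAAASNP", "AAAAAAAAASNL", matrix)
print(f"\nSNP -> SNL: {res.wt_category} -> {res.mt_category} "
      f"(score difference MT-WT = {res.score_difference:+.1f})")

# "Targeted" means the score clears the upper threshold: the protein
# is predicted to be imported into peroxisomes. The example matrix is
# a documented teaching device, not the published predictor's matrix.
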