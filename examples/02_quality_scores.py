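"""Position probability matrices and motif quality scores.

Builds a PPM from aligned SELEX-style winner sequences, scores motifs
under it, and shows the IUPAC-consensus construction.
"""

from rbpkit import ppm_from_iupac, ppm_from_winners, quality_score

# Four aligned winner sequences from a selection experiment
winners = ["UGCAUG", "UGCAUG", "UGCACG", "AGCAUG"]
ppm = ppm_from_winners(winners, matrix_id="demo")

print("PPM from", len(winners), "winners (rows = positions, cols = A C G U):")
for row in ppm.probs:
    print("  " + "  ".join(f"{p:.2f}" for p in row))

for motif in ("UGCAUG", "UGCACG", "AGCACG"):
    s = quality_score(motif, ppm)
    print(f"quality_score({motif}) = {s:.4f}")
# UGCAUG is the majority motif (3/4 at position 1 x 3/4 at position 5);
# rarer letter combinations multiply down accordingly.

single = ppm_from_winners(["ACGUA"])
print("single-winner motif scores", quality_score("ACGUA", single))
# Single-sequence experiments (EMSA, UV cross-linking) always score 1.0.

iupac_ppm = ppm_from_iupac("UGCAUGY")  # Y = C or U, equally likely
print("IUPAC matrix scores its own consensus:",
      quality_score("UGCAUGY", iupac_ppm))
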