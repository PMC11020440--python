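"""Column conservation and per-variant evolutionary scores from an MSA.

Builds a small alignment with one strongly conserved column and one
variable column, then prints the Conservation Index (CI), the log-odds
ratio (LOR) and the PROVEAN-style score (PVS) for two variants.
"""

import numpy as np

from varfit import (
    SubstitutionMatrix,
    Variant,
    conservation_profile,
    log_odds_ratio,
    provean_score,
    regularized_frequencies,
)
from varfit.alignment_features import MSA
from varfit.alphabet import encode_sequence

rows = [
    "ACDEF",   # query
    "ACDEF",
    "ACDEW",
    "ACNEF",
    "AVDEF",
    "ACDEY",
]
msa = MSA(ids=tuple(f"s{i}" for i in range(len(rows))),
          codes=np.vstack([encode_sequence(r) for r in rows]))

freq = regularized_frequencies(msa, theta=0.01)
ci = conservation_profile(freq)
print("per-column CI:", np.round(ci, 3))
print("  -> the invariant columns (1: always A, 4: always E) score highest;")
print("     high CI = column composition far from the alignment average\n")

matrix = SubstitutionMatrix.from_name("BLOSUM62")
for variant in (Variant(1, "A", "G"), Variant(5, "F", "W")):
    lor = log_odds_ratio(freq, variant)
    pvs = provean_score(msa, variant, matrix)
    print(f"{variant}: LOR = {lor:+.3f}, PVS = {pvs.value:+.3f}")
print("\nnegative LOR: the mutant residue is rarer than the wild-type at")
print("that column; negative PVS: homologs penalize the substitution.")
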