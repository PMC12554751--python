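"""From clone counts to a PSERM, on a tiny hand-checkable table.

Builds the count matrix for a single clone observed 8 times, converts it to
a pseudocounted probability matrix, a log2 scoring matrix against a 5%
uniform background, and finally the difference matrix between two rounds.
"""

import numpy as np
import pandas as pd

from psermkit import CloneTable, build_count_matrix, ppm_from_counts, \
    pserm, pssm_from_ppm
from psermkit.alphabet import AA_INDEX

clone = "SASFYYATYI"


def one_clone_table(round_label: str, n: int) -> CloneTable:
    counts = pd.DataFrame(
        {(round_label, 1): [n - n // 2], (round_label, 2): [n // 2]},
        index=pd.Index([clone], name="mutation_string"), dtype=np.int64,
    )
    counts.columns = pd.MultiIndex.from_tuples(counts.columns)
    return CloneTable(
        counts=counts,
        freqs=pd.DataFrame({round_label: [1.0]}, index=counts.index),
        totals={(round_label, 1): n - n // 2, (round_label, 2): n // 2},
        rounds=[round_label], replicates=[1, 2],
    )


cm = build_count_matrix(one_clone_table("R5", 8), "R5")
print(f"clone {clone}, 8 observations in R5")
print(f"count matrix entry for S at position 1: {cm.values[AA_INDEX['S'], 0]}")
print(f"total counts in the matrix: {cm.values.sum()} (= 8 obs x 10 positions)")

ppm = ppm_from_counts(cm)
print(f"\npseudocount sqrt(N) = sqrt(8) = {ppm.pseudocount:.4f}")
print(f"P(S at position 1) = (8 + 2.83) / (8 + 20*2.83) = "
      f"{ppm.values[AA_INDEX['S'], 0]:.4f}")
print(f"P(W at position 1) = {ppm.values[AA_INDEX['W'], 0]:.4f} "
      "(pseudocount only)")

pssm5 = pssm_from_ppm(ppm)  # 5% background
print(f"\nPSSM score of S at position 1: {pssm5.values[AA_INDEX['S'], 0]:+.3f} "
      "bits (log2 of P over the 5% background)")

# a second round where the clone was seen 24 times: 3x enrichment
pssm6 = pssm_from_ppm(ppm_from_counts(build_count_matrix(
    one_clone_table("R6", 24), "R6")))
diff = pserm(pssm6, pssm5)
print(f"\nPSERM (R6 - R5) entry for S at position 1: "
      f"{diff.values[AA_INDEX['S'], 0]:+.3f} bits")
print("positive entries mark residues enriched between rounds; the "
      "background cancels in the difference")
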