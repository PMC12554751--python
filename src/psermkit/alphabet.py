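"""Amino-acid alphabet, genetic-code helpers and NNK codon statistics.

The 20 canonical residues are kept in a fixed alphabetical one-letter order;
every matrix in :mod:`psermkit.matrices` indexes its rows by this order.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

#: Canonical residues, alphabetical one-letter codes. Row order of all matrices.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue -> row index.
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Codon -> residue for the standard genetic code (stop codons absent).
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)

STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: One deterministic codon per residue, used when synthesising reads.
AA_TO_CODON: dict[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def _nnk_frequencies() -> dict[str, float]:
    """Amino-acid marginals of the NNK degenerate codon (N=ACGT, K=GT).

    Of the 32 NNK codons exactly one (TAG) is a stop; it is excluded and the
    remaining 31 coding codons renormalised, so e.g. Leu/Arg/Ser each get 3/31
    and Met/Trp 1/31.
    """
    counts: dict[str, int] = {}
    for n1 in "ACGT":
        for n2 in "ACGT":
            for n3 in "GT":
                codon = n1 + n2 + n3
                if codon in STOP_CODONS:
                    continue
                aa = CODON_TO_AA[codon]
                counts[aa] = counts.get(aa, 0) + 1
    total = sum(counts.values())
    return {a: counts[a] / total for a in AMINO_ACIDS}


#: Residue proposal distribution produced by NNK saturation mutagenesis.
NNK_FREQUENCIES: dict[str, float] = _nnk_frequencies()


def is_canonical(seq: str) -> bool:
    """True if every character of *seq* is one of the 20 canonical residues."""
    return all(c in AA_INDEX for c in seq)
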