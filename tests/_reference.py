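"""Independent brute-force references used as oracles by the test suite.

Everything here is written with explicit loops (or routed through Biopython's
own translator), deliberately sharing no code path with the package
implementation it checks.
"""

from __future__ import annotations

import math
from collections import Counter

from Bio.Seq import Seq

AA = "ACDEFGHIKLMNPQRSTVWY"


def ref_translate(nt: str, offset: int, expected_codons: int | None = None):
    """Translate via Bio.Seq; reject on N codons / premature stops."""
    coding = nt.upper()[offset:]
    coding = coding[: 3 * (len(coding) // 3)]
    for i in range(0, len(coding), 3):
        if "N" in coding[i : i + 3]:
            return None  # any N codon rejects, even when Bio could resolve it
    aa = str(Seq(coding).translate())
    span = len(aa) if expected_codons is None else min(expected_codons, len(aa))
    stop = aa.find("*")
    if stop != -1 and stop < span:
        return None
    return aa if stop == -1 else aa[:stop]


def ref_pipeline(reads, offset, anchor, expected_length, positions,
                 max_mismatch=1) -> Counter:
    """Whole reads pipeline by hand-rules: translate, QC, slice, count."""
    counts: Counter[str] = Counter()
    for nt in reads:
        aa = ref_translate(nt, offset, expected_length)
        if aa is None or len(aa) != expected_length:
            continue
        mism = 0
        for i in range(6):
            if aa[i] != anchor[i]:
                mism += 1
        if mism > max_mismatch:
            continue
        counts["".join(aa[p] for p in positions)] += 1
    return counts


def ref_count_matrix(clone_counts: dict[str, int], length: int):
    """Residue-by-position counts as a dict of dicts."""
    m = {a: [0] * length for a in AA}
    for clone, n in clone_counts.items():
        for j, residue in enumerate(clone):
            m[residue][j] += n
    return m


def ref_ppm(count_m: dict[str, list[int]], n_total: int):
    pseudo = math.sqrt(n_total)
    denom = n_total + 20.0 * pseudo
    return {a: [(c + pseudo) / denom for c in row] for a, row in count_m.items()}


def ref_pssm(ppm: dict[str, list[float]], background: float):
    return {a: [math.log2(p / background) for p in row] for a, row in ppm.items()}


def ref_pserm(late: dict[str, list[float]], early: dict[str, list[float]]):
    return {a: [l - e for l, e in zip(late[a], early[a])] for a in late}


def ref_score(clone: str, matrix: dict[str, list[float]]) -> float:
    total = 0.0
    for j, residue in enumerate(clone):
        total += matrix[residue][j]
    return total
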