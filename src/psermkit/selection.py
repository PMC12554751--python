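"""Clone scoring, ranking and final selection.

A clone's PSERM score is the sum, over the L mutated positions, of the
matrix entry for its residue at that position — i.e. the summed per-site
log2 enrichment between the two rounds the PSERM compares. The selection
rule takes the clones ranked in the top K (default 40) under *both* PSERMs
and removes clones carrying an unpaired cysteine at a mutated position (a
developability liability: the scaffold's paired cysteines lie outside the
mutated sites, so any C in the mutation string is unpaired).

Comparator metrics for benchmarking: terminal-round frequency, the global
enrichment ratio log2(f_terminal / f_early) and the local enrichment ratio
log2(f_terminal / f_prior). Ratios with a zero numerator or denominator are
undefined and exclude the clone from that metric's ranking (no
pseudo-frequency is imputed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, is_canonical
from .errors import ConfigError, DataError
from .matrices import LogScoreMatrix
from .reads import CloneTable


def score_clone(mutation_string: str, matrix: LogScoreMatrix) -> float:
    """Sum the matrix entries of the clone's residues across all positions."""
    if len(mutation_string) != matrix.length:
        raise DataError(
            f"mutation string length {len(mutation_string)} != matrix "
            f"length {matrix.length}"
        )
    values = matrix.values
    return float(sum(values[AA_INDEX[c], j] for j, c in enumerate(mutation_string)))


def score_clones(clones: list[str], matrix: LogScoreMatrix) -> pd.Series:
    """Vectorised :func:`score_clone` over a clone list."""
    if not clones:
        return pd.Series(dtype=float)
    idx = np.array([[AA_INDEX[c] for c in s] for s in clones])
    if idx.shape[1] != matrix.length:
        raise DataError("mutation string length != matrix length")
    cols = np.arange(matrix.length)
    return pd.Series(matrix.values[idx, cols].sum(axis=1), index=clones)


def enrichment_metrics(
    table: CloneTable,
    terminal: str,
    early: str,
    prior: str,
    clones: list[str] | None = None,
) -> pd.DataFrame:
    """Terminal frequency plus global and local enrichment ratios per clone.

    Undefined ratios (zero frequency in numerator or denominator) are NaN.
    """
    for r in (terminal, early, prior):
        if r not in table.rounds:
            raise ConfigError(f"unknown round {r!r}")
    clones = list(table.clones) if clones is None else clones
    f_t = np.array([table.frequency(c, terminal) for c in clones])
    f_e = np.array([table.frequency(c, early) for c in clones])
    f_p = np.array([table.frequency(c, prior) for c in clones])
    with np.errstate(divide="ignore", invalid="ignore"):
        global_er = np.where((f_t > 0) & (f_e > 0), np.log2(f_t / f_e), np.nan)
        local_er = np.where((f_t > 0) & (f_p > 0), np.log2(f_t / f_p), np.nan)
    return pd.DataFrame(
        {"freq_terminal": f_t, "global_er": global_er, "local_er": local_er},
        index=pd.Index(clones, name="mutation_string"),
    )


def rank_top_k(
    scores: pd.Series,
    k: int = 40,
    exclude_wt: bool = False,
    wt_string: str | None = None,
) -> list[str]:
    """Top-k clones by descending score; deterministic lexicographic tie-break.

    Clones with an undefined (NaN) value are excluded from the ranking.
    """
    if k < 0:
        raise ConfigError("k must be non-negative")
    s = scores.dropna()
    if exclude_wt and wt_string is not None and wt_string in s.index:
        s = s.drop(wt_string)
    order = sorted(s.index, key=lambda c: (-s[c], c))
    return order[:k]


def overlap_selection(top_a: list[str] | set, top_b: list[str] | set) -> set[str]:
    """Clones ranked in the top K under both matrices."""
    return set(top_a) & set(top_b)


def cysteine_filter(clones: set[str] | list[str]) -> tuple[set[str], set[str]]:
    """Split clones into (kept, removed) by unpaired cysteine at a mutated site."""
    clones = set(clones)
    removed = {c for c in clones if "C" in c}
    return clones - removed, removed


@dataclass
class SelectionReport:
    """Ranked scores, top-K sets, their overlap, and the cysteine outcome."""

    scores: pd.DataFrame  # per clone: one column per metric
    top_k: dict[str, list[str]]  # metric -> ordered top-k clones
    overlap: set[str]
    removed_for_cysteine: set[str]
    final: set[str]
    k: int
    exclude_wt: bool
    wt_string: str | None = None
    pserm_metrics: tuple[str, str] | None = None

    def to_tsv(self, path: str | Path) -> None:
        out = self.scores.copy()
        for metric, top in self.top_k.items():
            rank = {c: i + 1 for i, c in enumerate(top)}
            out[f"rank_{metric}"] = [rank.get(c, np.nan) for c in out.index]
        out["in_overlap"] = [c in self.overlap for c in out.index]
        out["removed_cysteine"] = [c in self.removed_for_cysteine for c in out.index]
        out["selected"] = [c in self.final for c in out.index]
        out.to_csv(path, sep="\t", index_label="mutation_string",
                   float_format="%.17g")

    def summary(self) -> dict:
        return {
            "k": self.k,
            "exclude_wt": self.exclude_wt,
            "wt_string": self.wt_string,
            "pserm_metrics": list(self.pserm_metrics or ()),
            "n_scored": int(len(self.scores)),
            "top_k": {m: list(t) for m, t in self.top_k.items()},
            "overlap": sorted(self.overlap),
            "removed_for_cysteine": sorted(self.removed_for_cysteine),
            "final": sorted(self.final),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def select_clones(
    table: CloneTable,
    pserms: dict[str, LogScoreMatrix],
    k: int = 40,
    exclude_wt: bool = True,
    comparator_rounds: tuple[str, str, str] | None = None,
    clones: list[str] | None = None,
) -> SelectionReport:
    """Score, rank and select clones: top-K overlap of two PSERMs minus cysteines.

    ``pserms`` must contain exactly two matrices (the overlap rule is a
    two-matrix intersection). ``clones`` restricts scoring to a subset of the
    table — typically the stricter replicate-common set — while the matrices
    themselves may come from the permissive set. ``comparator_rounds`` is
    (terminal, early, prior) and adds the frequency/enrichment-ratio columns.
    """
    if len(pserms) != 2:
        raise ConfigError(f"selection needs exactly 2 PSERMs, got {len(pserms)}")
    clones = list(table.clones) if clones is None else list(clones)
    scores = pd.DataFrame(index=pd.Index(clones, name="mutation_string"))
    for name, matrix in pserms.items():
        scores[name] = score_clones(clones, matrix)
    if comparator_rounds is not None:
        terminal, early, prior = comparator_rounds
        scores = scores.join(enrichment_metrics(table, terminal, early, prior, clones))

    top_k = {
        m: rank_top_k(scores[m], k, exclude_wt=exclude_wt, wt_string=table.wt_string)
        for m in scores.columns
    }
    name_a, name_b = list(pserms)
    overlap = overlap_selection(top_k[name_a], top_k[name_b])
    kept, removed = cysteine_filter(overlap)
    return SelectionReport(
        scores=scores,
        top_k=top_k,
        overlap=overlap,
        removed_for_cysteine=removed,
        final=kept,
        k=k,
        exclude_wt=exclude_wt,
        wt_string=table.wt_string,
        pserm_metrics=(name_a, name_b),
    )


# ---------------------------------------------------------------------------
# CDR net charge


#: Side-chain pKa values used by default for the Henderson–Hasselbalch sum.
DEFAULT_PKA: dict[str, float] = {
    "D": 3.65, "E": 4.25, "H": 6.00, "C": 8.30,
    "Y": 10.07, "K": 10.53, "R": 12.48,
}

_BASIC = frozenset("RKH")


@dataclass
class ChargeModel:
    """pH and pKa table for sequence net-charge calculation.

    Termini are excluded by default: CDR fragments are internal stretches of
    the antibody chain, not free peptides.
    """

    pH: float = 7.4
    pka: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))
    include_termini: bool = False
    n_term_pka: float = 9.0
    c_term_pka: float = 2.0

    def __post_init__(self) -> None:
        bad = {a: v for a, v in self.pka.items() if not 0.0 < v < 14.0}
        if bad:
            raise ConfigError(f"pKa values outside (0, 14): {bad}")


def net_charge(seq: str, model: ChargeModel | None = None) -> float:
    """Henderson–Hasselbalch net charge of a sequence, in elementary charges.

    Basic groups (R, K, H) contribute +1/(1 + 10^(pH - pKa)); acidic groups
    (D, E, C, Y) contribute -1/(1 + 10^(pKa - pH)).
    """
    if model is None:
        model = ChargeModel()
    if not seq:
        raise DataError("empty sequence")
    if not is_canonical(seq):
        raise DataError(f"non-canonical residue in {seq!r}")
    charge = 0.0
    for residue in seq:
        pka = model.pka.get(residue)
        if pka is None:
            continue
        if residue in _BASIC:
            charge += 1.0 / (1.0 + 10.0 ** (model.pH - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - model.pH))
    if model.include_termini:
        charge += 1.0 / (1.0 + 10.0 ** (model.pH - model.n_term_pka))
        charge -= 1.0 / (1.0 + 10.0 ** (model.c_term_pka - model.pH))
    return charge
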