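"""Position-specific scoring matrices from round-level clone counts.

Four matrix flavours, all 20 residues x L positions with rows in the fixed
alphabetical residue order of :data:`psermkit.alphabet.AMINO_ACIDS`:

* **count matrix** — each clone contributes its round observations to the
  cell of its residue at every position;
* **PPM** (position probability matrix) — counts plus a pseudocount of
  sqrt(N) in every cell, normalised per position (N is the total number of
  observations in the round);
* **PSSM** — log2(PPM / b) against a uniform background b (default 5%), in
  bits;
* **PSERM** (position-specific enrichment ratio matrix) — the elementwise
  difference of the PSSMs of two consecutive sorting rounds. The background
  cancels, so a PSERM cell equals log2(p_late / p_early): the per-residue
  enrichment between rounds, in bits.

PSERMs exist because a dominant wild-type clone (~90-95% of reads per round
here) pins the largest PSSM score at every position to the wild-type
residue; differencing consecutive rounds removes that static component and
leaves the round-to-round enrichment signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS
from .errors import ConfigError, DataError
from .reads import CloneTable

DEFAULT_BACKGROUND = 0.05


def _frame(values: np.ndarray, length: int) -> pd.DataFrame:
    return pd.DataFrame(
        values,
        index=pd.Index(list(AMINO_ACIDS), name="residue"),
        columns=pd.RangeIndex(1, length + 1, name="position"),
    )


@dataclass
class CountMatrix:
    """Residue-by-position observation counts for one round."""

    values: np.ndarray  # (20, L) int64
    round_label: str
    n_total: int  # total observations in the round

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return _frame(self.values, self.length)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind=counts\n# round={self.round_label}\n"
                     f"# n_total={self.n_total}\n")
            self.to_frame().to_csv(fh, sep="\t")


@dataclass
class ProbMatrix:
    """Pseudocounted position probability matrix (columns sum to one)."""

    values: np.ndarray  # (20, L) float
    round_label: str
    pseudocount: float

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return _frame(self.values, self.length)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind=ppm\n# round={self.round_label}\n"
                     f"# pseudocount={self.pseudocount!r}\n")
            self.to_frame().to_csv(fh, sep="\t", float_format="%.17g")


@dataclass
class LogScoreMatrix:
    """Log-score matrix in bits: a round PSSM or a round-difference PSERM."""

    values: np.ndarray  # (20, L) float
    kind: str  # "pssm" | "pserm"
    background: float
    round_label: str | None = None  # pssm provenance
    round_pair: tuple[str, str] | None = None  # pserm provenance (late, early)

    @property
    def length(self) -> int:
        return self.values.shape[1]

    @property
    def label(self) -> str:
        if self.kind == "pssm":
            return f"pssm_{self.round_label}"
        late, early = self.round_pair  # type: ignore[misc]
        return f"pserm_{late}-{early}"

    def to_frame(self) -> pd.DataFrame:
        return _frame(self.values, self.length)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kind={self.kind}\n# label={self.label}\n"
                     f"# background={self.background!r}\n")
            self.to_frame().to_csv(fh, sep="\t", float_format="%.17g")


def build_count_matrix(
    table: CloneTable, round_label: str, exclude_wt: bool = False
) -> CountMatrix:
    """Tally residue observations per position from a round's clone counts.

    Round observations are the replicate-summed counts of each clone (the
    matrices need integers; replicate-averaged frequencies are reserved for
    the clone-level comparator metrics). An empty table gives a valid
    all-zero matrix with N = 0.
    """
    if round_label not in table.rounds:
        raise ConfigError(f"unknown round {round_label!r}")
    counts = table.round_counts(round_label)
    if exclude_wt and table.wt_string in counts.index:
        counts = counts.drop(table.wt_string)
    if len(counts) == 0:
        return CountMatrix(np.zeros((20, 0), dtype=np.int64), round_label, 0)
    lengths = {len(s) for s in counts.index}
    if len(lengths) != 1:
        raise DataError(f"mixed mutation-string lengths {sorted(lengths)}")
    (length,) = lengths
    values = np.zeros((20, length), dtype=np.int64)
    for clone, n in counts.items():
        if n == 0:
            continue
        for j, residue in enumerate(clone):
            values[AA_INDEX[residue], j] += n
    return CountMatrix(values, round_label, int(counts.sum()))


def ppm_from_counts(counts: CountMatrix) -> ProbMatrix:
    """Pseudocount and normalise a count matrix.

    The pseudocount is sqrt(N), N being the total observations in the round,
    added to every cell; each position is then normalised by N + 20*sqrt(N).
    All entries are strictly positive, so downstream log-scores are finite.
    """
    if counts.n_total <= 0:
        raise DataError("cannot build a PPM for a round with zero observations")
    pseudo = math.sqrt(counts.n_total)
    values = (counts.values + pseudo) / (counts.n_total + 20.0 * pseudo)
    return ProbMatrix(values, counts.round_label, pseudo)


def pssm_from_ppm(
    ppm: ProbMatrix, background: float = DEFAULT_BACKGROUND
) -> LogScoreMatrix:
    """log2(PPM / b) in bits; zero exactly where the PPM equals the background."""
    if not 0.0 < background < 1.0:
        raise ConfigError(f"background must be in (0, 1), got {background}")
    if np.any(ppm.values <= 0.0):
        raise DataError("PPM has non-positive entries; cannot take log2")
    values = np.log2(ppm.values / background)
    return LogScoreMatrix(values, "pssm", background, round_label=ppm.round_label)


def pserm(late: LogScoreMatrix, early: LogScoreMatrix) -> LogScoreMatrix:
    """Difference of two consecutive-round PSSMs (late minus early).

    The shared background cancels: the result is log2(p_late / p_early)
    regardless of b.
    """
    if late.kind != "pssm" or early.kind != "pssm":
        raise ConfigError("pserm inputs must both be PSSMs")
    if late.values.shape != early.values.shape:
        raise ConfigError("PSSM dimension mismatch")
    if late.background != early.background:
        raise ConfigError("PSSM background mismatch")
    return LogScoreMatrix(
        late.values - early.values,
        "pserm",
        late.background,
        round_pair=(late.round_label, early.round_label),  # type: ignore[arg-type]
    )


def pserms_for_rounds(
    table: CloneTable,
    round_pairs: list[tuple[str, str]],
    background: float = DEFAULT_BACKGROUND,
    exclude_wt: bool = False,
) -> dict[str, LogScoreMatrix]:
    """Build the PSERMs for the given (late, early) round pairs from one table."""
    needed = sorted({r for pair in round_pairs for r in pair})
    pssms = {
        r: pssm_from_ppm(
            ppm_from_counts(build_count_matrix(table, r, exclude_wt=exclude_wt)),
            background,
        )
        for r in needed
    }
    return {
        f"pserm_{late}-{early}": pserm(pssms[late], pssms[early])
        for late, early in round_pairs
    }
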