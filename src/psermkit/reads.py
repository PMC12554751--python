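"""From merged amplicon reads to a replicate-merged clone table.

The pipeline stage implemented here turns merged nucleotide reads (one FASTQ
or FASTA file per sorting round and sequencing replicate) into counts of
*mutation strings* — the concatenated residues at the L mutagenised CDR
positions, which serve as the clone identifier — and then merges the
replicate tallies into a single :class:`CloneTable`.

Quality control mirrors the study design it supports: a read is translated
from a per-sample reading-frame offset, kept only if the translated sequence
has the expected amino-acid length and begins with the expected six-residue
anchor (at most one mismatch tolerated), and then reduced to its mutation
string. Reads containing an ``N`` codon or a premature stop are rejected
before QC since they cannot yield a valid mutation string.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .alphabet import CODON_TO_AA, STOP_CODONS, is_canonical
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """A single merged nucleotide read with its sample annotations.

    ``frame_offset`` is the per-sample single-base shift introduced during
    library preparation to decrease sequence homology on the flow cell; the
    coding frame starts at this offset.
    """

    id: str
    nucleotides: str
    round_label: str
    replicate: int
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise DataError(f"read {self.id!r}: empty sequence")
        if self.replicate < 1:
            raise ConfigError(f"read {self.id!r}: replicate must be >= 1")


def translate_read(
    nucleotides: str,
    frame_offset: int = 0,
    expected_codons: int | None = None,
) -> str | None:
    """Translate the maximal in-frame prefix starting at ``frame_offset``.

    Returns the amino-acid sequence, or ``None`` when the read is rejected:
    a codon containing ``N`` anywhere, or a stop codon within the expected
    coding span (the whole read if ``expected_codons`` is not given), makes
    a valid mutation string impossible.

    Raises
    ------
    DataError
        If the sequence contains a symbol other than A, C, G, T, N, or is
        too short to yield a single codon after the offset.
    """
    if not 0 <= frame_offset < 3:
        raise ConfigError(f"frame_offset must be in 0..2, got {frame_offset}")
    seq = nucleotides.upper()
    if not _NUCLEOTIDES.issuperset(seq):
        bad = sorted(set(seq) - _NUCLEOTIDES)
        raise DataError(f"unknown nucleotide symbol(s) {bad}")
    coding = seq[frame_offset:]
    if len(coding) < 3:
        raise DataError("read too short to contain a codon after frame offset")
    n_codons = len(coding) // 3
    span = n_codons if expected_codons is None else min(expected_codons, n_codons)
    residues: list[str] = []
    for i in range(n_codons):
        codon = coding[3 * i : 3 * i + 3]
        if "N" in codon:
            return None
        if codon in STOP_CODONS:
            if i < span:
                return None  # premature stop inside the expected coding span
            break
        residues.append(CODON_TO_AA[codon])
    return "".join(residues)


def qc_filter(
    aa_seq: str, expected_length: int, anchor: str, max_mismatch: int = 1
) -> bool:
    """Keep a translated read iff it has the expected length and anchor.

    The anchor is the first six residues of the amplicon; up to
    ``max_mismatch`` substitutions within those six positions are tolerated.
    The remainder of the read is not compared to any template.
    """
    if len(anchor) != 6:
        raise ConfigError(f"anchor must be 6 residues, got {len(anchor)}")
    if expected_length < 6:
        raise ConfigError("expected_length must be >= 6")
    if len(aa_seq) != expected_length:
        return False
    mismatches = sum(a != b for a, b in zip(aa_seq[:6], anchor))
    return mismatches <= max_mismatch


def extract_mutation_string(aa_seq: str, positions: list[int]) -> str:
    """Concatenate the residues at the given 0-based positions, in order."""
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ConfigError("positions must be strictly increasing")
    if positions and positions[-1] >= len(aa_seq):
        raise IndexError(
            f"position {positions[-1]} out of range for length {len(aa_seq)}"
        )
    return "".join(aa_seq[p] for p in positions)


def tally(strings: Iterable[str]) -> Counter[str]:
    """Exact multiset counts of mutation strings (all must share one length)."""
    counts: Counter[str] = Counter(strings)
    lengths = {len(s) for s in counts}
    if len(lengths) > 1:
        raise DataError(f"mixed mutation-string lengths: {sorted(lengths)}")
    return counts


# ---------------------------------------------------------------------------
# sample processing


@dataclass
class QCStats:
    """Read-attrition bookkeeping for one (round, replicate) sample."""

    seen: int = 0
    rejected_translation: int = 0  # N codon or premature stop
    rejected_qc: int = 0  # wrong length or anchor
    kept: int = 0


@dataclass(frozen=True)
class SampleSpec:
    path: Path
    round_label: str
    replicate: int
    frame_offset: int = 0


@dataclass
class ReadManifest:
    """Amplicon layout plus the per-sample file list.

    ``positions`` are 0-based indices into the *translated* amplicon; mapping
    from CDR site names (Kabat-style) to read coordinates is configuration,
    not code.
    """

    anchor: str
    expected_length: int
    positions: list[int]
    rounds: list[str]
    samples: list[SampleSpec]
    wt_string: str | None = None
    max_anchor_mismatch: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ReadManifest":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            samples = [
                SampleSpec(
                    path=(path.parent / s["path"]).resolve(),
                    round_label=str(s["round"]),
                    replicate=int(s["replicate"]),
                    frame_offset=int(s.get("frame_offset", 0)),
                )
                for s in raw["samples"]
            ]
            manifest = cls(
                anchor=raw["anchor"],
                expected_length=int(raw["expected_length"]),
                positions=[int(p) for p in raw["positions"]],
                rounds=[str(r) for r in raw["rounds"]],
                samples=samples,
                wt_string=raw.get("wt_string"),
                max_anchor_mismatch=int(raw.get("max_anchor_mismatch", 1)),
            )
        except KeyError as exc:
            raise ConfigError(f"manifest {path}: missing key {exc}") from exc
        unknown = {s.round_label for s in manifest.samples} - set(manifest.rounds)
        if unknown:
            raise ConfigError(f"manifest samples use undeclared rounds {unknown}")
        return manifest


def iter_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTA or FASTQ, plain or gzipped."""
    path = Path(path)
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        if name.endswith((".fastq", ".fq")):
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq
        else:
            for title, seq in SimpleFastaParser(fh):
                yield title.split()[0], seq


def tally_reads(
    sequences: Iterable[str],
    *,
    frame_offset: int,
    anchor: str,
    expected_length: int,
    positions: list[int],
    max_anchor_mismatch: int = 1,
) -> tuple[Counter[str], QCStats]:
    """Run translate → QC → extract → count over a stream of reads.

    Amplicon libraries are dominated by a handful of distinct sequences, so
    the per-read outcome is memoised on the nucleotide string.
    """
    stats = QCStats()
    counts: Counter[str] = Counter()
    # outcome cache: nucleotides -> ("kept", mutation_string) | rejection tag
    cache: dict[str, tuple[str, str]] = {}
    for seq in sequences:
        stats.seen += 1
        outcome = cache.get(seq)
        if outcome is None:
            aa = translate_read(seq, frame_offset, expected_codons=expected_length)
            if aa is None:
                outcome = ("rejected_translation", "")
            elif not qc_filter(aa, expected_length, anchor, max_anchor_mismatch):
                outcome = ("rejected_qc", "")
            else:
                outcome = ("kept", extract_mutation_string(aa, positions))
            cache[seq] = outcome
        tag, mutation_string = outcome
        if tag == "kept":
            stats.kept += 1
            counts[mutation_string] += 1
        elif tag == "rejected_translation":
            stats.rejected_translation += 1
        else:
            stats.rejected_qc += 1
    return counts, stats


def tally_manifest(
    manifest: ReadManifest,
) -> tuple[dict[tuple[str, int], Counter[str]], dict[tuple[str, int], QCStats]]:
    """Tally every sample file declared in a manifest."""
    tallies: dict[tuple[str, int], Counter[str]] = {}
    all_stats: dict[tuple[str, int], QCStats] = {}
    for sample in manifest.samples:
        key = (sample.round_label, sample.replicate)
        if key in tallies:
            raise ConfigError(f"duplicate sample for round/replicate {key}")
        counts, stats = tally_reads(
            (seq for _id, seq in iter_sequences(sample.path)),
            frame_offset=sample.frame_offset,
            anchor=manifest.anchor,
            expected_length=manifest.expected_length,
            positions=manifest.positions,
            max_anchor_mismatch=manifest.max_anchor_mismatch,
        )
        logger.info(
            "sample %s rep %d: %d reads seen, %d rejected (translation), "
            "%d rejected (length/anchor), %d kept, %d unique clones",
            sample.round_label, sample.replicate, stats.seen,
            stats.rejected_translation, stats.rejected_qc, stats.kept,
            len(counts),
        )
        tallies[key] = counts
        all_stats[key] = stats
    return tallies, all_stats


# ---------------------------------------------------------------------------
# the clone table


@dataclass
class CloneTable:
    """Per-round, per-replicate clone counts with replicate-averaged frequencies.

    ``counts`` is indexed by mutation string with one integer column per
    (round, replicate); ``freqs`` holds f_{i,r}, the mean over replicates of
    the per-replicate frequency n_{i,r,k} / N_{r,k}, where N_{r,k} is the
    total of QC-passing reads in that replicate (absent observations count
    as zero). Rows are ordered by descending terminal-round frequency, ties
    broken lexicographically.
    """

    counts: pd.DataFrame  # MultiIndex columns (round, replicate)
    freqs: pd.DataFrame  # columns = rounds
    totals: dict[tuple[str, int], int]  # N_{r,k}: all QC-passing reads
    rounds: list[str]
    replicates: list[int]
    wt_string: str | None = None

    @property
    def clones(self) -> list[str]:
        return list(self.counts.index)

    def frequency(self, clone: str, round_label: str) -> float:
        """f_{i,r}; zero for clones absent from the table."""
        if clone not in self.freqs.index:
            return 0.0
        return float(self.freqs.at[clone, round_label])

    def round_counts(self, round_label: str) -> pd.Series:
        """Replicate-summed integer counts for one round."""
        if round_label not in self.rounds:
            raise ConfigError(f"unknown round {round_label!r}")
        return self.counts[round_label].sum(axis=1)

    # -- serialisation ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        flat = pd.DataFrame(index=self.counts.index)
        for r in self.rounds:
            for k in self.replicates:
                flat[f"n_{r}_{k}"] = self.counts[(r, k)]
        for r in self.rounds:
            flat[f"f_{r}"] = self.freqs[r]
        with open(path, "w") as fh:
            fh.write(f"# wt_string={self.wt_string or ''}\n")
            fh.write(f"# rounds={','.join(self.rounds)}\n")
            fh.write(f"# replicates={','.join(map(str, self.replicates))}\n")
            for (r, k), n in self.totals.items():
                fh.write(f"# total_{r}_{k}={n}\n")
            flat.to_csv(fh, sep="\t", index_label="mutation_string",
                        float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CloneTable":
        import io

        meta: dict[str, str] = {}
        lines = Path(path).read_text().splitlines(keepends=True)
        n_header = 0
        for line in lines:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            n_header += 1
        flat = pd.read_csv(
            io.StringIO("".join(lines[n_header:])), sep="\t",
            index_col="mutation_string",
        )
        rounds = meta["rounds"].split(",")
        replicates = [int(k) for k in meta["replicates"].split(",")]
        totals = {
            (r, k): int(meta[f"total_{r}_{k}"]) for r in rounds for k in replicates
        }
        counts = pd.DataFrame(
            {(r, k): flat[f"n_{r}_{k}"].astype(np.int64)
             for r in rounds for k in replicates}
        )
        counts.columns = pd.MultiIndex.from_tuples(counts.columns)
        freqs = pd.DataFrame({r: flat[f"f_{r}"] for r in rounds})
        return cls(
            counts=counts, freqs=freqs, totals=totals, rounds=rounds,
            replicates=replicates, wt_string=meta.get("wt_string") or None,
        )


def merge_replicates(
    tallies: Mapping[tuple[str, int], Mapping[str, int]],
    rounds: list[str],
    mode: str = "common-any-round",
    required_rounds: Iterable[str] | None = None,
    allow_absent_rounds: Iterable[str] | None = None,
    wt_string: str | None = None,
) -> CloneTable:
    """Merge per-replicate tallies into a CloneTable under a replicate filter.

    Two filters are selectable:

    ``common-any-round``
        keep clones present in *all* replicates of at least one round — the
        permissive set used to build the scoring matrices;
    ``common-required-rounds``
        keep clones present in all replicates of *every* round listed in
        ``required_rounds``, regardless of presence in ``allow_absent_rounds``
        — the stricter set that is actually scored and ranked.

    Frequencies of kept clones are averaged across replicates with absent
    (round, replicate) observations contributing zero; denominators are the
    per-replicate totals of QC-passing reads.
    """
    replicates = sorted({k for _, k in tallies})
    for r in rounds:
        present = [k for k in replicates if (r, k) in tallies]
        if len(present) < 2:
            raise ConfigError(
                f"round {r!r} has {len(present)} replicate(s); need >= 2"
            )
    if mode not in ("common-any-round", "common-required-rounds"):
        raise ConfigError(f"unknown replicate-filter mode {mode!r}")

    per_round_common: dict[str, set[str]] = {}
    for r in rounds:
        sets = [
            {c for c, n in tallies[(r, k)].items() if n > 0}
            for k in replicates
            if (r, k) in tallies
        ]
        per_round_common[r] = set.intersection(*sets) if sets else set()

    if mode == "common-any-round":
        kept: set[str] = set().union(*per_round_common.values())
    else:
        required = list(required_rounds or [])
        if not required:
            raise ConfigError("common-required-rounds mode needs required_rounds")
        missing = set(required) - set(rounds)
        if missing:
            raise ConfigError(f"required_rounds not among rounds: {sorted(missing)}")
        kept = set.intersection(*(per_round_common[r] for r in required))

    totals = {key: sum(t.values()) for key, t in tallies.items()}
    clone_list = sorted(kept)
    counts = pd.DataFrame(
        {
            (r, k): [tallies.get((r, k), {}).get(c, 0) for c in clone_list]
            for r in rounds
            for k in replicates
        },
        index=pd.Index(clone_list, name="mutation_string"),
        dtype=np.int64,
    )
    counts.columns = pd.MultiIndex.from_tuples(counts.columns)
    freqs = pd.DataFrame(index=counts.index, dtype=float)
    for r in rounds:
        reps = [k for k in replicates if (r, k) in tallies]
        per_rep = [counts[(r, k)] / totals[(r, k)] if totals[(r, k)] > 0
                   else counts[(r, k)] * 0.0 for k in reps]
        freqs[r] = sum(per_rep) / len(reps)

    table = CloneTable(
        counts=counts, freqs=freqs, totals=totals, rounds=rounds,
        replicates=replicates, wt_string=wt_string,
    )
    _sort_rows(table)
    logger.info(
        "merge_replicates(%s): %d clones kept from %d tallied samples",
        mode, len(clone_list), len(tallies),
    )
    return table


def _sort_rows(table: CloneTable) -> None:
    """Deterministic row order: descending terminal-round frequency, then name."""
    terminal = table.rounds[-1]
    order = sorted(
        table.freqs.index, key=lambda c: (-table.freqs.at[c, terminal], c)
    )
    table.counts = table.counts.loc[order]
    table.freqs = table.freqs.loc[order]
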