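"""Synthetic directed-evolution sorting campaigns with ground truth.

The generator emulates the data-generating process the analysis pipeline
consumes: an NNK-mutagenised antibody library displayed on yeast, enriched
over several sorting rounds of increasing stringency, and deep-sequenced in
duplicate at finite depth.

Model
-----
* **Library.** A wild-type clone dominating the pool (default 92%), plus
  thousands of distinct variants whose residues at the L mutated positions
  are drawn from the NNK codon amino-acid marginals. The residual mass is
  spread over variants by a symmetric Dirichlet draw with small
  concentration, producing the long tail of rare clones (down to
  ~1e-5..1e-6) characteristic of such libraries.
* **Fitness.** Latent binding fitness is additive on the log scale:
  w(s) = exp(sum_j e[s_j, j]) with wild-type residues fixed at effect 0, so
  w(WT) = 1. Effects default to Normal(-0.05, 0.3) — most mutations mildly
  deleterious, a minority beneficial — which holds the dominant wild type
  inside the 0.90–0.95 per-round frequency band under the default
  selection strengths.
* **Selection.** Each sorting round reweights the pool deterministically,
  f'(s) ∝ f(s) · w(s)^beta, with per-round selection strength beta; more
  stringent washes in late rounds are represented by larger beta. A sorting
  round captures only a finite number of cells (~0.1–2.5% of the 1e7 cells
  sorted), so the reweighted pool is then resampled through a multinomial
  bottleneck (default 1e5 cells; rare clones can go extinct). Both
  sequencing replicates observe the same post-bottleneck culture, as in the
  experiment.
* **Sequencing.** Each replicate is an independent multinomial draw of D
  reads from the post-selection pool; reads can optionally be emitted as
  FASTQ (anchor + scaffold + mutation-string codons) so the reads module can
  consume them end-to-end, with an optional per-base substitution error rate
  to stress the QC filter.

Everything is driven by a single integer seed; identical seed and config
give bit-identical output.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from .alphabet import AA_INDEX, AA_TO_CODON, AMINO_ACIDS, NNK_FREQUENCIES
from .errors import ConfigError, DataError
from .matrices import pserms_for_rounds
from .reads import CloneTable, merge_replicates
from .selection import SelectionReport, select_clones

logger = logging.getLogger(__name__)

#: Default per-round selection strengths: the sequenced rounds of a
#: five-round campaign with increasing stringency.
DEFAULT_ROUNDS: tuple[tuple[str, float], ...] = (
    ("R2", 0.10), ("R3", 0.15), ("R5", 0.20), ("R6", 0.25), ("R7", 0.30),
)

DEFAULT_WT = "GFTFSSYAMS"


@dataclass
class FitnessLandscape:
    """Additive per-position fitness effects; wild-type residues are zero."""

    effects: np.ndarray  # (20, L)
    wt_string: str

    def __post_init__(self) -> None:
        if self.effects.shape != (20, len(self.wt_string)):
            raise ConfigError("effects must be 20 x len(wt_string)")

    @classmethod
    def random(
        cls,
        wt_string: str,
        rng: np.random.Generator,
        effect_mean: float = -0.05,
        effect_sd: float = 0.3,
    ) -> "FitnessLandscape":
        effects = rng.normal(effect_mean, effect_sd, size=(20, len(wt_string)))
        for j, residue in enumerate(wt_string):
            effects[AA_INDEX[residue], j] = 0.0
        return cls(effects, wt_string)

    def log_fitness(self, clones: list[str]) -> np.ndarray:
        idx = np.array([[AA_INDEX[c] for c in s] for s in clones])
        cols = np.arange(idx.shape[1])
        return self.effects[idx, cols].sum(axis=1)

    def fitness(self, clone: str) -> float:
        return float(np.exp(self.log_fitness([clone])[0]))


@dataclass
class SimConfig:
    """Campaign parameters; the defaults describe the study conditions."""

    wt_string: str = DEFAULT_WT
    n_variants: int = 5000
    wt_fraction_initial: float = 0.92
    rounds: tuple[tuple[str, float], ...] = DEFAULT_ROUNDS
    depth: int = 1_000_000
    replicates: int = 2
    dirichlet_alpha: float = 0.3
    bottleneck: int | None = 100_000  # cells captured per sorting round
    effect_mean: float = -0.05
    effect_sd: float = 0.3
    fitness_noise_sd: float = 0.0
    seed: int = 0

    @property
    def length(self) -> int:
        return len(self.wt_string)

    @property
    def round_labels(self) -> list[str]:
        return [r for r, _ in self.rounds]

    def __post_init__(self) -> None:
        if not 0.0 < self.wt_fraction_initial <= 1.0:
            raise ConfigError("wt_fraction_initial must be in (0, 1]")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.bottleneck is not None and self.bottleneck < 1:
            raise ConfigError("bottleneck must be >= 1 or None")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if any(beta < 0 for _, beta in self.rounds):
            raise ConfigError("selection strengths must be >= 0")


@dataclass
class SimOutput:
    """Ground truth and sequenced observations of one synthetic campaign."""

    clones: list[str]  # wild type first
    fitness: pd.Series  # true fitness w(s) per clone
    landscape: FitnessLandscape
    pool_freqs: pd.DataFrame  # true post-selection frequencies, one col per round
    tallies: dict[tuple[str, int], Counter]
    table: CloneTable  # replicate-merged sequenced counts
    config: SimConfig


def make_library(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Draw the initial pool: clone strings and their frequencies (WT first).

    Variant residues are sampled per position from the NNK amino-acid
    marginals; duplicate draws and re-draws of the wild type are discarded
    until ``n_variants`` distinct variants exist. Variant mass is a
    symmetric Dirichlet split of 1 - wt_fraction.
    """
    L = config.length
    capacity = 31**L  # NNK encodes 31 coding codons per position
    if config.n_variants > capacity // 2:
        raise ConfigError(f"n_variants {config.n_variants} exceeds library capacity")
    residues = np.array(list(AMINO_ACIDS))
    probs = np.array([NNK_FREQUENCIES[a] for a in AMINO_ACIDS])
    variants: set[str] = set()
    while len(variants) < config.n_variants:
        need = config.n_variants - len(variants)
        draws = rng.choice(residues, size=(need + max(8, need // 8), L), p=probs)
        for row in draws:
            s = "".join(row)
            if s != config.wt_string:
                variants.add(s)
            if len(variants) == config.n_variants:
                break
    clone_list = [config.wt_string] + sorted(variants)
    freqs = np.empty(len(clone_list))
    freqs[0] = config.wt_fraction_initial
    if config.n_variants > 0:
        mass = 1.0 - config.wt_fraction_initial
        freqs[1:] = mass * rng.dirichlet(
            np.full(config.n_variants, config.dirichlet_alpha)
        )
    return clone_list, freqs


def simulate_round(
    freqs: np.ndarray, log_fitness: np.ndarray, beta: float
) -> np.ndarray:
    """Deterministic selection update f'(s) ∝ f(s) · w(s)^beta."""
    if beta == 0.0:
        return freqs.copy()
    weighted = freqs * np.exp(beta * log_fitness)
    return weighted / weighted.sum()


def simulate_sequencing(
    freqs: np.ndarray,
    depth: int,
    replicates: int,
    rng: np.random.Generator,
    clones: list[str],
) -> dict[int, Counter]:
    """Independent multinomial draws of ``depth`` reads per replicate."""
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    out: dict[int, Counter] = {}
    for k in range(1, replicates + 1):
        draw = rng.multinomial(depth, freqs)
        out[k] = Counter(
            {clones[i]: int(n) for i, n in enumerate(draw) if n > 0}
        )
    return out


def simulate_campaign(
    config: SimConfig | None = None, seed: int | None = None
) -> SimOutput:
    """Run a full campaign: library → rounds of selection → duplicate sequencing."""
    config = SimConfig() if config is None else config
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    clones, freqs = make_library(config, rng)
    landscape = FitnessLandscape.random(
        config.wt_string, rng, config.effect_mean, config.effect_sd
    )
    log_w = landscape.log_fitness(clones)
    if config.fitness_noise_sd > 0:
        noise = rng.normal(0.0, config.fitness_noise_sd, size=len(clones))
        noise[0] = 0.0  # the wild type anchors w = 1
        log_w = log_w + noise
    pool_freqs: dict[str, np.ndarray] = {}
    tallies: dict[tuple[str, int], Counter] = {}
    current = freqs
    for label, beta in config.rounds:
        current = simulate_round(current, log_w, beta)
        if config.bottleneck is not None:
            captured = rng.multinomial(config.bottleneck, current)
            current = captured / config.bottleneck
        pool_freqs[label] = current
        per_rep = simulate_sequencing(
            current, config.depth, config.replicates, rng, clones
        )
        for k, counts in per_rep.items():
            tallies[(label, k)] = counts
    table = merge_replicates(
        tallies, config.round_labels, mode="common-any-round",
        wt_string=config.wt_string,
    )
    return SimOutput(
        clones=clones,
        fitness=pd.Series(np.exp(log_w), index=clones, name="fitness"),
        landscape=landscape,
        pool_freqs=pd.DataFrame(pool_freqs, index=pd.Index(clones)),
        tallies=tallies,
        table=table,
        config=config,
    )


# ---------------------------------------------------------------------------
# FASTQ emission


@dataclass
class ReadLayout:
    """Synthetic amplicon layout: anchor + scaffold with the mutated sites.

    The translated amplicon is ``prefix + s[:5] + mid + s[5:] + suffix`` —
    a 30-residue stretch with two five-site blocks mimicking the heavy-CDR1
    / light-CDR2 arrangement. Nucleotides use one fixed codon per residue,
    preceded by ``frame_offset`` padding bases.
    """

    wt_string: str = DEFAULT_WT
    prefix: str = "DIQMTQSP"
    mid: str = "WYQQKPG"
    suffix: str = "KAPKL"
    split: int = 5

    @property
    def anchor(self) -> str:
        return self.prefix[:6]

    @property
    def expected_length(self) -> int:
        return len(self.prefix) + len(self.mid) + len(self.suffix) + len(self.wt_string)

    @property
    def positions(self) -> list[int]:
        a = len(self.prefix)
        b = a + self.split + len(self.mid)
        n_late = len(self.wt_string) - self.split
        return list(range(a, a + self.split)) + list(range(b, b + n_late))

    def amino_acids(self, mutation_string: str) -> str:
        s = mutation_string
        return self.prefix + s[: self.split] + self.mid + s[self.split :] + self.suffix

    def nucleotides(self, mutation_string: str, frame_offset: int = 0) -> str:
        aa = self.amino_acids(mutation_string)
        return "G" * frame_offset + "".join(AA_TO_CODON[a] for a in aa)


def emit_fastq(
    tallies: dict[tuple[str, int], Counter],
    layout: ReadLayout,
    outdir: str | Path,
    rounds: list[str],
    frame_offsets: dict[tuple[str, int], int] | None = None,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    wt_string: str | None = None,
) -> Path:
    """Write one FASTQ per (round, replicate) plus a pipeline manifest.

    ``error_rate`` applies independent per-base substitutions to each read
    (requires ``rng``). Returns the manifest path.
    """
    if error_rate > 0 and rng is None:
        raise ConfigError("error_rate > 0 requires an rng")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame_offsets = frame_offsets or {}
    samples = []
    for (label, k), counts in sorted(tallies.items()):
        offset = frame_offsets.get((label, k), 0)
        fname = f"{label}_rep{k}.fastq"
        with open(outdir / fname, "w") as fh:
            i = 0
            for clone in sorted(counts):
                n = counts[clone]
                seq = layout.nucleotides(clone, offset)
                if error_rate > 0:
                    for _ in range(n):
                        fh.write(f"@{label}_{k}_{i}\n"
                                 f"{_mutate(seq, error_rate, rng)}\n+\n"
                                 f"{'I' * len(seq)}\n")
                        i += 1
                else:
                    qual = "I" * len(seq)
                    block = [f"@{label}_{k}_{i + j}\n{seq}\n+\n{qual}\n"
                             for j in range(n)]
                    fh.writelines(block)
                    i += n
        samples.append(
            {"path": fname, "round": label, "replicate": k, "frame_offset": offset}
        )
    manifest = {
        "anchor": layout.anchor,
        "expected_length": layout.expected_length,
        "positions": layout.positions,
        "rounds": rounds,
        "wt_string": wt_string or layout.wt_string,
        "samples": samples,
    }
    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    hits = rng.random(len(seq)) < rate
    if not hits.any():
        return seq
    chars = list(seq)
    bases = "ACGT"
    for i in np.flatnonzero(hits):
        chars[i] = bases[rng.integers(0, 4)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# recovery benchmark


def evaluate_recovery(
    report: SelectionReport,
    truth: pd.Series,
    top_fraction: float = 0.01,
) -> dict:
    """Judge each ranking metric against the known fitness landscape.

    Returns the Spearman rank correlation of each metric's score with log
    fitness, the fraction of true top-``top_fraction`` variants captured in
    each metric's top-K, and the mean fitness of the final selection
    alongside the library's 90th fitness percentile. The wild type is not a
    variant and is excluded from the truth set.
    """
    missing = set(report.scores.index) - set(truth.index)
    if missing:
        raise DataError(f"{len(missing)} scored clones lack a truth entry")
    log_truth = np.log(truth)
    variants = truth.drop(report.wt_string) if report.wt_string in truth.index else truth
    n_top = max(1, int(np.ceil(top_fraction * len(variants))))
    true_top = set(variants.nlargest(n_top).index)

    spearman: dict[str, float] = {}
    capture: dict[str, float] = {}
    for metric in report.scores.columns:
        values = report.scores[metric].dropna()
        if report.wt_string in values.index:
            values = values.drop(report.wt_string)
        if len(values) >= 3:
            rho = spearmanr(values, log_truth.loc[values.index]).statistic
        else:
            rho = float("nan")
        spearman[metric] = float(rho)
        capture[metric] = len(set(report.top_k[metric]) & true_top) / n_top

    final = sorted(report.final)
    final_mean = float(truth.loc[final].mean()) if final else float("nan")
    return {
        "spearman": spearman,
        "capture_top_k": capture,
        "n_true_top": n_top,
        "final_mean_fitness": final_mean,
        "final_size": len(final),
        "library_fitness_p90": float(np.percentile(variants, 90.0)),
    }


def run_benchmark(
    seed: int,
    config: SimConfig | None = None,
    k: int = 40,
    required_rounds: tuple[str, ...] = ("R2", "R3", "R5", "R6"),
) -> dict:
    """One full in-silico campaign plus selection and recovery evaluation.

    Mirrors the analysis protocol: matrices from the permissive
    replicate-common clone set, scoring restricted to clones common to both
    replicates in every early round (terminal round may be absent), PSERMs
    for the last two round transitions, top-``k`` overlap, cysteine filter.
    """
    config = SimConfig() if config is None else config
    sim = simulate_campaign(config, seed=seed)
    labels = config.round_labels
    pairs = [(labels[-1], labels[-2]), (labels[-2], labels[-3])]
    pserms = pserms_for_rounds(sim.table, pairs)
    strict = merge_replicates(
        sim.tallies, labels, mode="common-required-rounds",
        required_rounds=list(required_rounds),
        allow_absent_rounds=[labels[-1]], wt_string=config.wt_string,
    )
    report = select_clones(
        sim.table, pserms, k=k, exclude_wt=True,
        comparator_rounds=(labels[-1], labels[0], labels[-2]),
        clones=strict.clones,
    )
    metrics = evaluate_recovery(report, sim.fitness)
    metrics["n_candidates"] = len(strict.clones)
    metrics["wt_freq_by_round"] = {
        r: float(sim.pool_freqs.loc[config.wt_string, r]) for r in labels
    }
    logger.info(
        "benchmark seed %d: %d candidates, final %d clones, "
        "PSERM capture %.2f", seed, metrics["n_candidates"],
        metrics["final_size"],
        metrics["capture_top_k"].get(report.pserm_metrics[0], float("nan")),
    )
    return metrics
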