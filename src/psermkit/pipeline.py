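"""End-to-end orchestration: tally → matrices → selection, with provenance.

`run_pipeline` is deterministic for fixed inputs and configuration; it
writes every intermediate artifact (clone tables, matrix TSVs, the selection
report) plus a machine-readable run manifest recording the package version,
a hash of the effective configuration and checksums of the input files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError
from .matrices import DEFAULT_BACKGROUND, build_count_matrix, ppm_from_counts, \
    pserms_for_rounds, pssm_from_ppm
from .reads import CloneTable, ReadManifest, merge_replicates, tally_manifest
from .selection import SelectionReport, select_clones

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs beyond the read manifest itself."""

    manifest: Path
    pserm_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("R7", "R6"), ("R6", "R5")]
    )
    k: int = 40
    background: float = DEFAULT_BACKGROUND
    required_rounds: list[str] = field(
        default_factory=lambda: ["R2", "R3", "R5", "R6"]
    )
    allow_absent_rounds: list[str] = field(default_factory=lambda: ["R7"])
    comparator_rounds: tuple[str, str, str] = ("R7", "R2", "R6")
    exclude_wt: bool = True
    matrices_exclude_wt: bool = False
    outdir: Path = Path("pserm_out")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                kwargs[f.name] = raw[f.name]
        if "manifest" not in kwargs:
            raise ConfigError(f"pipeline config {path}: missing 'manifest'")
        kwargs["manifest"] = (path.parent / kwargs["manifest"]).resolve()
        kwargs["outdir"] = Path(kwargs.get("outdir", "pserm_out"))
        if "pserm_pairs" in kwargs:
            kwargs["pserm_pairs"] = [tuple(p) for p in kwargs["pserm_pairs"]]
        if "comparator_rounds" in kwargs:
            kwargs["comparator_rounds"] = tuple(kwargs["comparator_rounds"])
        return cls(**kwargs)

    def validate(self, rounds: list[str]) -> None:
        if len(self.pserm_pairs) != 2:
            raise ConfigError("exactly two PSERM pairs drive the overlap rule")
        for late, early in self.pserm_pairs:
            if late not in rounds or early not in rounds:
                raise ConfigError(f"PSERM pair ({late},{early}) uses unknown rounds")
            if rounds.index(late) - rounds.index(early) != 1:
                raise ConfigError(
                    f"PSERM pair ({late},{early}) must be consecutive sequenced rounds"
                )
        missing = set(self.required_rounds) - set(rounds)
        if missing:
            raise ConfigError(f"required_rounds not in round order: {sorted(missing)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> SelectionReport:
    """Run tally → merge → matrices → selection and write all artifacts."""
    manifest = ReadManifest.from_yaml(config.manifest)
    config.validate(manifest.rounds)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tallies, stats = tally_manifest(manifest)
    total_seen = sum(s.seen for s in stats.values())
    total_kept = sum(s.kept for s in stats.values())
    logger.info("tally: %d reads seen, %d kept across %d samples",
                total_seen, total_kept, len(stats))

    table = merge_replicates(
        tallies, manifest.rounds, mode="common-any-round",
        wt_string=manifest.wt_string,
    )
    logger.info("replicate-common clone set (any round): %d clones", len(table.clones))
    table.to_tsv(outdir / "clone_table.tsv")

    strict = merge_replicates(
        tallies, manifest.rounds, mode="common-required-rounds",
        required_rounds=config.required_rounds,
        allow_absent_rounds=config.allow_absent_rounds,
        wt_string=manifest.wt_string,
    )
    logger.info("clones common to all replicates of rounds %s: %d",
                ",".join(config.required_rounds), len(strict.clones))
    strict.to_tsv(outdir / "clone_table_required_rounds.tsv")

    matrix_rounds = sorted({r for pair in config.pserm_pairs for r in pair})
    for r in matrix_rounds:
        cm = build_count_matrix(table, r, exclude_wt=config.matrices_exclude_wt)
        cm.to_tsv(outdir / f"counts_{r}.tsv")
        ppm = ppm_from_counts(cm)
        ppm.to_tsv(outdir / f"ppm_{r}.tsv")
        pssm_from_ppm(ppm, config.background).to_tsv(outdir / f"pssm_{r}.tsv")
    pserms = pserms_for_rounds(
        table, config.pserm_pairs, config.background,
        exclude_wt=config.matrices_exclude_wt,
    )
    for name, m in pserms.items():
        m.to_tsv(outdir / f"{name}.tsv")

    report = select_clones(
        table, pserms, k=config.k, exclude_wt=config.exclude_wt,
        comparator_rounds=config.comparator_rounds, clones=strict.clones,
    )
    logger.info(
        "selection: top-%d overlap of the two PSERMs has %d clones; "
        "%d removed for unpaired cysteine; %d selected",
        config.k, len(report.overlap), len(report.removed_for_cysteine),
        len(report.final),
    )
    report.to_tsv(outdir / "selection_report.tsv")
    report.to_json(outdir / "selection_summary.json")

    run_manifest = {
        "psermkit_version": __version__,
        "config": {
            "manifest": str(config.manifest),
            "pserm_pairs": [list(p) for p in config.pserm_pairs],
            "k": config.k,
            "background": config.background,
            "required_rounds": config.required_rounds,
            "allow_absent_rounds": config.allow_absent_rounds,
            "comparator_rounds": list(config.comparator_rounds),
            "exclude_wt": config.exclude_wt,
            "matrices_exclude_wt": config.matrices_exclude_wt,
        },
        "inputs": {
            str(s.path): _sha256(s.path) for s in manifest.samples
        },
        "qc": {
            f"{r}_rep{k}": dataclasses.asdict(s) for (r, k), s in stats.items()
        },
        "milestones": {
            "clones_common_any_round": len(table.clones),
            "clones_common_required_rounds": len(strict.clones),
            "overlap": len(report.overlap),
            "removed_for_cysteine": len(report.removed_for_cysteine),
            "final": len(report.final),
        },
    }
    run_manifest["config_hash"] = hashlib.sha256(
        json.dumps(run_manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    (outdir / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True) + "\n"
    )
    return report
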