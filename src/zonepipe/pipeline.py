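"""End-to-end orchestration: simulate -> zonation -> consensus -> DE -> report.

Each stage writes plain TSV/GMT artifacts into the run directory before
the next stage reads them back, so stages can be re-run individually or
swapped against external tools; a JSON manifest records the config
snapshot, seed, and a checksum per artifact. The whole run is a pure
function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as zio
from .diffexp import BulkExperiment, run_diffexp
from .enrichment import periportalization_report, rank_signature
from .synthetic import ConfigError, SimConfig, simulate_bulk_timecourse, simulate_layered_cells, simulate_study_sets
from .zonation import (
    GeneSet,
    assign_layers,
    build_consensus,
    call_zonation,
    filter_low_expression,
    normalize_cells,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "StageError", "run_all", "ALL_STAGES"]

ALL_STAGES = ("sim", "zonation", "consensus", "de", "enrich")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Full parameterisation of a pipeline run."""

    out_dir: str = "zonepipe_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulation (defaults are the study conditions; see SimConfig)
    sim: dict = field(default_factory=dict)
    # per-study noisy set generation for the consensus stage
    study_sensitivity: float = 0.8
    study_fpr: float = 0.005
    n_extra_studies: int = 2
    # thresholds
    min_cells: int = 15
    zonation_fdr: float = 0.001
    lfc_min: float = 1.5
    fdr_max: float = 0.05
    overlap_lfc_min: float = 0.8
    overlap_fdr_max: float = 0.2
    background_n: int = 20_000
    n_perm: int = 100_000
    min_studies: int = 2
    months: tuple[int, ...] = (2, 6, 12)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if not (0 < self.zonation_fdr < 1 and 0 < self.fdr_max < 1 and 0 < self.overlap_fdr_max < 1):
            raise ConfigError("FDR thresholds must lie in (0, 1)")
        if self.lfc_min < 0 or self.overlap_lfc_min < 0:
            raise ConfigError("logFC thresholds must be >= 0")
        if self.min_cells < 0 or self.background_n < 1 or self.n_perm < 100:
            raise ConfigError("invalid filter/background/permutation settings")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "months" in data:
            data["months"] = tuple(int(m) for m in data["months"])
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunManifest:
    """Record of one run: config snapshot, artifact checksums, timings."""

    config: dict
    seed: int
    version: str
    stages_run: list[str]
    checksums: dict[str, str]
    started: float
    finished: float

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sim_config(cfg: RunConfig) -> SimConfig:
    sim = dict(cfg.sim)
    if "bulk_effects" in sim:
        sim["bulk_effects"] = {
            int(m): tuple(float(x) for x in fc) for m, fc in sim["bulk_effects"].items()
        }
    sim.setdefault("seed", cfg.seed)
    return SimConfig(**sim)


def run_all(config: RunConfig | dict) -> RunManifest:
    """Execute the selected stages in dependency order.

    Stage outputs land in ``config.out_dir``; later stages read the
    earlier stages' files, so a subset of stages can be run against an
    existing directory. Failures raise :class:`StageError` naming the
    stage; missing inputs raise :class:`FileNotFoundError` naming the
    file.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.time()
    artifacts: list[Path] = []
    stages = [s for s in ALL_STAGES if s in config.stages]

    def _require(path: Path, what: str) -> Path:
        if not path.exists():
            raise FileNotFoundError(f"missing {what} file: {path}")
        return path

    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            if stage == "sim":
                sim_cfg = _sim_config(config)
                matrix, truth = simulate_layered_cells(sim_cfg)
                zio.write_counts_tsv(matrix.counts, matrix.gene_ids, matrix.cell_ids,
                                     out / "sc_counts.tsv")
                zio.write_layer_probs(matrix.layer_probs, matrix.cell_ids,
                                      out / "layer_probs.tsv")
                truth.gene_direction.to_csv(out / "truth_directions.tsv", sep="\t")
                truth.cell_layer.to_csv(out / "truth_layers.tsv", sep="\t")
                bulk, bulk_truth = simulate_bulk_timecourse(sim_cfg)
                zio.write_counts_tsv(bulk.counts, bulk.gene_ids, bulk.sample_ids,
                                     out / "bulk_counts.tsv")
                zio.write_design(bulk.design, out / "design.tsv")
                bulk_truth.bulk_logfc.to_csv(out / "truth_bulk_logfc.tsv", sep="\t")
                artifacts += [out / f for f in (
                    "sc_counts.tsv", "layer_probs.tsv", "truth_directions.tsv",
                    "truth_layers.tsv", "bulk_counts.tsv", "design.tsv",
                    "truth_bulk_logfc.tsv")]
            elif stage == "zonation":
                counts = zio.read_counts_tsv(_require(out / "sc_counts.tsv", "single-cell counts"))
                probs = zio.read_layer_probs(_require(out / "layer_probs.tsv", "layer probability"))
                from .zonation import LayeredCellMatrix

                matrix = LayeredCellMatrix(
                    counts=counts.to_numpy(), layer_probs=probs.to_numpy(),
                    gene_ids=list(counts.index), cell_ids=list(counts.columns),
                )
                matrix = filter_low_expression(matrix, min_cells=config.min_cells)
                expr = normalize_cells(matrix)
                layers = assign_layers(matrix.layer_probs)
                calls = call_zonation(expr, matrix.gene_ids, layers,
                                      fdr_threshold=config.zonation_fdr)
                calls.to_csv(out / "zonation_calls.tsv", sep="\t")
                pc = GeneSet("study0_pericentral",
                             frozenset(calls.index[calls["direction"] == "pericentral"]),
                             "pericentral")
                pp = GeneSet("study0_periportal",
                             frozenset(calls.index[calls["direction"] == "periportal"]),
                             "periportal")
                zio.write_gmt([pc, pp], out / "study0_sets.gmt")
                artifacts += [out / "zonation_calls.tsv", out / "study0_sets.gmt"]
            elif stage == "consensus":
                sets = zio.read_gmt(_require(out / "study0_sets.gmt", "study-0 gene set"))
                by_name = {s.name: s for s in sets}
                own = (by_name["study0_pericentral"].members,
                       by_name["study0_periportal"].members)
                directions = pd.read_csv(out / "truth_directions.tsv", sep="\t",
                                         index_col=0)["direction"]
                from .synthetic import TruthLabels

                extra = simulate_study_sets(
                    TruthLabels(gene_direction=directions),
                    sensitivity=config.study_sensitivity, fpr=config.study_fpr,
                    n_studies=config.n_extra_studies, seed=config.seed + 7,
                )
                pc, pp = build_consensus([own] + extra, min_studies=config.min_studies)
                zio.write_gmt([pc, pp], out / "consensus_sets.gmt")
                artifacts += [out / "consensus_sets.gmt"]
            elif stage == "de":
                counts = zio.read_counts_tsv(_require(out / "bulk_counts.tsv", "bulk counts"))
                design = zio.read_design(_require(out / "design.tsv", "design"))
                bulk = BulkExperiment(
                    counts=counts.to_numpy(), design=design,
                    gene_ids=list(counts.index), sample_ids=list(counts.columns),
                )
                tables, prior = run_diffexp(bulk, months=config.months)
                for m, table in tables.items():
                    table.to_csv(out / f"contrast_m{m}.tsv", sep="\t")
                    artifacts.append(out / f"contrast_m{m}.tsv")
                (out / "eb_prior.json").write_text(json.dumps(
                    {"d0": prior.d0 if np.isfinite(prior.d0) else "inf",
                     "s0_sq": prior.s0_sq}) + "\n")
                artifacts.append(out / "eb_prior.json")
            elif stage == "enrich":
                sets = zio.read_gmt(_require(out / "consensus_sets.gmt", "consensus set"))
                by_name = {s.name: s for s in sets}
                pc = GeneSet(by_name["consensus_pericentral"].name,
                             by_name["consensus_pericentral"].members, "pericentral")
                pp = GeneSet(by_name["consensus_periportal"].name,
                             by_name["consensus_periportal"].members, "periportal")
                signatures = {}
                for m in config.months:
                    table = pd.read_csv(
                        _require(out / f"contrast_m{m}.tsv", f"month-{m} contrast"),
                        sep="\t", index_col=0)
                    signatures[m] = rank_signature(table)
                report = periportalization_report(
                    signatures, pc, pp, n_perm=config.n_perm, seed=config.seed + 13)
                report.to_csv(out / "periportalization_report.tsv", sep="\t", index=False)
                artifacts.append(out / "periportalization_report.tsv")
        except (ConfigError, FileNotFoundError):
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with the stage named
            raise StageError(stage, str(exc)) from exc

    from . import __version__

    checksums = {str(p.relative_to(out)): _sha256(p) for p in artifacts}
    manifest = RunManifest(
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()},
        seed=config.seed,
        version=__version__,
        stages_run=stages,
        checksums=checksums,
        started=started,
        finished=time.time(),
    )
    manifest.write(out / "manifest.json")
    return manifest
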