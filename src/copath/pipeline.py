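"""End-to-end orchestration: simulate/load -> DE -> classify -> enrich.

A run is described by a small YAML config (see :class:`RunConfig`),
writes every intermediate table as TSV into one output directory, and
finishes with a machine-readable ``summary.json`` whose counts are
cross-checked against the tables they summarize. Identical config and
seed give identical outputs apart from the timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .core_io import (
    CountDataset,
    ExperimentDesign,
    GeneSetCollection,
    read_counts,
    read_gmt,
    write_counts,
    write_gmt,
    write_table,
)
from .de import estimate_size_factors, differential_expression
from .enrich import enrich_paths, render_heatmap
from .errors import ConfigError, CopathError
from .paths import (
    classify_paths,
    extract_restoration_sets,
    path_table,
    restoration_table,
)
from .synthetic import SimulationSpec, simulate_dataset, write_truth

logger = logging.getLogger("copath")

_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationSpec)}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Exactly one of (``counts`` + ``samples``) or ``simulation`` must be
    set: the pipeline either loads a real count matrix or simulates one.
    """

    out_dir: Path = Path("copath_run")
    counts: Path | None = None
    samples: Path | None = None
    gmt: Path | None = None
    simulation: dict | None = None
    reference: str | None = None
    path_order: list[str] | None = None
    injury: str | None = None
    treated: str | None = None
    lfc: float = 1.0
    q: float = 0.05
    pseudocount: float = 1.0
    min_mean_count: float = 5.0
    universe: str = "analyzed"
    bh_scope: str = "global"
    top_terms: int = 30
    fold_change_only: bool = False
    seed: int = 0
    force: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_real = self.counts is not None or self.samples is not None
        has_sim = self.simulation is not None
        if has_real and has_sim:
            raise ConfigError(
                "set either counts/samples or simulation, not both"
            )
        if not has_real and not has_sim:
            raise ConfigError(
                "one of counts+samples or simulation is required"
            )
        if has_real:
            if self.counts is None or self.samples is None:
                raise ConfigError("counts and samples must be set together")
            if self.gmt is None:
                raise ConfigError("gmt is required with real count input")
            if self.reference is None:
                raise ConfigError("reference is required with real count input")
        if has_sim:
            unknown = set(self.simulation) - _SIM_KEYS
            if unknown:
                raise ConfigError(
                    f"unknown simulation keys: {sorted(unknown)}"
                )
        if self.universe not in ("analyzed", "annotated"):
            raise ConfigError(
                f"universe must be 'analyzed' or 'annotated', got {self.universe!r}"
            )
        if self.bh_scope not in ("global", "per-path"):
            raise ConfigError(
                f"bh_scope must be 'global' or 'per-path', got {self.bh_scope!r}"
            )
        for key in ("lfc", "q", "pseudocount", "min_mean_count"):
            value = getattr(self, key)
            try:
                setattr(self, key, float(value))
            except (TypeError, ValueError):
                raise ConfigError(f"{key} must be a number, got {value!r}") from None
        for key in ("top_terms", "seed"):
            value = getattr(self, key)
            if isinstance(value, bool) or not isinstance(value, int):
                try:
                    setattr(self, key, int(str(value)))
                except (TypeError, ValueError):
                    raise ConfigError(
                        f"{key} must be an integer, got {value!r}"
                    ) from None
        self.out_dir = Path(self.out_dir)
        for key in ("counts", "samples", "gmt"):
            value = getattr(self, key)
            if value is not None:
                setattr(self, key, Path(value))


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML: {exc}") from None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of keys to values")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


@dataclass
class RunSummary:
    """Per-stage counts of one completed run, cross-checked at write time."""

    seed: int
    n_genes_input: int
    n_genes_analyzed: int
    calls_per_contrast: dict[str, dict[str, int]]
    path_sizes: dict[str, int]
    restoration_sizes: dict[str, int]
    n_enrichment_rows: int
    n_significant_enrichment: int
    versions: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _setup_logging(out_dir: Path, level: str) -> None:
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (
        logging.StreamHandler(),
        logging.FileHandler(out_dir / "run.log", mode="w"),
    ):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, CopathError):
                exc.args = (f"[stage {name}] {exc}",)
            elif exc is None:
                logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(cfg: RunConfig) -> RunSummary:
    """Execute every stage, write all tables, and return the summary."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    summary_path = out / "summary.json"
    if summary_path.exists() and not cfg.force:
        raise ConfigError(
            f"{summary_path} exists; pass force to overwrite a previous run"
        )
    _setup_logging(out, cfg.log_level)

    truth = None
    if cfg.simulation is not None:
        with _stage("simulate"):
            sim_kwargs = dict(cfg.simulation)
            sim_kwargs.setdefault("seed", cfg.seed)
            spec = SimulationSpec(**sim_kwargs)
            ds, sets, truth = simulate_dataset(spec)
            write_counts(ds, out / "counts.tsv", out / "samples.tsv")
            write_gmt(sets, out / "sets.gmt")
            write_truth(truth, out / "truth_genes.tsv", out / "truth_terms.tsv")
            design = spec.design
            injury = cfg.injury or (
                "SNL_vehicle" if "SNL_vehicle" in design.path_conditions else None
            )
            treated = cfg.treated or (
                "SNL_C286" if "SNL_C286" in design.path_conditions else None
            )
    else:
        with _stage("read_counts"):
            for key in ("counts", "samples", "gmt"):
                p = getattr(cfg, key)
                if not p.exists():
                    raise ConfigError(f"[read_counts] {key} file not found: {p}")
            ds = read_counts(cfg.counts, cfg.samples)
            sets = read_gmt(cfg.gmt)
            path_conditions = cfg.path_order or [
                c for c in ds.conditions if c != cfg.reference
            ]
            design = ExperimentDesign(
                reference_condition=cfg.reference,
                path_conditions=tuple(path_conditions),
            )
            injury, treated = cfg.injury, cfg.treated

    if cfg.path_order:
        design = ExperimentDesign(
            reference_condition=design.reference_condition,
            path_conditions=tuple(cfg.path_order),
        )
    if injury is None or treated is None:
        raise ConfigError(
            "injury and treated conditions are required to extract "
            "restoration sets"
        )

    with _stage("normalize_de"):
        factors = estimate_size_factors(ds)
        factors.rename_axis("sample").reset_index().to_csv(
            out / "size_factors.tsv", sep="\t", index=False, float_format="%.6g"
        )
        de = differential_expression(
            ds,
            design,
            lfc_threshold=cfg.lfc,
            q_threshold=cfg.q,
            pseudocount=cfg.pseudocount,
            min_mean_count=cfg.min_mean_count,
            fold_change_only=cfg.fold_change_only,
        )
        write_table(de, out / "de.tsv")

    with _stage("classify"):
        paths = classify_paths(de, design)
        write_table(path_table(paths), out / "paths.tsv")
        restoration = extract_restoration_sets(paths, design, injury, treated)
        write_table(restoration_table(restoration), out / "restoration.tsv")

    with _stage("enrich"):
        analyzed = set(de["gene"])
        universe = analyzed
        if cfg.universe == "annotated":
            universe = analyzed | {g for t in sets for g in sets.genes_of(t)}
        enrichment = enrich_paths(paths, sets, universe, bh_scope=cfg.bh_scope)
        write_table(enrichment, out / "enrichment.tsv")
        if not enrichment.empty:
            top = min(cfg.top_terms, enrichment["term"].nunique())
            render_heatmap(
                enrichment, top, out / "heatmap_matrix.tsv", out / "heatmap.png"
            )

    with _stage("summarize"):
        n_analyzed = de["gene"].nunique()
        calls = {
            cond: {
                call: int(
                    ((de["contrast"] == cond) & (de["call"] == call)).sum()
                )
                for call in ("up", "down", "unchanged")
            }
            for cond in design.path_conditions
        }
        summary = RunSummary(
            seed=cfg.seed,
            n_genes_input=len(ds.genes),
            n_genes_analyzed=n_analyzed,
            calls_per_contrast=calls,
            path_sizes={p.label_str: len(p) for p in paths},
            restoration_sizes={
                name: len(genes) for name, genes in restoration.as_dict().items()
            },
            n_enrichment_rows=len(enrichment),
            n_significant_enrichment=int((enrichment["q"] < 0.05).sum())
            if not enrichment.empty
            else 0,
            versions={
                "copath": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
            },
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
        _cross_check(summary, de, paths, enrichment, design)
        summary_path.write_text(summary.to_json() + "\n")
    logger.info("run complete: %s", summary_path)
    return summary


def _cross_check(summary: RunSummary, de, paths, enrichment, design) -> None:
    """Every summary count must equal the table it summarizes."""
    assert summary.n_genes_analyzed == de["gene"].nunique()
    assert sum(summary.path_sizes.values()) == de["gene"].nunique()
    for cond in design.path_conditions:
        sub = de[de["contrast"] == cond]
        assert sum(summary.calls_per_contrast[cond].values()) == len(sub)
    assert summary.n_enrichment_rows == len(enrichment)
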