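"""End-to-end orchestration: data -> variance partition -> precision curve
-> strategy grid -> selection, with seeded substreams and a run manifest.

Every stage draws its randomness from a named substream spawned off the
single master seed, so a stage can be reproduced in isolation and a full
rerun with the same config file is bit-identical.  All outputs are plain
delimited text plus a JSON manifest recording the config (and its hash),
the seed and the library versions used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import AnovaDesign, AnovaTable, PermutationConfig
from .data import Dialect, TraitDataset, read_trait_table, write_trait_table
from .errors import ConfigError
from .precision import BreakpointFit, PrecisionCurve, fit_breakpoint, resample_se_curve
from .selection import (
    ScreeningResult,
    SelectionResult,
    screen,
    select_sizes,
    whole_data_stats,
)
from .simulate import SynthConfig, TraitModel, generate_dataset
from .strategies import GridResult, builtin_strategies, run_grid

logger = logging.getLogger("itvsample")

_STAGES = ("simulate", "partition", "precision", "strategies", "select")


def log_event(stage: str, level: str, message: str) -> None:
    """Structured, timestamped log line for one pipeline event."""
    logger.log(
        getattr(logging, level.upper()), "[%s] %s", stage, message
    )


def configure_logging(quiet: bool = False) -> None:
    level = logging.WARNING if quiet else logging.INFO
    logging.basicConfig(
        level=level, format="%(asctime)s %(levelname)s %(message)s"
    )
    logger.setLevel(level)


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults follow the standard protocol
    (4999 strategy/precision replicates, 999 permutations, alpha .05,
    95% CI)."""

    seed: int = 0
    input: str | None = None  # CSV path; None -> synthesize
    synth: SynthConfig = field(default_factory=SynthConfig)
    traits: list[str] | None = None
    reps: int = 4999
    n_perm: int = 999
    alpha: float = 0.05
    ci_level: float = 0.95
    ss_type: str = "sequential"
    strategies: list[str] | None = None  # None -> full builtin registry
    precision_grid_step: int = 1
    outdir: str = "itvsample_out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = _synth_to_dict(self.synth)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synth" in d and not isinstance(d["synth"], SynthConfig):
            d["synth"] = _synth_from_dict(d["synth"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # hash the scientific config, not the destination
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _synth_to_dict(cfg: SynthConfig) -> dict:
    return {
        "individuals_per_quadrat": list(cfg.individuals_per_quadrat),
        "leaves_per_stratum": cfg.leaves_per_stratum,
        "traits": {
            name: {
                "grand_mean": m.grand_mean,
                "total_sd": m.total_sd,
                "variance_fractions": dict(m.variance_fractions),
            }
            for name, m in cfg.traits.items()
        },
        "empirical": cfg.empirical,
        "residual_corr": cfg.residual_corr,
    }


def _synth_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    if "traits" in d:
        d["traits"] = {
            name: TraitModel(**m) if not isinstance(m, TraitModel) else m
            for name, m in d["traits"].items()
        }
    if "individuals_per_quadrat" in d:
        d["individuals_per_quadrat"] = tuple(d["individuals_per_quadrat"])
    return SynthConfig(**d)


def stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    if stage not in _STAGES:
        raise ConfigError(f"unknown stage {stage!r}")
    return np.random.SeedSequence([int(master), _STAGES.index(stage)])


@dataclass
class RunResult:
    config: PipelineConfig
    dataset: TraitDataset
    anova: dict[str, AnovaTable]
    curves: dict[str, PrecisionCurve]
    breakpoints: dict[str, BreakpointFit]
    grid: GridResult
    screening: ScreeningResult
    selection: SelectionResult
    manifest: dict
    outdir: Path


def run_all(config: PipelineConfig) -> RunResult:
    """Execute the full pipeline and write all stage outputs + manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    t0 = time.time()
    stage = "setup"

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.12g")
        outputs.append(name)

    try:
        stage = "simulate"
        if config.input:
            dataset = read_trait_table(config.input, Dialect())
            log_event(stage, "info", f"read {len(dataset)} observations")
        else:
            dataset = generate_dataset(
                config.synth, seed=stage_seed(config.seed, "simulate")
            )
            log_event(stage, "info", f"generated {len(dataset)} observations")
            write_trait_table(dataset, outdir / "dataset.csv")
            outputs.append("dataset.csv")
        traits = config.traits or dataset.trait_names

        stage = "partition"
        design = AnovaDesign(dataset)
        perm_seq = stage_seed(config.seed, "partition").spawn(len(traits))
        anova: dict[str, AnovaTable] = {}
        for trait, ss in zip(traits, perm_seq):
            table = design.anova(dataset.values(trait), config.ss_type, trait=trait)
            table = design.permutation_pvalues(
                dataset.values(trait), table,
                PermutationConfig(n_perm=config.n_perm, alpha=config.alpha, seed=ss),
            )
            anova[trait] = table
            emit(f"anova_{trait}.csv", table.to_frame())
        log_event(stage, "info", f"partitioned variance for {len(traits)} trait(s)")

        stage = "precision"
        prec_seq = stage_seed(config.seed, "precision").spawn(len(traits))
        curves: dict[str, PrecisionCurve] = {}
        breakpoints: dict[str, BreakpointFit] = {}
        grid_n = np.arange(2, len(dataset) + 1, config.precision_grid_step)
        for trait, ss in zip(traits, prec_seq):
            curve = resample_se_curve(
                dataset, trait, n_grid=grid_n, reps=config.reps, seed=ss
            )
            curves[trait] = curve
            fit = fit_breakpoint(curve)
            breakpoints[trait] = fit
            if not fit.converged:
                log_event(stage, "warning", f"{trait}: breakpoint fit {fit.message}")
            emit(
                f"precision_{trait}.csv",
                pd.DataFrame({"n": curve.n, "mean_se": curve.se, "mean_cv": curve.cv}),
            )
        emit(
            "breakpoints.csv",
            pd.DataFrame(
                [
                    {
                        "trait": t,
                        "psi": f.psi,
                        "se_min": f.se_min,
                        "slope_left": f.slope_left,
                        "slope_right": f.slope_right,
                        "rss": f.rss,
                        "converged": f.converged,
                    }
                    for t, f in breakpoints.items()
                ]
            ),
        )

        stage = "strategies"
        registry = builtin_strategies()
        if config.strategies:
            missing = [s for s in config.strategies if s not in registry]
            if missing:
                raise ConfigError(f"unknown strategies: {missing}")
            specs = [registry[s] for s in config.strategies]
        else:
            specs = list(registry.values())
        grid = run_grid(
            dataset, specs, reps=config.reps,
            seed=int(
                stage_seed(config.seed, "strategies").generate_state(1)[0] % 2**31
            ),
        )
        for cell in grid.skipped:
            log_event(
                stage, "warning",
                f"skipped {cell.strategy} {cell.size.n_individuals}x"
                f"{cell.size.leaves_per_individual}: {cell.reason}",
            )
        emit("strategy_summaries.csv", grid.to_frame())
        emit("skipped_cells.csv", grid.skipped_frame())

        stage = "select"
        stats = {t: whole_data_stats(dataset, t, config.ci_level) for t in traits}
        se_min = {t: breakpoints[t].se_min for t in traits}
        screening = screen(grid, stats, se_min)
        selection = select_sizes(grid, stats, se_min, screening=screening)
        emit("screening.csv", screening.table)
        emit("s_table.csv", selection.s_table)
        with open(outdir / "selection.txt", "w") as fh:
            fh.write("\n".join(selection.audit) + "\n")
        outputs.append("selection.txt")
        log_event(stage, "info", "; ".join(selection.audit[-2:]))

        manifest = {
            "package": "itvsample",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "n_observations": len(dataset),
            "outputs": outputs,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        log_event("select", "info", f"pipeline finished in {time.time() - t0:.1f}s")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return RunResult(
            config=config, dataset=dataset, anova=anova, curves=curves,
            breakpoints=breakpoints, grid=grid, screening=screening,
            selection=selection, manifest=manifest, outdir=outdir,
        )
    except Exception as err:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {err}\n")
        log_event(stage, "error", str(err))
        raise
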