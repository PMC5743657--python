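"""Field sampling strategies and their Monte-Carlo evaluation.

A *strategy* fixes how individuals (trees) and leaves are chosen; a
*sampling size* fixes how many: ``n_individuals`` trees and
``leaves_per_individual`` leaves from each.  Sampling is multistage and
without replacement: stage 1 picks trees (uniformly anywhere, or a fixed,
as-equal-as-possible number per quadrat) and stage 2 picks leaves within
each chosen tree (uniformly among the eligible leaves, or stratified as
evenly as possible over the four canopy strata).  A strategy may also
restrict eligibility to a subset of strata — e.g. protocols that collect
only external "sun" leaves.

The registry in :func:`builtin_strategies` contains the four unrestricted
designs (RANDOM, Q_fixed, stRANDOM, stQ_fixed) and the literature-protocol
variants restricted to external (cor*, per*) or upper-external (*_b)
strata, the latter carrying their recommended preset sizes (5 leaves x 5
individuals minimum, 4 x 10 preferred).

Each (strategy, size) cell is simulated for ``reps`` replicates; every
replicate records the trait mean, SE = SD/sqrt(total leaves) pooled over
individuals, and CV = SD/mean, and the cell summary averages these over
replicates.  Infeasible cells (not enough eligible leaves or individuals)
are reported as skipped, not raised, when running a whole grid.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
import pandas as pd

from .data import STRATA, TraitDataset
from .errors import ConfigError, InfeasibleSampleError

Stratum = tuple[str, str]


@dataclass(frozen=True)
class StrategySpec:
    """How individuals and leaves are selected, before fixing the size."""

    name: str
    individual_selection: str = "random"  # "random" | "per_quadrat"
    leaf_selection: str = "random"  # "random" | "stratified"
    allowed_strata: tuple[Stratum, ...] = STRATA
    preset: tuple[int, int] | None = None  # (n_individuals, leaves_per_individual)

    def __post_init__(self) -> None:
        if self.individual_selection not in ("random", "per_quadrat"):
            raise ConfigError(
                f"unknown individual_selection {self.individual_selection!r}"
            )
        if self.leaf_selection not in ("random", "stratified"):
            raise ConfigError(f"unknown leaf_selection {self.leaf_selection!r}")
        if not self.allowed_strata:
            raise ConfigError("allowed_strata must be non-empty")
        if any(s not in STRATA for s in self.allowed_strata):
            raise ConfigError(f"strata must be among {STRATA}")


@dataclass(frozen=True, order=True)
class SamplingSize:
    n_individuals: int
    leaves_per_individual: int

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.leaves_per_individual < 1:
            raise ConfigError("sampling size components must be >= 1")

    @property
    def total_leaves(self) -> int:
        return self.n_individuals * self.leaves_per_individual


@dataclass(frozen=True)
class TraitStats:
    mean: float  # mean of replicate means
    se: float  # mean of replicate SEs
    cv: float  # mean of replicate CVs


@dataclass
class StrategySummary:
    strategy: str
    size: SamplingSize
    stats: dict[str, TraitStats]
    reps: int
    seed: object = None


@dataclass
class SkippedCell:
    strategy: str
    size: SamplingSize
    reason: str


@dataclass
class GridResult:
    summaries: list[StrategySummary] = field(default_factory=list)
    skipped: list[SkippedCell] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            for trait, st in s.stats.items():
                rows.append(
                    {
                        "strategy": s.strategy,
                        "n_individuals": s.size.n_individuals,
                        "leaves_per_individual": s.size.leaves_per_individual,
                        "total_leaves": s.size.total_leaves,
                        "trait": trait,
                        "mean": st.mean,
                        "se": st.se,
                        "cv": st.cv,
                        "reps": s.reps,
                    }
                )
        return pd.DataFrame(rows)

    def skipped_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": c.strategy,
                    "n_individuals": c.size.n_individuals,
                    "leaves_per_individual": c.size.leaves_per_individual,
                    "reason": c.reason,
                }
                for c in self.skipped
            ]
        )


_EXTERNAL = (("a", "E"), ("b", "E"))
_UPPER_EXTERNAL = (("b", "E"),)


def builtin_strategies() -> dict[str, StrategySpec]:
    """The named strategy registry, in presentation order."""
    specs = [
        StrategySpec("RANDOM"),
        StrategySpec("Q_fixed", individual_selection="per_quadrat"),
        StrategySpec("stRANDOM", leaf_selection="stratified"),
        StrategySpec(
            "stQ_fixed", individual_selection="per_quadrat",
            leaf_selection="stratified",
        ),
        StrategySpec("cor", allowed_strata=_EXTERNAL, preset=(10, 4)),
        StrategySpec("cor_min", allowed_strata=_EXTERNAL, preset=(5, 5)),
        StrategySpec("per", allowed_strata=_EXTERNAL, preset=(10, 4)),
        StrategySpec("per_min", allowed_strata=_EXTERNAL, preset=(5, 5)),
        StrategySpec("cor_b", allowed_strata=_UPPER_EXTERNAL, preset=(10, 4)),
        StrategySpec("cor_min_b", allowed_strata=_UPPER_EXTERNAL, preset=(5, 5)),
        StrategySpec("per_b", allowed_strata=_UPPER_EXTERNAL, preset=(10, 4)),
        StrategySpec("per_min_b", allowed_strata=_UPPER_EXTERNAL, preset=(5, 5)),
    ]
    return {s.name: s for s in specs}


def even_allocation(total: int, n_bins: int) -> list[int]:
    """Split ``total`` into ``n_bins`` counts as equal as possible, giving
    the remainder to the earliest bins (deterministic tie-break)."""
    base, rem = divmod(total, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


class _DesignIndex:
    """Row-index lookup tables for one dataset, reused across cells."""

    def __init__(self, dataset: TraitDataset) -> None:
        df = dataset.frame
        key = list(zip(df["quadrat"].astype(str), df["individual"].astype(str)))
        self.individuals = sorted(set(key))
        self.n_individuals = len(self.individuals)
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        self.quadrats = sorted({q for q, _ in self.individuals})
        self.quadrat_members = {
            q: np.array([i for i, (qq, _) in enumerate(self.individuals) if qq == q])
            for q in self.quadrats
        }
        self.rows: dict[tuple[int, Stratum], list[int]] = {}
        h = df["h_class"].astype(str).to_numpy()
        p = df["position"].astype(str).to_numpy()
        for r, ind in enumerate(key):
            self.rows.setdefault((pos[ind], (h[r], p[r])), []).append(r)

    def stratum_counts(self, stratum: Stratum) -> list[int]:
        return [len(self.rows.get((i, stratum), ())) for i in range(self.n_individuals)]

    def eligible_rows(self, i: int, strata: tuple[Stratum, ...]) -> list[int]:
        out: list[int] = []
        for s in STRATA:  # fixed stratum order keeps row order deterministic
            if s in strata:
                out.extend(self.rows.get((i, s), ()))
        return out


def _check_feasible(index: _DesignIndex, spec: StrategySpec, size: SamplingSize):
    """Validate a cell; returns the per-quadrat and per-stratum allocations."""
    quota = None
    if size.n_individuals > index.n_individuals:
        raise InfeasibleSampleError(
            f"{spec.name}: {size.n_individuals} individuals requested but only"
            f" {index.n_individuals} available"
        )
    if spec.individual_selection == "per_quadrat":
        quota = even_allocation(size.n_individuals, len(index.quadrats))
        for q, k in zip(index.quadrats, quota):
            have = len(index.quadrat_members[q])
            if k > have:
                raise InfeasibleSampleError(
                    f"{spec.name}: quadrat {q} has {have} individuals,"
                    f" {k} requested"
                )
    alloc = None
    if spec.leaf_selection == "stratified":
        order = [s for s in STRATA if s in spec.allowed_strata]
        alloc = dict(zip(order, even_allocation(size.leaves_per_individual, len(order))))
        for s, a in alloc.items():
            cap = min(index.stratum_counts(s))
            if a > cap:
                raise InfeasibleSampleError(
                    f"{spec.name}: stratum {s[0]}-{s[1]} holds {cap} leaves per"
                    f" individual, {a} requested"
                )
    else:
        caps = [
            len(index.eligible_rows(i, spec.allowed_strata))
            for i in range(index.n_individuals)
        ]
        if size.leaves_per_individual > min(caps):
            strata = ",".join(f"{h}-{p}" for h, p in spec.allowed_strata)
            raise InfeasibleSampleError(
                f"{spec.name}: strata {{{strata}}} hold {min(caps)} eligible"
                f" leaves per individual, {size.leaves_per_individual} requested"
            )
    return quota, alloc


def _choose(rng: np.random.Generator, pool: int, k: int, reps: int) -> np.ndarray:
    """(reps, k) independent without-replacement draws from range(pool)."""
    keys = rng.random((reps, pool))
    return np.argpartition(keys, k - 1, axis=1)[:, :k]


def _sample_rows(
    index: _DesignIndex,
    spec: StrategySpec,
    size: SamplingSize,
    rng: np.random.Generator,
    reps: int,
) -> np.ndarray:
    """(reps, total_leaves) dataset row indices drawn under the strategy."""
    quota, alloc = _check_feasible(index, spec, size)

    # stage 1: individuals
    if spec.individual_selection == "per_quadrat":
        parts = []
        for q, k in zip(index.quadrats, quota):
            if k == 0:
                continue
            members = index.quadrat_members[q]
            parts.append(members[_choose(rng, len(members), k, reps)])
        chosen = np.concatenate(parts, axis=1)
    else:
        chosen = _choose(rng, index.n_individuals, size.n_individuals, reps)

    # stage 2: leaves within each chosen individual
    blocks = []
    if spec.leaf_selection == "stratified":
        for s, a in alloc.items():
            if a == 0:
                continue
            counts = index.stratum_counts(s)
            if len(set(counts)) != 1:
                raise ConfigError(
                    "stratified sampling requires equal per-individual stratum"
                    " counts"
                )
            mat = np.array([index.rows[(i, s)] for i in range(index.n_individuals)])
            slots = _choose(rng, counts[0], a, reps * chosen.shape[1]).reshape(
                reps, chosen.shape[1], a
            )
            blocks.append(mat[chosen[:, :, None], slots])
    else:
        elig = [
            index.eligible_rows(i, spec.allowed_strata)
            for i in range(index.n_individuals)
        ]
        counts = {len(e) for e in elig}
        if len(counts) != 1:
            # unbalanced designs: per-replicate loop (slow path)
            out = np.empty((reps, size.total_leaves), dtype=int)
            for r in range(reps):
                cols = []
                for i in chosen[r]:
                    cols.append(
                        rng.choice(elig[i], size.leaves_per_individual, replace=False)
                    )
                out[r] = np.concatenate(cols)
            return out
        m = counts.pop()
        mat = np.array(elig)
        slots = _choose(
            rng, m, size.leaves_per_individual, reps * chosen.shape[1]
        ).reshape(reps, chosen.shape[1], size.leaves_per_individual)
        blocks.append(mat[chosen[:, :, None], slots])
    rows = np.concatenate(blocks, axis=2)
    return rows.reshape(reps, -1)


def draw_sample(
    dataset: TraitDataset,
    spec: StrategySpec,
    size: SamplingSize,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw one multistage sample; returns dataset row positions."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return _sample_rows(_DesignIndex(dataset), spec, size, rng, reps=1)[0]


def simulate_strategy(
    dataset: TraitDataset,
    spec: StrategySpec,
    size: SamplingSize,
    reps: int = 4999,
    seed=None,
    _index: _DesignIndex | None = None,
) -> StrategySummary:
    """Replicate a (strategy, size) cell and summarize per-trait statistics."""
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    index = _index or _DesignIndex(dataset)
    rng = np.random.default_rng(seed)
    rows = _sample_rows(index, spec, size, rng, reps)
    total = size.total_leaves
    stats: dict[str, TraitStats] = {}
    for trait in dataset.trait_names:
        values = dataset.values(trait)[rows]
        means = values.mean(axis=1)
        if total >= 2:
            sd = values.std(axis=1, ddof=1)
            se = sd / sqrt(total)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv = sd / means
            stats[trait] = TraitStats(
                float(means.mean()), float(se.mean()), float(cv.mean())
            )
        else:
            warnings.warn("single-leaf samples have no SE/CV; reporting NaN")
            stats[trait] = TraitStats(float(means.mean()), float("nan"), float("nan"))
    return StrategySummary(spec.name, size, stats, reps=reps, seed=seed)


def cell_seed(seed: int | None, strategy: str, size: SamplingSize):
    """Independent, reproducible substream for one grid cell."""
    tag = zlib.crc32(strategy.encode()) & 0x7FFFFFFF
    return np.random.SeedSequence(
        [0 if seed is None else int(seed), tag,
         size.n_individuals, size.leaves_per_individual]
    )


def default_size_grid(dataset: TraitDataset) -> list[SamplingSize]:
    """Every (individuals, leaves per individual) combination the design
    supports, from 1 x 1 up to all individuals x the common leaf count."""
    index = _DesignIndex(dataset)
    max_leaves = min(
        len(index.eligible_rows(i, STRATA)) for i in range(index.n_individuals)
    )
    return [
        SamplingSize(i, l)
        for i in range(1, index.n_individuals + 1)
        for l in range(1, max_leaves + 1)
    ]


def run_grid(
    dataset: TraitDataset,
    specs,
    size_grid: list[SamplingSize] | None = None,
    reps: int = 4999,
    seed: int | None = None,
) -> GridResult:
    """Simulate every feasible (strategy, size) cell.

    Strategies with a preset size are evaluated at that size only; the
    others run over ``size_grid`` (default: the full design grid).  Cells
    are seeded independently from the master seed, so any one of them can
    be reproduced in isolation with :func:`simulate_strategy` and
    :func:`cell_seed`.  Infeasible cells and single-leaf cells are recorded
    as skipped.
    """
    if isinstance(specs, dict):
        specs = list(specs.values())
    index = _DesignIndex(dataset)
    grid = size_grid or default_size_grid(dataset)
    result = GridResult()
    for spec in specs:
        sizes = [SamplingSize(*spec.preset)] if spec.preset else grid
        for size in sizes:
            if size.total_leaves < 2:
                result.skipped.append(
                    SkippedCell(spec.name, size, "single leaf: SE undefined")
                )
                continue
            try:
                _check_feasible(index, spec, size)
            except InfeasibleSampleError as err:
                result.skipped.append(SkippedCell(spec.name, size, str(err)))
                continue
            result.summaries.append(
                simulate_strategy(
                    dataset, spec, size, reps=reps,
                    seed=cell_seed(seed, spec.name, size), _index=index,
                )
            )
    return result
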