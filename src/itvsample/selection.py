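"""Two-step selection of sampling strategy and sampling size.

Step 1 screens whole strategies: a strategy is *accurate* if its trait means
(aggregated over its simulated size grid) fall inside the 95% confidence
interval of the whole-data mean, and *precise* if its aggregated mean SE does
not exceed the minimum acceptable precision ``se_min`` (the precision-curve
flex point).  Both must hold for every trait; interval membership is closed
(a mean exactly on a CI bound passes).

Step 2 ranks sizes within the most accurate admissible strategy by the
standardized deviation

    S = |x_m - mean_whole| / SD_whole

summed over traits.  The *minimum* size is the cheapest size (fewest total
leaves, ties to fewer individuals) whose per-size means lie in the CI and
whose mean SE meets ``se_min`` for all traits.  The *optimal* size is the
admissible size producing the largest one-step drop of the summed S along
the sequence of admissible sizes ordered by total leaves — the point where
extra effort last buys a substantial accuracy gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import TraitDataset
from .errors import ConfigError, ItvSampleError
from .strategies import GridResult, SamplingSize, StrategySummary

__all__ = [
    "WholeDataStats",
    "ScreeningResult",
    "SelectionResult",
    "whole_data_stats",
    "standardized_deviation",
    "screen",
    "select_sizes",
]


@dataclass(frozen=True)
class WholeDataStats:
    """Mean, spread and t-based CI of a trait over the full dataset."""

    trait: str
    mean: float
    sd: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0

    def contains(self, value: float) -> bool:
        """Closed-interval CI membership."""
        return bool(self.ci_low <= value <= self.ci_high)


def whole_data_stats(dataset: TraitDataset, trait: str, level: float = 0.95) -> WholeDataStats:
    """Whole-dataset mean with t-based confidence interval."""
    values = dataset.values(trait)
    n = values.size
    if n < 2:
        raise ConfigError("whole-data statistics need at least 2 observations")
    if not 0 < level < 1:
        raise ConfigError("confidence level must be in (0, 1)")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    se = sd / math.sqrt(n)
    tq = float(sps.t.ppf(0.5 + level / 2, n - 1))
    return WholeDataStats(
        trait=trait, mean=mean, sd=sd, se=se,
        ci_low=mean - tq * se, ci_high=mean + tq * se, n=n, level=level,
    )


def standardized_deviation(x_m: float, whole_mean: float, whole_sd: float) -> float:
    """Accuracy score S = |x_m - whole_mean| / whole_sd."""
    if not whole_sd > 0:
        raise ConfigError("whole-data SD must be positive")
    return abs(x_m - whole_mean) / whole_sd


@dataclass
class ScreeningResult:
    table: pd.DataFrame
    admissible: list[str]
    reasons: dict[str, str] = field(default_factory=dict)


def _as_summaries(source) -> tuple[list[StrategySummary], list]:
    if isinstance(source, GridResult):
        return source.summaries, source.skipped
    return list(source), []


def screen(
    source,
    stats: dict[str, WholeDataStats],
    se_min: dict[str, float],
    aggregate: str = "median",
) -> ScreeningResult:
    """Strategy-level accuracy/precision screening.

    ``source`` is a :class:`GridResult` or an iterable of summaries.  Each
    strategy's per-size means and SEs are aggregated over its size grid
    (median by default, mean by flag) and compared with the whole-data CI
    and ``se_min`` per trait.
    """
    if aggregate not in ("median", "mean"):
        raise ConfigError("aggregate must be 'median' or 'mean'")
    agg = np.nanmedian if aggregate == "median" else np.nanmean
    summaries, skipped = _as_summaries(source)
    traits = list(stats)
    missing = [t for t in traits if t not in se_min]
    if missing:
        raise ConfigError(f"se_min missing for trait(s): {missing}")

    by_strategy: dict[str, list[StrategySummary]] = {}
    for s in summaries:
        for t in traits:
            if t not in s.stats:
                raise ConfigError(
                    f"summary for {s.strategy} lacks trait {t!r}"
                )
        by_strategy.setdefault(s.strategy, []).append(s)
    names = list(by_strategy)
    for cell in skipped:  # strategies whose every cell was infeasible
        if cell.strategy not in by_strategy and cell.strategy not in names:
            names.append(cell.strategy)

    rows = []
    admissible = []
    reasons: dict[str, str] = {}
    for name in names:
        cells = by_strategy.get(name, [])
        if not cells:
            rows.append({"strategy": name, "admissible": False})
            reasons[name] = "no feasible sizes"
            continue
        row: dict = {"strategy": name, "n_sizes": len(cells)}
        ok = True
        why = []
        for t in traits:
            m = float(agg([c.stats[t].mean for c in cells]))
            e = float(agg([c.stats[t].se for c in cells]))
            in_ci = stats[t].contains(m)
            precise = bool(np.isfinite(e) and e <= se_min[t])
            row.update(
                {
                    f"{t}_mean": m,
                    f"{t}_se": e,
                    f"{t}_in_ci": in_ci,
                    f"{t}_precise": precise,
                }
            )
            if not in_ci:
                why.append(f"{t} mean {m:.4g} outside CI")
            if not precise:
                why.append(f"{t} SE {e:.4g} above se_min")
            ok = ok and in_ci and precise
        row["admissible"] = ok
        rows.append(row)
        if ok:
            admissible.append(name)
        else:
            reasons[name] = "; ".join(why)
    return ScreeningResult(pd.DataFrame(rows), admissible, reasons)


@dataclass
class SelectionResult:
    admissible_strategies: list[str]
    best_strategy: str | None
    s_table: pd.DataFrame
    minimum_size: SamplingSize | None
    optimal_size: SamplingSize | None
    audit: list[str] = field(default_factory=list)

    @property
    def no_admissible(self) -> bool:
        return self.best_strategy is None


def _s_table(
    summaries: list[StrategySummary],
    stats: dict[str, WholeDataStats],
    se_min: dict[str, float],
) -> pd.DataFrame:
    rows = []
    traits = list(stats)
    for s in summaries:
        row = {
            "strategy": s.strategy,
            "n_individuals": s.size.n_individuals,
            "leaves_per_individual": s.size.leaves_per_individual,
            "total_leaves": s.size.total_leaves,
        }
        ok = True
        sum_s = 0.0
        for t in traits:
            st = s.stats[t]
            s_val = standardized_deviation(st.mean, stats[t].mean, stats[t].sd)
            in_ci = stats[t].contains(st.mean)
            precise = bool(np.isfinite(st.se) and st.se <= se_min[t])
            row[f"S_{t}"] = s_val
            row[f"{t}_in_ci"] = in_ci
            row[f"{t}_precise"] = precise
            sum_s += s_val
            ok = ok and in_ci and precise
        row["sum_S"] = sum_s
        row["size_admissible"] = ok
        rows.append(row)
    return pd.DataFrame(rows)


def select_sizes(
    source,
    stats: dict[str, WholeDataStats],
    se_min: dict[str, float],
    screening: ScreeningResult | None = None,
    aggregate: str = "median",
) -> SelectionResult:
    """Apply the two-step selection and report minimum and optimal sizes."""
    summaries, _ = _as_summaries(source)
    if not summaries:
        raise ItvSampleError("no strategy summaries to select from")
    if screening is None:
        screening = screen(source, stats, se_min, aggregate=aggregate)
    audit = [f"screened {len(set(s.strategy for s in summaries))} strategies;"
             f" admissible: {screening.admissible or 'none'}"]
    if not screening.admissible:
        return SelectionResult([], None, pd.DataFrame(), None, None,
                               audit + ["no admissible design"])

    table = _s_table(
        [s for s in summaries if s.strategy in screening.admissible],
        stats, se_min,
    )
    # most accurate admissible strategy: lowest median summed S over its sizes
    ranking = (
        table.groupby("strategy")["sum_S"].median().sort_values()
    )
    best = str(ranking.index[0])
    audit.append(
        "strategy accuracy ranking (median sum S): "
        + ", ".join(f"{k}={v:.4f}" for k, v in ranking.items())
    )

    cand = table[(table["strategy"] == best) & table["size_admissible"]].copy()
    cand = cand.sort_values(
        ["total_leaves", "n_individuals", "sum_S"]
    ).reset_index(drop=True)
    if len(cand) == 0:
        audit.append(f"{best}: no size meets the per-size criteria")
        return SelectionResult(
            screening.admissible, best, table, None, None, audit
        )
    minimum = SamplingSize(
        int(cand.loc[0, "n_individuals"]), int(cand.loc[0, "leaves_per_individual"])
    )
    audit.append(
        f"minimum size: {minimum.n_individuals} individuals x"
        f" {minimum.leaves_per_individual} leaves"
        f" ({minimum.total_leaves} leaves total)"
    )

    if len(cand) == 1:
        optimal = minimum
        audit.append("single admissible size: optimal equals minimum")
    else:
        drops = cand["sum_S"].to_numpy()[:-1] - cand["sum_S"].to_numpy()[1:]
        k = int(np.argmax(drops)) + 1  # ties -> earliest, i.e. fewest leaves
        optimal = SamplingSize(
            int(cand.loc[k, "n_individuals"]),
            int(cand.loc[k, "leaves_per_individual"]),
        )
        audit.append(
            f"largest sum-S drop ({drops[k - 1]:.4f}) at"
            f" {optimal.n_individuals} x {optimal.leaves_per_individual}"
        )
    return SelectionResult(screening.admissible, best, table, minimum, optimal, audit)
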