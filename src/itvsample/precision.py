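"""Resampling precision curves and their broken-line flex point.

The precision of a trait estimate from ``n`` leaves is summarized by the
standard error SD/sqrt(n) of simple random subsamples drawn without
replacement from the full dataset.  Averaged over many replicates per ``n``,
the mean SE traces a decreasing curve; its flex point — the breakpoint psi of
a two-segment linear fit — marks the sample size beyond which extra leaves
buy little extra precision.  The fitted SE at psi (``se_min``) is used
downstream as the minimum acceptable precision for screening sampling
strategies.  An analogous CV curve (SD/mean) is built alongside.

The broken-line model is y = b0 + b1*n + b2*(n - psi)_+ with a single free
breakpoint, estimated by an exhaustive grid search over interior grid points
followed by iterative linearization (the gap-coefficient update of broken-
line regression: refit with the extra column -1{n > psi} and shift psi by
the ratio of its coefficient to the slope change until the shift vanishes).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data import TraitDataset
from .errors import ConfigError

__all__ = [
    "PrecisionCurve",
    "BreakpointFit",
    "resample_se_curve",
    "fit_breakpoint",
    "fit_segmented",
]


@dataclass
class PrecisionCurve:
    """Mean SE and CV of resampled trait means over a grid of sample sizes."""

    trait: str
    n: np.ndarray
    se: np.ndarray
    cv: np.ndarray
    reps: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.se = np.asarray(self.se, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        if not (np.diff(self.n) > 0).all():
            raise ConfigError("sample-size grid must be strictly increasing")
        if (self.n < 2).any():
            raise ConfigError("SE is undefined below n = 2")


def resample_se_curve(
    dataset: TraitDataset | np.ndarray,
    trait: str | None = None,
    n_grid=None,
    reps: int = 4999,
    seed: int | None = None,
) -> PrecisionCurve:
    """Build the mean SE / CV versus sample-size curve by resampling.

    For each ``n`` in the grid, ``reps`` simple random samples of ``n``
    leaves are drawn without replacement; each replicate contributes
    SE = SD/sqrt(n) and CV = SD/mean, and the curve stores the arithmetic
    mean over replicates.  ``n = 1`` entries are dropped with a warning
    (a single leaf has no SE); n beyond the dataset size is an error.
    """
    if isinstance(dataset, TraitDataset):
        values = dataset.values(trait)
    else:
        values = np.asarray(dataset, dtype=float)
        trait = trait or "trait"
    big_n = values.size
    if reps < 2:
        raise ConfigError("reps must be >= 2")
    if n_grid is None:
        n_grid = np.arange(2, big_n + 1)
    n_grid = np.asarray(sorted(set(int(v) for v in np.asarray(n_grid).ravel())))
    if (n_grid < 1).any() or (n_grid > big_n).any():
        raise ConfigError(f"sample sizes must lie in [1, {big_n}]")
    if (n_grid == 1).any():
        warnings.warn("n = 1 excluded from the precision curve (SE undefined)")
        n_grid = n_grid[n_grid > 1]
    if n_grid.size == 0:
        raise ConfigError("empty sample-size grid")

    rng = np.random.default_rng(seed)
    mean_se = np.empty(n_grid.size)
    mean_cv = np.empty(n_grid.size)
    for j, n in enumerate(n_grid):
        if n == big_n:  # every subsample is the whole dataset
            sd = values.std(ddof=1)
            mean_se[j] = sd / math.sqrt(n)
            mean_cv[j] = sd / values.mean()
            continue
        keys = rng.random((reps, big_n))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        sample = values[idx]
        sd = sample.std(axis=1, ddof=1)
        mean_se[j] = float(np.mean(sd / math.sqrt(n)))
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_cv[j] = float(np.mean(sd / sample.mean(axis=1)))
    return PrecisionCurve(trait=trait, n=n_grid, se=mean_se, cv=mean_cv,
                          reps=reps, seed=seed)


@dataclass
class BreakpointFit:
    """A fitted two-segment (broken-line) regression."""

    psi: float
    se_min: float  # fitted curve value at psi
    intercept: float
    slope_left: float
    slope_right: float
    rss: float
    converged: bool
    n_iter: int
    message: str = ""


def _segmented_ols(x: np.ndarray, y: np.ndarray, psi: float):
    u = np.clip(x - psi, 0.0, None)
    design = np.column_stack([np.ones_like(x), x, u])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ coef) ** 2))
    return coef, rss


def fit_segmented(x, y, tol: float = 1e-8, max_iter: int = 100) -> BreakpointFit:
    """Estimate a single breakpoint on raw (x, y) pairs.

    Grid-search initialization over interior x values, then iterative
    linearization.  A flat problem (no RSS gain over a straight line)
    returns ``converged=False`` with a diagnostic message.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 6:
        raise ConfigError("breakpoint fit needs at least 6 grid points")
    order = np.argsort(x)
    x, y = x[order], y[order]

    line = np.column_stack([np.ones_like(x), x])
    line_coef, _, _, _ = np.linalg.lstsq(line, y, rcond=None)
    line_rss = float(np.sum((y - line @ line_coef) ** 2))

    # exhaustive initialization: candidate breakpoints at interior x values
    # with at least two points strictly on each side
    candidates = [float(c) for c in np.unique(x)[1:-1] if
                  (x < c).sum() >= 2 and (x > c).sum() >= 2]
    if not candidates:
        raise ConfigError("no admissible interior breakpoint candidates")
    grid = [(psi, *_segmented_ols(x, y, psi)) for psi in candidates]
    psi0, coef0, rss0 = min(grid, key=lambda g: g[2])

    scale = float(np.sum((y - y.mean()) ** 2)) or 1.0
    if line_rss - rss0 <= 1e-10 * scale:
        b0, b1, b2 = coef0
        return BreakpointFit(
            psi=psi0, se_min=float(b0 + b1 * psi0), intercept=float(b0),
            slope_left=float(b1), slope_right=float(b1 + b2), rss=rss0,
            converged=False, n_iter=0,
            message="RSS flat: no breakpoint improves on a straight line",
        )

    psi = psi0
    best = (psi0, coef0, rss0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = np.clip(x - psi, 0.0, None)
        v = -(x > psi).astype(float)
        design = np.column_stack([np.ones_like(x), x, u, v])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        b_u, b_v = coef[2], coef[3]
        if abs(b_u) < 1e-12 * (abs(coef[1]) + 1e-12):
            break  # slope change vanished; not identifiable from here
        step = b_v / b_u
        new_psi = psi + step
        if not (x[1] <= new_psi <= x[-2]):
            break  # left the admissible range; keep grid solution
        psi = float(new_psi)
        coef3, rss = _segmented_ols(x, y, psi)
        if rss <= best[2]:
            best = (psi, coef3, rss)
        if abs(step) < tol:
            converged = True
            break
    psi, coef, rss = best
    b0, b1, b2 = coef
    return BreakpointFit(
        psi=float(psi), se_min=float(b0 + b1 * psi), intercept=float(b0),
        slope_left=float(b1), slope_right=float(b1 + b2), rss=float(rss),
        converged=converged, n_iter=it,
        message="" if converged else "iteration stopped; best grid fit returned",
    )


def fit_breakpoint(curve: PrecisionCurve, response: str = "se") -> BreakpointFit:
    """Fit the flex point of a precision curve (``response`` = se or cv)."""
    if response not in ("se", "cv"):
        raise ConfigError("response must be 'se' or 'cv'")
    fit = fit_segmented(curve.n.astype(float), getattr(curve, response))
    if fit.se_min < 0:  # dispersion measures cannot be negative
        fit = dataclasses.replace(fit, se_min=0.0)
    return fit
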