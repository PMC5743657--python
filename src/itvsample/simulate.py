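"""Synthetic leaf-trait datasets with a controlled hierarchical variance
structure.

The generator emulates a nested canopy sampling campaign: a few quadrats,
an uneven number of tree individuals per quadrat, and a balanced within-crown
design of ``leaves_per_stratum`` leaves in each of the four (height class x
external/internal) strata — 12 leaves per individual at the default of 3.
Each trait value is

    y = grand_mean + sum of term effects + residual,

where the terms are the main effects and interactions of the canopy model
(quadrat, individual-within-quadrat, height class, canopy position, and
their interactions) and each term receives a configurable fraction of the
total variance.

Two sampling modes are offered.  In the default *empirical* mode the realized
effect vectors are orthogonalized sequentially against all preceding model
terms and rescaled so each term's realized sum of squares is exactly
``fraction * total_sd^2 * (N - 1)`` (the convention of
``MASS::mvrnorm(empirical = TRUE)``); a sequential ANOVA on such data returns
the configured variance shares exactly, which makes parameter-recovery tests
sharp.  With ``empirical=False`` level effects are plain i.i.d. Gaussian
draws with variance ``fraction * total_sd^2`` — the natural sampling model,
appropriate e.g. for null-distribution (type-I error) studies, where the
empirical mode's orthogonality conditioning would be unfaithful.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import ModelTerm, standard_terms, _indicator, _orth_complement
from .data import STRATA, TraitDataset
from .errors import ConfigError

#: Variance-structure terms the generator understands, in model order.
GENERATOR_TERMS: tuple[str, ...] = tuple(t.name for t in standard_terms())

#: Default variance fractions per trait: SS shares of the terms that are
#: clearly supported for each trait in holm-oak canopy data (main effects
#: for both traits, plus the quadrat x position and height x position
#: interactions for osmotic potential); the remainder is residual.
SLA_FRACTIONS: dict[str, float] = {
    "quadrat": 0.012,
    "h_class": 0.185,
    "position": 0.026,
    "individual": 0.150,
    "residual": 0.627,
}
PI_FRACTIONS: dict[str, float] = {
    "quadrat": 0.039,
    "h_class": 0.014,
    "position": 0.026,
    "individual": 0.222,
    "quadrat:position": 0.024,
    "h_class:position": 0.010,
    "residual": 0.665,
}


@dataclass(frozen=True)
class TraitModel:
    """Marginal model for one trait: location, spread and variance shares."""

    grand_mean: float
    total_sd: float
    variance_fractions: Mapping[str, float]

    def validated(self) -> dict[str, float]:
        fr = dict(self.variance_fractions)
        unknown = set(fr) - set(GENERATOR_TERMS) - {"residual"}
        if unknown:
            raise ConfigError(f"unknown variance terms: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()):
            raise ConfigError("variance fractions must be non-negative")
        total = sum(fr.values())
        if total != 0 and abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"variance fractions must sum to 1 (or all be 0), got {total}"
            )
        if self.total_sd < 0:
            raise ConfigError("total_sd must be non-negative")
        return fr


@dataclass(frozen=True)
class SynthConfig:
    """Design shape plus per-trait variance structure.

    Defaults mirror the motivating holm-oak campaign: three quadrats with
    5/17/12 individuals, 3 leaves in each of the four canopy strata (408
    leaves in total), specific leaf area around 8.02 mm^2/mg and osmotic
    potential around 3.29 -MPa.
    """

    individuals_per_quadrat: tuple[int, ...] = (5, 17, 12)
    leaves_per_stratum: int = 3
    traits: Mapping[str, TraitModel] = field(
        default_factory=lambda: {
            "sla": TraitModel(8.02, 0.96, SLA_FRACTIONS),
            "pi": TraitModel(3.29, 1.01, PI_FRACTIONS),
        }
    )
    empirical: bool = True
    residual_corr: float = 0.0
    seed: int | None = None

    def validate(self) -> None:
        if not self.individuals_per_quadrat or any(
            k < 1 for k in self.individuals_per_quadrat
        ):
            raise ConfigError("each quadrat needs at least one individual")
        if self.leaves_per_stratum < 1:
            raise ConfigError("leaves_per_stratum must be >= 1")
        if not self.traits:
            raise ConfigError("at least one trait is required")
        if not -1.0 <= self.residual_corr <= 1.0:
            raise ConfigError("residual_corr must be in [-1, 1]")
        for model in self.traits.values():
            model.validated()

    @property
    def n_observations(self) -> int:
        return sum(self.individuals_per_quadrat) * 4 * self.leaves_per_stratum


def study_config(**overrides) -> SynthConfig:
    """The default study-shaped configuration (408 leaves, 34 individuals)."""
    return SynthConfig(**overrides)


def azimuth_to_exposure(azimuth) -> np.ndarray:
    """Map azimuth degrees in [0, 360) to N/E/S/W sectors.

    East is (45, 135], south (135, 225], west (225, 315], north the rest;
    the measure-zero sector boundaries are assigned to the counter-clockwise
    neighbour (45 -> N, 135 -> E, 225 -> S, 315 -> W).
    """
    u = np.asarray(azimuth, dtype=float)
    out = np.full(u.shape, "N", dtype="<U1")
    out[(u > 45) & (u <= 135)] = "E"
    out[(u > 135) & (u <= 225)] = "S"
    out[(u > 225) & (u <= 315)] = "W"
    return out


def assign_exposures(rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw random azimuths uniform on [0, 360) and bin them into sectors."""
    return azimuth_to_exposure(rng.uniform(0.0, 360.0, size))


def _design_frame(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for qi, n_ind in enumerate(config.individuals_per_quadrat, start=1):
        quadrat = f"Q{qi}"
        for ii in range(1, n_ind + 1):
            individual = f"I{ii:02d}"
            leaf = 0
            for h, p in STRATA:
                for _ in range(config.leaves_per_stratum):
                    leaf += 1
                    rows.append(
                        (quadrat, individual, f"L{leaf:02d}", h, p)
                    )
    df = pd.DataFrame(
        rows, columns=["quadrat", "individual", "leaf_id", "h_class", "position"]
    )
    df["exposure"] = assign_exposures(rng, len(df))
    return df


def generate_dataset(config: SynthConfig, seed: int | None = None) -> TraitDataset:
    """Generate one dataset; identical (config, seed) pairs give identical data."""
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    df = _design_frame(config, rng)
    n = len(df)

    # model-term spans, shared by every trait
    terms = standard_terms()
    q0 = np.full((n, 1), 1.0 / math.sqrt(n))
    blocks: dict[str, np.ndarray] = {}
    basis = q0
    for t in terms:
        b = _orth_complement(_indicator(df, t.factors), basis)
        blocks[t.name] = b  # may be empty if the term is aliased in this design
        if b.shape[1]:
            basis = np.hstack([basis, b])
    full_basis = basis
    needs_effects = any(
        m.total_sd > 0 and sum(m.validated().values()) > 0
        for m in config.traits.values()
    )
    if config.empirical and needs_effects and n - full_basis.shape[1] <= 0:
        raise ConfigError(
            "empirical mode needs residual degrees of freedom; enlarge the design"
        )

    trait_names = list(config.traits)
    resid_z = rng.standard_normal((n, len(trait_names)))
    if config.residual_corr and len(trait_names) >= 2:
        rho = config.residual_corr
        resid_z[:, 1] = rho * resid_z[:, 0] + math.sqrt(1 - rho**2) * resid_z[:, 1]

    for k, name in enumerate(trait_names):
        model = config.traits[name]
        fractions = model.validated()
        sd = model.total_sd
        y = np.full(n, float(model.grand_mean))
        if sd > 0 and sum(fractions.values()) > 0:
            for t in terms:
                f = fractions.get(t.name, 0.0)
                if f <= 0:
                    continue
                b = blocks[t.name]
                if b.shape[1] == 0:
                    raise ConfigError(
                        f"term {t.name!r} carries variance but is aliased in"
                        " this design"
                    )
                if config.empirical:
                    v = b @ rng.standard_normal(b.shape[1])
                    v *= math.sqrt(f * sd**2 * (n - 1)) / np.linalg.norm(v)
                else:
                    z = _indicator(df, t.factors)
                    v = z @ (rng.standard_normal(z.shape[1]) * math.sqrt(f) * sd)
                y = y + v
            f_res = fractions.get("residual", 0.0)
            if f_res > 0:
                eps = resid_z[:, k]
                if config.empirical:
                    eps = eps - full_basis @ (full_basis.T @ eps)
                    eps = eps * (
                        math.sqrt(f_res * sd**2 * (n - 1)) / np.linalg.norm(eps)
                    )
                else:
                    eps = eps * math.sqrt(f_res) * sd
                y = y + eps
        df[name] = y
    return TraitDataset(df, trait_names=trait_names, validate=False)
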