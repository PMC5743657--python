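"""Leaf-level trait tables for hierarchical canopy sampling designs.

A dataset is a flat table of leaves (one row per leaf pair measured for all
traits), each labelled with its position in a nested spatial design:

* ``quadrat`` — sampling plot (three 10 x 10 m plots in the motivating study),
* ``individual`` — tree, unique within its quadrat,
* ``h_class`` — canopy height class, ``a`` (base to 2.5 m) or ``b`` (above),
* ``position`` — horizontal canopy stratum, ``E`` (external) or ``I``
  (internal),
* ``exposure`` — azimuthal exposure, one of N/E/S/W.

Trait columns hold positive values: ``sla`` is specific leaf area in mm^2/mg
and ``pi`` is the magnitude of leaf osmotic potential in -MPa (a negative
water potential stored as a positive number, following the common reporting
convention).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

FACTOR_COLUMNS = ("quadrat", "individual", "h_class", "position", "exposure")
H_CLASSES = ("a", "b")
POSITIONS = ("E", "I")
EXPOSURES = ("N", "E", "S", "W")
STRATA = tuple((h, p) for h in H_CLASSES for p in POSITIONS)

#: Traits recognised by default when a file does not declare its trait columns.
DEFAULT_TRAITS = ("sla", "pi")
#: Traits whose values must be strictly positive (sla by definition, pi by
#: the positive-magnitude sign convention).
POSITIVE_TRAITS = frozenset({"sla", "pi"})

_LEVELS = {"h_class": H_CLASSES, "position": POSITIONS, "exposure": EXPOSURES}


@dataclass(frozen=True)
class Dialect:
    """How to interpret a delimited trait table.

    Parameters
    ----------
    sep
        Field separator (default comma).
    columns
        Optional mapping from canonical column names (``quadrat``,
        ``individual``, ``h_class``, ``position``, ``exposure``, ``leaf_id``
        and trait names) to the headers actually used in the file.
    traits
        Trait columns to read.  ``None`` means: whichever of the default
        traits (``sla``, ``pi``) are present.  Undeclared extra columns are
        ignored.
    negative_traits
        Traits recorded with their physical (negative) sign in the file;
        values are negated on input so the dataset stores positive
        magnitudes.  Typically ``("pi",)`` for osmotic potential in MPa.
    """

    sep: str = ","
    columns: Mapping[str, str] | None = None
    traits: tuple[str, ...] | None = None
    negative_traits: tuple[str, ...] = ()

    def rename(self, canonical: str) -> str:
        if self.columns and canonical in self.columns:
            return self.columns[canonical]
        return canonical


class TraitDataset:
    """Validated leaf-level trait table.

    Wraps a :class:`pandas.DataFrame` with the factor columns listed in
    :data:`FACTOR_COLUMNS`, a ``leaf_id`` column unique within each
    (quadrat, individual), and one numeric column per trait.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        trait_names: Sequence[str] | None = None,
        validate: bool = True,
    ) -> None:
        frame = frame.reset_index(drop=True).copy()
        if trait_names is None:
            trait_names = [t for t in DEFAULT_TRAITS if t in frame.columns]
        self.trait_names: list[str] = list(trait_names)
        if "leaf_id" not in frame.columns:
            # stable synthetic ids: running count within each individual
            frame["leaf_id"] = (
                frame.groupby(["quadrat", "individual"], sort=False)
                .cumcount()
                .add(1)
                .map("L{:02d}".format)
            )
        self.frame = frame
        if validate:
            self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        df = self.frame
        if not self.trait_names:
            raise SchemaError("dataset declares no trait columns")
        missing = [c for c in FACTOR_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        missing_t = [t for t in self.trait_names if t not in df.columns]
        if missing_t:
            raise SchemaError(f"missing trait column(s): {', '.join(missing_t)}")
        if len(df) == 0:
            raise ValidationError("dataset has no observations")
        for col, levels in _LEVELS.items():
            bad = ~df[col].astype(str).isin(levels)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(
                    f"illegal {col} level {df[col].iloc[row]!r} in row {row}"
                    f" (allowed: {', '.join(levels)})"
                )
        dup = df.duplicated(subset=["quadrat", "individual", "leaf_id"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValidationError(
                f"duplicate (quadrat, individual, leaf_id) in row {row}"
            )
        for t in self.trait_names:
            values = pd.to_numeric(df[t], errors="coerce").to_numpy(float)
            bad = ~np.isfinite(values)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"non-numeric or non-finite value for trait {t!r} in row {row}"
                )
            if t in POSITIVE_TRAITS and (values <= 0).any():
                row = int(np.flatnonzero(values <= 0)[0])
                raise ValidationError(
                    f"trait {t!r} must be positive; row {row} has {values[row]!r}"
                )
            df[t] = values

    # -- basic protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_observations(self) -> int:
        return len(self.frame)

    def values(self, trait: str) -> np.ndarray:
        if trait not in self.trait_names:
            raise SchemaError(f"unknown trait {trait!r}")
        return self.frame[trait].to_numpy(float)

    def equals(self, other: "TraitDataset", atol: float = 1e-9) -> bool:
        if self.trait_names != other.trait_names:
            return False
        a, b = self.frame, other.frame
        if len(a) != len(b):
            return False
        cols = list(FACTOR_COLUMNS) + ["leaf_id"]
        if not (a[cols].astype(str).to_numpy() == b[cols].astype(str).to_numpy()).all():
            return False
        for t in self.trait_names:
            if not np.allclose(a[t], b[t], rtol=0, atol=atol):
                return False
        return True


@dataclass
class DesignSummary:
    """Bookkeeping counts for a hierarchical sampling design."""

    n_quadrats: int
    n_individuals: int
    n_leaves: int
    individuals_per_quadrat: dict[str, int] = field(default_factory=dict)
    leaves_per_individual: dict[tuple[str, str], int] = field(default_factory=dict)
    stratum_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    stratum_counts_per_individual: dict[tuple[str, str], dict[tuple[str, str], int]] = field(
        default_factory=dict
    )


def summarize_design(dataset: TraitDataset) -> DesignSummary:
    """Count quadrats, individuals, leaves and canopy-stratum cells."""
    df = dataset.frame
    ind = df["quadrat"].astype(str) + "\x1f" + df["individual"].astype(str)
    per_quadrat = (
        df.assign(_ind=ind).groupby("quadrat", sort=True)["_ind"].nunique().to_dict()
    )
    leaves = df.groupby(["quadrat", "individual"], sort=True).size()
    strata = df.groupby(["h_class", "position"], sort=True).size()
    per_ind_strata: dict[tuple[str, str], dict[tuple[str, str], int]] = {}
    for (q, i, h, p), n in (
        df.groupby(["quadrat", "individual", "h_class", "position"], sort=True)
        .size()
        .items()
    ):
        per_ind_strata.setdefault((q, i), {})[(h, p)] = int(n)
    summary = DesignSummary(
        n_quadrats=int(df["quadrat"].nunique()),
        n_individuals=int(ind.nunique()),
        n_leaves=int(len(df)),
        individuals_per_quadrat={str(k): int(v) for k, v in per_quadrat.items()},
        leaves_per_individual={(str(q), str(i)): int(n) for (q, i), n in leaves.items()},
        stratum_counts={(str(h), str(p)): int(n) for (h, p), n in strata.items()},
        stratum_counts_per_individual=per_ind_strata,
    )
    assert summary.n_individuals == sum(summary.individuals_per_quadrat.values())
    assert summary.n_leaves == sum(summary.leaves_per_individual.values())
    return summary


def compute_sla(leaf_area, dry_weight):
    """Specific leaf area: fresh leaf area (mm^2) over dry mass (mg).

    Accepts scalars or arrays; both inputs must be strictly positive.
    """
    area = np.asarray(leaf_area, dtype=float)
    mass = np.asarray(dry_weight, dtype=float)
    if (area <= 0).any() or (mass <= 0).any() or not (
        np.isfinite(area).all() and np.isfinite(mass).all()
    ):
        raise ValidationError("leaf area and dry weight must be finite and positive")
    out = area / mass
    return float(out) if out.ndim == 0 else out


def read_trait_table(path, dialect: Dialect | None = None) -> TraitDataset:
    """Read a delimited leaf-level trait table into a validated dataset."""
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    if dialect.columns:
        reverse = {v: k for k, v in dialect.columns.items()}
        df = df.rename(columns=reverse)
    missing = [c for c in FACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if dialect.traits is not None:
        traits = list(dialect.traits)
        absent = [t for t in traits if t not in df.columns]
        if absent:
            raise SchemaError(f"{path}: missing trait column(s): {', '.join(absent)}")
    else:
        traits = [t for t in DEFAULT_TRAITS if t in df.columns]
        if not traits:
            raise SchemaError(
                f"{path}: no recognised trait column among {DEFAULT_TRAITS}"
            )
    keep = [c for c in list(FACTOR_COLUMNS) + ["leaf_id"] if c in df.columns]
    df = df[keep + traits]
    for t in traits:
        values = pd.to_numeric(df[t], errors="coerce")
        bad = values.isna() & df[t].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: unparseable value {df[t].iloc[row]!r} for trait {t!r}"
                f" in row {row}"
            )
        if t in dialect.negative_traits:
            values = -values
        df[t] = values
    return TraitDataset(df, trait_names=traits)


def write_trait_table(dataset: TraitDataset, path, dialect: Dialect | None = None) -> None:
    """Write a dataset as delimited text, re-readable by :func:`read_trait_table`.

    Trait values are written with 12 significant digits so a round trip
    changes them by less than 1e-9 relative.
    """
    dialect = dialect or Dialect()
    if not dataset.trait_names:
        raise SchemaError("dataset declares no trait columns")
    df = dataset.frame[list(FACTOR_COLUMNS) + ["leaf_id"] + dataset.trait_names].copy()
    for t in dataset.trait_names:
        if t in dialect.negative_traits:
            df[t] = -df[t]
    if dialect.columns:
        df = df.rename(columns=dict(dialect.columns))
    df.to_csv(path, sep=dialect.sep, index=False, float_format="%.12g")
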