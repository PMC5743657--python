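"""Permutational ANOVA for nested/crossed canopy sampling designs.

With a univariate response and Euclidean distance, permutational multivariate
ANOVA reduces to classical ANOVA sums of squares, tested by permutation
instead of the F distribution.  This module implements that reduction
directly:

* every factor is treated as fixed; ``individual`` is nested in ``quadrat``;
* term sums of squares are computed by orthogonal projection.  Each term's
  model subspace is the span of its cell indicators orthogonalized against
  all of its marginal (ancestor) terms, so nesting is handled exactly and
  both sequential (Type I) and partial (Type III-like, extra-SS-given-all-
  other-terms) decompositions are available;
* the pseudo-F ratio for every term uses the residual mean square as
  denominator;
* p-values come from permutation of residuals under the reduced model
  (Freedman–Lane): for each tested term, residuals of the model containing
  all *other* terms are permuted, added back to the reduced-model fit, and
  the term's extra-SS pseudo-F is recomputed.

Variance explained by a term is reported as its share of the total corrected
sum of squares (SS ratio), not as a REML variance component.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import TraitDataset
from .errors import AliasingError, ConfigError, SchemaError

_RANK_TOL = 1e-9


@dataclass(frozen=True)
class ModelTerm:
    """A main effect or interaction entering the linear model.

    ``factors`` lists design columns; the special factor ``individual`` is
    always read as individual-within-quadrat (labels qualified by quadrat).
    """

    name: str
    factors: tuple[str, ...]

    def expanded(self) -> frozenset[str]:
        """Factor set with nesting made explicit (individual implies quadrat)."""
        out = set(self.factors)
        if "individual" in out:
            out.add("quadrat")
        return frozenset(out)


def standard_terms() -> list[ModelTerm]:
    """The full canopy model in its conventional order: main effects, then
    two-way interactions, then three-way interactions."""
    spec = [
        ("quadrat",),
        ("h_class",),
        ("position",),
        ("individual",),
        ("quadrat", "h_class"),
        ("quadrat", "position"),
        ("h_class", "position"),
        ("individual", "h_class"),
        ("individual", "position"),
        ("quadrat", "h_class", "position"),
        ("individual", "h_class", "position"),
    ]
    return [ModelTerm(":".join(f), f) for f in spec]


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation test.

    ``method="sampled"`` draws ``n_perm`` random permutations and uses the
    add-one convention p = (1 + #{F* >= F}) / (1 + n_perm).  With
    ``method="exhaustive"`` (small datasets only) every permutation is
    enumerated and p is the exact tail proportion including the identity.
    """

    n_perm: int = 999
    alpha: float = 0.05
    seed: int | None = None
    method: str = "sampled"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.method not in ("sampled", "exhaustive"):
            raise ConfigError(f"unknown permutation method {self.method!r}")


@dataclass
class AnovaTable:
    """Per-term ANOVA decomposition with SS-ratio variance percentages."""

    terms: list[str]
    df: dict[str, int]
    ss: dict[str, float]
    residual_df: int
    residual_ss: float
    total_ss: float
    ss_type: str
    trait: str | None = None
    p_perm: dict[str, float] | None = None
    n_perm: int | None = None

    @property
    def ms(self) -> dict[str, float]:
        return {t: self.ss[t] / self.df[t] for t in self.terms}

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df if self.residual_df > 0 else math.nan

    @property
    def pseudo_f(self) -> dict[str, float]:
        denom = self.residual_ms
        if not np.isfinite(denom) or denom <= 0:
            return {t: math.nan for t in self.terms}
        return {t: self.ms[t] / denom for t in self.terms}

    def variance_percent(self) -> dict[str, float]:
        if self.total_ss <= 0:
            return {t: math.nan for t in [*self.terms, "residual"]}
        out = {t: 100.0 * self.ss[t] / self.total_ss for t in self.terms}
        out["residual"] = 100.0 * self.residual_ss / self.total_ss
        return out

    def to_frame(self) -> pd.DataFrame:
        pct = self.variance_percent()
        f = self.pseudo_f
        rows = [
            {
                "term": t,
                "df": self.df[t],
                "SS": self.ss[t],
                "MS": self.ms[t],
                "pseudo_F": f[t],
                "p_perm": (self.p_perm or {}).get(t, math.nan),
                "variance_percent": pct[t],
            }
            for t in self.terms
        ]
        rows.append(
            {
                "term": "residual",
                "df": self.residual_df,
                "SS": self.residual_ss,
                "MS": self.residual_ms,
                "pseudo_F": math.nan,
                "p_perm": math.nan,
                "variance_percent": pct["residual"],
            }
        )
        rows.append(
            {
                "term": "total",
                "df": self.residual_df + sum(self.df.values()),
                "SS": self.total_ss,
                "MS": math.nan,
                "pseudo_F": math.nan,
                "p_perm": math.nan,
                "variance_percent": 100.0 if self.total_ss > 0 else math.nan,
            }
        )
        return pd.DataFrame(rows)


def _orth_complement(block: np.ndarray, basis: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis of col(block) minus the span of ``basis``."""
    x = block.astype(float, copy=True)
    if basis is not None and basis.shape[1]:
        # two Gram-Schmidt passes for numerical safety
        x -= basis @ (basis.T @ x)
        x -= basis @ (basis.T @ x)
    if not x.shape[1]:
        return x
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    keep = s > _RANK_TOL * max(x.shape[0], 1) * (s[0] if s.size else 1.0)
    return u[:, keep]


def _indicator(frame: pd.DataFrame, factors: tuple[str, ...]) -> np.ndarray:
    cols = []
    for f in factors:
        if f not in frame.columns:
            raise SchemaError(f"model factor {f!r} not present in the data")
        col = frame[f].astype(str)
        if f == "individual":
            col = frame["quadrat"].astype(str) + "\x1f" + col
        cols.append(col.to_numpy())
    key = cols[0]
    for c in cols[1:]:
        key = np.char.add(np.char.add(key.astype(str), "\x1f"), c.astype(str))
    codes, uniques = pd.factorize(key)
    z = np.zeros((len(key), len(uniques)))
    z[np.arange(len(key)), codes] = 1.0
    return z


class AnovaDesign:
    """Precomputed projection bases for a fixed design and term list.

    Building the bases once and reusing them across responses (or across
    simulated datasets sharing a layout) keeps repeated fits cheap.
    """

    def __init__(self, frame, terms: list[ModelTerm] | None = None) -> None:
        if isinstance(frame, TraitDataset):
            frame = frame.frame
        self.frame = frame
        self.terms = list(terms) if terms is not None else standard_terms()
        self.n = len(frame)
        n = self.n
        q0 = np.full((n, 1), 1.0 / math.sqrt(n))
        self._q0 = q0

        # contrast basis per term: cell indicators orthogonalized against
        # every ancestor term (and the intercept)
        indicators = {t.name: _indicator(frame, t.factors) for t in self.terms}
        self._contrast: dict[str, np.ndarray] = {}
        for t in self.terms:
            anc_blocks = [q0] + [
                indicators[u.name]
                for u in self.terms
                if u.expanded() < t.expanded()
            ]
            anc_basis = _orth_complement(np.hstack(anc_blocks), None)
            c = _orth_complement(indicators[t.name], anc_basis)
            if c.shape[1] == 0:
                raise AliasingError(
                    f"term {t.name!r} is aliased: no estimable degrees of freedom"
                    " in this design"
                )
            self._contrast[t.name] = c

        # sequential bases (in term order) and the full-model basis
        self._seq_blocks: dict[str, np.ndarray] = {}
        basis = q0
        for t in self.terms:
            b = _orth_complement(self._contrast[t.name], basis)
            if b.shape[1] != self._contrast[t.name].shape[1]:
                raise AliasingError(
                    f"term {t.name!r} is partially confounded with preceding terms"
                )
            self._seq_blocks[t.name] = b
            basis = np.hstack([basis, b])
        self._q_full = basis
        self.rank = basis.shape[1]
        self.residual_df = n - self.rank
        if self.residual_df <= 0:
            raise AliasingError("design leaves no residual degrees of freedom")
        self._q_reduced: dict[str, np.ndarray] = {}

    @property
    def full_basis(self) -> np.ndarray:
        return self._q_full

    def term_df(self, name: str) -> int:
        return self._contrast[name].shape[1]

    def reduced_basis(self, name: str) -> np.ndarray:
        """Orthonormal basis of the model containing every term but ``name``."""
        if name not in self._q_reduced:
            basis = self._q0
            for t in self.terms:
                if t.name == name:
                    continue
                b = _orth_complement(self._contrast[t.name], basis)
                basis = np.hstack([basis, b])
            self._q_reduced[name] = basis
        return self._q_reduced[name]

    # -- fitting --------------------------------------------------------

    def anova(self, y: np.ndarray, ss_type: str = "sequential",
              trait: str | None = None) -> AnovaTable:
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ConfigError(f"response must have length {self.n}")
        total = float(y @ y - self.n * y.mean() ** 2)
        fullfit = float((self._q_full.T @ y) @ (self._q_full.T @ y))
        residual = max(float(y @ y) - fullfit, 0.0)
        ss: dict[str, float] = {}
        df: dict[str, int] = {}
        if ss_type == "sequential":
            for t in self.terms:
                proj = self._seq_blocks[t.name].T @ y
                ss[t.name] = float(proj @ proj)
                df[t.name] = self._seq_blocks[t.name].shape[1]
        elif ss_type == "partial":
            for t in self.terms:
                qr = self.reduced_basis(t.name)
                redfit = float((qr.T @ y) @ (qr.T @ y))
                ss[t.name] = max(fullfit - redfit, 0.0)
                df[t.name] = self.rank - qr.shape[1]
        else:
            raise ConfigError(f"unknown ss_type {ss_type!r}")
        return AnovaTable(
            terms=[t.name for t in self.terms],
            df=df,
            ss=ss,
            residual_df=self.residual_df,
            residual_ss=residual,
            total_ss=total,
            ss_type=ss_type,
            trait=trait,
        )

    def permutation_pvalues(
        self, y: np.ndarray, table: AnovaTable, cfg: PermutationConfig
    ) -> AnovaTable:
        """Freedman–Lane permutation p-values for every term in ``table``."""
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(cfg.seed)
        yy = float(y @ y)
        a_full = self._q_full.T @ y
        fullfit = float(a_full @ a_full)
        ss_res = max(yy - fullfit, 0.0)
        pvals: dict[str, float] = {}
        for t in self.terms:
            qr = self.reduced_basis(t.name)
            df_t = self.rank - qr.shape[1]
            a_red = qr.T @ y
            ss_term = max(fullfit - float(a_red @ a_red), 0.0)
            if ss_term <= 0 and ss_res <= 0:
                pvals[t.name] = 1.0  # constant response: nothing to test
                continue
            if ss_res <= 0 or self.residual_df == 0:
                pvals[t.name] = math.nan
                continue
            f_obs = (ss_term / df_t) / (ss_res / self.residual_df)
            fitted = qr @ a_red
            resid = y - fitted
            if cfg.method == "exhaustive":
                if self.n > 9:
                    raise ConfigError("exhaustive enumeration limited to n <= 9")
                f_all = []
                for perm in itertools.permutations(range(self.n)):
                    f_all.append(self._perm_f(fitted + resid[list(perm)], qr, df_t))
                f_all = np.asarray(f_all)
                pvals[t.name] = float(
                    np.mean(f_all >= f_obs - 1e-12 * max(1.0, abs(f_obs)))
                )
            else:
                perms = rng.permuted(
                    np.broadcast_to(resid, (cfg.n_perm, self.n)).copy(), axis=1
                )
                ystar = fitted[:, None] + perms.T
                af = self._q_full.T @ ystar
                ar = qr.T @ ystar
                ssf = np.einsum("ij,ij->j", af, af)
                ssr = np.einsum("ij,ij->j", ar, ar)
                sst = np.einsum("ij,ij->j", ystar, ystar)
                ss_term_p = np.maximum(ssf - ssr, 0.0)
                ss_res_p = np.maximum(sst - ssf, 0.0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    f_perm = (ss_term_p / df_t) / (ss_res_p / self.residual_df)
                exceed = int(
                    np.sum(f_perm >= f_obs - 1e-12 * max(1.0, abs(f_obs)))
                )
                pvals[t.name] = (1 + exceed) / (1 + cfg.n_perm)
        return replace(table, p_perm=pvals, n_perm=cfg.n_perm)

    def _perm_f(self, ystar: np.ndarray, qr: np.ndarray, df_t: int) -> float:
        af = self._q_full.T @ ystar
        ar = qr.T @ ystar
        ss_term = max(float(af @ af) - float(ar @ ar), 0.0)
        ss_res = max(float(ystar @ ystar) - float(af @ af), 0.0)
        if ss_res <= 0:
            return math.inf if ss_term > 0 else 0.0
        return (ss_term / df_t) / (ss_res / self.residual_df)


# -- spec-level convenience surface -------------------------------------


def fit_anova(
    dataset: TraitDataset,
    trait: str,
    terms: list[ModelTerm] | None = None,
    ss_type: str = "sequential",
) -> AnovaTable:
    """Fit the (permutational) ANOVA decomposition for one trait."""
    design = AnovaDesign(dataset, terms)
    return design.anova(dataset.values(trait), ss_type=ss_type, trait=trait)


def permutation_pvalues(
    dataset: TraitDataset,
    trait: str,
    table: AnovaTable,
    cfg: PermutationConfig | None = None,
    terms: list[ModelTerm] | None = None,
) -> AnovaTable:
    """Attach Freedman–Lane permutation p-values to a fitted table."""
    cfg = cfg or PermutationConfig()
    design = AnovaDesign(dataset, terms)
    if list(table.df) != [t.name for t in design.terms]:
        raise ConfigError("table terms do not match the supplied term list")
    return design.permutation_pvalues(dataset.values(trait), table, cfg)


def variance_percentages(table: AnovaTable) -> dict[str, float]:
    """Variance explained per term as a percentage of total SS."""
    return table.variance_percent()


def grouped_percentages(table: AnovaTable) -> dict[str, float]:
    """Group explained variance into canopy-related terms (h_class, position
    and every interaction containing them) versus plot/individual terms."""
    pct = table.variance_percent()
    canopy = 0.0
    plot_individual = 0.0
    for t in table.terms:
        factors = set(t.split(":"))
        if factors & {"h_class", "position"}:
            canopy += pct[t]
        else:
            plot_individual += pct[t]
    return {
        "canopy": canopy,
        "plot_individual": plot_individual,
        "residual": pct["residual"],
    }
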