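"""Variance partitioning: classical-ANOVA equivalence, permutation tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import itvsample as iv
from conftest import toy_dataset


def oneway_terms():
    return [iv.ModelTerm("h_class", ("h_class",))]


def test_balanced_oneway_matches_hand_computation():
    ds = toy_dataset([1, 2, 3, 4, 5, 6], "aaabbb")
    for ss_type in ("sequential", "partial"):
        t = iv.fit_anova(ds, "y", terms=oneway_terms(), ss_type=ss_type)
        assert t.ss["h_class"] == pytest.approx(13.5, abs=1e-10)
        assert t.residual_ss == pytest.approx(4.0, abs=1e-10)
        assert t.df["h_class"] == 1 and t.residual_df == 4
        assert t.pseudo_f["h_class"] == pytest.approx(13.5, abs=1e-9)


def test_pseudo_f_equals_classical_f_oneway(rng):
    values = rng.normal(size=24)
    groups = "ab" * 6 + "ba" * 6
    ds = toy_dataset(values, groups)
    t = iv.fit_anova(ds, "y", terms=oneway_terms())
    f, _ = sps.f_oneway(values[np.array(list(groups)) == "a"],
                        values[np.array(list(groups)) == "b"])
    assert t.pseudo_f["h_class"] == pytest.approx(f, rel=1e-10)


def test_balanced_two_factor_matches_statsmodels():
    """Sequential SS on a balanced crossed design agrees with an independent
    Type-I ANOVA implementation."""
    smf = pytest.importorskip("statsmodels.formula.api")
    from statsmodels.stats.anova import anova_lm

    rng = np.random.default_rng(5)
    h = np.repeat(["a", "b"], 10)
    p = np.tile(np.repeat(["E", "I"], 5), 2)
    y = rng.normal(size=20) + (h == "b") * 0.8 + (p == "I") * 0.3
    ds = toy_dataset(y, h, position=list(p))
    terms = [
        iv.ModelTerm("h_class", ("h_class",)),
        iv.ModelTerm("position", ("position",)),
        iv.ModelTerm("h_class:position", ("h_class", "position")),
    ]
    mine = iv.fit_anova(ds, "y", terms=terms)
    frame = ds.frame.assign(y=y)
    ref = anova_lm(smf.ols("y ~ C(h_class) * C(position)", frame).fit(), typ=1)
    for term, ref_row in zip(terms, ["C(h_class)", "C(position)",
                                     "C(h_class):C(position)"]):
        assert mine.ss[term.name] == pytest.approx(ref.loc[ref_row, "sum_sq"],
                                                   rel=1e-9)
    assert mine.residual_ss == pytest.approx(ref.loc["Residual", "sum_sq"], rel=1e-9)
    # balanced design: sequential and partial decompositions coincide
    part = iv.fit_anova(ds, "y", terms=terms, ss_type="partial")
    for term in terms:
        assert part.ss[term.name] == pytest.approx(mine.ss[term.name], abs=1e-9)


def test_full_design_ss_additivity(study_dataset):
    for trait in study_dataset.trait_names:
        t = iv.fit_anova(study_dataset, trait)
        assert sum(t.ss.values()) + t.residual_ss == pytest.approx(
            t.total_ss, rel=1e-8
        )
        pct = iv.variance_percentages(t)
        assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)


def test_grouped_percentages_partition(study_dataset):
    t = iv.fit_anova(study_dataset, "sla")
    g = iv.grouped_percentages(t)
    assert g["canopy"] + g["plot_individual"] + g["residual"] == pytest.approx(100.0)
    # canopy group collects every term touching h_class or position
    pct = iv.variance_percentages(t)
    expect = sum(v for k, v in pct.items()
                 if k != "residual" and ({"h_class", "position"} & set(k.split(":"))))
    assert g["canopy"] == pytest.approx(expect)


def test_constant_response_degenerates_cleanly():
    ds = toy_dataset([2.0] * 6, "aaabbb")
    t = iv.fit_anova(ds, "y", terms=oneway_terms())
    assert t.ss["h_class"] == pytest.approx(0.0, abs=1e-12)
    assert t.residual_ss == pytest.approx(0.0, abs=1e-12)
    assert math.isnan(t.pseudo_f["h_class"])
    t = iv.permutation_pvalues(ds, "y", t, iv.PermutationConfig(n_perm=49, seed=0),
                               terms=oneway_terms())
    assert t.p_perm["h_class"] == 1.0


def test_aliased_term_raises():
    ds = toy_dataset([1, 2, 3, 4], "aaaa")
    with pytest.raises(iv.AliasingError, match="h_class"):
        iv.fit_anova(ds, "y", terms=oneway_terms())


def test_permutation_p_matches_full_enumeration():
    """Exhaustively enumerated permutation p-value equals an independent
    brute-force oracle on a tiny two-group dataset."""
    values = [1.3, 0.2, 2.9, 3.8]
    groups = "aabb"
    ds = toy_dataset(values, groups)
    t = iv.fit_anova(ds, "y", terms=oneway_terms())
    t = iv.permutation_pvalues(
        ds, "y", t,
        iv.PermutationConfig(n_perm=1, method="exhaustive"), terms=oneway_terms(),
    )
    # oracle: recompute the classical F for every relabelling of the response
    y = np.asarray(values)
    labels = np.array(list(groups))
    f_obs = sps.f_oneway(y[labels == "a"], y[labels == "b"])[0]
    f_all = [
        sps.f_oneway(np.asarray(p)[labels == "a"], np.asarray(p)[labels == "b"])[0]
        for p in itertools.permutations(y)
    ]
    expected = np.mean(np.asarray(f_all) >= f_obs - 1e-12)
    assert t.p_perm["h_class"] == pytest.approx(expected, abs=1e-12)


def test_permutation_p_enumeration_eight_obs():
    values = [0.4, 1.9, 1.1, 0.2, 3.1, 2.6, 4.0, 2.2]
    groups = "aabbabba"
    ds = toy_dataset(values, groups)
    t = iv.fit_anova(ds, "y", terms=oneway_terms())
    t = iv.permutation_pvalues(
        ds, "y", t,
        iv.PermutationConfig(n_perm=1, method="exhaustive"), terms=oneway_terms(),
    )
    y = np.asarray(values)
    labels = np.array(list(groups))
    f_obs = sps.f_oneway(y[labels == "a"], y[labels == "b"])[0]
    f_all = np.array(
        [
            sps.f_oneway(np.asarray(p)[labels == "a"], np.asarray(p)[labels == "b"])[0]
            for p in itertools.permutations(y)
        ]
    )
    assert t.p_perm["h_class"] == pytest.approx(
        np.mean(f_all >= f_obs - 1e-12), abs=1e-12
    )


def test_sampled_pvalues_deterministic_and_powerful(small_dataset):
    cfg = iv.SynthConfig(
        individuals_per_quadrat=(3, 4, 3),
        leaves_per_stratum=3,
        traits={"sla": iv.TraitModel(8.0, 1.0, {"h_class": 0.5, "residual": 0.5})},
    )
    hits = 0
    for seed in range(5):
        ds = iv.generate_dataset(cfg, seed=seed)
        t = iv.fit_anova(ds, "sla")
        t = iv.permutation_pvalues(ds, "sla", t,
                                   iv.PermutationConfig(n_perm=99, seed=seed))
        t2 = iv.permutation_pvalues(ds, "sla", t,
                                    iv.PermutationConfig(n_perm=99, seed=seed))
        assert t.p_perm == t2.p_perm  # same seed, same p-values
        hits += t.p_perm["h_class"] == pytest.approx(1 / 100)
    assert hits >= 4  # strong height effect pinned at the permutation floor


def test_permutation_config_validation():
    with pytest.raises(iv.ConfigError):
        iv.PermutationConfig(n_perm=0)
    with pytest.raises(iv.ConfigError):
        iv.PermutationConfig(method="bootstrap")


def test_nested_design_matches_vegan_adonis2(tmp_path):
    """Sequential SS and df on an unbalanced nested design agree with an
    independent permutational-ANOVA implementation (vegan::adonis2 via R)."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    cfg = iv.SynthConfig(
        individuals_per_quadrat=(2, 3, 2),
        leaves_per_stratum=2,
        traits={
            "y": iv.TraitModel(
                5.0, 1.0,
                {"quadrat": 0.05, "h_class": 0.2, "position": 0.05,
                 "individual": 0.2, "individual:h_class": 0.1,
                 "h_class:position": 0.05, "residual": 0.35},
            )
        },
    )
    ds = iv.generate_dataset(cfg, seed=4)
    mine = iv.fit_anova(ds, "y")
    df = ds.frame.copy()
    df["ind"] = df["quadrat"].astype(str) + "_" + df["individual"].astype(str)
    data_path = tmp_path / "leaves.csv"
    df.to_csv(data_path, index=False)
    script = tmp_path / "oracle.R"
    script.write_text(
        'suppressMessages(library(vegan))\n'
        f'd <- read.csv("{data_path}", stringsAsFactors = TRUE)\n'
        'res <- adonis2(dist(d$y) ~ quadrat + h_class + position + ind +\n'
        '  quadrat:h_class + quadrat:position + h_class:position +\n'
        '  ind:h_class + ind:position + quadrat:h_class:position +\n'
        '  ind:h_class:position, data = d, permutations = 2, by = "terms")\n'
        'write.csv(data.frame(Df = res$Df, SS = res$SumOfSqs),\n'
        f'          "{tmp_path / "oracle.csv"}", row.names = FALSE)\n'
    )
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
    import pandas as pd

    ref = pd.read_csv(tmp_path / "oracle.csv")
    terms = [t.name for t in iv.standard_terms()]
    for i, term in enumerate(terms):
        assert mine.df[term] == ref.loc[i, "Df"], term
        assert mine.ss[term] == pytest.approx(ref.loc[i, "SS"], abs=1e-8), term
    assert mine.residual_df == ref.loc[len(terms), "Df"]
    assert mine.residual_ss == pytest.approx(ref.loc[len(terms), "SS"], abs=1e-8)
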