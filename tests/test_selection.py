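"""Accuracy/precision screening and minimum/optimal size selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import itvsample as iv
from conftest import toy_dataset
from itvsample.strategies import SamplingSize, StrategySummary, TraitStats


def make_stats(mean=8.0, sd=1.0, half=0.1, trait="sla", n=100):
    return iv.WholeDataStats(
        trait=trait, mean=mean, sd=sd, se=sd / np.sqrt(n),
        ci_low=mean - half, ci_high=mean + half, n=n,
    )


def make_summary(strategy, n_ind, leaves, mean, se, trait="sla", cv=0.1):
    return StrategySummary(
        strategy, SamplingSize(n_ind, leaves),
        {trait: TraitStats(mean, se, cv)}, reps=99,
    )


def test_whole_data_stats_hand_example():
    ds = toy_dataset([1.0, 2.0, 3.0], "aab")
    s = iv.whole_data_stats(ds, "y")
    assert s.mean == 2.0 and s.sd == pytest.approx(1.0)
    assert s.se == pytest.approx(1 / np.sqrt(3))
    t2 = 4.302652729911275  # t quantile, df=2, 97.5%
    assert s.ci_low == pytest.approx(2 - t2 / np.sqrt(3), rel=1e-9)
    assert s.ci_high == pytest.approx(2 + t2 / np.sqrt(3), rel=1e-9)


def test_whole_data_stats_study(study_dataset):
    s = iv.whole_data_stats(study_dataset, "sla")
    assert s.mean == pytest.approx(8.02, abs=1e-9)
    assert s.ci_low < 8.02 < s.ci_high
    assert s.ci_high - s.ci_low == pytest.approx(2 * 1.9659 * 0.96 / np.sqrt(408),
                                                 rel=1e-3)


def test_constant_data_degenerate():
    ds = toy_dataset([2.0, 2.0, 2.0], "aab")
    s = iv.whole_data_stats(ds, "y")
    assert s.degenerate and s.ci_low == s.ci_high == 2.0
    with pytest.raises(iv.ConfigError):
        iv.standardized_deviation(1.0, 2.0, 0.0)


def test_standardized_deviation_examples():
    assert iv.standardized_deviation(8.02, 8.02, 1.5) == 0.0
    assert iv.standardized_deviation(8.32, 8.02, 1.5) == pytest.approx(0.2)


@settings(derandomize=True, max_examples=50)
@given(
    x=st.floats(-50, 50), m=st.floats(-50, 50),
    a=st.floats(0.1, 10), b=st.floats(-5, 5),
)
def test_standardized_deviation_affine_invariant(x, m, a, b):
    s1 = iv.standardized_deviation(x, m, 2.0)
    s2 = iv.standardized_deviation(a * x + b, a * m + b, a * 2.0)
    assert s2 == pytest.approx(s1, rel=1e-9, abs=1e-12)


def test_screen_boundary_and_conjunction():
    stats = {
        "sla": make_stats(8.0, 1.0, 0.1, "sla"),
        "pi": make_stats(3.3, 1.0, 0.1, "pi"),
    }
    se_min = {"sla": 0.3, "pi": 0.3}

    def summary(name, sla_mean, pi_mean, se=0.2):
        s = make_summary(name, 5, 5, sla_mean, se)
        s.stats["pi"] = TraitStats(pi_mean, se, 0.1)
        return s

    res = iv.screen(
        [
            summary("on_boundary", 8.1, 3.3),  # mean exactly on the CI bound
            summary("one_trait_off", 8.0, 3.45),
            summary("imprecise", 8.0, 3.3, se=0.31),
        ],
        stats, se_min,
    )
    assert res.admissible == ["on_boundary"]
    assert "pi mean" in res.reasons["one_trait_off"]
    assert "above se_min" in res.reasons["imprecise"]


def test_screen_monotone_in_ci_width():
    stats_narrow = {"sla": make_stats(8.0, 1.0, 0.05)}
    stats_wide = {"sla": make_stats(8.0, 1.0, 0.2)}
    summaries = [make_summary("A", 5, 5, 8.08, 0.1),
                 make_summary("B", 5, 5, 7.99, 0.1)]
    narrow = iv.screen(summaries, stats_narrow, {"sla": 0.3}).admissible
    wide = iv.screen(summaries, stats_wide, {"sla": 0.3}).admissible
    assert set(narrow) <= set(wide)
    assert wide == ["A", "B"]


def test_single_admissible_size_is_minimum_and_optimal():
    stats = {"sla": make_stats()}
    result = iv.select_sizes([make_summary("A", 5, 5, 8.02, 0.2)], stats,
                             {"sla": 0.3})
    assert result.best_strategy == "A"
    assert result.minimum_size == result.optimal_size == SamplingSize(5, 5)


def test_largest_drop_picks_optimal_size():
    stats = {"sla": make_stats(8.0, 1.0, 0.5)}
    # S values: 0.30, 0.28, 0.08 (sharp drop), 0.07: optimal at the drop
    summaries = [
        make_summary("A", 5, 1, 8.30, 0.05),
        make_summary("A", 5, 2, 8.28, 0.05),
        make_summary("A", 10, 4, 8.08, 0.05),
        make_summary("A", 30, 2, 8.07, 0.05),
    ]
    result = iv.select_sizes(summaries, stats, {"sla": 0.3})
    assert result.minimum_size == SamplingSize(5, 1)
    assert result.optimal_size == SamplingSize(10, 4)
    assert any("drop" in line for line in result.audit)


def test_minimum_tie_prefers_fewer_individuals():
    stats = {"sla": make_stats(8.0, 1.0, 0.5)}
    summaries = [
        make_summary("A", 4, 3, 8.10, 0.05),
        make_summary("A", 3, 4, 8.20, 0.05),  # same 12 leaves, fewer trees
        make_summary("A", 10, 2, 8.01, 0.05),
    ]
    result = iv.select_sizes(summaries, stats, {"sla": 0.3})
    assert result.minimum_size == SamplingSize(3, 4)


def test_no_admissible_design_reported():
    stats = {"sla": make_stats(8.0, 1.0, 0.01)}
    result = iv.select_sizes([make_summary("A", 5, 5, 9.0, 0.2)], stats,
                             {"sla": 0.3})
    assert result.no_admissible
    assert result.minimum_size is None and result.optimal_size is None
    assert any("no admissible" in line for line in result.audit)


def test_selection_on_simulated_grid(small_dataset):
    """End-to-end: the unrestricted random strategy screens in on its own
    simulated grid and yields a coherent minimum <= optimal effort pair."""
    stats = {t: iv.whole_data_stats(small_dataset, t)
             for t in small_dataset.trait_names}
    grid = iv.run_grid(
        small_dataset,
        [iv.builtin_strategies()["RANDOM"]],
        reps=299, seed=5,
    )
    se_min = {t: 0.25 for t in small_dataset.trait_names}
    result = iv.select_sizes(grid, stats, se_min)
    assert result.best_strategy == "RANDOM"
    assert result.minimum_size is not None
    assert (result.minimum_size.total_leaves
            <= result.optimal_size.total_leaves * 10)
    # audit trail is recomputable: every admissible row satisfies both rules
    adm = result.s_table[result.s_table["size_admissible"]]
    for t in small_dataset.trait_names:
        assert ((adm[f"S_{t}"] >= 0).all())
        assert adm[f"{t}_precise"].all() and adm[f"{t}_in_ci"].all()
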