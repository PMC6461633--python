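import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidshift.diffstats import (
    StatsError,
    bh_fdr,
    differential_table,
    paired_panel_summary,
    paired_t_log2,
    per_subject_log2fc,
    signed_fold_change,
)
from lipidshift.synthetic_data import (
    SimulationConfig,
    preset_glucocorticoid_study,
    simulate_experiment,
)
from lipidshift.quantify import correct_s1p_interference, quantify_table


def brute_force_bh(p):
    """Independent BH oracle: sort, scale by m/rank, cumulative minimum."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def test_per_subject_log2fc():
    assert per_subject_log2fc(1.0, 2.0) == 1.0
    assert per_subject_log2fc(4.0, 1.0) == -2.0
    assert per_subject_log2fc(3.0, 3.0) == 0.0
    with pytest.raises(StatsError, match="P1"):
        per_subject_log2fc(0.0, 1.0, label="P1/PC 34:1")


@pytest.mark.parametrize(
    "log2fc, expected", [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0), (2.0, 4.0), (-2.0, -4.0)]
)
def test_signed_fold_change(log2fc, expected):
    assert signed_fold_change(log2fc) == pytest.approx(expected)


def test_paired_t_matches_df2_closed_form():
    """For df=2 the t CDF has the closed form F(t) = 1/2 + t / (2 sqrt(2+t^2))."""
    before = np.array([1.0, 1.0, 1.0])
    after = 2.0 ** np.array([1.0, 2.0, 3.0])
    t, df, p = paired_t_log2(before, after)
    assert df == 2
    assert t == pytest.approx(2.0 / (1.0 / math.sqrt(3.0)), abs=1e-4)
    closed_form_p = 2.0 * (0.5 - t / (2.0 * math.sqrt(2.0 + t * t)))
    assert p == pytest.approx(closed_form_p, abs=1e-6)
    assert p == pytest.approx(0.0742, abs=2e-4)
    # sign symmetry
    t2, _, p2 = paired_t_log2(after, before)
    assert t2 == pytest.approx(-t)
    assert p2 == pytest.approx(p)


def test_paired_t_degenerate_and_scaling_invariance():
    t, df, p = paired_t_log2([2.0, 3.0], [2.0, 3.0])
    assert math.isnan(t) and math.isnan(p) and df == 1
    with pytest.raises(StatsError):
        paired_t_log2([1.0], [2.0])
    # multiplying before and after of each subject by its own constant
    # leaves the paired differences unchanged
    b = np.array([1.0, 2.0, 4.0, 1.5])
    a = np.array([2.0, 3.0, 9.0, 2.0])
    c = np.array([5.0, 0.1, 7.0, 2.0])
    t1, _, p1 = paired_t_log2(b, a)
    t2, _, p2 = paired_t_log2(b * c, a * c)
    assert t1 == pytest.approx(t2)
    assert p1 == pytest.approx(p2)


def test_bh_fdr_frozen_examples():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    assert np.allclose(bh_fdr([0.005, 0.03, 0.5]), [0.015, 0.045, 0.5])
    assert np.allclose(bh_fdr([1.0]), [1.0])
    with pytest.raises(StatsError):
        bh_fdr([-0.1, 0.5])


def test_bh_fdr_nan_entries_excluded_from_family():
    adj = bh_fdr([0.005, np.nan, 0.03, 0.5])
    assert np.isnan(adj[1])
    assert np.allclose(adj[[0, 2, 3]], brute_force_bh([0.005, 0.03, 0.5]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.lists(
        st.integers(min_value=0, max_value=100).map(lambda k: k / 100.0),
        min_size=1,
        max_size=8,
    )
)
def test_bh_fdr_equals_brute_force_on_grid(p):
    assert np.allclose(bh_fdr(p), brute_force_bh(p))
    assert (bh_fdr(p) >= np.asarray(p) - 1e-12).all()


def test_bh_fdr_exhaustive_short_vectors():
    grid = [0.0, 0.01, 0.04, 0.05, 0.2, 0.5, 0.99, 1.0]
    for n in (1, 2, 3):
        for combo in itertools.product(grid, repeat=n):
            assert np.allclose(bh_fdr(combo), brute_force_bh(combo))


def _planted_sim():
    cfg = preset_glucocorticoid_study(seed=11)
    sim = simulate_experiment(cfg)
    corrected = correct_s1p_interference(sim.areas)
    quant = quantify_table(corrected, sim.istd_map)
    study = sim.metadata.loc[sim.metadata.role == "study", "sample_id"]
    return sim, quant.concentration.reindex(study)


def test_differential_table_recovers_planted_effect():
    """A 2x multiplier on Hex1Cer at the design noise levels is recovered
    significantly with mean log2FC near 1 in the prednisolone arm (n=8)."""
    sim, conc = _planted_sim()
    table = differential_table(conc, sim.metadata, "prednisolone")
    hex1 = table[table.lipid_class == "Hex1Cer"]
    assert hex1["significant"].mean() >= 0.8
    assert hex1["mean_log2fc"].mean() == pytest.approx(1.0, abs=0.2)
    assert (np.sign(table["fold_change"]) == np.sign(table["mean_log2fc"]).replace(0, 1)).all()
    assert (table["p_fdr"].dropna() >= table["p_raw"].dropna() - 1e-12).all()


def test_differential_table_null_when_after_equals_before():
    sim, conc = _planted_sim()
    meta = sim.metadata
    study = meta.loc[meta.role == "study"]
    # overwrite after-samples with the before values: no species can move
    forced = conc.copy()
    for subj in study.subject_id.unique():
        sub = study[study.subject_id == subj].set_index("timepoint")["sample_id"]
        forced.loc[sub["after"]] = conc.loc[sub["before"]].to_numpy()
    for group in ("prednisolone", "tetracosactide"):
        table = differential_table(forced, meta, group)
        assert not table["significant"].any()
        assert table["p_raw"].isna().all()  # all differences exactly zero


def test_differential_missing_pair_errors():
    sim, conc = _planted_sim()
    meta = sim.metadata[sim.metadata.sample_id != "P3_after"]
    with pytest.raises(StatsError, match="P3"):
        differential_table(conc, meta, "prednisolone")


def test_drop_subject_changes_n():
    sim, conc = _planted_sim()
    t_all = differential_table(conc, sim.metadata, "tetracosactide")
    t_drop = differential_table(conc, sim.metadata, "tetracosactide", drop_subjects=("T6",))
    assert t_all.attrs["n_subjects"] == 6
    assert t_drop.attrs["n_subjects"] == 5
    assert "log2fc_T6" not in t_drop.columns


def test_fdr_scope_class_vs_group():
    sim, conc = _planted_sim()
    by_group = differential_table(conc, sim.metadata, "prednisolone", fdr_scope="group")
    by_class = differential_table(conc, sim.metadata, "prednisolone", fdr_scope="class")
    assert np.allclose(by_group["p_raw"], by_class["p_raw"], equal_nan=True)
    # within one class, class-scoped BH equals BH run on that class alone
    pi = by_class[by_class.lipid_class == "PI"]
    assert np.allclose(pi["p_fdr"], brute_force_bh(pi["p_raw"].to_numpy()))


def test_paired_panel_summary_signed_median():
    before = pd.DataFrame({"cortisol": [1.0, 1.0, 1.0], "lipase": [1.0, 2.0, 4.0]})
    after = pd.DataFrame({"cortisol": [2.0, 4.0, 8.0], "lipase": [0.5, 0.5, 1.0]})
    out = paired_panel_summary(before, after)
    assert out.loc["cortisol", "median_fc_signed"] == pytest.approx(4.0)
    assert out.loc["lipase", "median_fc_signed"] == pytest.approx(-4.0)


def test_paired_panel_summary_even_n_decrease():
    """Median of per-subject signed FCs: (0.5, 0.25) -> (-2, -4) -> -3."""
    before = pd.DataFrame({"x": [1.0, 1.0]})
    after = pd.DataFrame({"x": [0.5, 0.25]})
    out = paired_panel_summary(before, after)
    assert out.loc["x", "median_fc_signed"] == pytest.approx(-3.0)
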