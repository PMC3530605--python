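"""Per-probe ANOVA/LSD statistics against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oascreen.datamodel import PipelineConfig
from oascreen.diffexp import (
    StatisticalError,
    call_probe,
    probe_anova,
    probe_calls_for_contrast,
)
from oascreen.normalize import ma_transform
from oascreen.simulate import simulate_experiment
from oascreen.datamodel import SimConfig


def oracle_lsd(groups):
    """Textbook one-way ANOVA with Fisher-LSD pairwise p-values.

    Deliberately naive: explicit loops and running sums, no shared code
    with the implementation under test.
    """
    names = list(groups)
    k = len(names)
    all_vals = [v for g in names for v in groups[g]]
    n_total = len(all_vals)
    grand = sum(all_vals) / n_total
    sse = 0.0
    means = {}
    for g in names:
        m = sum(groups[g]) / len(groups[g])
        means[g] = m
        for v in groups[g]:
            sse += (v - m) ** 2
    df = n_total - k
    mse = sse / df
    ssb = sum(len(groups[g]) * (means[g] - grand) ** 2 for g in names)
    if mse == 0:
        omnibus = 0.0 if ssb > 0 else 1.0
    else:
        omnibus = stats.f.sf((ssb / (k - 1)) / mse, k - 1, df)
    pairs = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = (mse * (1 / len(groups[a]) + 1 / len(groups[b]))) ** 0.5
            if se == 0:
                pairs[(a, b)] = 0.0 if means[a] != means[b] else 1.0
            else:
                t = (means[a] - means[b]) / se
                pairs[(a, b)] = 2 * stats.t.sf(abs(t), df)
    return omnibus, pairs


def test_null_groups_with_jitter_produce_no_calls():
    """Equal groups up to a tiny jitter: valid p-values, never a call
    (the nano-scale fold changes cannot clear the 1.5-fold threshold)."""
    rng = np.random.default_rng(0)
    cfg = PipelineConfig()
    groups = {f"g{i}": (rng.normal(0, 1e-9, 3) + 0.0).tolist() for i in range(4)}
    _, pairs = probe_anova(groups)
    for (a, b), p in pairs.items():
        assert 0.0 <= p <= 1.0
        fc = np.mean(groups[a]) - np.mean(groups[b])
        assert call_probe("p", "c", "x", p, fc, cfg).call == "not_significant"


def test_strong_single_group_shift_detected():
    rng = np.random.default_rng(1)
    means = [0.0, 2.0, 0.0, 0.0]
    groups = {
        f"g{i}": (m + rng.normal(0, 0.1, 3)).tolist() for i, m in enumerate(means)
    }
    omnibus, pairs = probe_anova(groups)
    assert omnibus < 1e-6
    assert pairs[("g0", "g1")] < 0.001
    o_omni, o_pairs = oracle_lsd(groups)
    assert omnibus == pytest.approx(o_omni, rel=1e-10)
    for key in pairs:
        assert pairs[key] == pytest.approx(o_pairs[key], rel=1e-10)


def test_two_group_case_equals_pooled_t():
    groups = {"t": [1.0, 1.1, 0.9], "c": [-1.0, -0.9, -1.1]}
    _, pairs = probe_anova(groups)
    # hand computation: pooled t-test on the six numbers
    t_stat, p_hand = stats.ttest_ind(groups["t"], groups["c"], equal_var=True)
    assert pairs[("t", "c")] == pytest.approx(p_hand, rel=1e-10)


def test_oracle_equivalence_on_random_instances():
    """100 random small instances match the brute-force oracle to 1e-10."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        k = rng.integers(2, 5)
        groups = {
            f"g{i}": rng.normal(rng.normal(0, 1), rng.uniform(0.05, 1.0),
                                rng.integers(2, 6)).tolist()
            for i in range(k)
        }
        omnibus, pairs = probe_anova(groups)
        o_omni, o_pairs = oracle_lsd(groups)
        assert omnibus == pytest.approx(o_omni, rel=1e-10)
        for key in pairs:
            assert pairs[key] == pytest.approx(o_pairs[key], rel=1e-10)


def test_vectorized_path_matches_scalar_anova(small_experiment):
    _, probes, design, _ = small_experiment
    ratios = ma_transform(probes, design)
    cfg = PipelineConfig()
    calls = probe_calls_for_contrast(ratios, design, "diploid", "co2_at_lowlight", cfg)
    d = design.loc[design["stage"] == "diploid"]
    sub = ratios.loc[~ratios["is_control"]].merge(
        d[["array_id", "pco2_pa", "light_umol"]], on="array_id"
    )
    rng = np.random.default_rng(5)
    sample = rng.choice(calls["probe_id"].to_numpy(), size=25, replace=False)
    for pid in sample:
        rows = sub.loc[sub["probe_id"] == pid]
        groups = {
            f"{p}_{l}": g["M"].tolist()
            for (p, l), g in rows.groupby(["pco2_pa", "light_umol"])
        }
        _, pairs = probe_anova(groups)
        key = ("101.3_50", "38.5_50")
        want = pairs.get(key, pairs.get(key[::-1]))
        got = calls.loc[calls["probe_id"] == pid, "p_value"].iloc[0]
        assert got == pytest.approx(want, rel=1e-10)


def test_group_with_one_replicate_is_statistical_error():
    with pytest.raises(StatisticalError, match="fewer than 2"):
        probe_anova({"a": [1.0, 2.0], "b": [0.5]})
    with pytest.raises(StatisticalError):
        probe_anova({"a": [1.0, 2.0]})


def test_call_probe_thresholds_conjunctive(cfg):
    up = call_probe("p", "c", "co2_at_lowlight", 0.01, 0.8, cfg)
    assert up.call == "up"  # fold 2^0.8 = 1.74 >= 1.5, p <= 0.05
    weak_fold = call_probe("p", "c", "co2_at_lowlight", 0.01, 0.5, cfg)
    assert weak_fold.call == "not_significant"  # fold 1.41 < 1.5
    weak_p = call_probe("p", "c", "co2_at_lowlight", 0.2, 2.0, cfg)
    assert weak_p.call == "not_significant"
    down = call_probe("p", "c", "co2_at_lowlight", 0.01, -0.8, cfg)
    assert down.call == "down"


def test_symmetry_negating_m_swaps_calls(small_experiment):
    _, probes, design, _ = small_experiment
    ratios = ma_transform(probes, design)
    cfg = PipelineConfig()
    calls = probe_calls_for_contrast(ratios, design, "diploid", "co2_at_lowlight", cfg)
    flipped = ratios.copy()
    flipped["M"] = -flipped["M"]
    calls_f = probe_calls_for_contrast(flipped, design, "diploid", "co2_at_lowlight", cfg)
    merged = calls.merge(calls_f, on="probe_id", suffixes=("", "_f"))
    assert np.allclose(merged["p_value"], merged["p_value_f"], equal_nan=True)
    swap = {"up": "down", "down": "up", "not_significant": "not_significant"}
    assert (merged["call"].map(swap) == merged["call_f"]).all()


def test_monotonicity_in_effect_size():
    """Scaling up the group separation never demotes an up-call."""
    rng = np.random.default_rng(7)
    base = rng.normal(0, 0.15, (4, 3))
    cfg = PipelineConfig()
    prev_call = None
    for shift in (0.0, 0.3, 0.6, 1.0, 2.0):
        groups = {f"g{i}": (base[i] + (shift if i == 0 else 0)).tolist() for i in range(4)}
        _, pairs = probe_anova(groups)
        fc = np.mean(groups["g0"]) - np.mean(groups["g1"])
        pc = call_probe("p", "c", "x", pairs[("g0", "g1")], fc, cfg)
        if prev_call == "up":
            assert pc.call == "up"
        prev_call = pc.call
    assert prev_call == "up"


def test_untestable_probe_marked_and_kept():
    scfg = SimConfig(n_clusters=30, seed=1)
    probes, design, _ = simulate_experiment(scfg)
    # kill two of three replicates of one group for one probe
    pid = "c01_p1" if (probes["probe_id"] == "c01_p1").any() else probes["probe_id"].iloc[0]
    d = design.loc[(design.stage == "diploid") & (design.pco2_pa == 101.3)
                   & (design.light_umol == 50), "array_id"].iloc[:2]
    mask = (probes["probe_id"] == pid) & probes["array_id"].isin(set(d))
    probes.loc[mask, "qc_ok"] = False
    ratios = ma_transform(probes, design)
    calls = probe_calls_for_contrast(
        ratios, design, "diploid", "co2_at_lowlight", PipelineConfig()
    )
    row = calls.loc[calls["probe_id"] == pid].iloc[0]
    assert not row["testable"]
    assert row["call"] == "not_significant"
    assert calls.attrs["n_untestable"] >= 1
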