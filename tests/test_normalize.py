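"""MA transformation, LOWESS correction, and common-reference contrasts."""

import numpy as np
import pandas as pd
import pytest

from oascreen.datamodel import (
    ContrastError,
    NormalizationError,
    PipelineConfig,
    SimConfig,
)
from oascreen.normalize import (
    contrast_ratios,
    lowess_correct,
    ma_transform,
)
from oascreen.simulate import simulate_experiment, spikein_truth

from conftest import toy_probe_frame


def _toy_design():
    return pd.DataFrame(
        [
            {"array_id": "a1", "stage": "diploid", "pco2_pa": 38.5,
             "light_umol": 50, "replicate": 1, "sample_dye": "cy5"},
            {"array_id": "a2", "stage": "diploid", "pco2_pa": 101.3,
             "light_umol": 50, "replicate": 1, "sample_dye": "cy5"},
        ]
    )


def test_ma_closed_form():
    df = toy_probe_frame()
    out = ma_transform(df, _toy_design())
    p1 = out.loc[out["probe_id"] == "c1_p1"].iloc[0]
    assert p1["M"] == pytest.approx(1.0)
    assert p1["A"] == pytest.approx(0.5 * np.log2(200 * 100))
    p2 = out.loc[out["probe_id"] == "c1_p2"].iloc[0]
    assert p2["M"] == pytest.approx(0.0)


def test_ma_skips_qc_failures_and_counts_them():
    df = toy_probe_frame()
    df.loc[0, "qc_ok"] = False
    out = ma_transform(df, _toy_design())
    assert len(out) == 5
    assert out.attrs["skipped_per_array"] == {"a1": 1}


def test_ma_unknown_array_rejected():
    df = toy_probe_frame()
    df.loc[0, "array_id"] = "mystery"
    with pytest.raises(ContrastError, match="mystery"):
        ma_transform(df, _toy_design())


@pytest.fixture(scope="module")
def biased_arrays():
    """Zero-effect experiment with a planted sinusoidal dye bias of 0.5."""
    scfg = SimConfig(
        n_clusters=250, seed=13,
        fraction_core_oa=0, fraction_ll_specific=0, fraction_hl_specific=0,
        fraction_core_light=0, fraction_silent=0, fraction_stage_only_expression=0,
        probe_noise_sd=0, replicate_noise_sd=0,
        dye_bias_amplitude=0.5,
    )
    probes, design, _ = simulate_experiment(scfg)
    return scfg, ma_transform(probes, design)


def test_lowess_flattens_planted_bias(biased_arrays):
    _, ratios = biased_arrays
    corrected = lowess_correct(ratios, span=0.4, iterations=3)
    nc = corrected.loc[~corrected["is_control"]]
    med = nc.groupby("array_id")["M"].apply(lambda m: np.median(np.abs(m)))
    assert med.max() < 0.05
    # before correction the bias is plainly visible
    raw_med = (
        ratios.loc[~ratios["is_control"]]
        .groupby("array_id")["M"]
        .apply(lambda m: np.median(np.abs(m)))
    )
    assert raw_med.min() > 0.1


def test_spikeins_recovered_but_never_fitted(biased_arrays):
    scfg, ratios = biased_arrays
    corrected = lowess_correct(ratios, span=0.4, iterations=3)
    sp = corrected.loc[corrected["is_control"]].merge(
        spikein_truth(scfg), on="probe_id"
    )
    assert (sp["M"] - sp["planted_m"]).abs().max() < 0.1


def test_correction_near_identity_without_bias():
    """No planted bias and no noise: the fitted trend is flat, so the
    correction changes nothing beyond fit wiggle."""
    scfg = SimConfig(n_clusters=200, seed=3, dye_bias_amplitude=0.0,
                     probe_noise_sd=0.0, replicate_noise_sd=0.0,
                     fraction_silent=0, fraction_stage_only_expression=0)
    probes, design, _ = simulate_experiment(scfg)
    ratios = ma_transform(probes, design)
    corrected = lowess_correct(ratios, span=0.4, iterations=3)
    assert (corrected["M"] - ratios["M"]).abs().max() < 0.02


def test_correction_idempotent_and_preserves_a(biased_arrays):
    _, ratios = biased_arrays
    once = lowess_correct(ratios, span=0.4, iterations=3)
    twice = lowess_correct(once, span=0.4, iterations=3)
    assert (twice["M"] - once["M"]).abs().max() < 0.02
    assert np.array_equal(once["A"].to_numpy(), ratios["A"].to_numpy())


def test_too_few_probes_is_normalization_error():
    df = toy_probe_frame()  # 3 probes per array only
    ratios = ma_transform(df, _toy_design())
    with pytest.raises(NormalizationError, match="a1"):
        lowess_correct(ratios)


def test_contrast_ratios_common_reference_arithmetic():
    """M_g1 = {1,1,1}, M_g2 = {-1,-1,-1} implies log2(T1/T2) = 2."""
    rows = []
    design_rows = []
    for g, (pco2, ms) in enumerate({101.3: [1.0] * 3, 38.5: [-1.0] * 3}.items()):
        for rep, m in enumerate(ms, start=1):
            aid = f"g{g}_r{rep}"
            design_rows.append(
                {"array_id": aid, "stage": "diploid", "pco2_pa": pco2,
                 "light_umol": 50, "replicate": rep, "sample_dye": "cy5"}
            )
            rows.append(
                {"array_id": aid, "probe_id": "p1", "cluster_id": "c1",
                 "is_control": False, "M": m, "A": 10.0}
            )
    ratios = pd.DataFrame(rows)
    design = pd.DataFrame(design_rows)
    out = contrast_ratios(ratios, design, "diploid", "co2_at_lowlight")
    t = out.loc[out["group"] == "treatment", "M"]
    c = out.loc[out["group"] == "control", "M"]
    assert t.mean() - c.mean() == pytest.approx(2.0)
    assert out.attrs["unbalanced_probes"] == []


def test_contrast_ratios_flags_unbalanced_and_missing_group():
    rows, design_rows = [], []
    for g, pco2 in enumerate([101.3, 38.5]):
        for rep in range(1, 4):
            aid = f"g{g}_r{rep}"
            design_rows.append(
                {"array_id": aid, "stage": "diploid", "pco2_pa": pco2,
                 "light_umol": 50, "replicate": rep, "sample_dye": "cy5"}
            )
            if not (g == 0 and rep == 3):  # one qc-failed replicate in g1
                rows.append(
                    {"array_id": aid, "probe_id": "p1", "cluster_id": "c1",
                     "is_control": False, "M": 0.5, "A": 9.0}
                )
    out = contrast_ratios(
        pd.DataFrame(rows), pd.DataFrame(design_rows), "diploid", "co2_at_lowlight"
    )
    assert out.attrs["unbalanced_probes"] == ["p1"]
    sizes = out.groupby("group").size()
    assert sizes["treatment"] == 2 and sizes["control"] == 3

    with pytest.raises(ContrastError):
        contrast_ratios(
            pd.DataFrame(rows), pd.DataFrame(design_rows), "haploid", "co2_at_lowlight"
        )


def test_reference_cancellation_exact_on_clean_data(clean_experiment):
    """For noise-free data, mean(M_t) - mean(M_c) equals the planted effect."""
    _, probes, design, truth = clean_experiment
    ratios = ma_transform(probes, design)
    out = contrast_ratios(ratios, design, "diploid", "co2_at_lowlight")
    eff = truth.set_index("cluster_id")["co2_effect_ll"]
    expressed = truth.set_index("cluster_id")["expressed_in_stage"].isin(
        ["both", "diploid_only"]
    )
    fc = (
        out.groupby(["probe_id", "cluster_id", "group"])["M"]
        .mean()
        .unstack("group")
    )
    fc["diff"] = fc["treatment"] - fc["control"]
    for (pid, cid), row in fc.iterrows():
        if expressed[cid]:
            assert row["diff"] == pytest.approx(eff[cid], abs=1e-9), (pid, cid)
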