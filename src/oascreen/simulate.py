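"""Synthetic two-color common-reference experiments with planted truth.

The generator emulates the screening study's layout: 2 life-cycle
stages x 2 pCO2 x 2 light, biological triplicates (24 arrays), three
probes per transcript cluster, every sample hybridized against a pooled
common reference. Planted structure:

* response classes for the CO2 factor (core = responds under both
  light levels, low-light-specific, high-light-specific) and for the
  light factor;
* stage-specific genome utilization: a responsive cluster is expressed
  in both stages with probability ``fraction_stage_shared``, otherwise
  in exactly one (its intensities sit near background in the other);
* intensity-dependent dye bias, a smooth sinusoid in A added to the
  log-ratio (split between the channels so A is untouched);
* probe anomalies: a *divergent* probe carries the planted effect with
  inverted sign, a *dead* probe returns uncorrelated noise;
* spike-in control probes at fixed log-ratios {-2, -1, 0, 1, 2}.

Intensities are log-normal: everything is Gaussian on the log2 scale
and exponentiated at the end. The biological replicate effect is drawn
once per (cluster, array) and shared by the cluster's three probes, so
probe concordance is informative, as the collapse rules assume.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    CONTRAST_LABELS,
    DirectedGeneSet,
    LIGHT_LEVELS,
    N_REPLICATES,
    PCO2_LEVELS,
    PipelineConfig,
    PROBES_PER_CLUSTER,
    SimConfig,
    STAGES,
)

SPIKEIN_LOG_RATIOS = (-2.0, -1.0, 0.0, 1.0, 2.0)

TRUTH_COLUMNS = [
    "cluster_id",
    "expressed_in_stage",
    "co2_effect_ll",
    "co2_effect_hl",
    "light_effect_380",
    "light_effect_1000",
    "divergent_probe",
    "dead_probe",
]

#: contrast label -> truth effect column (the directly planted factor effect)
CONTRAST_EFFECT_COLUMN = {
    "co2_at_lowlight": "co2_effect_ll",
    "co2_at_highlight": "co2_effect_hl",
    "light_at_lowco2": "light_effect_380",
    "light_at_highco2": "light_effect_1000",
}


def contrast_effect(truth: pd.DataFrame, contrast: str) -> pd.Series:
    """The planted cell-mean difference realized by a contrast.

    The generator builds the (high CO2, high light) cell as
    baseline + co2_effect_hl + light_effect_1000, so the four
    contrasts of the 2x2 share three degrees of freedom: the light
    contrast at high CO2 realizes
    ``co2_effect_hl + light_effect_1000 - co2_effect_ll``. A
    light-level-specific CO2 response therefore *implies* a light
    response at high CO2 — an identity of the factorial layout, not an
    artifact. The recovery oracle must use these realized differences.
    """
    if contrast == "light_at_highco2":
        return (
            truth["co2_effect_hl"]
            + truth["light_effect_1000"]
            - truth["co2_effect_ll"]
        )
    return truth[CONTRAST_EFFECT_COLUMN[contrast]]

# probe ranks carrying each anomaly (at most one probe per anomaly)
_DIVERGENT_RANK = 2
_DEAD_RANK = 1

_PROBE_AFFINITY_SD = 0.25  # probe sequence affinity, cancels in M


def _make_design() -> pd.DataFrame:
    rows = []
    for stage in STAGES:
        for pco2 in PCO2_LEVELS:
            for light in LIGHT_LEVELS:
                for rep in range(1, N_REPLICATES + 1):
                    aid = f"{stage[:3]}_{int(round(pco2 * 10))}_{light}_r{rep}"
                    rows.append(
                        {
                            "array_id": aid,
                            "stage": stage,
                            "pco2_pa": pco2,
                            "light_umol": light,
                            "replicate": rep,
                            "sample_dye": "cy5",
                        }
                    )
    return pd.DataFrame(rows)


def _assign_classes(cfg: SimConfig, rng: np.random.Generator):
    """Partition clusters into response classes and stage-expression groups."""
    n = cfg.n_clusters
    order = rng.permutation(n)
    counts = {
        "core_oa": int(round(cfg.fraction_core_oa * n)),
        "ll_oa": int(round(cfg.fraction_ll_specific * n)),
        "hl_oa": int(round(cfg.fraction_hl_specific * n)),
        "core_light": int(round(cfg.fraction_core_light * n)),
        "ll_light": int(round(cfg.fraction_ll_specific_light * n)),
        "hl_light": int(round(cfg.fraction_hl_specific_light * n)),
    }
    cls = np.full(n, "null", dtype=object)
    pos = 0
    for name, k in counts.items():
        cls[order[pos : pos + k]] = name
        pos += k

    responsive = cls != "null"
    # stage expression: 0 = both, 1 = diploid_only, 2 = haploid_only, 3 = neither
    expr = np.zeros(n, dtype=int)
    u = rng.random(n)
    stage_pick = rng.integers(1, 3, size=n)  # 1 or 2
    # responsive clusters: shared across stages w.p. fraction_stage_shared
    expr[responsive] = np.where(
        u[responsive] < cfg.fraction_stage_shared, 0, stage_pick[responsive]
    )
    # null clusters: small silent fraction, some single-stage housekeeping split
    null = ~responsive
    u2 = rng.random(n)
    expr[null & (u2 < cfg.fraction_silent)] = 3
    sel = null & (u2 >= cfg.fraction_silent) & (
        u2 < cfg.fraction_silent + cfg.fraction_stage_only_expression
    )
    expr[sel] = stage_pick[sel]
    return cls, expr


def simulate_experiment(
    cfg: SimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (probe_table, design, truth) for one synthetic experiment.

    The same seed yields bit-identical tables. Probe table rows are
    ordered by array, then cluster, then probe rank, with spike-in
    control probes appended per array.
    """
    rng = np.random.default_rng(cfg.seed)
    design = _make_design()
    n = cfg.n_clusters
    n_arrays = len(design)

    cls, expr = _assign_classes(cfg, rng)

    # planted signed log2 effects
    mag = rng.normal(cfg.effect_log2_mean, cfg.effect_log2_sd, size=n)
    mag = np.abs(mag)
    sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    eff = sign * mag
    co2_ll = np.where(np.isin(cls, ["core_oa", "ll_oa"]), eff, 0.0)
    co2_hl = np.where(np.isin(cls, ["core_oa", "hl_oa"]), eff, 0.0)
    light_380 = np.where(np.isin(cls, ["core_light", "ll_light"]), eff, 0.0)
    light_1000 = np.where(np.isin(cls, ["core_light", "hl_light"]), eff, 0.0)
    # effects are meaningless for unexpressed clusters
    silent = expr == 3
    for arr in (co2_ll, co2_hl, light_380, light_1000):
        arr[silent] = 0.0

    divergent = rng.random(n) < cfg.anomaly_rate_divergent
    dead = rng.random(n) < cfg.anomaly_rate_dead

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)

    width = len(str(n))
    cluster_ids = np.array([f"c{str(i + 1).zfill(width)}" for i in range(n)], dtype=object)

    expr_names = np.array(["both", "diploid_only", "haploid_only", "neither"], dtype=object)
    truth = pd.DataFrame(
        {
            "cluster_id": cluster_ids,
            "expressed_in_stage": expr_names[expr],
            "co2_effect_ll": co2_ll,
            "co2_effect_hl": co2_hl,
            "light_effect_380": light_380,
            "light_effect_1000": light_1000,
            "divergent_probe": divergent,
            "dead_probe": dead,
        }
    )

    # --- per-probe / per-array signal assembly (vectorized) ---------------
    n_probes = n * PROBES_PER_CLUSTER
    cl_of_probe = np.repeat(np.arange(n), PROBES_PER_CLUSTER)
    rank = np.tile(np.arange(PROBES_PER_CLUSTER), n)
    affinity = rng.normal(0.0, _PROBE_AFFINITY_SD, size=n_probes)

    stage_idx = (design["stage"] == "haploid").astype(int).to_numpy()  # 0 dip, 1 hap
    co2_high = (design["pco2_pa"] == PCO2_LEVELS[1]).to_numpy()
    light_high = (design["light_umol"] == LIGHT_LEVELS[1]).to_numpy()

    # expressed[c, s] for s in {diploid, haploid}
    expressed = np.stack(
        [np.isin(expr, [0, 1]), np.isin(expr, [0, 2])], axis=1
    )  # (n, 2)
    expressed_anywhere = expressed.any(axis=1)
    ref_level = np.where(expressed_anywhere, baseline, cfg.background_log2)

    # planted treatment effect per (cluster, array): CO2 effect at the
    # array's light level plus light effect at the array's CO2 level
    eff_ca = np.zeros((n, n_arrays))
    for a in range(n_arrays):
        e = np.zeros(n)
        if co2_high[a]:
            e += co2_hl if light_high[a] else co2_ll
        if light_high[a]:
            e += light_1000 if co2_high[a] else light_380
        eff_ca[:, a] = e

    rep_effect = rng.normal(0.0, cfg.replicate_noise_sd, size=(n, n_arrays))

    expr_level_ca = np.where(
        expressed[np.arange(n)[:, None], stage_idx[None, :]],
        baseline[:, None],
        cfg.background_log2,
    )  # (n, n_arrays)
    is_expr_ca = expressed[np.arange(n)[:, None], stage_idx[None, :]]

    # probe-level sign flip for the divergent probe
    divsign = np.ones(n_probes)
    divsign[divergent[cl_of_probe] & (rank == _DIVERGENT_RANK)] = -1.0
    is_dead = dead[cl_of_probe] & (rank == _DEAD_RANK)

    noise_s = rng.normal(0.0, 1.0, size=(n_probes, n_arrays)) * cfg.probe_noise_sd
    noise_r = rng.normal(0.0, 1.0, size=(n_probes, n_arrays)) * cfg.probe_noise_sd
    dead_noise = rng.normal(0.0, 1.0, size=(n_probes, n_arrays)) * cfg.dead_probe_sd

    sample_log2 = (
        expr_level_ca[cl_of_probe]
        + (eff_ca[cl_of_probe] * divsign[:, None] + rep_effect[cl_of_probe])
        * is_expr_ca[cl_of_probe]
        + affinity[:, None]
        + noise_s
    )
    # dead probes: uncorrelated noise around the reference level
    dead_sample = ref_level[cl_of_probe][:, None] + affinity[:, None] + dead_noise
    sample_log2 = np.where(is_dead[:, None], dead_sample, sample_log2)

    ref_log2 = ref_level[cl_of_probe][:, None] + affinity[:, None] + noise_r

    # intensity-dependent dye bias, split so A is unchanged
    if cfg.dye_bias_amplitude != 0.0:
        a_pre = 0.5 * (sample_log2 + ref_log2)
        m_bias = cfg.dye_bias_amplitude * np.sin(2.0 * np.pi * a_pre / cfg.dye_bias_period)
        sample_log2 = sample_log2 + 0.5 * m_bias
        ref_log2 = ref_log2 - 0.5 * m_bias

    probe_ids = np.array(
        [f"{cluster_ids[c]}_p{r + 1}" for c, r in zip(cl_of_probe, rank)], dtype=object
    )

    # --- spike-ins --------------------------------------------------------
    n_spike = cfg.n_spikein
    if n_spike > 0:
        spike_m = np.array(
            [SPIKEIN_LOG_RATIOS[i % len(SPIKEIN_LOG_RATIOS)] for i in range(n_spike)]
        )
        lo = cfg.baseline_log2_mean - 1.5 * cfg.baseline_log2_sd
        hi = cfg.baseline_log2_mean + 1.5 * cfg.baseline_log2_sd
        spike_a = np.linspace(lo, hi, n_spike) if n_spike > 1 else np.array([(lo + hi) / 2])
        sp_noise_s = rng.normal(0.0, 1.0, size=(n_spike, n_arrays)) * cfg.probe_noise_sd
        sp_noise_r = rng.normal(0.0, 1.0, size=(n_spike, n_arrays)) * cfg.probe_noise_sd
        sp_sample = spike_a[:, None] + 0.5 * spike_m[:, None] + sp_noise_s
        sp_ref = spike_a[:, None] - 0.5 * spike_m[:, None] + sp_noise_r
        if cfg.dye_bias_amplitude != 0.0:
            a_pre = 0.5 * (sp_sample + sp_ref)
            m_bias = cfg.dye_bias_amplitude * np.sin(
                2.0 * np.pi * a_pre / cfg.dye_bias_period
            )
            sp_sample = sp_sample + 0.5 * m_bias
            sp_ref = sp_ref - 0.5 * m_bias
        spike_cluster = np.array(
            [f"SPIKE_{i + 1:02d}" for i in range(n_spike)], dtype=object
        )
        spike_probe = np.array(
            [f"SPIKE_{i + 1:02d}_p1" for i in range(n_spike)], dtype=object
        )

    # --- assemble long-format probe table ---------------------------------
    frames = []
    for a, aid in enumerate(design["array_id"]):
        frames.append(
            pd.DataFrame(
                {
                    "array_id": aid,
                    "probe_id": probe_ids,
                    "cluster_id": cluster_ids[cl_of_probe],
                    "is_control": False,
                    "sample_intensity": np.exp2(sample_log2[:, a]),
                    "reference_intensity": np.exp2(ref_log2[:, a]),
                    "qc_ok": True,
                }
            )
        )
        if n_spike > 0:
            frames.append(
                pd.DataFrame(
                    {
                        "array_id": aid,
                        "probe_id": spike_probe,
                        "cluster_id": spike_cluster,
                        "is_control": True,
                        "sample_intensity": np.exp2(sp_sample[:, a]),
                        "reference_intensity": np.exp2(sp_ref[:, a]),
                        "qc_ok": True,
                    }
                )
            )
    probe_table = pd.concat(frames, ignore_index=True)
    return probe_table, design, truth


def spikein_truth(cfg: SimConfig) -> pd.DataFrame:
    """Planted log-ratio of each spike-in probe (for benchmark checks)."""
    rows = [
        {
            "probe_id": f"SPIKE_{i + 1:02d}_p1",
            "cluster_id": f"SPIKE_{i + 1:02d}",
            "planted_m": SPIKEIN_LOG_RATIOS[i % len(SPIKEIN_LOG_RATIOS)],
        }
        for i in range(cfg.n_spikein)
    ]
    return pd.DataFrame(rows)


def truth_to_expected_sets(
    truth: pd.DataFrame, cfg: PipelineConfig
) -> Dict[Tuple[str, str], DirectedGeneSet]:
    """Recovery oracle: the directed set each contrast should find.

    A cluster belongs to the expected set of (stage, contrast) when it
    is expressed in that stage and its planted effect magnitude reaches
    ``log2(fc_threshold)``; the direction is the effect's sign.
    """
    thr = np.log2(cfg.fc_threshold)
    out: Dict[Tuple[str, str], DirectedGeneSet] = {}
    for stage in STAGES:
        expressed = truth["expressed_in_stage"].isin(["both", f"{stage}_only"])
        for contrast in CONTRAST_LABELS:
            eff = contrast_effect(truth, contrast)
            member = expressed & (eff.abs() >= thr)
            members = {
                cid: ("up" if e > 0 else "down")
                for cid, e in zip(truth.loc[member, "cluster_id"], eff[member])
            }
            out[(stage, contrast)] = DirectedGeneSet(
                label=f"expected {stage} {contrast}",
                contrast=contrast,
                stage=stage,
                members=members,
            )
    return out


# ---------------------------------------------------------------------------
# Toy annotation (keyword-bearing descriptions for the category module)
# ---------------------------------------------------------------------------

_TOY_DESCRIPTIONS = [
    ("glucose-6-phosphate dehydrogenase", "KOG0563", "carbon_metabolism"),
    ("trehalose-6-phosphate synthase/phosphatase", "KOG1050", "carbon_metabolism"),
    ("glucan beta-1,3-glucosidase", "KOG2254", "carbon_metabolism"),
    ("fucoxanthin-chlorophyll a/c binding protein", "KOG1624", "light_reactions"),
    ("phytoene desaturase", "KOG0714", "light_reactions"),
    ("zeaxanthin epoxidase", "KOG1399", "light_reactions"),
    ("sphingosine-1-kinase", "KOG1116", "signaling"),
    ("phosphatidylinositolphosphate kinase", "KOG0229", "signaling"),
    ("CBL-interacting protein kinase", "KOG0583", "signaling"),
    ("Ca2+/H+ antiporter", "KOG1397", "ion_fluxes"),
    ("Na+/H+ exchanger", "KOG1966", "ion_fluxes"),
    ("bicarbonate transporter with EF-hand motif", "KOG2821", "ion_fluxes"),
    ("hypothetical protein", "", ""),
    ("conserved unknown protein", "", ""),
    ("ribosomal protein L12", "KOG3402", ""),
    ("tubulin alpha chain", "KOG1376", ""),
]


def toy_annotation(truth: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Deterministic toy annotation table for a simulated experiment.

    Cycles realistic descriptions (including keyword-bearing ones for
    all four functional categories) over the clusters; e-values are
    planted well inside the screening cutoffs, with a sprinkle of weak
    alignments so the filters have something to remove.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, cid in enumerate(truth["cluster_id"]):
        desc, kog, _cat = _TOY_DESCRIPTIONS[i % len(_TOY_DESCRIPTIONS)]
        weak = rng.random() < 0.05
        e1 = 1e-3 if weak else 10.0 ** (-rng.uniform(8, 40))
        rows.append(
            {
                "cluster_id": cid,
                "model_1": f"em_model_{2 * i + 1:05d}",
                "evalue_1": e1,
                "model_2": f"em_model_{2 * i + 2:05d}",
                "evalue_2": min(1.0, e1 * 10.0 ** rng.uniform(1, 4)),
                "kog_class": kog,
                "description": desc,
            }
        )
    return pd.DataFrame(rows)
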