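import numpy as np
import pandas as pd
import pytest

from oascreen.datamodel import PipelineConfig, SimConfig
from oascreen.simulate import simulate_experiment


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_experiment():
    """A modest noisy experiment with planted effects and anomalies."""
    scfg = SimConfig(
        n_clusters=200,
        seed=7,
        anomaly_rate_divergent=0.02,
        anomaly_rate_dead=0.02,
    )
    probes, design, truth = simulate_experiment(scfg)
    return scfg, probes, design, truth


@pytest.fixture(scope="session")
def clean_experiment():
    """Zero-noise, zero-anomaly experiment (exact-recovery regime)."""
    scfg = SimConfig(
        n_clusters=120,
        seed=11,
        probe_noise_sd=0.0,
        replicate_noise_sd=0.0,
        anomaly_rate_divergent=0.0,
        anomaly_rate_dead=0.0,
        dye_bias_amplitude=0.0,
    )
    probes, design, truth = simulate_experiment(scfg)
    return scfg, probes, design, truth


def toy_probe_frame():
    """Two arrays x one cluster with three probes, hand-enterable numbers."""
    rows = []
    for aid in ("a1", "a2"):
        for p, (s, r) in {
            "c1_p1": (200.0, 100.0),
            "c1_p2": (100.0, 100.0),
            "c1_p3": (50.0, 100.0),
        }.items():
            rows.append(
                {
                    "array_id": aid,
                    "probe_id": p,
                    "cluster_id": "c1",
                    "is_control": False,
                    "sample_intensity": s,
                    "reference_intensity": r,
                    "qc_ok": True,
                }
            )
    return pd.DataFrame(rows)
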