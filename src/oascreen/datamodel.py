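"""Shared data model: configuration objects, call records, gene sets, errors.

Tabular data (probe tables, designs, normalized ratios, probe/cluster
calls) travels through the pipeline as :class:`pandas.DataFrame` with
fixed column schemas (see :mod:`oascreen.io`); the dataclasses here
cover the structured, non-tabular objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------

STAGES = ("diploid", "haploid")

#: pCO2 treatment levels in Pa (present-day vs ocean-acidification scenario).
PCO2_LEVELS = (38.5, 101.3)

#: Growth light levels in umol photons m-2 s-1.
LIGHT_LEVELS = (50, 300)

N_REPLICATES = 3
PROBES_PER_CLUSTER = 3

#: Fixed contrast vocabulary. Each is evaluated separately per stage.
#: The first-named group is the "treatment" (numerator of the implied
#: treatment-vs-treatment ratio): high CO2 vs low CO2, high light vs low light.
CONTRAST_LABELS = (
    "co2_at_lowlight",
    "co2_at_highlight",
    "light_at_lowco2",
    "light_at_highco2",
)

#: contrast label -> ((treatment pco2, treatment light), (control pco2, control light))
CONTRAST_GROUPS: Dict[str, Tuple[Tuple[float, int], Tuple[float, int]]] = {
    "co2_at_lowlight": ((101.3, 50), (38.5, 50)),
    "co2_at_highlight": ((101.3, 300), (38.5, 300)),
    "light_at_lowco2": ((38.5, 300), (38.5, 50)),
    "light_at_highco2": ((101.3, 300), (101.3, 50)),
}

DIRECTIONS = ("up", "down")

CALL_VALUES = ("up", "down", "not_significant")

CLUSTER_STATUS = (
    "regulated",
    "excluded_divergent",
    "excluded_single_probe",
    "not_regulated",
    "untestable",
)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class FormatError(ValueError):
    """A table violates the expected on-disk format (missing column, bad enum)."""


class IntegrityError(ValueError):
    """A table violates a cross-row invariant (duplicate keys, probe in two clusters)."""


class ConfigError(ValueError):
    """An invalid configuration value."""


class NormalizationError(RuntimeError):
    """An array cannot be normalized (e.g. too few usable probes)."""


class ContrastError(ValueError):
    """A contrast references a treatment group absent from the design."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Thresholds and knobs governing the analysis chain.

    alpha
        Per-probe significance level for the pairwise contrast p-value.
    fc_threshold
        Minimum fold change (linear scale, >= 1) a probe must reach,
        applied symmetrically to up- and down-regulation.
    min_concordant_probes
        Concordant significant probes required to call a cluster regulated.
    loess_span, loess_iterations
        LOWESS smoothing fraction and robustifying iteration count for
        the within-array dye-bias fit.
    evalue_blast, evalue_b2g
        E-value cutoffs for the model alignments and for the free-text
        description evidence in the annotation table (alignments with
        e-value strictly greater than the cutoff are discarded).
    multiple_comparison
        "lsd" (Fisher's least significant difference from the pooled
        ANOVA mean square, default) or "tukey" (studentized range).
    """

    alpha: float = 0.05
    fc_threshold: float = 1.5
    min_concordant_probes: int = 2
    loess_span: float = 0.4
    loess_iterations: int = 3
    evalue_blast: float = 1e-5
    evalue_b2g: float = 1e-6
    multiple_comparison: str = "lsd"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.fc_threshold < 1.0:
            raise ConfigError(f"fc_threshold must be >= 1, got {self.fc_threshold}")
        if self.min_concordant_probes < 1:
            raise ConfigError("min_concordant_probes must be >= 1")
        if not 0.0 < self.loess_span <= 1.0:
            raise ConfigError(f"loess_span must lie in (0, 1], got {self.loess_span}")
        if self.loess_iterations < 0:
            raise ConfigError("loess_iterations must be >= 0")
        if self.evalue_blast <= 0 or self.evalue_b2g <= 0:
            raise ConfigError("e-value cutoffs must be strictly positive")
        if self.multiple_comparison not in ("lsd", "tukey"):
            raise ConfigError(
                f"multiple_comparison must be 'lsd' or 'tukey', got {self.multiple_comparison!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimConfig:
    """Parameters of the synthetic two-color common-reference experiment.

    The generator plants a 2 stage x 2 pCO2 x 2 light factorial with
    biological triplicates, three probes per transcript cluster, and a
    pooled-reference channel shared across arrays.

    Fractions partition the clusters into response classes for the CO2
    factor (core = responds under both lights; ll/hl = responds under
    exactly one light) and analogously for the light factor.
    ``fraction_stage_shared`` is the probability that a responsive
    cluster is expressed (and responds) in both life-cycle stages;
    the remainder is assigned to a single stage, emulating
    ploidy-specific genome utilization.
    """

    n_clusters: int = 1000
    fraction_core_oa: float = 0.10
    fraction_ll_specific: float = 0.05
    fraction_hl_specific: float = 0.05
    fraction_core_light: float = 0.05
    fraction_ll_specific_light: float = 0.0
    fraction_hl_specific_light: float = 0.0
    fraction_stage_shared: float = 0.5
    fraction_silent: float = 0.02
    fraction_stage_only_expression: float = 0.10
    effect_log2_mean: float = 1.5
    effect_log2_sd: float = 0.3
    probe_noise_sd: float = 0.2
    replicate_noise_sd: float = 0.1
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    background_log2: float = 4.0
    dye_bias_amplitude: float = 0.0
    dye_bias_period: float = 16.0
    anomaly_rate_divergent: float = 0.0
    anomaly_rate_dead: float = 0.0
    dead_probe_sd: float = 0.5
    n_spikein: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_core_oa,
            self.fraction_ll_specific,
            self.fraction_hl_specific,
            self.fraction_core_light,
            self.fraction_ll_specific_light,
            self.fraction_hl_specific_light,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError("response fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + 1e-12:
            raise ConfigError("response fractions must sum to <= 1")
        if not 0.0 <= self.fraction_stage_shared <= 1.0:
            raise ConfigError("fraction_stage_shared must lie in [0, 1]")
        for name in ("anomaly_rate_divergent", "anomaly_rate_dead"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must lie in [0, 1)")
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.probe_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Calls and gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeCall:
    """Outcome of testing one probe for one contrast."""

    probe_id: str
    cluster_id: str
    contrast: str
    p_value: float
    log2fc: float
    call: str  # up | down | not_significant
    testable: bool = True


@dataclass(frozen=True)
class ClusterCall:
    """Collapsed call for one transcript cluster and contrast.

    ``mean_fold_change`` is signed: its sign encodes the direction and
    its magnitude is the geometric mean of the hit probes' fold changes
    (i.e. the arithmetic mean of |log2fc| back-transformed). Zero when
    the cluster is not regulated.
    """

    cluster_id: str
    contrast: str
    status: str
    direction: str  # up | down | none
    n_hit_probes: int
    mean_fold_change: float


@dataclass
class DirectedGeneSet:
    """A named set of (cluster, direction) pairs for one contrast."""

    label: str
    contrast: str
    stage: str
    members: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c: d for c, d in self.members.items() if d not in DIRECTIONS}
        if bad:
            raise IntegrityError(f"invalid directions in gene set {self.label!r}: {bad}")

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.members.values() if d == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for d in self.members.values() if d == "down")

    def __len__(self) -> int:
        return len(self.members)

    def clusters(self) -> set:
        return set(self.members)


@dataclass
class VennPartition:
    """Identity-based partition of two directed gene sets.

    ``core`` holds the identity intersection (directions taken from the
    first parent); ``discordant`` lists intersection members whose
    directions disagree between the parents. Disjointness and the
    counting identities |only_first| + |core| = |first| hold by
    construction.
    """

    core: DirectedGeneSet
    only_first: DirectedGeneSet
    only_second: DirectedGeneSet
    discordant: List[str] = field(default_factory=list)
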