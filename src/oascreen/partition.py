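"""Direction-aware gene-set algebra over collapsed cluster calls.

The screening design yields, per life-cycle stage, an ocean-
acidification (CO2) response set under each light level and a light
response set under each CO2 level. The algebra mirrors the standard
Venn treatment of such factorial screens:

* *core response*: identity intersection of the two parent sets
  (a factor's responders under both levels of the other factor);
* *condition-specific response*: identity set difference parent\\core;
* *stage-independent response*: identity intersection of the two
  stages' core sets, with a concordance filter for the "uniform"
  report.

Core membership is decided by cluster identity, not by direction
agreement, so the counting identities |parent \\ core| = |parent| -
|core| always hold exactly; members whose directions disagree between
the parents stay in the core but are listed as discordant.
"""

from __future__ import annotations

from typing import Dict, Tuple

import pandas as pd

from .datamodel import (
    CONTRAST_LABELS,
    DirectedGeneSet,
    STAGES,
    VennPartition,
)

#: Figure-style set labels: per stage, the OA response under high and
#: low light and the cores; light responses analogously.
SET_LABELS = {
    ("diploid", "co2_at_highlight"): "A",
    ("diploid", "co2_at_lowlight"): "B",
    ("haploid", "co2_at_highlight"): "D",
    ("haploid", "co2_at_lowlight"): "E",
}


def build_set(
    calls: pd.DataFrame, stage: str, contrast: str, label: str
) -> DirectedGeneSet:
    """Directed set of regulated clusters for one stage and contrast.

    Only clusters with status ``regulated`` enter; excluded and
    unregulated clusters never appear in any set.
    """
    sub = calls.loc[
        (calls["stage"] == stage)
        & (calls["contrast"] == contrast)
        & (calls["status"] == "regulated")
    ]
    members = dict(zip(sub["cluster_id"], sub["direction"]))
    return DirectedGeneSet(label=label, contrast=contrast, stage=stage, members=members)


def intersect_core(
    first: DirectedGeneSet, second: DirectedGeneSet, label: str = ""
) -> VennPartition:
    """Identity-based Venn partition of two directed gene sets.

    Core = clusters present in both parents (direction from the first
    parent; direction disagreements listed in ``discordant``);
    only_first / only_second = identity set differences.
    """
    common = first.clusters() & second.clusters()
    core = {c: first.members[c] for c in common}
    discordant = sorted(
        c for c in common if first.members[c] != second.members[c]
    )
    only_first = {c: d for c, d in first.members.items() if c not in common}
    only_second = {c: d for c, d in second.members.items() if c not in common}
    lbl = label or f"{first.label}&{second.label}"
    return VennPartition(
        core=DirectedGeneSet(
            label=lbl, contrast=first.contrast, stage=first.stage, members=core
        ),
        only_first=DirectedGeneSet(
            label=f"{first.label}\\{lbl}",
            contrast=first.contrast,
            stage=first.stage,
            members=only_first,
        ),
        only_second=DirectedGeneSet(
            label=f"{second.label}\\{lbl}",
            contrast=second.contrast,
            stage=second.stage,
            members=only_second,
        ),
        discordant=discordant,
    )


def stage_independent_overlap(
    core_diploid: DirectedGeneSet, core_haploid: DirectedGeneSet
) -> VennPartition:
    """Overlap the two stages' core responses across stages.

    Identity intersection as in :func:`intersect_core`; "reacting
    uniformly in both stages" additionally requires concordant
    direction, so discordant members are flagged and excluded from the
    uniform report (``partition.core`` keeps them; callers use
    ``uniform_members`` for the concordant subset).
    """
    part = intersect_core(core_diploid, core_haploid, label="stage_independent")
    return part


def uniform_members(part: VennPartition) -> Dict[str, str]:
    """Concordant-direction subset of a partition's core."""
    return {
        c: d for c, d in part.core.members.items() if c not in set(part.discordant)
    }


def _set_counts(s: DirectedGeneSet) -> dict:
    return {"total": len(s), "up": s.n_up, "down": s.n_down}


def venn_counts(calls: pd.DataFrame) -> dict:
    """Full count report over all 8 primary sets, cores and differences.

    Builds, per stage, the OA response under high/low light and the
    light response under high/low CO2, intersects each factor's pair
    into its core, computes the condition-specific differences, and
    overlaps the two stages' OA (and light) cores across stages.
    Every reported set carries total/up/down counts (up + down =
    total by construction).
    """
    report: dict = {"sets": {}, "partitions": {}}
    cores: Dict[Tuple[str, str], DirectedGeneSet] = {}
    for stage in STAGES:
        sets = {
            contrast: build_set(
                calls,
                stage,
                contrast,
                SET_LABELS.get((stage, contrast), f"{stage}:{contrast}"),
            )
            for contrast in CONTRAST_LABELS
        }
        for contrast, s in sets.items():
            report["sets"][f"{stage}/{contrast}"] = _set_counts(s)

        for factor, (hi, lo) in {
            "oa": ("co2_at_highlight", "co2_at_lowlight"),
            "light": ("light_at_highco2", "light_at_lowco2"),
        }.items():
            part = intersect_core(sets[hi], sets[lo], label=f"{stage}_{factor}_core")
            cores[(stage, factor)] = part.core
            report["partitions"][f"{stage}/{factor}"] = {
                "core": _set_counts(part.core),
                "only_first": _set_counts(part.only_first),
                "only_second": _set_counts(part.only_second),
                "discordant": part.discordant,
            }

    for factor in ("oa", "light"):
        part = stage_independent_overlap(
            cores[("diploid", factor)], cores[("haploid", factor)]
        )
        uniform = uniform_members(part)
        report["partitions"][f"stage_independent/{factor}"] = {
            "core": _set_counts(part.core),
            "only_first": _set_counts(part.only_first),
            "only_second": _set_counts(part.only_second),
            "discordant": part.discordant,
            "uniform": {
                "total": len(uniform),
                "up": sum(1 for d in uniform.values() if d == "up"),
                "down": sum(1 for d in uniform.values() if d == "down"),
            },
        }
    return report
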