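"""Probe-set consistency rules: merge <=3 probe calls into a cluster call.

Decision order for the testable probes of one cluster and contrast:

1. significant calls in both directions        -> excluded_divergent
   (the probe set is dropped as a whole; divergence trumps everything)
2. exactly one significant probe, rest unaltered -> excluded_single_probe
3. >= ``min_concordant_probes`` concordant significant probes
                                               -> regulated (direction =
   the common direction; n_hit_probes = significant-probe count;
   mean_fold_change = signed geometric mean of the hit probes' folds)
4. no significant probe                        -> not_regulated

Clusters with fewer than two testable probes are ``untestable``.
"Unaltered" means not called up/down, i.e. failing either the p-value
or the fold-change threshold. With three probes and
``min_concordant_probes = 2`` these rules are exactly the screening
procedure of keeping a cluster unless its probes diverge or only one
of three responds; the two-probe pattern [significant, unaltered] is
excluded as a conservative extension of the one-of-three rule.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import ClusterCall, IntegrityError, PipelineConfig, ProbeCall


def collapse_cluster(
    probe_calls: Sequence[ProbeCall], cfg: PipelineConfig
) -> ClusterCall:
    """Collapse the probe calls of one cluster/contrast into a ClusterCall."""
    if not probe_calls:
        raise IntegrityError("collapse_cluster needs at least one probe call")
    cluster_ids = {c.cluster_id for c in probe_calls}
    contrasts = {c.contrast for c in probe_calls}
    if len(cluster_ids) != 1 or len(contrasts) != 1:
        raise IntegrityError(
            f"mixed cluster/contrast in collapse input: {cluster_ids}, {contrasts}"
        )
    cluster_id = probe_calls[0].cluster_id
    contrast = probe_calls[0].contrast

    testable = [c for c in probe_calls if c.testable]
    n_up = sum(1 for c in testable if c.call == "up")
    n_down = sum(1 for c in testable if c.call == "down")
    n_sig = n_up + n_down

    def done(status: str, direction: str = "none", n_hit: int = 0, mfc: float = 0.0):
        return ClusterCall(
            cluster_id=cluster_id,
            contrast=contrast,
            status=status,
            direction=direction,
            n_hit_probes=n_hit,
            mean_fold_change=mfc,
        )

    if len(testable) < 2:
        return done("untestable")
    if n_up > 0 and n_down > 0:
        return done("excluded_divergent")
    if n_sig == 1:
        return done("excluded_single_probe")
    if n_sig >= cfg.min_concordant_probes:
        direction = "up" if n_up > 0 else "down"
        hits = [c for c in testable if c.call == direction]
        mean_abs_log2 = float(np.mean([abs(c.log2fc) for c in hits]))
        mfc = float(2.0 ** mean_abs_log2)
        if direction == "down":
            mfc = -mfc
        return done("regulated", direction, n_sig, mfc)
    if n_sig == 0:
        return done("not_regulated")
    # n_sig between 2 and min_concordant_probes-1 (only reachable when the
    # concordance requirement is raised above 2)
    return done("excluded_single_probe" if n_sig == 1 else "not_regulated")


def collapse_all(
    probe_calls: pd.DataFrame, cfg: PipelineConfig
) -> Tuple[pd.DataFrame, Dict[str, Dict[str, int]]]:
    """Collapse a full probe-call table; returns (cluster calls, tally).

    The tally maps each (stage, contrast) pair, rendered as
    ``"stage/contrast"``, to per-status counts — the analog of the
    screening logs that reported how many probe sets each exclusion
    rule removed per hybridization comparison.
    """
    records: List[dict] = []
    tally: Dict[str, Dict[str, int]] = {}
    group_cols = ["stage", "contrast", "cluster_id"]
    for (stage, contrast, cluster_id), sub in probe_calls.groupby(
        group_cols, sort=True
    ):
        calls = [
            ProbeCall(
                probe_id=r.probe_id,
                cluster_id=r.cluster_id,
                contrast=r.contrast,
                p_value=r.p_value,
                log2fc=r.log2fc,
                call=r.call,
                testable=bool(r.testable),
            )
            for r in sub.itertuples()
        ]
        cc = collapse_cluster(calls, cfg)
        records.append(
            {
                "cluster_id": cc.cluster_id,
                "stage": stage,
                "contrast": cc.contrast,
                "status": cc.status,
                "direction": cc.direction,
                "n_hit_probes": cc.n_hit_probes,
                "mean_fold_change": cc.mean_fold_change,
            }
        )
        key = f"{stage}/{contrast}"
        tally.setdefault(key, Counter())[cc.status] += 1
    out = pd.DataFrame.from_records(
        records,
        columns=[
            "cluster_id",
            "stage",
            "contrast",
            "status",
            "direction",
            "n_hit_probes",
            "mean_fold_change",
        ],
    )
    return out, {k: dict(v) for k, v in tally.items()}
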