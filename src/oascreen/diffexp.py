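"""Per-probe significance and fold-change calling.

The test is a one-way fixed-effects ANOVA across the (up to four)
pCO2 x light treatment groups of one life-cycle stage, with pairwise
contrast p-values from Fisher's least-significant-difference t
statistic on the pooled residual mean square:

    t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j)),   df = N - k

A probe is called up/down for a contrast only when the pairwise
p-value passes ``alpha`` AND the fold change passes ``fc_threshold``
(conjunctive thresholds); the direction is the sign of the log2 fold
change. Tukey's HSD (studentized range on the same pooled MSE) is
available behind ``PipelineConfig.multiple_comparison = "tukey"``.
No across-probe multiple-testing correction is applied by default; an
optional Benjamini-Hochberg adjustment can be requested explicitly.
"""

from __future__ import annotations

from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CONTRAST_GROUPS,
    PipelineConfig,
    ProbeCall,
)
from .normalize import group_m_values

#: canonical order of the four treatment cells within a stage
CELL_ORDER: Tuple[Tuple[float, int], ...] = (
    (38.5, 50),
    (38.5, 300),
    (101.3, 50),
    (101.3, 300),
)


class StatisticalError(ValueError):
    """A probe cannot be tested (e.g. a group with < 2 replicates)."""


def _pooled_anova(values: Sequence[np.ndarray]):
    """Group means, pooled MSE and error df for a list of 1-D value arrays."""
    means = np.array([np.mean(g) for g in values])
    ns = np.array([len(g) for g in values])
    sse = float(sum(np.sum((g - m) ** 2) for g, m in zip(values, means)))
    df = int(ns.sum() - len(values))
    return means, ns, sse, df


def _pair_p(diff: float, mse: float, n_i: int, n_j: int, df: int, k: int, method: str) -> float:
    if df <= 0:
        return float("nan")
    se2 = mse * (1.0 / n_i + 1.0 / n_j)
    if se2 == 0.0:
        return 0.0 if diff != 0.0 else 1.0
    t = diff / np.sqrt(se2)
    if method == "tukey":
        return float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
    return float(2.0 * stats.t.sf(abs(t), df))


def probe_anova(
    values_by_group: Mapping[str, Sequence[float]],
    method: str = "lsd",
) -> Tuple[float, Dict[Tuple[str, str], float]]:
    """One-way ANOVA across treatment groups for a single probe.

    Returns ``(omnibus_p, pairwise_p)`` where ``pairwise_p`` maps each
    unordered group-name pair to its contrast p-value. Raises
    :class:`StatisticalError` when fewer than two groups are supplied
    or any group holds fewer than two replicate values.
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise StatisticalError("ANOVA needs at least two groups")
    groups = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if any(len(g) < 2 for g in groups):
        bad = names[next(i for i, g in enumerate(groups) if len(g) < 2)]
        raise StatisticalError(f"group {bad!r} has fewer than 2 replicates")
    means, ns, sse, df = _pooled_anova(groups)
    k = len(groups)
    grand = float(np.concatenate(groups).mean())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    if sse == 0.0:
        omnibus = 0.0 if ssb > 0.0 else 1.0
    else:
        f = (ssb / (k - 1)) / (sse / df)
        omnibus = float(stats.f.sf(f, k - 1, df))
    mse = sse / df if df > 0 else np.nan
    pairwise: Dict[Tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            pairwise[(names[i], names[j])] = _pair_p(
                float(means[i] - means[j]), mse, int(ns[i]), int(ns[j]), df, k, method
            )
    return omnibus, pairwise


def call_probe(
    probe_id: str,
    cluster_id: str,
    contrast: str,
    p_value: float,
    log2fc: float,
    cfg: PipelineConfig,
    testable: bool = True,
) -> ProbeCall:
    """Apply the conjunctive p-value and fold-change thresholds."""
    thr = np.log2(cfg.fc_threshold)
    call = "not_significant"
    if testable and np.isfinite(p_value) and p_value <= cfg.alpha:
        if log2fc >= thr:
            call = "up"
        elif log2fc <= -thr:
            call = "down"
    return ProbeCall(
        probe_id=probe_id,
        cluster_id=cluster_id,
        contrast=contrast,
        p_value=float(p_value),
        log2fc=float(log2fc),
        call=call,
        testable=testable,
    )


def _anova_lsd_vectorized(
    values: np.ndarray,
    cell_of_col: np.ndarray,
    pair: Tuple[int, int],
    method: str,
):
    """Vectorized pooled-MSE pairwise test over a probe x array M matrix.

    ``values`` may contain NaN for missing (qc-failed) replicates.
    Returns (p, log2fc, testable) arrays, one entry per probe row.
    """
    n_probes = values.shape[0]
    cells = np.unique(cell_of_col)
    means = np.full((n_probes, len(CELL_ORDER)), np.nan)
    counts = np.zeros((n_probes, len(CELL_ORDER)), dtype=int)
    sse = np.zeros(n_probes)
    for c in cells:
        cols = cell_of_col == c
        sub = values[:, cols]
        n = np.sum(~np.isnan(sub), axis=1)
        m = np.nansum(sub, axis=1) / np.maximum(n, 1)
        m[n == 0] = np.nan
        with np.errstate(invalid="ignore"):
            dev = sub - m[:, None]
            sse += np.nansum(dev * dev, axis=1)
        means[:, c] = m
        counts[:, c] = n
    n_total = counts.sum(axis=1)
    k_eff = (counts > 0).sum(axis=1)
    df = n_total - k_eff
    i, j = pair
    n_i, n_j = counts[:, i], counts[:, j]
    testable = (n_i >= 2) & (n_j >= 2) & (df > 0)
    diff = means[:, i] - means[:, j]

    with np.errstate(divide="ignore", invalid="ignore"):
        mse = np.where(df > 0, sse / np.maximum(df, 1), np.nan)
        se2 = mse * (1.0 / np.maximum(n_i, 1) + 1.0 / np.maximum(n_j, 1))
        t = np.abs(diff) / np.sqrt(se2)
    p = np.full(n_probes, np.nan)
    ok = testable & (se2 > 0)
    if method == "tukey":
        p[ok] = stats.studentized_range.sf(t[ok] * np.sqrt(2.0), k_eff[ok], df[ok])
    else:
        p[ok] = 2.0 * stats.t.sf(t[ok], df[ok])
    # zero pooled variance: exact replication -> p driven by the mean difference
    degen = testable & (se2 == 0)
    p[degen] = np.where(diff[degen] != 0.0, 0.0, 1.0)
    return p, diff, testable


def probe_calls_for_contrast(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    stage: str,
    contrast: str,
    cfg: PipelineConfig,
    adjust_bh: bool = False,
) -> pd.DataFrame:
    """Call every probe of one stage for one contrast.

    Returns a probe-call table (columns probe_id, cluster_id, stage,
    contrast, p_value, log2fc, call, testable). Probes untestable for
    the contrast (a group with < 2 usable replicates) are retained
    with ``call = not_significant`` and ``testable = False`` so the
    collapse stage can count them.
    """
    mat, groups = group_m_values(normalized, design, stage)
    cell_index = {cell: k for k, cell in enumerate(CELL_ORDER)}
    cols = list(mat.columns)
    cell_of_col = np.array([cell_index[groups[a]] for a in cols])
    (t_cell, c_cell) = CONTRAST_GROUPS[contrast]
    pair = (cell_index[t_cell], cell_index[c_cell])
    values = mat.to_numpy(dtype=float)
    p, log2fc, testable = _anova_lsd_vectorized(
        values, cell_of_col, pair, cfg.multiple_comparison
    )
    if adjust_bh:
        from statsmodels.stats.multitest import multipletests

        finite = np.isfinite(p)
        adj = p.copy()
        if finite.any():
            adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
        p = adj

    thr = np.log2(cfg.fc_threshold)
    sig = testable & np.isfinite(p) & (p <= cfg.alpha)
    call = np.where(
        sig & (log2fc >= thr),
        "up",
        np.where(sig & (log2fc <= -thr), "down", "not_significant"),
    )
    probe_ids = mat.index.get_level_values("probe_id")
    cluster_ids = mat.index.get_level_values("cluster_id")
    out = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "cluster_id": cluster_ids,
            "stage": stage,
            "contrast": contrast,
            "p_value": p,
            "log2fc": log2fc,
            "call": call,
            "testable": testable,
        }
    )
    out.attrs["n_untestable"] = int((~testable).sum())
    return out
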