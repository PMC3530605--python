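"""MA transformation, within-array LOWESS dye-bias correction, contrasts.

M is always defined sample-minus-reference on the log2 scale,
independent of which dye the sample carried (the design records the
orientation but no dye-swap averaging is performed). The LOWESS fit of
M on A is computed per array over non-control, quality-passing probes;
control/spike-in probes are corrected by the fit but never influence
it, so they remain an unbiased benchmark of the correction. A values
are never modified.

Because every sample is hybridized against the same pooled reference,
the treatment-vs-treatment log-ratio for a probe is simply the
difference of group-mean M values; the reference cancels.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .datamodel import (
    CONTRAST_GROUPS,
    ContrastError,
    NormalizationError,
)

#: Minimum usable non-control probes for a per-array LOWESS fit.
MIN_PROBES_FOR_FIT = 20

#: Gross M outliers (|M - median| beyond this many robust SDs) are kept
#: out of the LOWESS fit. They are still corrected by it. This keeps
#: probes of transcripts absent in one stage (log-ratios of several
#: units against the pooled reference) from steering the dye-bias
#: trend, which must reflect the unchanged majority of probes.
OUTLIER_NSD = 6.0
_MAD_TO_SD = 1.4826


def ma_transform(records: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Convert a probe intensity table to per-probe M/A coordinates.

    Probes with ``qc_ok = False`` (which includes any non-positive
    intensity) are skipped; the number skipped per array is available
    in ``result.attrs["skipped_per_array"]``. Arrays present in the
    probe table but absent from the design raise ``ContrastError``.
    """
    known = set(design["array_id"])
    unknown = set(records["array_id"]) - known
    if unknown:
        raise ContrastError(f"array(s) missing from design: {sorted(unknown)[:3]}")

    skipped = (
        records.loc[~records["qc_ok"]].groupby("array_id").size().to_dict()
    )
    ok = records.loc[records["qc_ok"]].copy()
    s = ok["sample_intensity"].to_numpy(dtype=float)
    r = ok["reference_intensity"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "array_id": ok["array_id"].to_numpy(),
            "probe_id": ok["probe_id"].to_numpy(),
            "cluster_id": ok["cluster_id"].to_numpy(),
            "is_control": ok["is_control"].to_numpy(),
            "M": np.log2(s) - np.log2(r),
            "A": 0.5 * (np.log2(s) + np.log2(r)),
        }
    )
    out.attrs["skipped_per_array"] = skipped
    return out


def _fit_lowess(m: np.ndarray, a: np.ndarray, span: float, iterations: int):
    """LOWESS fit of M on A; returns an interpolator over the fitted curve."""
    fitted = sm_lowess(
        m, a, frac=span, it=iterations, return_sorted=True
    )
    xs, ys = fitted[:, 0], fitted[:, 1]
    # collapse duplicate x for stable interpolation
    if len(xs) > 1 and np.any(np.diff(xs) == 0):
        ux, inv = np.unique(xs, return_inverse=True)
        uy = np.zeros_like(ux)
        np.add.at(uy, inv, ys)
        counts = np.bincount(inv)
        uy = uy / counts
        xs, ys = ux, uy
    return lambda x: np.interp(x, xs, ys)


def lowess_correct(
    ratios: pd.DataFrame, span: float = 0.4, iterations: int = 3
) -> pd.DataFrame:
    """Subtract the per-array LOWESS trend of M on A.

    The trend is fitted over non-control probes only; all probes
    (including controls) are corrected by interpolating the fitted
    curve at their A. Arrays with fewer than ``MIN_PROBES_FOR_FIT``
    usable non-control probes raise :class:`NormalizationError`.
    Output has the same rows and A values as the input.
    """
    out = ratios.copy()
    m_corr = out["M"].to_numpy(dtype=float).copy()
    a_all = out["A"].to_numpy(dtype=float)
    is_control = out["is_control"].to_numpy(dtype=bool)
    for array_id, idx in out.groupby("array_id", sort=False).indices.items():
        idx = np.asarray(idx)
        fit_idx = idx[~is_control[idx]]
        if len(fit_idx) < MIN_PROBES_FOR_FIT:
            raise NormalizationError(
                f"array {array_id!r}: only {len(fit_idx)} usable non-control probes "
                f"(need >= {MIN_PROBES_FOR_FIT}) for the LOWESS fit"
            )
        med = np.median(m_corr[fit_idx])
        mad = np.median(np.abs(m_corr[fit_idx] - med))
        keep = np.abs(m_corr[fit_idx] - med) <= OUTLIER_NSD * _MAD_TO_SD * mad
        if keep.sum() >= max(MIN_PROBES_FOR_FIT, len(fit_idx) // 2):
            fit_idx = fit_idx[keep]
        predict = _fit_lowess(
            m_corr[fit_idx], a_all[fit_idx], span=span, iterations=iterations
        )
        m_corr[idx] = m_corr[idx] - predict(a_all[idx])
    out["M"] = m_corr
    return out


def contrast_ratios(
    ratios: pd.DataFrame,
    design: pd.DataFrame,
    stage: str,
    contrast: str,
) -> pd.DataFrame:
    """Per-probe replicate M values for the two groups of a contrast.

    Returns one row per (probe, replicate M value) in long format with
    columns probe_id, cluster_id, group ("treatment"/"control"), M.
    The implied treatment-vs-treatment log2 ratio of a probe is
    mean(M_treatment) - mean(M_control), exploiting the common
    reference. Raises :class:`ContrastError` when a group has no
    arrays in the design.
    """
    if contrast not in CONTRAST_GROUPS:
        raise ContrastError(f"unknown contrast {contrast!r}")
    (t_pco2, t_light), (c_pco2, c_light) = CONTRAST_GROUPS[contrast]
    d = design.loc[design["stage"] == stage]
    t_arrays = d.loc[(d["pco2_pa"] == t_pco2) & (d["light_umol"] == t_light), "array_id"]
    c_arrays = d.loc[(d["pco2_pa"] == c_pco2) & (d["light_umol"] == c_light), "array_id"]
    if len(t_arrays) == 0 or len(c_arrays) == 0:
        raise ContrastError(
            f"contrast {contrast!r} in stage {stage!r}: a group has no replicates"
        )
    sub = ratios.loc[~ratios["is_control"]]
    t = sub.loc[sub["array_id"].isin(set(t_arrays))].copy()
    t["group"] = "treatment"
    c = sub.loc[sub["array_id"].isin(set(c_arrays))].copy()
    c["group"] = "control"
    out = pd.concat([t, c], ignore_index=True)[
        ["probe_id", "cluster_id", "group", "M"]
    ]
    counts = out.groupby(["probe_id", "group"]).size().unstack(fill_value=0)
    unbalanced = counts.index[
        (counts.get("treatment", 0) != counts.get("control", 0))
    ].tolist() if not counts.empty else []
    out.attrs["unbalanced_probes"] = unbalanced
    return out


def group_m_values(
    ratios: pd.DataFrame, design: pd.DataFrame, stage: str
) -> Tuple[pd.DataFrame, Dict[str, Tuple[float, int]]]:
    """Wide per-probe M matrix for one stage, with group labels per array.

    Returns (matrix, groups) where matrix is indexed by probe_id with
    one column per array of the stage, and groups maps array_id to its
    (pco2, light) treatment cell. Used by the ANOVA caller, which
    needs all four treatment groups of the stage at once for the
    pooled error term.
    """
    d = design.loc[design["stage"] == stage]
    sub = ratios.loc[
        ~ratios["is_control"] & ratios["array_id"].isin(set(d["array_id"]))
    ]
    mat = sub.pivot_table(
        index=["probe_id", "cluster_id"], columns="array_id", values="M", sort=True
    )
    groups = {
        row.array_id: (row.pco2_pa, row.light_umol) for row in d.itertuples()
    }
    return mat, groups
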