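"""Readers and writers for every on-disk table.

All tables are UTF-8 TSV with a header row; absent values are written
as ``"."``. Probe tables are long format (one row per probe per array).
Readers validate formats and cross-row invariants; quality failures are
flagged, never dropped, so downstream stages own all exclusion logic.
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ClusterCall,
    FormatError,
    IntegrityError,
    LIGHT_LEVELS,
    N_REPLICATES,
    PCO2_LEVELS,
    PROBES_PER_CLUSTER,
    STAGES,
)

NA_TOKEN = "."

PROBE_COLUMNS = [
    "array_id",
    "probe_id",
    "cluster_id",
    "is_control",
    "sample_intensity",
    "reference_intensity",
    "qc_ok",
]

DESIGN_COLUMNS = [
    "array_id",
    "stage",
    "pco2_pa",
    "light_umol",
    "replicate",
    "sample_dye",
]

ANNOTATION_COLUMNS = [
    "cluster_id",
    "model_1",
    "evalue_1",
    "model_2",
    "evalue_2",
    "kog_class",
    "description",
]

NORMALIZED_COLUMNS = ["array_id", "probe_id", "cluster_id", "is_control", "M", "A"]

PROBECALL_COLUMNS = [
    "probe_id",
    "cluster_id",
    "stage",
    "contrast",
    "p_value",
    "log2fc",
    "call",
    "testable",
]

CLUSTERCALL_COLUMNS = [
    "cluster_id",
    "stage",
    "contrast",
    "status",
    "direction",
    "n_hit_probes",
    "mean_fold_change",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing required column(s): {', '.join(missing)}")


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False,
    }
    s = series.astype(str).str.strip().str.lower().map(mapping)
    if s.isna().any():
        bad = series[s.isna()].iloc[0]
        raise FormatError(f"column {column!r} contains non-boolean value {bad!r}")
    return s.astype(bool)


# ---------------------------------------------------------------------------
# Probe tables
# ---------------------------------------------------------------------------

def read_probe_table(path) -> pd.DataFrame:
    """Read a long-format probe intensity table.

    Rows with non-positive intensities are retained but flagged
    ``qc_ok = False``. Raises :class:`IntegrityError` on duplicate
    (array_id, probe_id) rows, on a probe mapped to more than one
    cluster, or on a non-control cluster with more than three probes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, PROBE_COLUMNS, f"probe table {path}")
    df = df[PROBE_COLUMNS].copy()
    for col in ("sample_intensity", "reference_intensity"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise FormatError(f"column {col!r} is not numeric: {exc}") from None
    df["is_control"] = _parse_bool(df["is_control"], "is_control")
    df["qc_ok"] = _parse_bool(df["qc_ok"], "qc_ok")

    dup = df.duplicated(subset=["array_id", "probe_id"])
    if dup.any():
        key = df.loc[dup, ["array_id", "probe_id"]].iloc[0].tolist()
        raise IntegrityError(f"duplicate (array_id, probe_id) row: {key}")

    n_clusters = df.groupby("probe_id")["cluster_id"].nunique()
    multi = n_clusters[n_clusters > 1]
    if not multi.empty:
        raise IntegrityError(
            f"probe {multi.index[0]!r} maps to {multi.iloc[0]} different cluster_ids"
        )

    probes_per = (
        df.loc[~df["is_control"]].groupby("cluster_id")["probe_id"].nunique()
    )
    over = probes_per[probes_per > PROBES_PER_CLUSTER]
    if not over.empty:
        raise IntegrityError(
            f"non-control cluster {over.index[0]!r} has {over.iloc[0]} probes "
            f"(at most {PROBES_PER_CLUSTER} allowed)"
        )

    nonpos = (df["sample_intensity"] <= 0) | (df["reference_intensity"] <= 0)
    df.loc[nonpos, "qc_ok"] = False
    return df


def write_probe_table(df: pd.DataFrame, path) -> None:
    out = df[PROBE_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Design tables
# ---------------------------------------------------------------------------

def read_design(path) -> pd.DataFrame:
    """Read and validate an experiment design table.

    Returns the design with a ``.attrs["incomplete_cells"]`` list of the
    (stage, pco2, light) cells holding fewer than three replicates;
    incomplete cells are reported, not fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, DESIGN_COLUMNS, f"design table {path}")
    df = df[DESIGN_COLUMNS].copy()

    bad_stage = ~df["stage"].isin(STAGES)
    if bad_stage.any():
        raise FormatError(f"unknown stage value {df.loc[bad_stage, 'stage'].iloc[0]!r}")
    df["pco2_pa"] = pd.to_numeric(df["pco2_pa"], errors="coerce")
    if not df["pco2_pa"].isin(PCO2_LEVELS).all():
        bad = df.loc[~df["pco2_pa"].isin(PCO2_LEVELS), "pco2_pa"].iloc[0]
        raise FormatError(f"unknown pco2_pa value {bad!r} (expected {PCO2_LEVELS})")
    df["light_umol"] = pd.to_numeric(df["light_umol"], errors="coerce")
    if not df["light_umol"].isin(LIGHT_LEVELS).all():
        bad = df.loc[~df["light_umol"].isin(LIGHT_LEVELS), "light_umol"].iloc[0]
        raise FormatError(f"unknown light_umol value {bad!r} (expected {LIGHT_LEVELS})")
    df["light_umol"] = df["light_umol"].astype(int)
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    if df["replicate"].isna().any() or not df["replicate"].isin([1, 2, 3]).all():
        raise FormatError("replicate must be an integer in 1..3")
    df["replicate"] = df["replicate"].astype(int)
    if not df["sample_dye"].isin(["cy3", "cy5"]).all():
        bad = df.loc[~df["sample_dye"].isin(["cy3", "cy5"]), "sample_dye"].iloc[0]
        raise FormatError(f"unknown sample_dye value {bad!r}")

    key = ["stage", "pco2_pa", "light_umol", "replicate"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise IntegrityError(f"duplicate design row: {df.loc[dup, key].iloc[0].tolist()}")
    if df["array_id"].duplicated().any():
        raise IntegrityError("duplicate array_id in design")

    counts = df.groupby(["stage", "pco2_pa", "light_umol"]).size()
    incomplete = [cell for cell, n in counts.items() if n < N_REPLICATES]
    df.attrs["incomplete_cells"] = incomplete
    return df


def write_design(df: pd.DataFrame, path) -> None:
    df[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------

def read_annotation_table(path) -> pd.DataFrame:
    """Read a cluster annotation table (best two gene models + KOG + text).

    Empty fields (``"."`` or blank) parse as absent (NaN / empty
    string). No e-value filtering happens here. An evalue_1 > evalue_2
    ordering violation raises a warning, not an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ANNOTATION_COLUMNS, f"annotation table {path}")
    df = df[ANNOTATION_COLUMNS].copy()
    for col in ("model_1", "model_2", "kog_class", "description"):
        df[col] = df[col].replace(NA_TOKEN, "")
    for col in ("evalue_1", "evalue_2"):
        raw = df[col].replace({NA_TOKEN: "", "": ""})
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = vals.isna() & (raw != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"malformed e-value {raw.iloc[row]!r} in column {col!r}, data row {row + 1}"
            )
        df[col] = vals
    if df["cluster_id"].duplicated().any():
        raise IntegrityError("duplicate cluster_id in annotation table")
    both = df["evalue_1"].notna() & df["evalue_2"].notna()
    disordered = both & (df["evalue_1"] > df["evalue_2"])
    if disordered.any():
        warnings.warn(
            f"{int(disordered.sum())} annotation row(s) have evalue_1 > evalue_2 "
            "(best-model ordering violated)",
            stacklevel=2,
        )
    same = (
        (df["model_1"] != "") & (df["model_1"] == df["model_2"])
    )
    if same.any():
        warnings.warn(
            f"{int(same.sum())} annotation row(s) list the same model twice",
            stacklevel=2,
        )
    return df


def write_annotation_table(df: pd.DataFrame, path) -> None:
    out = df[ANNOTATION_COLUMNS].copy()
    for col in ("model_1", "model_2", "kog_class", "description"):
        out[col] = out[col].replace("", NA_TOKEN)
    for col in ("evalue_1", "evalue_2"):
        out[col] = out[col].map(lambda v: NA_TOKEN if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Normalized ratios / probe calls / cluster calls
# ---------------------------------------------------------------------------

def write_normalized(df: pd.DataFrame, path) -> None:
    df[NORMALIZED_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_normalized(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"array_id": str, "probe_id": str, "cluster_id": str})
    _require_columns(df, NORMALIZED_COLUMNS, f"normalized table {path}")
    return df[NORMALIZED_COLUMNS]


def write_probe_calls(df: pd.DataFrame, path) -> None:
    df[PROBECALL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_probe_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "cluster_id": str})
    _require_columns(df, PROBECALL_COLUMNS, f"probe-call table {path}")
    return df[PROBECALL_COLUMNS]


def write_cluster_calls(df: pd.DataFrame, path) -> None:
    df[CLUSTERCALL_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cluster_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str})
    _require_columns(df, CLUSTERCALL_COLUMNS, f"cluster-call table {path}")
    return df[CLUSTERCALL_COLUMNS]


# ---------------------------------------------------------------------------
# Simulator truth tables
# ---------------------------------------------------------------------------

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


def write_truth(df: pd.DataFrame, path) -> None:
    df[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str})
    _require_columns(df, TRUTH_COLUMNS, f"truth table {path}")
    for col in ("divergent_probe", "dead_probe"):
        if df[col].dtype != bool:
            df[col] = _parse_bool(df[col], col)
    return df[TRUTH_COLUMNS]


# ---------------------------------------------------------------------------
# Gene lists
# ---------------------------------------------------------------------------

GENELIST_COLUMNS = [
    "cluster_id",
    "contrast",
    "direction",
    "n_hit_probes",
    "mean_fold_change",
    "model_1",
    "evalue_1",
    "model_2",
    "evalue_2",
    "kog_class",
    "description",
    "categories",
]


def write_gene_list(
    calls: Iterable[ClusterCall],
    path,
    annotations: Optional[pd.DataFrame] = None,
    categories: Optional[dict] = None,
) -> pd.DataFrame:
    """Write regulated clusters with hit-probe counts and averaged fold changes.

    ``annotations`` is an (already filtered) annotation table indexed by
    or containing ``cluster_id``; ``categories`` maps cluster_id to a
    list of category tags. Rows are sorted by cluster_id; absent fields
    are written as ``"."``.
    """
    rows = []
    ann = None
    if annotations is not None:
        ann = annotations.set_index("cluster_id") if "cluster_id" in annotations.columns else annotations
    for call in sorted(calls, key=lambda c: (c.cluster_id, c.contrast)):
        row = {
            "cluster_id": call.cluster_id,
            "contrast": call.contrast,
            "direction": call.direction,
            "n_hit_probes": call.n_hit_probes,
            "mean_fold_change": repr(round(float(call.mean_fold_change), 10)),
            "model_1": NA_TOKEN,
            "evalue_1": NA_TOKEN,
            "model_2": NA_TOKEN,
            "evalue_2": NA_TOKEN,
            "kog_class": NA_TOKEN,
            "description": NA_TOKEN,
            "categories": NA_TOKEN,
        }
        if ann is not None and call.cluster_id in ann.index:
            rec = ann.loc[call.cluster_id]
            for col in ("model_1", "model_2", "kog_class", "description"):
                val = rec.get(col, "")
                if isinstance(val, str) and val:
                    row[col] = val
            for col in ("evalue_1", "evalue_2"):
                val = rec.get(col, np.nan)
                if pd.notna(val):
                    row[col] = repr(float(val))
        if categories and call.cluster_id in categories and categories[call.cluster_id]:
            row["categories"] = ",".join(sorted(categories[call.cluster_id]))
        rows.append(row)
    out = pd.DataFrame(rows, columns=GENELIST_COLUMNS)
    out.to_csv(path, sep="\t", index=False)
    return out


def read_gene_list(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, GENELIST_COLUMNS, f"gene list {path}")
    return df


def check_annotation_coverage(
    probe_table: pd.DataFrame, annotation: pd.DataFrame
) -> List[str]:
    """Return non-control cluster_ids in the probe table that lack an annotation row.

    Unmatched clusters are reported, never dropped.
    """
    probe_clusters = set(probe_table.loc[~probe_table["is_control"], "cluster_id"])
    annotated = set(annotation["cluster_id"])
    return sorted(probe_clusters - annotated)
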