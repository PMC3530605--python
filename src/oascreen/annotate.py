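"""Annotation filtering and keyword-based functional categorization.

The annotation table is precomputed (best two gene-model alignments
with e-values, a KOG class and a free-text description per transcript
cluster); this module only applies the screening cutoffs — alignments
with e-value strictly greater than ``evalue_blast`` (default 1e-5) are
discarded, and the free-text/KOG evidence is kept only when supported
at ``evalue_b2g`` (default 1e-6) — and then tags regulated clusters
with the four broad functional categories of interest (carbon
metabolism, light reactions, signaling, inorganic ion fluxes) via a
version-controlled keyword map. The keyword map replaces manual
curation: identical inputs and map give identical counts, and adding a
keyword can only grow the counts.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .datamodel import ConfigError, DirectedGeneSet, PipelineConfig

CATEGORIES = ("carbon_metabolism", "light_reactions", "signaling", "ion_fluxes")


def default_category_map() -> Dict[str, List[str]]:
    """The packaged keyword map (data/categories.yaml)."""
    text = resources.files("oascreen").joinpath("data/categories.yaml").read_text()
    return load_category_map_text(text)


def load_category_map_text(text: str) -> Dict[str, List[str]]:
    raw = yaml.safe_load(text)
    return validate_category_map(raw)


def load_category_map(path) -> Dict[str, List[str]]:
    with open(path, "r", encoding="utf-8") as fh:
        return load_category_map_text(fh.read())


def validate_category_map(raw: Mapping) -> Dict[str, List[str]]:
    if not raw:
        raise ConfigError("empty category map")
    if set(raw) != set(CATEGORIES):
        raise ConfigError(
            f"category map must define exactly {CATEGORIES}, got {sorted(raw)}"
        )
    out = {}
    for cat, kws in raw.items():
        if not kws:
            raise ConfigError(f"category {cat!r} has an empty keyword list")
        out[cat] = [str(k).lower() for k in kws]
    return out


def filter_annotations(records: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Apply the e-value cutoffs to an annotation table.

    Model hits with e-value > ``cfg.evalue_blast`` are blanked. The
    description / KOG evidence is retained only while the best
    surviving model e-value is <= ``cfg.evalue_b2g`` (the table holds
    no separate e-value for the free-text evidence, so the best model
    alignment stands proxy for its support). Clusters with no
    surviving evidence get ``annotated = False`` but stay in the
    table — gene lists report them with ``"."`` fields.
    """
    out = records.copy()
    for m, e in (("model_1", "evalue_1"), ("model_2", "evalue_2")):
        drop = out[e].notna() & (out[e] > cfg.evalue_blast)
        out.loc[drop, m] = ""
        out.loc[drop, e] = np.nan
        absent = out[m] == ""
        out.loc[absent, e] = np.nan
    best = out[["evalue_1", "evalue_2"]].min(axis=1)
    weak_text = best.isna() | (best > cfg.evalue_b2g)
    out.loc[weak_text, "description"] = ""
    out.loc[weak_text, "kog_class"] = ""
    out["annotated"] = (
        (out["model_1"] != "")
        | (out["model_2"] != "")
        | (out["description"] != "")
        | (out["kog_class"] != "")
    )
    return out


def assign_categories(
    clusters: Iterable[str],
    annotations: pd.DataFrame,
    category_map: Optional[Mapping[str, List[str]]] = None,
) -> Dict[str, List[str]]:
    """Tag clusters whose description or KOG class matches a keyword.

    Matching is case-insensitive regex search (plain substrings work
    unchanged); model identifiers are never matched. Returns
    cluster_id -> sorted list of category tags (possibly empty).
    """
    cmap = validate_category_map(category_map) if category_map else default_category_map()
    patterns = {
        cat: [re.compile(kw, re.IGNORECASE) for kw in kws] for cat, kws in cmap.items()
    }
    ann = annotations.set_index("cluster_id") if "cluster_id" in annotations.columns else annotations
    tags: Dict[str, List[str]] = {}
    for cid in clusters:
        found = []
        if cid in ann.index:
            rec = ann.loc[cid]
            text = f"{rec.get('description', '')} {rec.get('kog_class', '')}"
            for cat in CATEGORIES:
                if any(p.search(text) for p in patterns[cat]):
                    found.append(cat)
        tags[cid] = sorted(found)
    return tags


def category_counts(
    sets: Iterable[DirectedGeneSet], tags: Mapping[str, List[str]]
) -> pd.DataFrame:
    """Per-set, per-category up/down counts of categorized clusters.

    A cluster may contribute to several categories (once each) but
    counts once in the per-set ``categorized`` total. Returns a tidy
    frame with one row per (set label, category) plus a ``_total`` row
    per set carrying the categorized-gene total.
    """
    rows = []
    for s in sets:
        categorized = 0
        per_cat = {cat: {"up": 0, "down": 0} for cat in CATEGORIES}
        for cid, direction in s.members.items():
            cats = tags.get(cid, [])
            if cats:
                categorized += 1
            for cat in cats:
                per_cat[cat][direction] += 1
        for cat in CATEGORIES:
            rows.append(
                {
                    "set_label": s.label,
                    "category": cat,
                    "up": per_cat[cat]["up"],
                    "down": per_cat[cat]["down"],
                }
            )
        rows.append(
            {"set_label": s.label, "category": "_total", "up": categorized, "down": 0}
        )
    return pd.DataFrame(rows, columns=["set_label", "category", "up", "down"])
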