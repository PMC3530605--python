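"""End-to-end orchestration: simulate -> normalize -> test -> collapse ->
partition -> annotate, with a reproducible run report.

Every stage writes its intermediate table, so each number in the
report can be recomputed from the files it references; the resolved
configuration (and seed) is echoed into the report for provenance.
The same seed and configuration give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import io as oio
from .annotate import (
    assign_categories,
    category_counts,
    default_category_map,
    filter_annotations,
    load_category_map,
)
from .collapse import collapse_all
from .datamodel import (
    CONTRAST_LABELS,
    ClusterCall,
    ConfigError,
    DirectedGeneSet,
    PipelineConfig,
    SimConfig,
    STAGES,
)
from .diffexp import probe_calls_for_contrast
from .normalize import lowess_correct, ma_transform
from .partition import SET_LABELS, build_set, venn_counts
from .simulate import simulate_experiment, toy_annotation

__all__ = ["run_all", "load_config", "PipelineConfig", "SimConfig"]


def load_config(path) -> Dict[str, object]:
    """Read a YAML run config with optional ``pipeline:`` and ``simulate:`` blocks."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return build_configs(raw)


def build_configs(raw: Dict) -> Dict[str, object]:
    def pick(cls, block):
        names = {f.name for f in dc_fields(cls)}
        unknown = set(block) - names
        if unknown:
            raise ConfigError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
        return cls(**block)

    return {
        "pipeline": pick(PipelineConfig, raw.get("pipeline", {}) or {}),
        "simulate": pick(SimConfig, raw.get("simulate", {}) or {}),
        "categories": raw.get("categories"),
    }


def run_all(
    out_dir,
    pipeline_cfg: Optional[PipelineConfig] = None,
    sim_cfg: Optional[SimConfig] = None,
    probe_table: Optional[str] = None,
    design: Optional[str] = None,
    annotation: Optional[str] = None,
    category_map_path: Optional[str] = None,
    simulate: bool = True,
) -> dict:
    """Run the full chain and return the run report (also written as JSON).

    With ``simulate=True`` (default) a synthetic experiment is
    generated from ``sim_cfg``; otherwise ``probe_table`` and
    ``design`` (and optionally ``annotation``) must point to existing
    TSV files.
    """
    cfg = pipeline_cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if simulate:
        scfg = sim_cfg or SimConfig()
        probes, design_df, truth = simulate_experiment(scfg)
        ann_df = toy_annotation(truth, seed=scfg.seed)
        oio.write_probe_table(probes, out / "probe_table.tsv")
        oio.write_design(design_df, out / "design.tsv")
        oio.write_truth(truth, out / "truth.tsv")
        oio.write_annotation_table(ann_df, out / "annotation.tsv")
    else:
        if probe_table is None or design is None:
            raise ConfigError(
                "run_all without --simulate needs probe_table and design paths"
            )
        for path, stage_name in ((probe_table, "probe table"), (design, "design")):
            if not Path(path).exists():
                raise FileNotFoundError(
                    f"stage normalize: missing {stage_name} file {path}"
                )
        probes = oio.read_probe_table(probe_table)
        design_df = oio.read_design(design)
        ann_df = (
            oio.read_annotation_table(annotation) if annotation else pd.DataFrame(
                columns=oio.ANNOTATION_COLUMNS
            )
        )

    # normalize
    ratios = ma_transform(probes, design_df)
    skipped = ratios.attrs.get("skipped_per_array", {})
    normalized = lowess_correct(
        ratios, span=cfg.loess_span, iterations=cfg.loess_iterations
    )
    oio.write_normalized(normalized, out / "normalized.tsv")

    # per-probe calls, all stages and contrasts
    call_frames = []
    n_untestable = 0
    for stage in STAGES:
        for contrast in CONTRAST_LABELS:
            pc = probe_calls_for_contrast(normalized, design_df, stage, contrast, cfg)
            n_untestable += pc.attrs.get("n_untestable", 0)
            call_frames.append(pc)
    probe_calls = pd.concat(call_frames, ignore_index=True)
    oio.write_probe_calls(probe_calls, out / "probecalls.tsv")

    # collapse
    cluster_calls, tally = collapse_all(probe_calls, cfg)
    oio.write_cluster_calls(cluster_calls, out / "clustercalls.tsv")
    with open(out / "tally.json", "w", encoding="utf-8") as fh:
        json.dump(tally, fh, indent=2, sort_keys=True)

    # partition
    venn = venn_counts(cluster_calls)
    with open(out / "venn_summary.json", "w", encoding="utf-8") as fh:
        json.dump(venn, fh, indent=2, sort_keys=True)

    # annotate + gene lists + category counts
    filtered = filter_annotations(ann_df, cfg) if len(ann_df) else ann_df
    cmap = load_category_map(category_map_path) if category_map_path else default_category_map()
    regulated = cluster_calls.loc[cluster_calls["status"] == "regulated"]
    tags = assign_categories(sorted(set(regulated["cluster_id"])), filtered, cmap) if len(
        filtered
    ) else {}

    sets = []
    genesets_dir = out / "genesets"
    genesets_dir.mkdir(exist_ok=True)
    for stage in STAGES:
        for contrast in CONTRAST_LABELS:
            label = SET_LABELS.get((stage, contrast), f"{stage}:{contrast}")
            s = build_set(cluster_calls, stage, contrast, label)
            sets.append(s)
            calls = [
                ClusterCall(
                    cluster_id=r.cluster_id,
                    contrast=r.contrast,
                    status=r.status,
                    direction=r.direction,
                    n_hit_probes=int(r.n_hit_probes),
                    mean_fold_change=float(r.mean_fold_change),
                )
                for r in regulated.loc[
                    (regulated["stage"] == stage) & (regulated["contrast"] == contrast)
                ].itertuples()
            ]
            oio.write_gene_list(
                calls,
                genesets_dir / f"{stage}_{contrast}.tsv",
                annotations=filtered if len(filtered) else None,
                categories=tags,
            )
    cat_counts = category_counts(sets, tags)
    cat_counts.to_csv(out / "category_counts.tsv", sep="\t", index=False)

    report = {
        "version": __import__("oascreen").__version__,
        "seed": (sim_cfg or SimConfig()).seed if simulate else None,
        "config": {
            "pipeline": cfg.to_dict(),
            "simulate": (sim_cfg or SimConfig()).to_dict() if simulate else None,
        },
        "probes_read": int(len(probes)),
        "probes_skipped_qc": {k: int(v) for k, v in sorted(skipped.items())},
        "probe_tests_untestable": int(n_untestable),
        "cluster_status_tally": tally,
        "venn_counts": venn,
        "category_counts": cat_counts.to_dict(orient="records"),
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
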