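"""End-to-end orchestration: filter -> aggregate -> screen -> test -> summarize.

Stages communicate through files in the output directory so each can be
re-run independently; ``manifest.json`` captures the exact configuration,
input digests, seed and stage counts needed to reproduce a run.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_model import (
    PipelineConfig,
    dump_json,
    read_annotations,
    read_feature_table,
    sha256_of,
    write_enrichment_table,
    write_feature_table,
)
from .feature_filtering import FilterReport, run_filter_cascade
from .subnetwork_enrichment import (
    aggregate_subnetworks,
    detect_treatment_only,
    enrichment_ttests,
    ontology_composition,
    profile_log10,
    rf_screen,
)

__all__ = ["RunManifest", "run_all"]


@dataclass
class RunManifest:
    config: dict
    inputs: dict
    seed: int
    filter_report: dict
    n_subnetworks: int = 0
    n_selected: int = 0
    n_significant: int = 0
    n_enriched_treatment: int = 0
    n_enriched_control: int = 0
    n_treatment_only: int = 0
    stage_seconds: dict = field(default_factory=dict)
    version: str = __version__


def run_all(
    feature_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
    annotations_path: str | Path | None = None,
) -> RunManifest:
    """Run the full exometabolite identification chain and write all outputs.

    Writes ``filtered_features.csv``, ``filter_report.json``,
    ``subnetwork_profiles.csv``, ``enrichment.csv`` (per-subnetwork
    statistics), ``enriched_features.csv`` (the curated per-feature table),
    ``ontology_summary.csv`` and ``manifest.json`` under ``out_dir``.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    matrix, features, samples = read_feature_table(feature_path, metadata_path)
    annotations = None
    if annotations_path is not None and Path(annotations_path).exists():
        annotations = read_annotations(annotations_path)
    elif annotations_path is not None:
        warnings.warn(
            f"annotation file {annotations_path} not found; ontology summary "
            "will report everything unclassified",
            stacklevel=2,
        )
    timings["read"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    filtered, features_kept, report = run_filter_cascade(matrix, features, samples, cfg)
    write_feature_table(filtered, features_kept, out / "filtered_features.csv")
    dump_json(report.to_dict(), out / "filter_report.json")
    timings["filter"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    profiles_raw = aggregate_subnetworks(filtered, features_kept)
    profiles_log = profile_log10(profiles_raw, cfg)
    profiles_raw.to_csv(out / "subnetwork_profiles.csv", float_format="%.12g")
    timings["aggregate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mda, selected = rf_screen(profiles_log, samples, cfg)
    timings["rf_screen"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    results = enrichment_ttests(profiles_log, samples, mda, selected, cfg)
    results = detect_treatment_only(filtered, features_kept, samples, results, cfg)
    results.to_csv(out / "enrichment.csv", float_format="%.12g")
    write_enrichment_table(
        results, features_kept, filtered, samples, annotations,
        out / "enriched_features.csv",
    )
    timings["tests"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    summary = ontology_composition(profiles_raw, samples, results, annotations)
    summary.to_csv(out / "ontology_summary.csv", index=False, float_format="%.12g")
    timings["ontology"] = time.perf_counter() - t0

    inputs = {"features": sha256_of(feature_path), "metadata": sha256_of(metadata_path)}
    if annotations is not None:
        inputs["annotations"] = sha256_of(annotations_path)
    manifest = RunManifest(
        config=cfg.to_dict(),
        inputs=inputs,
        seed=cfg.rng_seed,
        filter_report=report.to_dict(),
        n_subnetworks=len(profiles_raw),
        n_selected=int(results["selected"].sum()),
        n_significant=int((results["direction"] != "none").sum()),
        n_enriched_treatment=int((results["direction"] == "treatment").sum()),
        n_enriched_control=int((results["direction"] == "control").sum()),
        n_treatment_only=int(results["treatment_only"].sum()),
        stage_seconds={k: round(v, 3) for k, v in timings.items()},
    )
    dump_json(manifest, out / "manifest.json")
    dump_json(
        {"seed": cfg.rng_seed, "config": cfg.to_dict(), "version": __version__},
        out / "run_log.json",
    )
    return manifest
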