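"""Configured end-to-end pipeline runs, fixtures, and the run manifest.

Stages execute in method order: (simulate?) -> normalize -> extract -> map
-> enrich (-> track).  Every run writes CSVs for each stage, the figures,
and a JSON manifest recording package version, seeds and all parameters;
re-running the same configuration is bit-identical for all CSV outputs.
Per-stage logging counts the filopodia included and excluded with reasons
(short profile, zero shaft mean, ...), because exclusions would otherwise
be invisible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import PipelineConfig, params_to_yaml
from .enrichment import (classify_localization, plot_enrichment,
                         summarize_enrichment)
from .errors import InsufficientDataError, ShortProfileError
from .imaging import auto_adjust, read_image, write_image
from .mapping import (POICohort, assemble_map, bin_profile, plot_map,
                      summarize_cohort)
from .profiles import (export_profiles, profile_length, read_traces_csv,
                       sample_profile, write_traces_csv)
from .synthetic import (LifetimeMix, NoiseParams, generate_binned_cohort,
                        generate_tip_movie, generate_traces,
                        localization_class, read_movie, render_scene,
                        write_movie)
from .tracking import lifetime_distribution, track_movie

logger = logging.getLogger("filomap")

__all__ = ["run_pipeline", "make_fixtures", "demo_config", "rendered_cohort"]

#: POI classes simulated by a demo/simulation run; the uniform membrane
#: marker doubles as the plasma-membrane reference cohort.
SIMULATED_POIS = {
    "tip_protein": ("tip_enriched", {}),
    "shaft_protein": ("shaft_enriched", {}),
    "subdomain_protein": ("shaft_subdomain", {}),
    "plasma_membrane (CAAX)": ("uniform", {}),
    "cytoplasmic_control": ("absent", {}),
}


def demo_config(output_dir: str = "filomap_demo", seed: int = 0) -> PipelineConfig:
    """A small, self-contained simulation configuration."""
    return PipelineConfig(output_dir=output_dir, simulate=True, seed=seed,
                          n_filopodia_per_class=40)


def rendered_cohort(
    poi_class,
    n: int,
    seed: int,
    poi_name: Optional[str] = None,
    mapping=None,
    normalization=None,
    noise: Optional[NoiseParams] = None,
    image_shape: tuple[int, int] = (1400, 1024),
    per_scene: int = 25,
) -> POICohort:
    """The full image route for one protein: render -> normalize -> bin.

    Renders ``ceil(n / per_scene)`` independent fields of view of
    ``per_scene`` filopodia each, auto-adjusts them, samples the traces and
    bins the POI channel; short profiles are excluded and logged.  This is
    the cohort constructor used by simulation-mode pipeline runs.
    """
    import warnings as _warnings

    noise = NoiseParams() if noise is None else noise
    n_scenes = max(1, int(np.ceil(n / per_scene)))
    profiles, lengths = [], []
    n_short = 0
    for s in range(n_scenes):
        traces = generate_traces(per_scene, seed=seed + 7 * s,
                                 image_shape=image_shape)
        scene = render_scene(traces, poi_class, noise=noise,
                             seed=seed + 7 * s + 3, image_shape=image_shape)
        adjusted = auto_adjust(scene.image, normalization)
        for trace in scene.traces:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                prof = sample_profile(adjusted, trace)
            try:
                binned = bin_profile(prof, "poi", mapping)
            except ShortProfileError:
                n_short += 1
                continue
            profiles.append(binned)
            lengths.append(profile_length(prof))
    name = poi_name or poi_class.name
    if n_short:
        logger.info("POI %s: %d profiles excluded (short)", name, n_short)
    return POICohort(name, profiles[:n] if len(profiles) > n else profiles,
                     lengths_um=lengths[:n] if len(lengths) > n else lengths)


def _image_cohort(config: PipelineConfig, outdir: Path):
    """Normalize a user image, sample its traces, and bin the POI channel."""
    image = read_image(config.image_path)
    traces = read_traces_csv(config.traces_path,
                             pixel_size_um=image.pixel_size_um)
    adjusted = auto_adjust(image, config.normalization)
    write_image(adjusted, outdir / "normalized.tiff")
    profiles, binned, lengths, n_short = [], [], [], 0
    for trace in traces:
        prof = sample_profile(adjusted, trace)
        profiles.append(prof)
        try:
            binned.append(bin_profile(prof, adjusted.channel_names[0],
                                      config.mapping))
            lengths.append(profile_length(prof))
        except ShortProfileError:
            n_short += 1
    export_profiles(profiles, outdir / "profiles.csv", poi_name=config.poi_name)
    if n_short:
        logger.info("%d profiles excluded (short)", n_short)
    return POICohort(config.poi_name, binned, lengths_um=lengths)


def _write_binned(cohorts, path: Path) -> None:
    rows = []
    for cohort in cohorts:
        for b in cohort.profiles:
            for i, v in enumerate(b.bins, start=1):
                rows.append((cohort.poi_name, b.filopodium_id, i, v))
    pd.DataFrame(rows, columns=["poi_name", "filopodium_id", "bin_index", "value"]
                 ).to_csv(path, index=False)


def run_pipeline(config: PipelineConfig, outdir: Optional[str | Path] = None) -> Path:
    """Execute the configured pipeline; returns the run directory.

    In simulation mode a cohort is generated for each entry of
    ``SIMULATED_POIS`` (rendered scenes, normalized, sampled and binned);
    in image mode the configured image/traces pair gives a single cohort.
    Outputs: binned-profile CSV, per-POI summary CSV, map matrix CSV,
    heatmap, enrichment CSVs and boxplot, optional tracking CSVs, and a
    JSON manifest. Any stage error aborts with a stage-labeled message;
    partial outputs are retained.
    """
    config.validate()
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params_to_yaml(config, outdir / "config.yaml")
    stage = "simulate" if config.simulate else "extract"
    try:
        if config.simulate:
            cohorts = [
                rendered_cohort(localization_class(cls, **ov),
                                config.n_filopodia_per_class,
                                seed=config.seed + 1000 * i, poi_name=poi,
                                mapping=config.mapping,
                                normalization=config.normalization)
                for i, (poi, (cls, ov)) in enumerate(SIMULATED_POIS.items())
            ]
        else:
            cohorts = [_image_cohort(config, outdir)]

        stage = "map"
        _write_binned(cohorts, outdir / "binned_profiles.csv")
        summaries = [summarize_cohort(c, config.mapping,
                                      map_positives_only=not config.include_negatives_in_map)
                     for c in cohorts]
        pd.DataFrame([
            dict(poi_name=s.poi_name, n_filopodia=s.n_filopodia,
                 percent_positive=s.percent_positive, category=s.category,
                 median_length_um=float(np.median(s.lengths_um)) if s.lengths_um else np.nan)
            for s in summaries
        ]).to_csv(outdir / "poi_summary.csv", index=False)
        fmap = assemble_map(summaries, eparams=config.enrichment)
        fmap.matrix.to_csv(outdir / "map_matrix.csv")
        plot_map(fmap, config.enrichment, outdir / "heatmap.png")

        stage = "enrich"
        enr = {}
        for cohort in cohorts:
            try:
                enr[cohort.poi_name] = summarize_enrichment(
                    cohort, config.enrichment,
                    positives_only=config.positives_only_ratios,
                    mapping_params=config.mapping)
            except InsufficientDataError as exc:
                logger.info("enrichment skipped for %s: %s", cohort.poi_name, exc)
        ref = enr.get(config.enrichment.reference_poi)
        if ref is not None:
            for name, summary in enr.items():
                classify_localization(summary, ref, config.enrichment)
        ratio_rows = [
            (s.poi_name, i, r)
            for s in enr.values() for i, r in enumerate(s.ratios)
        ]
        pd.DataFrame(ratio_rows, columns=["poi_name", "ratio_index", "ratio"]
                     ).to_csv(outdir / "enrichment_ratios.csv", index=False)
        pd.DataFrame([
            dict(poi_name=s.poi_name, n=len(s.ratios), median=s.stats.median,
                 q1=s.stats.q1, q3=s.stats.q3,
                 whisker_low=s.stats.whisker_low, whisker_high=s.stats.whisker_high,
                 n_outliers=len(s.stats.outliers), n_excluded=s.n_excluded,
                 classification=s.classification, p_value=s.p_value)
            for s in enr.values()
        ]).to_csv(outdir / "enrichment_summary.csv", index=False)
        if enr:
            plot_enrichment(list(enr.values()), outdir / "enrichment_boxplot.png",
                            config.enrichment)

        if config.track:
            stage = "track"
            if config.movie_path:
                stack, meta = read_movie(config.movie_path)
                px = float(meta.get("pixel_size_um", 0.16))
            else:
                stack, _truth = generate_tip_movie(
                    n_spots=12, n_frames=40, drift_um_per_frame=0.1,
                    seed=config.seed + 99)
                px = 0.16
                write_movie(stack, outdir / "movie.tiff", px,
                            config.tracking.frame_interval_s)
            tracks = track_movie(stack, config.tracking, pixel_size_um=px)
            pd.DataFrame([
                dict(track_id=t.track_id, frame=d.frame,
                     x_um=d.x_px * px, y_um=d.y_px * px, quality=d.quality)
                for t in tracks for d in t.detections
            ]).to_csv(outdir / "tracks.csv", index=False)
            table, _summary = lifetime_distribution(tracks, config.tracking)
            table.to_csv(outdir / "lifetime_summary.csv", index=False)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    manifest = {
        "filomap_version": _version,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def make_fixtures(seed: int = 0, outdir: str | Path = "fixtures") -> Path:
    """Write the miniature test dataset: 5 class cohorts x 50 filopodia + 1 movie.

    Profile-level cohorts (binned CSVs) for each localization class and one
    short tip-punctum movie; deterministic for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(["tip_enriched", "shaft_enriched", "shaft_subdomain",
                              "uniform", "absent"]):
        cohort = generate_binned_cohort(50, localization_class(name),
                                        noise_sd=1500.0, seed=seed + i)
        rows = [(cohort.poi_name, b.filopodium_id, j, v)
                for b in cohort.profiles for j, v in enumerate(b.bins, start=1)]
        pd.DataFrame(rows, columns=["poi_name", "filopodium_id", "bin_index", "value"]
                     ).to_csv(outdir / f"cohort_{name}.csv", index=False)
    stack, truth = generate_tip_movie(n_spots=10, n_frames=30, seed=seed + 50)
    write_movie(stack, outdir / "movie.tiff", 0.16, 5.0)
    truth.to_csv(outdir / "movie_truth.csv", index=False)
    return outdir
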