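"""End-to-end orchestration: simulate -> responses -> tuning -> searchlight ->
borders -> report, with every intermediate persisted so each stage can be
rerun (or replaced by user-supplied input) independently.

All randomness flows from one master seed through named child seeds, so the
result tables of a run are byte-identical under an identical configuration.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .exceptions import ParameterError, StageError
from .gradients import GradientReversalDetector
from .phantom import (StimulusSchedule, VolumeSeries, VoxelTuningParams,
                      make_field_layout, make_schedule, simulate_experiment)
from .responses import (estimate_responses, split_run_reliability,
                        voxelwise_activation_test)
from .searchlight import (cluster_threshold, preprocess_timeseries,
                          searchlight_accuracy, sphere_neighborhoods,
                          z_threshold)
from .tuning import TuningSummarizer, accuracy_metric_correlations, \
    compare_best_frequency_maps


@dataclass
class RunConfig:
    """All stage parameters of one reproducible run."""

    seed: int = 0
    # --- phantom ---------------------------------------------------------
    sheet_shape: tuple = (40, 40)
    layout: dict = field(default_factory=dict)
    n_conditions: int = 8
    reps_per_condition: int = 20
    epoch_len: int = 2
    n_dummy: int = 4
    n_runs: int = 2
    f_min: float = 200.0
    f_max: float = 8000.0
    noise_sd: float = 1.0
    jitter_semitones: float = 1.0
    amplitude: float = 2.0
    tuning_fwhm_oct: float = 1.5
    baseline_level: float = 100.0
    n_z: int = 3
    voxel_size_mm: tuple = (1.5, 1.5, 2.5)
    # --- external input (skips simulation when both are set) -------------
    nifti_path: str | None = None
    trial_table_path: str | None = None
    sheet_z: int | None = None
    # --- responses --------------------------------------------------------
    smooth_fwhm_mm: float | None = 2.0
    activation_alpha: float = 0.01
    reliability_resamples: int = 10_000
    # --- searchlight ------------------------------------------------------
    classification_enabled: bool = True
    core_mask_path: str | None = None
    radius_mm: float = 4.0
    classifier: str = "svm"
    svm_C: float = 1.0
    knn_k: int = 1
    n_folds: int = 5
    voxel_p: float = 0.01
    cluster_p: float = 0.05
    n_perm: int = 1000
    lowess_frac: float = 0.5
    # --- tuning -----------------------------------------------------------
    axis: str = "log2"
    fit_roex: bool = True
    # --- borders ----------------------------------------------------------
    orientation_step_deg: float = 1.0
    stability_min: float = 60.0
    reference_axis_deg: float = 0.0
    bf_smooth_sigma: float = 1.0
    border_min_cells: int = 8
    bootstrap_n: int = 2000

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sheet_shape"] = list(self.sheet_shape)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.sheet_shape = tuple(cfg.sheet_shape)
        cfg.voxel_size_mm = tuple(cfg.voxel_size_mm)
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text) or {})
        import json

        return cls.from_dict(json.loads(text))

    def stage_seeds(self) -> dict:
        """Named per-stage seeds derived deterministically from the master."""
        names = ["schedule", "simulate", "reliability", "cluster", "borders"]
        ss = np.random.SeedSequence(self.seed)
        return {n: int(s.generate_state(1)[0] % 2**31)
                for n, s in zip(names, ss.spawn(len(names)))}


@dataclass
class ParcellationReport:
    """Aggregated end-of-run summary; every number traces to a stage file."""

    config: dict
    seeds: dict
    core: dict
    borders: list
    direction_stats: dict | None
    reliability: dict | None
    best_frequency_method_correlation: dict | None
    accuracy_correlations: dict | None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except (ParameterError, StageError):
                raise
            except Exception as e:                   # pragma: no cover
                raise StageError(f"stage '{name}' failed: {e}") from e
        return wrapper
    return deco


@_stage("simulate")
def simulate_stage(cfg: RunConfig, outdir: Path, seeds: dict):
    if cfg.nifti_path and cfg.trial_table_path:
        series = tio.read_experiment(cfg.nifti_path, cfg.trial_table_path)
        series.sheet_z = cfg.sheet_z if cfg.sheet_z is not None else \
            series.data.shape[2] // 2
        return series, None
    layout = make_field_layout(cfg.sheet_shape,
                               dict(cfg.layout, f_lo=cfg.f_min, f_hi=cfg.f_max)
                               if "f_lo" not in cfg.layout else cfg.layout)
    schedule = make_schedule(cfg.n_conditions, cfg.reps_per_condition,
                             cfg.epoch_len, cfg.n_dummy, cfg.n_runs,
                             seeds["schedule"], cfg.f_min, cfg.f_max)
    tuning = VoxelTuningParams(cfg.tuning_fwhm_oct, cfg.amplitude,
                               cfg.baseline_level)
    series = simulate_experiment(layout, tuning, schedule, cfg.noise_sd,
                                 cfg.jitter_semitones, seeds["simulate"],
                                 n_z=cfg.n_z, sheet_z=cfg.sheet_z,
                                 voxel_size_mm=cfg.voxel_size_mm)
    tio.write_volume_series(series, outdir / "series.nii.gz",
                            outdir / "trials.tsv")
    (outdir / "layout.json").write_text(layout.to_json())
    return series, layout


@_stage("responses")
def responses_stage(cfg: RunConfig, outdir: Path, seeds: dict,
                    series: VolumeSeries):
    table = estimate_responses(series, smooth_fwhm_mm=cfg.smooth_fwhm_mm)
    tio.write_response_table(table, outdir / "responses.tsv",
                             outdir / "responses.meta.json")
    act = voxelwise_activation_test(table, cfg.activation_alpha)
    tio.write_map(act.astype(float), series.voxel_size_mm,
                  outdir / "activation_mask.nii.gz")
    reliability = None
    if series.schedule.n_runs >= 2 and series.schedule.n_conditions >= 3:
        runs = [estimate_responses(series, smooth_fwhm_mm=cfg.smooth_fwhm_mm,
                                   run=r) for r in (1, 2)]
        rel = split_run_reliability(runs[0], runs[1],
                                    cfg.reliability_resamples,
                                    seeds["reliability"])
        reliability = {"median_r": rel.median_r, "p_value": rel.p_value,
                       "ranksum_stat": rel.ranksum_stat,
                       "n_excluded": rel.n_excluded,
                       "n_voxels": int(rel.correlations.size)}
        tio.write_json(reliability, outdir / "reliability.json")
    return table, act, reliability


@_stage("tuning")
def tuning_stage(cfg: RunConfig, outdir: Path, table):
    summ = TuningSummarizer(axis=cfg.axis, fit_roex=cfg.fit_roex).fit(table).summary_
    df = summ.to_frame()
    df.to_csv(outdir / "tuning.tsv", sep="\t", index=False)
    method_corr = None
    if cfg.fit_roex:
        try:
            r, p = compare_best_frequency_maps(
                np.log2(summ.centroid_hz()), np.log2(summ.roex_peak_hz))
            method_corr = {"pearson_r": r, "p": p}
        except ParameterError:
            pass
    return summ, method_corr


@_stage("searchlight")
def searchlight_stage(cfg: RunConfig, outdir: Path, seeds: dict,
                      series: VolumeSeries):
    pre = preprocess_timeseries(series, lowess_frac=cfg.lowess_frac)
    nbh = sphere_neighborhoods(series.brain_mask, series.voxel_size_mm,
                               cfg.radius_mm)
    amap = searchlight_accuracy(pre, nbh, classifier=cfg.classifier,
                                C=cfg.svm_C, n_neighbors=cfg.knn_k,
                                n_folds=cfg.n_folds)
    z = amap.z_map()
    core = cluster_threshold(z, z_threshold(cfg.voxel_p), cfg.cluster_p,
                             {"n_perm": cfg.n_perm}, seed=seeds["cluster"])
    tio.write_map(amap.accuracy, series.voxel_size_mm, outdir / "accuracy.nii.gz")
    tio.write_map(z, series.voxel_size_mm, outdir / "zmap.nii.gz")
    tio.write_map(core.mask.astype(float), series.voxel_size_mm,
                  outdir / "core_mask.nii.gz")
    tio.write_json({
        "n_test": amap.n_test, "chance": amap.p0, "classifier": amap.classifier,
        "n_folds": amap.n_folds, "z_star": core.z_star,
        "cluster_size_threshold": core.cluster_size_threshold,
        "achieved_alpha": core.achieved_alpha, "n_perm": core.n_perm,
        "cluster_correction": "Monte-Carlo max-cluster-size null "
                              "(random-field theory not used)",
    }, outdir / "searchlight.json")
    return amap, core


@_stage("borders")
def borders_stage(cfg: RunConfig, outdir: Path, seeds: dict, series,
                  summary, core_mask3d, activation_mask3d=None):
    z = series.sheet_z if series.sheet_z is not None else series.data.shape[2] // 2
    bf_vol = summary.as_volume(np.log2(summary.centroid_hz()))
    bf_sheet = bf_vol[:, :, z]
    core_sheet = np.asarray(core_mask3d, bool)[:, :, z]
    valid_sheet = core_sheet.copy()
    if activation_mask3d is not None:
        # tuning analysis is restricted to voxels with a significant response
        valid_sheet &= np.asarray(activation_mask3d, bool)[:, :, z]
    det = GradientReversalDetector(cfg.orientation_step_deg, cfg.stability_min,
                                   cfg.reference_axis_deg, cfg.bf_smooth_sigma,
                                   cfg.border_min_cells, cfg.bootstrap_n,
                                   seeds["borders"])
    det.fit(np.where(valid_sheet, bf_sheet, np.nan), valid_sheet,
            f_range_hz=(cfg.f_min, cfg.f_max))
    tio.write_map(det.composite_.composite.astype(float),
                  series.voxel_size_mm, outdir / "composite_edges.nii.gz")
    tio.write_map(np.where(core_sheet, bf_sheet, np.nan),
                  series.voxel_size_mm, outdir / "best_frequency.nii.gz")
    borders = [{"n_cells": b.n_cells, "stability_deg": b.stability,
                "frequency_class": b.frequency_class,
                "representative_angle_deg": b.representative_angle,
                "cells": [list(c) for c in b.cells]} for b in det.borders_]
    tio.write_json(borders, outdir / "borders.json")
    ds = det.direction_stats_
    direction = None
    if ds is not None:
        direction = {"mean_deg": ds.mean_deg, "ci95": list(ds.ci95),
                     "hist_counts": [int(c) for c in ds.hist_counts],
                     "bin_edges": [float(e) for e in ds.bin_edges],
                     "n": ds.n, "n_zero_excluded": ds.n_zero_excluded}
        tio.write_json(direction, outdir / "direction_stats.json")
    return borders, direction


def run_pipeline(config: RunConfig, outdir) -> ParcellationReport:
    """Execute all stages in order, persisting every intermediate.

    Identical configuration and seed reproduce the result tables
    byte-identically; any stage failure aborts with a stage-tagged error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    tio.write_json(config.to_dict(), outdir / "config.json")

    series, _layout = simulate_stage(config, outdir, seeds)
    table, act_mask, reliability = responses_stage(config, outdir, seeds, series)
    summary, method_corr = tuning_stage(config, outdir, table)

    acc_corr = None
    if config.classification_enabled:
        amap, core = searchlight_stage(config, outdir, seeds, series)
        core_mask = core.mask
        acc_corr = accuracy_metric_correlations(amap.accuracy, summary, table)
        tio.write_json(acc_corr, outdir / "accuracy_correlations.json")
        core_info = {"n_voxels": int(core.mask.sum()),
                     "z_star": core.z_star,
                     "cluster_size_threshold": core.cluster_size_threshold,
                     "source": "searchlight"}
    elif config.core_mask_path:
        core_arr, _ = tio.read_map(config.core_mask_path)
        core_mask = core_arr.astype(bool)
        core_info = {"n_voxels": int(core_mask.sum()), "source": "user"}
    else:
        core_mask = act_mask
        core_info = {"n_voxels": int(core_mask.sum()), "source": "activation"}
    if core_mask.any():
        from scipy import ndimage

        com = ndimage.center_of_mass(core_mask)
        core_info["centroid_mm"] = [
            float(c * s) for c, s in zip(com, config.voxel_size_mm)]
        core_info["volume_mm3"] = float(
            core_mask.sum() * math.prod(config.voxel_size_mm))

    borders, direction = borders_stage(config, outdir, seeds, series, summary,
                                       core_mask, act_mask)
    report = ParcellationReport(config.to_dict(), seeds, core_info,
                                [{k: v for k, v in b.items() if k != "cells"}
                                 for b in borders],
                                direction, reliability, method_corr, acc_corr)
    tio.write_json(report.to_dict(), outdir / "report.json")
    return report
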