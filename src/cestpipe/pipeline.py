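"""End-to-end orchestration: simulate -> load -> B0-correct -> fit ->
aggregate -> test, plus the Monte-Carlo harnesses used for statistical
calibration and parameter-recovery studies.

All randomness flows from one root seed expanded per subject/study via
``numpy.random.SeedSequence`` spawning, so any subject or study is
independently reproducible and identical configuration + seed yields a
bit-identical statistics table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .b0 import FieldMap, build_field_map
from .fitting import (
    ContrastMaps,
    FitConfig,
    default_fit_config,
    fit_stack,
    fit_voxel,
    pool_auc,
)
from .io import RoiLabelMap, StudyDesign, normalize_stack, read_study, write_study
from .spectra import default_cest_schedule, default_pools
from .stats import (
    aggregate_roi,
    apply_outlier_exclusion,
    summarize,
)
from .synthetic import PhantomConfig, StudyBundle, generate_phantom_study

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "simulate_study",
    "analyze_study",
    "analyze_bundle",
    "run_parameter_recovery",
    "run_null_calibration",
    "run_effect_recovery",
]

_KNOWN_KEYS = {
    "seed", "output_dir", "grid_shape", "n_per_group", "groups", "noise_sd",
    "b0_amplitude_ppm", "effects", "wassr", "fit", "stats", "regions",
    "fit_mode",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; ``examples/pipeline.yaml``
    shows the YAML shape.  Unknown keys are rejected so typos cannot
    silently revert a stage to its defaults."""

    seed: int = 0
    output_dir: str = "cest_run"
    grid_shape: tuple[int, int] = (64, 64)
    n_per_group: int = 4
    groups: tuple[str, ...] = ("vehicle", "ART", "nicotine", "cotreat")
    noise_sd: float = 0.005
    b0_amplitude_ppm: float = 0.1
    # None = phantom's default regional effects; {} = explicit null study
    effects: dict | None = None
    wassr: dict = dc_field(default_factory=lambda: {
        "search_bound_ppm": 0.5, "grid_step_ppm": 0.01})
    fit: dict = dc_field(default_factory=dict)
    stats: dict = dc_field(default_factory=lambda: {
        "outlier_k": 1.5, "welch": False})
    regions: tuple[str, ...] | None = None
    fit_mode: str = "voxel"  # or "roi_spectrum"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update(overrides)
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        if "effects" in raw:
            raw["effects"] = {tuple(k.split("/")): v for k, v in raw["effects"].items()} \
                if isinstance(raw["effects"], dict) else raw["effects"]
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(
            {k: sorted(map(str, v.items())) if isinstance(v, dict) else str(v)
             for k, v in vars(self).items()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def phantom_config(self, seed: int | None = None) -> PhantomConfig:
        kwargs = dict(
            grid_shape=self.grid_shape, groups=self.groups,
            n_per_group=self.n_per_group, noise_sd=self.noise_sd,
            b0_amplitude_ppm=self.b0_amplitude_ppm,
            seed=self.seed if seed is None else seed,
        )
        if self.effects is not None:
            kwargs["effects"] = dict(self.effects)
        return PhantomConfig(**kwargs)

    def fit_config(self, seed: int | None = None) -> FitConfig:
        return default_fit_config(seed=self.seed if seed is None else seed,
                                  **self.fit)


def simulate_study(config: PipelineConfig, out_dir: str | Path | None = None,
                   force: bool = False) -> tuple[StudyBundle, list[Path]]:
    """Generate and write the full synthetic study plus a manifest."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output dir {out} is non-empty; use force=True/--force")
    bundle = generate_phantom_study(config.phantom_config())
    written = write_study(bundle, out)
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_subjects": len(bundle.subjects),
        "files": sorted(p.name for p in written),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return bundle, written + [out / "manifest.json"]


@dataclass
class AnalysisResult:
    field_maps: dict[str, FieldMap]
    contrast_maps: dict[str, ContrastMaps]
    roi_table: pd.DataFrame
    stats_table: pd.DataFrame
    report: dict
    fit_maps: dict = dc_field(default_factory=dict)  # sid -> StackFitResult (voxel mode)


def analyze_study(study_dir: str | Path, config: PipelineConfig) -> AnalysisResult:
    """Run WASSR -> fit -> aggregate -> stats on an on-disk study."""
    subjects, design, label_map, cest_sched, wassr_sched = read_study(study_dir)
    return _analyze(subjects, design, label_map,
                    wassr_sched.offsets_ppm, config)


def analyze_bundle(bundle: StudyBundle, config: PipelineConfig) -> AnalysisResult:
    """In-memory fast path over a freshly generated bundle (no disk IO)."""
    from .io import ZSpectrumStack

    subjects = {}
    for s in bundle.subjects:
        cest = ZSpectrumStack(s.cest, bundle.config.schedule.offsets_ppm,
                              bundle.mask, reference=s.reference)
        wassr = ZSpectrumStack(s.wassr, bundle.config.wassr_schedule.offsets_ppm,
                               bundle.mask, reference=s.reference)
        subjects[s.subject_id] = {"cest": cest, "wassr": wassr}
    design = StudyDesign(pd.DataFrame(bundle.design, columns=["subject_id", "group"]))
    label_map = RoiLabelMap(bundle.labels, bundle.legend)
    return _analyze(subjects, design, label_map,
                    bundle.config.wassr_schedule.offsets_ppm, config)


def _analyze(subjects, design, label_map, wassr_offsets, config: PipelineConfig):
    t0 = time.time()
    if config.regions is not None and "whole_brain" not in config.regions:
        config = PipelineConfig(**{**vars(config),
                                   "regions": tuple(config.regions) + ("whole_brain",)})
    fit_cfg = config.fit_config()
    field_maps: dict[str, FieldMap] = {}
    contrast_maps: dict[str, ContrastMaps] = {}
    fit_maps: dict = {}
    timings = {}
    apply_b0 = config.b0_amplitude_ppm != 0 or config.fit_mode == "voxel"
    for sid, data in subjects.items():
        cest = normalize_stack(data["cest"])
        field_map = None
        if apply_b0:
            wassr = normalize_stack(data["wassr"])
            field_map = build_field_map(
                wassr.signal, wassr_offsets, wassr.mask, **config.wassr)
            field_maps[sid] = field_map
        if config.fit_mode == "roi_spectrum":
            contrast_maps[sid] = _fit_roi_spectra(cest, field_map, label_map, fit_cfg,
                                                  config.regions)
        else:
            fit_maps[sid], contrast_maps[sid] = fit_stack(cest, field_map, fit_cfg)
    timings["fit_s"] = time.time() - t0
    roi_table = aggregate_roi(contrast_maps, label_map, design, regions=config.regions)
    roi_table = apply_outlier_exclusion(roi_table, k=config.stats.get("outlier_k", 1.5))
    stats_table = summarize(roi_table, welch=config.stats.get("welch", False))
    report = {
        "config_hash": config.hash(),
        "n_subjects": len(subjects),
        "n_excluded_rows": int(roi_table["excluded"].sum()),
        "runtime_s": time.time() - t0,
        **timings,
    }
    return AnalysisResult(field_maps, contrast_maps, roi_table, stats_table, report,
                          fit_maps)


def _fit_roi_spectra(cest, field_map, label_map, fit_cfg, regions):
    """ROI-averaged-spectrum mode: B0-correct voxel spectra (if a field
    map is given), average within each region, fit the mean spectrum
    once per region.  The per-pool 'map' holds that region's AUC at its
    voxels so aggregation is shared with the voxelwise path."""
    from .b0 import correct_spectrum

    regions = list(regions) if regions is not None else label_map.region_names
    shape = cest.grid_shape
    names = [p.name for p in fit_cfg.pools]
    auc = {n: np.full(shape, np.nan) for n in names}
    for region in regions:
        if region == "whole_brain":
            continue  # aggregated below from its member voxels
        rmask = label_map.region_mask(region) & cest.mask
        if field_map is not None:
            rmask &= field_map.ok_mask()
        if not rmask.any():
            continue
        if field_map is None:
            mean_spec = cest.signal[rmask].mean(axis=0)
        else:
            specs = [
                correct_spectrum(cest.signal[ij], cest.offsets_ppm,
                                 float(field_map.shift_ppm[ij]))
                for ij in zip(*np.nonzero(rmask))
            ]
            mean_spec = np.nanmean(np.array(specs), axis=0)
        result = fit_voxel(mean_spec, cest.offsets_ppm, fit_cfg)
        if result is None or not result.converged:
            continue
        for n in names:
            auc[n][rmask] = pool_auc(result.pools[n], fit_cfg.auc_convention,
                                     fit_cfg.auc_window_ppm)
    # whole_brain needs no fit of its own: its ROI mean aggregates the
    # member voxels' values, i.e. the voxel-count-weighted mean of the
    # region fits.
    return ContrastMaps(auc, fit_cfg.auc_convention, fit_cfg.auc_window_ppm,
                        fit_cfg.hash())


# ---------------------------------------------------------------------------
# Harnesses


def run_parameter_recovery(
    noise_sds: Sequence[float] = (0.0, 0.002, 0.005, 0.01),
    n_voxels: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Bias/RMSE of recovered pool amplitudes and AUCs versus ground
    truth across seeded noisy spectra, one row per (noise_sd, pool)."""
    from .synthetic import simulate_zspectrum

    schedule = default_cest_schedule()
    pools = default_pools()
    cfg = default_fit_config(seed=seed)
    root = np.random.SeedSequence(seed)
    rows = []
    for noise_sd in noise_sds:
        errs: dict[str, list[float]] = {p.name: [] for p in pools}
        auc_errs: dict[str, list[float]] = {p.name: [] for p in pools}
        for child in root.spawn(n_voxels):
            rng = np.random.default_rng(child)
            z = simulate_zspectrum(pools, schedule, noise_sd=noise_sd, seed=rng)
            res = fit_voxel(z, schedule.offsets_ppm, cfg, rng=rng)
            for p in pools:
                fit_p = res.pools[p.name]
                errs[p.name].append(fit_p.amplitude - p.amplitude)
                auc_errs[p.name].append(pool_auc(fit_p) - pool_auc(p))
        for p in pools:
            e = np.array(errs[p.name])
            ae = np.array(auc_errs[p.name])
            rows.append({
                "noise_sd": noise_sd, "pool": p.name,
                "amp_truth": p.amplitude,
                "amp_bias": float(e.mean()), "amp_rmse": float(np.sqrt((e ** 2).mean())),
                "amp_rel_rmse": float(np.sqrt((e ** 2).mean()) / p.amplitude),
                "auc_bias": float(ae.mean()), "auc_rmse": float(np.sqrt((ae ** 2).mean())),
            })
    return pd.DataFrame(rows)


def _mc_config(grid: int, noise_sd: float, effects: dict) -> PipelineConfig:
    return PipelineConfig(
        grid_shape=(grid, grid), noise_sd=noise_sd, b0_amplitude_ppm=0.0,
        effects=effects, fit_mode="roi_spectrum",
        fit={"multistart_count": 1},
    )


def run_null_calibration(
    n_studies: int = 500,
    seed: int = 0,
    grid: int = 16,
    noise_sd: float = 0.005,
    alpha: float = 0.05,
) -> dict:
    """Type-I error calibration: simulate null studies (all effect
    factors 1.0, n = 4/group), run the full analysis, and count the
    fraction of pairwise tests rejecting at ``alpha``.  Under a
    well-calibrated pipeline this sits near alpha."""
    config = _mc_config(grid, noise_sd, effects={})
    root = np.random.SeedSequence(seed)
    n_reject = n_tests = 0
    for child in root.spawn(n_studies):
        study_seed = int(child.generate_state(1)[0] % (2**31))
        bundle = generate_phantom_study(config.phantom_config(seed=study_seed))
        result = analyze_bundle(bundle, config)
        pcols = [c for c in result.stats_table.columns if c.startswith("p_")]
        pvals = result.stats_table[pcols].to_numpy().ravel()
        pvals = pvals[np.isfinite(pvals)]
        n_tests += pvals.size
        n_reject += int((pvals < alpha).sum())
    return {"rejection_rate": n_reject / max(n_tests, 1),
            "n_tests": n_tests, "n_studies": n_studies}


def run_effect_recovery(
    n_studies: int = 100,
    seed: int = 0,
    grid: int = 16,
    noise_sd: float = 0.005,
    effect: float = 0.7,
    group: str = "ART",
    region: str = "thalamus",
    pool: str = "GLU",
) -> dict:
    """Effect-direction recovery: with a multiplicative amplitude
    deficit in one (group, region, pool), count the fraction of seeded
    studies in which that group's estimated ROI-mean AUC falls below the
    vehicle group's."""
    config = _mc_config(grid, noise_sd, effects={(group, region, pool): effect})
    root = np.random.SeedSequence(seed)
    n_below = 0
    ratios = []
    for child in root.spawn(n_studies):
        study_seed = int(child.generate_state(1)[0] % (2**31))
        bundle = generate_phantom_study(config.phantom_config(seed=study_seed))
        result = analyze_bundle(bundle, config)
        sub = result.roi_table
        sel = (sub["region"] == region) & (sub["pool"] == pool) & ~sub["excluded"]
        mean_g = sub.loc[sel & (sub["group"] == group), "value"].mean()
        mean_v = sub.loc[sel & (sub["group"] == "vehicle"), "value"].mean()
        n_below += mean_g < mean_v
        ratios.append(mean_g / mean_v)
    return {"fraction_below_vehicle": n_below / n_studies,
            "mean_ratio": float(np.mean(ratios)), "n_studies": n_studies}
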