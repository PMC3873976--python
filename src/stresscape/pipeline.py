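"""End-to-end orchestration: synthesize -> covariates -> smooth -> model ->
predict -> summarize.

One configuration object (loadable from YAML) drives the whole analysis.
A master integer seed derives a named substream for every stochastic stage,
so a rerun with the same config and seed produces byte-identical outputs;
the run manifest records effective config, derived seeds, per-stage
row/cell counts, and a checksum for every file written.

The male and female pipelines run independently end-to-end (separate
windows, surfaces, models, predictions) but share one pooled set of class
breaks computed from the combined input marks, so stress classes are
directly comparable between the sexes.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy.stats import ttest_ind

from . import covariates as cov
from . import summarize as summ
from . import synth
from .forest import ForestConfig, stratified_fit
from .raster import ConfigurationError, CovariateStack, GridRaster
from .smoothing import (
    MarkedPointPattern, SmoothingConfig, bootstrap_stability, mcp_window,
    smooth_marks,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one run needs; see docs for field meanings."""

    out_dir: str = "run_out"
    seed: int = 0
    landscape: dict = field(default_factory=dict)     # LandscapeSpec kwargs
    generative: dict = field(default_factory=dict)    # GenerativeModel kwargs
    n_points: int = 300
    smoothing: dict = field(default_factory=dict)     # SmoothingConfig kwargs
    forest: dict = field(default_factory=dict)        # ForestConfig kwargs
    bootstrap_replicates: int = 99
    run_bootstrap: bool = True
    summaries: bool = True
    min_points_per_sex: int = 10
    #: fraction of each extent dimension covered by the central sampling
    #: window; < 1 leaves an unsampled margin for out-of-window prediction
    sampling_fraction: float = 0.65

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _stage_seed(master: int, name: str) -> int:
    """Deterministic per-stage integer seed below 2**31."""
    return (master * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_generative() -> dict:
    # moderate multi-variable signal: elevation/protection raise stress,
    # road influence lowers it, vegetation productivity lowers it
    return {
        "coefficients": {
            "elev": 0.35, "pa": 0.30, "rd_dd": -0.25,
            "dhi_cum": -0.20, "cc": 0.15,
        },
        "intercept": float(np.log(1.2)),
        "noise_sd": 0.35,
    }


def compare_sexes(pattern: MarkedPointPattern) -> dict:
    """Welch two-sided t-tests of male vs female marks, raw and ln scale."""
    if pattern.sex is None:
        return {"skipped": True, "reason": "no sex attribute"}
    sex = np.asarray(pattern.sex)
    m = pattern.marks[sex == "male"]
    f = pattern.marks[sex == "female"]
    if m.size < 2 or f.size < 2:
        return {"skipped": True, "reason": "need >= 2 samples per sex"}
    raw = ttest_ind(m, f, equal_var=False)
    ln = ttest_ind(np.log(m), np.log(f), equal_var=False)
    return {
        "skipped": False,
        "n_male": int(m.size), "n_female": int(f.size),
        "mean_male": float(m.mean()), "mean_female": float(f.mean()),
        "p_raw": float(raw.pvalue), "p_ln": float(ln.pvalue),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": asdict(cfg),
        "stages": [],
        "files": {},
        "seeds": {},
    }

    def finish_stage(name: str, **info) -> None:
        manifest["stages"].append({"name": name, **info})

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    def write_csv(frame: pd.DataFrame, path: Path) -> None:
        frame.to_csv(path, index=False, float_format="%.10g")
        record(path)

    stage = "synthesize"
    try:
        land_kwargs = dict(cfg.landscape)
        land_kwargs.setdefault("seed", _stage_seed(cfg.seed, "landscape"))
        spec = synth.LandscapeSpec(**land_kwargs)
        fields = synth.generate_fields(spec)
        vectors = synth.generate_vectors(spec)
        gen_kwargs = cfg.generative or _default_generative()
        model = synth.GenerativeModel(**gen_kwargs)
        finish_stage(stage, n_field_layers=len(fields),
                     vector_layers=sorted(vectors))
        manifest["seeds"][stage] = land_kwargs["seed"]

        stage = "covariates"
        stack = cov.build_standard_stack(vectors=vectors, fields=fields,
                                         reference_year=spec.reference_year)
        layer_manifest = stack.write_dir(out / "stack")
        for name in stack.names:
            record(out / "stack" / f"{name}.asc")
        record(out / "stack" / "layers.csv")
        for name, records in vectors.items():
            path = out / f"{name}.geojson"
            synth.write_geojson(records, path)
            record(path)
        finish_stage(stage, n_layers=len(stack),
                     layers=sorted(stack.names))

        stage = "sample_points"
        pts_seed = _stage_seed(cfg.seed, "points")
        manifest["seeds"][stage] = pts_seed
        if not 0.0 < cfg.sampling_fraction <= 1.0:
            raise ConfigurationError("sampling_fraction must be in (0, 1]")
        import shapely.affinity
        from shapely.geometry import box as _box

        sampling_window = shapely.affinity.scale(
            _box(*spec.extent), cfg.sampling_fraction, cfg.sampling_fraction
        )
        pattern, truth = synth.generate_hcc_points(
            stack, model, cfg.n_points, window=sampling_window, seed=pts_seed
        )
        pattern.to_dataframe().to_csv(out / "hcc_points.csv", index=False)
        record(out / "hcc_points.csv")
        sex_report = compare_sexes(pattern)
        finish_stage(stage, n_points=pattern.n,
                     generative_r2=truth.generative_r2,
                     sex_comparison=sex_report)

        breaks = summ.ClassBreaks.from_marks(pattern.marks)
        habitat = summ.habitat_mask(stack)
        smoothing_cfg = SmoothingConfig(**cfg.smoothing)
        forest_cfg = ForestConfig(
            **{"seed": _stage_seed(cfg.seed, "forest"), **cfg.forest}
        )
        manifest["seeds"]["forest"] = forest_cfg.seed
        manifest["class_breaks"] = {"q1": breaks.q1, "q3": breaks.q3}

        sexes = ("male", "female")
        unit_tables = {}
        for sex in sexes:
            sel = np.asarray(pattern.sex) == sex
            if sel.sum() < cfg.min_points_per_sex:
                finish_stage(f"smooth_{sex}", skipped=True,
                             reason=f"only {int(sel.sum())} points")
                continue
            sub = pattern.subset(np.flatnonzero(sel))

            stage = f"smooth_{sex}"
            window = mcp_window(sub)
            surface = smooth_marks(sub, window, smoothing_cfg,
                                   template=stack.template)
            surface.raster.to_ascii(out / f"hcc_smooth_{sex}.asc")
            record(out / f"hcc_smooth_{sex}.asc")
            info = {"n_points": sub.n,
                    "n_cells": int(surface.raster.valid_mask().sum()),
                    "empty_cells": surface.empty_cell_count}
            if cfg.run_bootstrap:
                boot_seed = _stage_seed(cfg.seed, f"bootstrap_{sex}")
                manifest["seeds"][f"bootstrap_{sex}"] = boot_seed
                report, _ = bootstrap_stability(
                    sub, window, smoothing_cfg,
                    n_replicates=cfg.bootstrap_replicates, seed=boot_seed,
                )
                info.update(
                    stable_proportion=report.stable_proportion,
                    ks_p=report.ks_p, mwu_p=report.mwu_p,
                    n_replicates=report.n_replicates,
                )
            finish_stage(stage, **info)

            stage = f"model_{sex}"
            models = stratified_fit(
                surface, stack, vectors.get("parks", []), forest_cfg,
                importance_seed=_stage_seed(cfg.seed, f"importance_{sex}"),
            )
            model_info = {}
            for stratum, res in models.items():
                fm = res["model"]
                write_csv(res["importance"],
                          out / f"importance_{sex}_{stratum}.csv")
                model_info[stratum] = {
                    "n_rows": res["table"].n,
                    "oob_var_explained": fm.oob_var_explained,
                    "oob_mse": fm.oob_mse,
                    "validation_r2": fm.validation_r2,
                    "effective_mtry": fm.effective_mtry,
                }
            finish_stage(stage, models=model_info)

            stage = f"predict_{sex}"
            total_model = models["total"]["model"]
            pred = summ.predict_surface(
                total_model, stack,
                exclusion=[{"geometry": window.polygon}],
                habitat=habitat,
            )
            classified = summ.classify_surface(pred, breaks)
            pred.to_ascii(out / f"hcc_pred_{sex}.asc")
            classified.to_ascii(out / f"hcc_class_{sex}.asc")
            record(out / f"hcc_pred_{sex}.asc")
            record(out / f"hcc_class_{sex}.asc")
            pvals = pred.values[pred.valid_mask()]
            finish_stage(stage, n_cells=int(pvals.size),
                         mean_pred=float(pvals.mean()) if pvals.size else None)

            if cfg.summaries:
                stage = f"summarize_{sex}"
                profile = summ.covariate_profile(pred, stack, breaks)
                write_csv(profile, out / f"covariate_profile_{sex}.csv")
                zones = vectors.get("conservation", [])
                states = vectors.get("habitat_state", [])
                if zones:
                    ut = summ.unit_area_table(classified, zones)
                    unit_tables[sex] = ut
                    write_csv(ut, out / f"unit_area_{sex}.csv")
                    zf = summ.zone_frequency(pred, zones, bins=20)
                    write_csv(zf, out / f"zone_frequency_{sex}.csv")
                if states:
                    sf = summ.zone_frequency(pred, states, bins=20)
                    write_csv(sf, out / f"state_frequency_{sex}.csv")
                finish_stage(stage, tables_written=True)
            else:
                finish_stage(f"summarize_{sex}", skipped=True,
                             reason="summaries disabled in config")
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
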