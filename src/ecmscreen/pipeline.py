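"""End-to-end pipeline: synthesize -> segment -> register -> fit -> IC50 -> stats.

A YAML config (validated with pydantic before any work starts) drives the
stages in dependency order. Every stage writes its artifact plus a SHA256
checksum into a run manifest that records the seed and the config hash,
so a rerun with the same config is bit-identical for deterministic stages
and seed-identical for stochastic ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import synth
from .dose_response import build_curve, ic50_log_interp
from .kinetics import FitConfig, fit_exponential
from .registration import register_cells, registration_summary
from .segmentation import SegmentationParams, mask_iou, sweep_segmentation
from .stats import HierarchicalModelSpec, fit_hierarchical_growth_model, sign_test_two_sided

log = logging.getLogger("ecmscreen.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "demo_config"]


class SceneConfig(BaseModel):
    image_shape: tuple[int, int] = (512, 512)
    disc_center: tuple[float, float] = (256.0, 256.0)
    disc_radius: float = 150.0
    n_cells_on: int = 150
    n_cells_off: int = 60


class GrowthConfig(BaseModel):
    n0: float = 1500.0
    rate: float = 0.03
    times: list[float] = Field(default_factory=lambda: [0, 12, 24, 36, 48, 60, 72])
    noise_cv: float = 0.05


class DoseResponseConfig(BaseModel):
    doses: list[float] = Field(default_factory=lambda: list(synth.DEFAULT_DOSES_UM))
    hill_ic50: float = 0.32
    hill_slope: float = 1.0


class SegmentationGridConfig(BaseModel):
    std_kernels: list[int] = Field(default_factory=lambda: [5, 7, 9])
    struct_sizes: list[int] = Field(default_factory=lambda: [5, 7])
    texture_threshold: float = 60.0
    candidate_threshold: float = 120.0
    circularity_weight: float = 1.0


class EffectsConfig(BaseModel):
    n_experiments: int = 4
    n_replicates: int = 3
    contrast: tuple[str, str, str] = ("plate", "Softwell 2 kPa", "Softwell 0.2 kPa")
    chains: int = 2
    warmup: int = 400
    draws: int = 600


class PipelineConfig(BaseModel):
    seed: int = 0
    outdir: Path = Path("ecmscreen_run")
    scene: SceneConfig | None = SceneConfig()
    growth: GrowthConfig = GrowthConfig()
    dose_response: DoseResponseConfig | None = DoseResponseConfig()
    segmentation: SegmentationGridConfig = SegmentationGridConfig()
    effects: EffectsConfig | None = EffectsConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def demo_config(outdir: str | Path = "ecmscreen_demo", seed: int = 0) -> PipelineConfig:
    """A small end-to-end configuration that runs in well under a minute."""
    cfg = PipelineConfig(seed=seed, outdir=Path(outdir))
    cfg.effects = EffectsConfig(n_experiments=3, n_replicates=2, chains=2, warmup=300, draws=400)
    return cfg


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all configured stages and return the run manifest.

    Stage outputs are pure functions of (inputs, config, seed). Any stage
    failure halts the run with the stage name; the manifest written so
    far is preserved under ``manifest.json`` in the output directory.
    """
    outdir = Path(config.outdir)
    if not outdir.exists():
        log.info("creating output directory %s", outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json()
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {},
    }
    manifest_path = outdir / "manifest.json"

    def record(stage: str, artifacts: dict[str, Path], extra: dict | None = None) -> None:
        manifest["stages"][stage] = {
            "artifacts": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in artifacts.items()},
            **(extra or {}),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    stage = "init"
    try:
        if config.scene is not None:
            stage = "synthesize-scene"
            scene = synth.gen_well_scene(
                synth.DiscSceneParams(
                    image_shape=tuple(config.scene.image_shape),
                    disc_center=tuple(config.scene.disc_center),
                    disc_radius=config.scene.disc_radius,
                    n_cells_on=config.scene.n_cells_on,
                    n_cells_off=config.scene.n_cells_off,
                    seed=config.seed,
                )
            )
            paths = synth.write_scene(scene, outdir, stem="scene")
            record(stage, paths)

            stage = "segment"
            g = config.segmentation
            grid = [
                SegmentationParams(
                    std_kernel=k,
                    struct_size=s,
                    texture_threshold=g.texture_threshold,
                    candidate_threshold=g.candidate_threshold,
                )
                for k in g.std_kernels
                for s in g.struct_sizes
            ]
            expected_area = float(np.pi * config.scene.disc_radius**2)
            best, ranked = sweep_segmentation(
                scene.image, scene.profile, grid, expected_area, g.circularity_weight
            )
            import imageio.v3 as iio

            mask_path = outdir / "mask.png"
            iio.imwrite(mask_path, (best.mask.astype(np.uint8) * 255))
            report = {
                "score": best.score,
                "area_px": best.area,
                "circularity": best.circularity(),
                "iou_vs_truth": mask_iou(best.mask, scene.mask),
                "n_grid": len(grid),
            }
            report_path = outdir / "segmentation.json"
            report_path.write_text(json.dumps(report, indent=2))
            record(stage, {"mask": mask_path, "report": report_path}, report)

            stage = "register"
            reg = register_cells(scene.cells.drop(columns=["on_disc"]), best)
            reg_path = outdir / "registered.csv"
            reg.to_csv(reg_path, index=False)
            summary_path = outdir / "registration_summary.json"
            summary_path.write_text(
                registration_summary(reg).to_json(orient="records", indent=2)
            )
            record(stage, {"registered": reg_path, "summary": summary_path})

        stage = "fit-growth"
        doses_cfg = config.dose_response
        growth = synth.GrowthParams(
            n0=config.growth.n0,
            rate=config.growth.rate,
            times=config.growth.times,
            noise_cv=config.growth.noise_cv,
            seed=config.seed,
        )
        if doses_cfg is not None:
            curves = synth.gen_dose_response(
                growth, doses_cfg.doses, doses_cfg.hill_ic50, doses_cfg.hill_slope
            )
        else:
            curves = {0.0: synth.gen_growth_counts(growth)}
        fits = {d: fit_exponential(c, FitConfig()) for d, c in curves.items()}
        fits_path = outdir / "growth_fits.csv"
        pd.DataFrame(
            [
                {"dose_uM": d, "n0_hat": f.n0_hat, "rate_hat": f.rate_hat,
                 "rate_se": f.rate_se, "rss": f.rss, "converged": f.converged}
                for d, f in sorted(fits.items())
            ]
        ).to_csv(fits_path, index=False)
        record(stage, {"fits": fits_path})

        if doses_cfg is not None:
            stage = "ic50"
            curve = build_curve(fits)
            est = ic50_log_interp(curve)
            ic50_path = outdir / "ic50.json"
            ic50_path.write_text(
                json.dumps({"ic50_uM": est.value, "censored": est.censored,
                            "true_ic50_uM": doses_cfg.hill_ic50}, indent=2)
            )
            record(stage, {"ic50": ic50_path})

        if config.effects is not None:
            stage = "stats"
            e = config.effects
            table, truth = synth.gen_effects_table(
                synth.EffectsTableSpec(
                    n_experiments=e.n_experiments, n_replicates=e.n_replicates, seed=config.seed
                )
            )
            table_path = outdir / "rates.csv"
            table.to_csv(table_path, index=False)
            post = fit_hierarchical_growth_model(
                table,
                HierarchicalModelSpec(
                    contrasts=(tuple(e.contrast),),
                    chains=e.chains, warmup=e.warmup, draws=e.draws, seed=config.seed,
                ),
            )
            # sign test on experiment-mean differences across ordered plate stiffness
            piv = table.groupby(["experiment", "plate"])["rate"].mean().unstack()
            deltas = (piv["Softwell 2 kPa"] - piv["Softwell 0.2 kPa"]).tolist()
            st = sign_test_two_sided(deltas)
            stats_path = outdir / "stats.json"
            stats_path.write_text(
                json.dumps(
                    {
                        "posterior": json.loads(post.summary.to_json(orient="index")),
                        "converged": post.converged,
                        "sign_test": {"n": st.n, "k": st.k, "p": st.p_two_sided},
                        "true_contrast": truth["plate_effects"]["Softwell 2 kPa"]
                        - truth["plate_effects"]["Softwell 0.2 kPa"],
                    },
                    indent=2,
                )
            )
            record(stage, {"stats": stats_path})
    except Exception as err:  # halt with the stage name, keep partial manifest
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
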