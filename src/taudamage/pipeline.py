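"""End-to-end orchestration: generate -> quantify -> fit -> evaluate -> fatigue.

A :class:`PipelineConfig` (YAML-loadable) names the stages to run, the
input/output paths, the constants preset and the seeds.  ``run_pipeline``
executes the enabled stages in order, writes every stage artifact as CSV or
JSON/YAML under ``out_dir`` plus a deterministic ``manifest.json`` (package
version, seeds, config hash, output listing), and aborts on any stage error
with the stage name attached.  Identical config and seed give bit-identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fatigue import ExposureProfile, StrainLifeModel, stage_curve_points
from .fitting import DamageProgressionModel, STAGE_YEARS_OF_PLAY
from .histology import SliceImage, ThresholdConfig, quantify_slice, write_observations_csv
from .isv import evaluate_trajectory
from .params import get_preset
from .synthetic import example_g_level_proportions, generate_slice_mask, \
    generate_trajectory, stage_fixture_spec

log = logging.getLogger("taudamage.pipeline")

STAGES = ("generate", "quantify", "fit", "evaluate", "fatigue")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (all stages optional)."""

    out_dir: str
    stages: tuple = STAGES
    seed: int = 0
    preset: str = "section31_text"
    units: str = "cm2"
    # generate
    n_trajectory_points: int = 76
    t_max: float = 1.0
    noise_cv: float = 0.0
    # quantify
    masks_dir: str | None = None       # defaults to the generated masks
    pixel_scale: float = 0.1           # cm/px, used for externally supplied masks
    threshold_method: str = "otsu"
    connectivity: int = 8
    # fit
    observations_csv: str | None = None  # defaults to the generated trajectory
    loss: str = "log_linear_ols"
    # fatigue
    exposure_csv: str | None = None    # defaults to the synthetic illustration
    position: str = "lineman"
    annual_impacts: int = 10128
    strain_life_points_csv: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.units not in ("cm2", "mm2"):
            raise ValueError("units must be 'cm2' or 'mm2'")
        get_preset(self.preset)  # fail fast on bad preset names

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in cfg:
            cfg["stages"] = tuple(cfg["stages"])
        return cls(**cfg)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d


def demo_config(out_dir: str | Path, seed: int = 0) -> PipelineConfig:
    """The bundled synthetic demonstration: noiseless end-to-end run whose
    fitted constants equal the generating preset."""
    return PipelineConfig(out_dir=str(out_dir), seed=seed, noise_cv=0.0)


def _validate_inputs(config: PipelineConfig) -> None:
    """Check every referenced path before any computation."""
    for stage, path in (("quantify", config.masks_dir),
                        ("fit", config.observations_csv),
                        ("fatigue", config.exposure_csv),
                        ("fatigue", config.strain_life_points_csv)):
        if stage in config.stages and path is not None and not Path(path).exists():
            raise PipelineError(f"stage {stage!r}: input path {path!r} does not exist")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in canonical order and return the run report."""
    _validate_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    report: dict = {"stages_run": []}

    def emit(path: Path) -> Path:
        outputs.append(str(path.relative_to(out)))
        return path

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            if stage == "generate":
                _stage_generate(config, out, emit)
            elif stage == "quantify":
                report["observations"] = _stage_quantify(config, out, emit)
            elif stage == "fit":
                report["fit"] = _stage_fit(config, out, emit)
            elif stage == "evaluate":
                report["trajectory_csv"] = _stage_evaluate(config, out, emit, report)
            elif stage == "fatigue":
                report["fatigue"] = _stage_fatigue(config, out, emit, report)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        report["stages_run"].append(stage)
        log.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

    cfg_dict = config.to_dict()
    manifest = {
        "package": "taudamage",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["manifest"] = str(out / "manifest.json")
    return report


def _stage_generate(config: PipelineConfig, out: Path, emit) -> None:
    masks_dir = out / "masks"
    masks_dir.mkdir(exist_ok=True)
    gt_rows = []
    for stage_lv in (1, 2, 3, 4):
        spec = stage_fixture_spec(stage_lv, seed=config.seed + stage_lv)
        img, gt = generate_slice_mask(spec)
        from .histology import DamageMask

        DamageMask(gt.mask, spec.pixel_scale).save(emit(masks_dir / f"stage{stage_lv}.png"))
        gt_rows.append({"stage": stage_lv, "n_regions": gt.n_regions,
                        "area_fraction": gt.area_fraction,
                        "total_damaged_area_cm2": gt.total_damaged_area_cm2,
                        "pairwise_min_nnd_cm": gt.pairwise_min_nnd})
    pd.DataFrame(gt_rows).to_csv(emit(out / "ground_truth.csv"), index=False)

    params = get_preset(config.preset)
    times = np.linspace(0.0, config.t_max, config.n_trajectory_points)
    obs = generate_trajectory(params, times, noise_cv=config.noise_cv, seed=config.seed)
    df = pd.DataFrame({"time": [o.time for o in obs],
                       "eta": [o.nucleation_density for o in obs],
                       "v": [o.damaged_area for o in obs],
                       "nnd": [o.nnd for o in obs],
                       "phi": [o.damage_fraction / 100.0 for o in obs]})
    df.to_csv(emit(out / "synthetic_observations.csv"), index=False)


def _stage_quantify(config: PipelineConfig, out: Path, emit) -> str:
    masks_dir = Path(config.masks_dir) if config.masks_dir else out / "masks"
    if not masks_dir.is_dir():
        raise PipelineError(f"stage 'quantify': masks directory {masks_dir} not found "
                            "(run 'generate' first or set masks_dir)")
    paths = sorted(masks_dir.glob("*.png")) + sorted(masks_dir.glob("*.tif*"))
    if not paths:
        raise PipelineError(f"stage 'quantify': no PNG/TIFF masks under {masks_dir}")
    tc = ThresholdConfig(method=config.threshold_method,
                         fixed_value=127.5 if config.threshold_method == "fixed" else None)
    observations = [quantify_slice(SliceImage.from_file(p, config.pixel_scale, p.stem),
                                   tc, config.connectivity)
                    for p in paths]
    csv_path = emit(out / "observations.csv")
    write_observations_csv(observations, csv_path, area_units=config.units)
    return str(csv_path)


def _stage_fit(config: PipelineConfig, out: Path, emit) -> dict:
    src = Path(config.observations_csv) if config.observations_csv \
        else out / "synthetic_observations.csv"
    if not src.exists():
        raise PipelineError(f"stage 'fit': observations file {src} not found")
    model = DamageProgressionModel.from_csv(src, loss=config.loss,
                                            coalescence_source=config.preset)
    results = model.fit()
    results.params.to_yaml(emit(out / "fitted_params.yaml"))
    (emit(out / "fit_report.json")).write_text(
        json.dumps(results.to_report(), indent=2, sort_keys=True))
    return results.to_report()


def _stage_evaluate(config: PipelineConfig, out: Path, emit, report: dict) -> str:
    fitted = out / "fitted_params.yaml"
    if fitted.exists():
        from .params import ISVParams

        params = ISVParams.from_yaml(fitted)
    else:
        params = get_preset(config.preset)
    times = np.linspace(0.0, config.t_max, max(config.n_trajectory_points, 2))
    traj = evaluate_trajectory(times, params)
    path = emit(out / "trajectory.csv")
    traj.to_csv(path)
    return str(path)


def _stage_fatigue(config: PipelineConfig, out: Path, emit, report: dict) -> dict:
    if config.exposure_csv:
        profile = ExposureProfile.from_csv(config.exposure_csv, position=config.position)
    else:
        profile = ExposureProfile.from_proportions(
            config.position, config.annual_impacts, example_g_level_proportions())
    profile.to_frame().to_csv(emit(out / "exposure_bins.csv"), index=False)

    # damage level per stage: evaluate phi at years-of-play normalized by stage 4
    params = get_preset(config.preset)
    years = [STAGE_YEARS_OF_PLAY[k] for k in (1, 2, 3, 4)]
    t_norm = np.array(years, dtype=float) / max(years)
    phi = evaluate_trajectory(t_norm, params).phi
    points = stage_curve_points(profile, phi)
    points.to_csv(emit(out / "stage_points.csv"), index=False)

    result: dict = {"profile": {"position": profile.position,
                                "annual_impacts": profile.annual_impacts}}
    if config.strain_life_points_csv:
        pts = pd.read_csv(config.strain_life_points_csv)[["reversals", "amplitude"]].to_numpy()
        curve = StrainLifeModel(pts).fit()
        (emit(out / "strain_life.json")).write_text(
            json.dumps(curve.to_dict(), indent=2, sort_keys=True))
        result["strain_life"] = curve.to_dict()
    return result
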