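"""End-to-end orchestration: generate -> calibrate -> ROI -> preprocess ->
fit/compare -> map -> texture -> correlate, configured and seeded.

A single global seed fans out to per-stage seeds through a stable hash of the
stage name, so each stage is independently reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .chemometrics import RegressionModel, SplitSpec, model_comparison_table, predict
from .io import Hypercube, ROISelection, calibrate_reflectance, extract_roi, mean_spectrum, write_envi
from .mapping import DistributionMap, predict_pixelwise, render_pseudocolor, shared_scale
from .preprocess import PreprocessSpec
from .synthetic import GeneratorConfig
from .texture import DEFAULT_LEVELS, map_contrast, spearman_matrix

log = logging.getLogger(__name__)

ANALYTE_COLUMNS = {"mc": "mc", "rs": "rs_mg_per_g", "chewiness": "chewiness_N"}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one via a stable hash."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    roi: ROISelection = field(default_factory=lambda: ROISelection(height=48, width=48))
    preprocess: list = field(
        default_factory=lambda: [
            PreprocessSpec(method="SG"),
            PreprocessSpec(method="GF"),
            PreprocessSpec(method="N"),
        ]
    )
    models: tuple = ("PLSR", "PCR")
    split: SplitSpec = field(default_factory=SplitSpec)
    glcm_levels: int = DEFAULT_LEVELS
    max_components: int = 15
    colormap: str = "jet"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.preprocess:
            raise ValueError("need at least one preprocess candidate")
        if not self.models:
            raise ValueError("need at least one model kind")
        for kind in self.models:
            if kind not in ("PLSR", "PCR"):
                raise ValueError(f"unknown model kind {kind!r}")
        if self.roi.height > self.generator.n_rows or self.roi.width > self.generator.n_cols:
            raise ValueError(
                f"ROI {self.roi.height}x{self.roi.width} exceeds scene "
                f"{self.generator.n_rows}x{self.generator.n_cols}"
            )

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "roi": {
                "height": self.roi.height,
                "width": self.roi.width,
                "placement": self.roi.placement,
                "row_start": self.roi.row_start,
                "col_start": self.roi.col_start,
            },
            "preprocess": [p.to_dict() for p in self.preprocess],
            "models": list(self.models),
            "split": {
                "method": self.split.method,
                "cal_fraction": self.split.cal_fraction,
                "seed": self.split.seed,
                "cv_folds": self.split.cv_folds,
                "leave_one_out": self.split.leave_one_out,
            },
            "glcm_levels": self.glcm_levels,
            "max_components": self.max_components,
            "colormap": self.colormap,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {
            "generator", "roi", "preprocess", "models", "split",
            "glcm_levels", "max_components", "colormap", "seed",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "generator" in d:
            kwargs["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "roi" in d:
            kwargs["roi"] = ROISelection(**d["roi"])
        if "preprocess" in d:
            kwargs["preprocess"] = [PreprocessSpec.from_dict(p) for p in d["preprocess"]]
        if "models" in d:
            kwargs["models"] = tuple(d["models"])
        if "split" in d:
            kwargs["split"] = SplitSpec(**d["split"])
        for key in ("glcm_levels", "max_components", "colormap", "seed"):
            if key in d:
                kwargs[key] = d[key]
        return cls(**kwargs)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default, and cross-validate a YAML/JSON pipeline config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    cfg = PipelineConfig.from_dict(raw)
    log.info("effective config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Dataset assembly (generate + calibrate + ROI + mean spectrum)
# ---------------------------------------------------------------------------

def build_dataset(
    cfg: PipelineConfig, records: list | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean ROI reflectance spectrum per sample, via the full acquisition chain.

    Each scene is generated, black/white calibrated, cropped to the ROI and
    averaged — the cube itself is discarded to keep memory flat.
    """
    gen = replace(cfg.generator, seed=stage_seed(cfg.seed, "generate"))
    records = records if records is not None else synthetic.make_sample_table(gen)
    endmembers = synthetic.make_endmembers(synthetic.make_wavelength_grid(gen))
    spectra = np.empty((len(records), gen.n_bands))
    for i, rec in enumerate(records):
        scene = synthetic.make_scene_for_record(gen, rec, endmembers=endmembers)
        refl = calibrate_reflectance(scene.raw_cube, scene.dark_frame, scene.white_frame)
        spectra[i] = mean_spectrum(extract_roi(refl, cfg.roi))
    table = synthetic.sample_table_to_frame(records)
    return table, spectra


def fit_models(cfg: PipelineConfig, table: pd.DataFrame, spectra: np.ndarray):
    """Cross pretreatments x model kinds x analytes; return (table, best models)."""
    labels = {a: table[col].to_numpy() for a, col in ANALYTE_COLUMNS.items()}
    split = replace(cfg.split, seed=stage_seed(cfg.seed, "split"))
    comparison = model_comparison_table(
        spectra,
        labels,
        preprocess_specs=list(cfg.preprocess),
        model_kinds=tuple(cfg.models),
        split=split,
        max_k=cfg.max_components,
    )
    best_models: dict[str, RegressionModel] = {}
    for analyte in labels:
        row = comparison[(comparison["analyte"] == analyte) & comparison["best"]].iloc[0]
        pp = next(p for p in cfg.preprocess if p.tag == row["preprocess"])
        from .chemometrics import evaluate_model

        model, _ = evaluate_model(
            spectra,
            labels[analyte],
            row["model"],
            pp,
            split=split,
            n_components=int(row["n_components"]),
            analyte=analyte,
        )
        best_models[analyte] = model
    return comparison, best_models


def compute_maps_and_contrast(
    cfg: PipelineConfig,
    records: list,
    best_models: dict[str, RegressionModel],
    keep_for: set[tuple[str, float]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Pixel-wise maps for every sample; per-sample 4-direction GLCM contrast.

    Maps of representative samples (first panelist/replicate per bread x time,
    or the ``keep_for`` cells) are retained for rendering; contrast is
    computed on a per-analyte shared quantization range so uniformity is
    comparable across chew times.
    """
    gen = replace(cfg.generator, seed=stage_seed(cfg.seed, "generate"))
    endmembers = synthetic.make_endmembers(synthetic.make_wavelength_grid(gen))
    maps: dict[str, list[DistributionMap]] = {a: [] for a in best_models}
    rows = []
    kept: dict[tuple[str, float, str], DistributionMap] = {}
    for rec in records:
        scene = synthetic.make_scene_for_record(gen, rec, endmembers=endmembers)
        refl = calibrate_reflectance(scene.raw_cube, scene.dark_frame, scene.white_frame)
        roi_cube = extract_roi(refl, cfg.roi)
        row = {"sample_id": rec.sample_id}
        for analyte, model in best_models.items():
            dmap = predict_pixelwise(roi_cube, model)
            maps[analyte].append(dmap)
            if keep_for is None:
                keep = rec.panelist == 0 and rec.replicate == 0
            else:
                keep = (rec.bread_type, rec.chew_time) in keep_for
            if keep and (rec.bread_type, rec.chew_time, analyte) not in kept:
                kept[(rec.bread_type, rec.chew_time, analyte)] = dmap
        rows.append(row)
    # shared quantization range per analyte, then contrast
    ranges = {a: shared_scale(ms) for a, ms in maps.items()}
    for i, rec in enumerate(records):
        for analyte in best_models:
            rows[i][f"contrast_{analyte}"] = map_contrast(
                maps[analyte][i], levels=cfg.glcm_levels, value_range=ranges[analyte]
            )
    return pd.DataFrame(rows), {"kept_maps": kept, "ranges": ranges}


def correlation_stage(table: pd.DataFrame, contrast_table: pd.DataFrame):
    merged = table.merge(contrast_table, on="sample_id")
    variables = ["mc", "rs_mg_per_g", "chewiness_N", "contrast_mc", "contrast_rs", "contrast_chewiness"]
    variables = [v for v in variables if v in merged.columns]
    return spearman_matrix(merged[variables]), merged


def render_correlation_heatmap(corr, out_path: str | Path) -> Path:
    """Annotated rho heatmap with significance stars (correlation-figure analog)."""
    out_path = Path(out_path)
    k = len(corr.variables)
    fig, ax = plt.subplots(figsize=(1.1 * k + 2, 1.0 * k + 1.5), dpi=110)
    im = ax.imshow(corr.rho, cmap="coolwarm", vmin=-1, vmax=1)
    ax.set_xticks(range(k), corr.variables, rotation=45, ha="right")
    ax.set_yticks(range(k), corr.variables)
    for i in range(k):
        for j in range(k):
            txt = f"{corr.rho[i, j]:.2f}{corr.stars[i, j]}"
            ax.text(j, i, txt, ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(out_path, metadata={"Software": "hsichem"})
    plt.close(fig)
    return out_path


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and write all artifacts; returns the run report.

    Deterministic: two runs with the same config produce identical reports.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    log.info("pipeline run, config hash %s", chash)

    gen = replace(cfg.generator, seed=stage_seed(cfg.seed, "generate"))
    records = synthetic.make_sample_table(gen)
    table, spectra = build_dataset(cfg, records=records)
    table.to_csv(outdir / "sample_table.csv", index=False)
    pd.DataFrame(spectra).to_csv(outdir / "mean_spectra.csv", index=False)

    comparison, best_models = fit_models(cfg, table, spectra)
    comparison.to_csv(outdir / "comparison_table.csv", index=False)
    for analyte, model in best_models.items():
        (outdir / f"model_{analyte}.json").write_text(json.dumps(model.to_dict()))

    contrast_table, extras = compute_maps_and_contrast(cfg, records, best_models)
    contrast_table.to_csv(outdir / "contrast_table.csv", index=False)
    maps_dir = outdir / "maps"
    maps_dir.mkdir(exist_ok=True)
    for (bread, t, analyte), dmap in extras["kept_maps"].items():
        render_pseudocolor(
            dmap,
            maps_dir / f"{analyte}_{bread}_t{t:g}.png",
            colormap=cfg.colormap,
            display_range=extras["ranges"][analyte],
            title=f"{analyte} | {bread} @ {t:g}s",
        )

    corr, merged = correlation_stage(table, contrast_table)
    frames = corr.to_frames()
    for name, df in frames.items():
        df.to_csv(outdir / f"correlation_{name}.csv")
    render_correlation_heatmap(corr, outdir / "correlation_heatmap.png")
    merged.to_csv(outdir / "sample_table_with_contrast.csv", index=False)

    report = {
        "config_hash": chash,
        "config": cfg.to_dict(),
        "n_samples": len(records),
        "comparison": comparison.round(12).to_dict(orient="records"),
        "best_models": {
            a: {"kind": m.kind, "preprocess": m.preprocess.tag, "n_components": m.n_components}
            for a, m in best_models.items()
        },
        "correlation_rho": np.round(corr.rho, 12).tolist(),
        "correlation_variables": corr.variables,
    }
    report["report_hash"] = hashlib.sha256(
        json.dumps(report, sort_keys=True).encode()
    ).hexdigest()
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def write_scene(scene, outdir: str | Path, stem: str) -> None:
    """Serialize one scene as ENVI cubes (raw, dark, white, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_envi(scene.raw_cube, outdir / f"{stem}_raw.hdr")
    wl = scene.raw_cube.wavelengths
    write_envi(Hypercube(scene.dark_frame.data, wl, kind="raw"), outdir / f"{stem}_dark.hdr")
    write_envi(Hypercube(scene.white_frame.data, wl, kind="raw"), outdir / f"{stem}_white.hdr")
    write_envi(scene.true_reflectance, outdir / f"{stem}_truth.hdr")
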