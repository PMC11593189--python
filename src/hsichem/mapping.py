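"""Pixel-wise model application and pseudo-color rendering of analyte maps."""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .chemometrics import RegressionModel, predict
from .io import Hypercube
from .preprocess import apply_chain

#: blue -> red; warmer colors mean higher values
DEFAULT_COLORMAP = "jet"


@dataclass
class DistributionMap:
    values: np.ndarray  # rows x cols, NaN outside mask
    mask: np.ndarray
    analyte: str
    display_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside mask")
        if self.display_range is not None and self.display_range[0] >= self.display_range[1]:
            raise ValueError("display_range lo must be < hi")

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def predict_pixelwise(
    cube: Hypercube, model: RegressionModel, mask: np.ndarray | None = None
) -> DistributionMap:
    """Preprocess and predict every masked pixel's spectrum; NaN elsewhere."""
    if cube.kind != "reflectance":
        raise ValueError("predict_pixelwise expects a calibrated reflectance cube")
    if cube.n_bands != model.n_bands:
        raise ValueError(f"cube has {cube.n_bands} bands, model expects {model.n_bands}")
    if mask is None:
        mask = np.ones(cube.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    spectra = cube.data[mask]
    spectra = apply_chain(spectra, model.preprocess)
    values = np.full(cube.shape[:2], np.nan)
    values[mask] = predict(model, spectra)
    return DistributionMap(values, mask, analyte=model.analyte or "analyte")


def shared_scale(maps: list[DistributionMap], percentile: float = 1.0) -> tuple[float, float]:
    """Common (lo, hi) display range over the pooled masked values of all maps.

    Uses the ``percentile``..(100 - ``percentile``) span so a single outlier
    cannot stretch every map's color scale. Degenerate ranges are padded.
    """
    if not maps:
        raise ValueError("need at least one map")
    pooled = np.concatenate([m.masked_values for m in maps])
    lo = float(np.percentile(pooled, percentile))
    hi = float(np.percentile(pooled, 100.0 - percentile))
    if lo >= hi:
        lo, hi = lo - 1.0, hi + 1.0
    return lo, hi


def render_pseudocolor(
    dmap: DistributionMap,
    out_path: str | Path,
    colormap: str = DEFAULT_COLORMAP,
    display_range: tuple[float, float] | None = None,
    title: str | None = None,
) -> Path:
    """Write a PNG with a linear blue-to-red color mapping and a color bar.

    Values beyond the display range clamp to the endpoint colors; background
    (unmasked) pixels render neutral gray. A JSON sidecar records the analyte
    and range. Deterministic: identical inputs produce identical bytes.
    """
    out_path = Path(out_path)
    rng_ = display_range or dmap.display_range
    if rng_ is None:
        vals = dmap.masked_values
        rng_ = (float(vals.min()), float(vals.max()))
        if rng_[0] >= rng_[1]:
            rng_ = (rng_[0] - 1.0, rng_[1] + 1.0)
    lo, hi = rng_

    fig, ax = plt.subplots(figsize=(4.2, 3.6), dpi=120)
    shown = np.ma.masked_array(dmap.values, mask=~dmap.mask)
    cmap = plt.get_cmap(colormap).copy()
    cmap.set_bad("0.85")
    im = ax.imshow(shown, cmap=cmap, vmin=lo, vmax=hi, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=dmap.analyte)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.savefig(out_path, format="png", metadata={"Software": "hsichem"})
    plt.close(fig)
    out_path.with_suffix(".json").write_text(
        json.dumps(
            {"analyte": dmap.analyte, "display_range": [lo, hi], "colormap": colormap},
            indent=2,
        )
    )
    return out_path


def map_to_csv(dmap: DistributionMap, out_path: str | Path) -> Path:
    """Export the raw value grid (NaN for background) as CSV."""
    out_path = Path(out_path)
    np.savetxt(out_path, dmap.values, delimiter=",", fmt="%.10g")
    return out_path
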