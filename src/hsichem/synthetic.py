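"""Synthetic bolus scenes: endmember spectra, spatial analyte fields, raw cubes.

The generator builds scenes the calibration stage can invert exactly:
per-pixel absorbance A(lambda) = sum_k c_k * eps_k(lambda), true reflectance
R = exp(-A) (times optional smooth illumination scatter), and raw intensity
I = B + R * (W - B) + detector noise. Analyte label trajectories over chew
time are saturating curves anchored at measured endpoints for the two bread
formulations (white and 50% whole-wheat), interpolated in ``fiber_factor``
for other formulations.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Hypercube, ReferenceFrame

ANALYTES = ("mc", "rs", "chewiness")

#: endmember linked to each analyte label
ANALYTE_ENDMEMBER = {"mc": "water", "rs": "starch_sugar", "chewiness": "fiber"}

#: optical concentration per label unit (label -> concentration is linear)
OPTICAL_SCALE = {"mc": 1.0, "rs": 0.04, "chewiness": 0.008}

#: constant fat background concentration (not linked to any label)
FAT_CONCENTRATION = 0.3

# Measured endpoint anchors (start, end) per analyte at fiber_factor 0 and 0.5.
# MC is a fraction, RSs mg/g, chewiness N; curves interpolate linearly in
# fiber_factor between the two anchor formulations.
_ANCHORS = {
    "mc": {0.0: (0.4228, 0.5510), 0.5: (0.3433, 0.4724)},
    "rs": {0.0: (2.00, 12.00), 0.5: (1.50, 8.00)},
    "chewiness": {0.0: (29.16, 2.00), 0.5: (53.36, 2.44)},
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_rows: int = 64
    n_cols: int = 64
    n_bands: int = 512
    wavelength_start: float = 899.0
    wavelength_end: float = 1748.0
    bread_types: dict = field(default_factory=lambda: {"B0": 0.0, "B50": 0.5})
    chew_times: tuple = (0.0, 6.0, 12.0, 18.0)
    n_panelists: int = 8
    n_replicates: int = 3
    noise_sd: float = 0.005
    scatter_cv: float = 0.02
    label_noise_cv: float = 0.05
    field_smoothness: float = 4.0
    dark_level: float = 0.05
    white_level: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 8:
            raise ValueError("n_bands must be >= 8")
        if self.wavelength_start >= self.wavelength_end:
            raise ValueError("wavelength_start must be < wavelength_end")
        if self.noise_sd < 0 or self.scatter_cv < 0 or self.label_noise_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if min(self.n_rows, self.n_cols, self.n_panelists, self.n_replicates) < 1:
            raise ValueError("all counts must be >= 1")
        if not self.bread_types:
            raise ValueError("at least one bread type is required")
        for label, ff in self.bread_types.items():
            if not 0.0 <= float(ff) <= 1.0:
                raise ValueError(f"fiber_factor for {label!r} must be in [0, 1]")
        if self.white_level <= self.dark_level:
            raise ValueError("white_level must exceed dark_level")

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "n_bands": self.n_bands,
            "wavelength_start": self.wavelength_start,
            "wavelength_end": self.wavelength_end,
            "bread_types": dict(self.bread_types),
            "chew_times": list(self.chew_times),
            "n_panelists": self.n_panelists,
            "n_replicates": self.n_replicates,
            "noise_sd": self.noise_sd,
            "scatter_cv": self.scatter_cv,
            "label_noise_cv": self.label_noise_cv,
            "field_smoothness": self.field_smoothness,
            "dark_level": self.dark_level,
            "white_level": self.white_level,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "chew_times" in d:
            d["chew_times"] = tuple(float(t) for t in d["chew_times"])
        return cls(**d)


@dataclass
class EndmemberSpectrum:
    name: str
    absorptivity: np.ndarray

    def __post_init__(self) -> None:
        self.absorptivity = np.asarray(self.absorptivity, dtype=float)
        if np.any(self.absorptivity < 0):
            raise ValueError(f"endmember {self.name!r} has negative absorptivity")


@dataclass
class ConcentrationField:
    analyte: str
    values: np.ndarray
    target_mean: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("concentration field has negative values")
        if abs(self.values.mean() - self.target_mean) > 1e-9:
            raise ValueError("field mean deviates from target_mean by more than 1e-9")


@dataclass
class SampleRecord:
    sample_id: str
    bread_type: str
    chew_time: float
    panelist: int
    replicate: int
    mc: float
    rs: float
    chewiness: float

    def __post_init__(self) -> None:
        if min(self.mc, self.rs, self.chewiness) < 0:
            raise ValueError("labels must be nonnegative")


@dataclass
class SyntheticScene:
    raw_cube: Hypercube
    dark_frame: ReferenceFrame
    white_frame: ReferenceFrame
    true_reflectance: Hypercube
    fields: list
    record: SampleRecord
    foreground: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def make_wavelength_grid(config: GeneratorConfig) -> np.ndarray:
    """Evenly spaced grid from wavelength_start to wavelength_end inclusive."""
    return np.linspace(config.wavelength_start, config.wavelength_end, config.n_bands)


#: default absorption bands per endmember: (center nm, width nm, amplitude)
DEFAULT_BANDS = {
    "water": [(960.0, 25.0, 0.35), (1450.0, 40.0, 1.0)],
    "starch_sugar": [(990.0, 35.0, 0.9)],
    "fat": [(1200.0, 25.0, 0.7)],
    "fiber": [(1520.0, 300.0, 0.5)],
}


def make_endmembers(
    grid: np.ndarray, bands: dict[str, list[tuple[float, float, float]]] | None = None
) -> list[EndmemberSpectrum]:
    """Gaussian-band absorptivity spectra on the wavelength grid.

    Water absorbs at 960 and (more strongly) 1450 nm, fat at 1200 nm,
    starch/sugar near 990 nm, fiber as one broad band. A band center outside
    the grid contributes only its tail and triggers a warning.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be sorted ascending")
    bands = bands if bands is not None else DEFAULT_BANDS
    out = []
    for name, band_list in bands.items():
        eps = np.zeros_like(grid)
        for center, width, amplitude in band_list:
            if amplitude < 0 or width <= 0:
                raise ValueError(f"band ({center}, {width}, {amplitude}) invalid for {name!r}")
            if not grid[0] <= center <= grid[-1]:
                warnings.warn(
                    f"endmember {name!r}: band center {center} nm outside grid "
                    f"[{grid[0]}, {grid[-1]}]; only its tail contributes"
                )
            eps += amplitude * np.exp(-((grid - center) ** 2) / (2.0 * width**2))
        out.append(EndmemberSpectrum(name, eps))
    return out


def make_field(
    shape: tuple[int, int],
    target_mean: float,
    heterogeneity: float,
    smoothness: float = 4.0,
    seed: int | np.random.Generator = 0,
) -> ConcentrationField:
    """Smoothed Gaussian random field, nonnegative, rescaled to ``target_mean``.

    ``heterogeneity`` is the requested coefficient of variation. An error is
    raised if clipping negatives would remove more than 10% of the mass.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be > 0")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if heterogeneity == 0:
        return ConcentrationField("", np.full(shape, float(target_mean)), float(target_mean))
    z = rng.standard_normal(shape)
    if smoothness > 0:
        z = ndimage.gaussian_filter(z, smoothness, mode="reflect")
    z = (z - z.mean()) / z.std()
    values = target_mean * (1.0 + heterogeneity * z)
    removed = -values[values < 0].sum()
    if removed > 0.10 * target_mean * values.size:
        raise ValueError(
            f"heterogeneity {heterogeneity} clips {removed / (target_mean * values.size):.1%} "
            "of field mass (> 10%)"
        )
    values = np.clip(values, 0.0, None)
    values *= target_mean / values.mean()
    return ConcentrationField("", values, float(target_mean))


def disk_mask(shape: tuple[int, int], radius_fraction: float = 0.4) -> np.ndarray:
    """Centered disk covering ``radius_fraction`` of the smaller dimension."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    radius = radius_fraction * min(shape)
    return (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2


def assemble_scene(
    config: GeneratorConfig,
    record: SampleRecord,
    fields: dict[str, ConcentrationField],
    endmembers: list[EndmemberSpectrum],
    rng: np.random.Generator | None = None,
    foreground: np.ndarray | None = None,
    background_reflectance: float = 0.98,
) -> SyntheticScene:
    """Compose absorbance from fields x endmembers and wrap it in raw frames.

    ``fields`` maps endmember names to concentration fields; every endmember
    must be covered. Outside an optional ``foreground`` mask, reflectance is
    the constant bright ``background_reflectance`` (an empty dish).
    """
    rng = rng or np.random.default_rng(config.seed)
    by_name = {em.name: em for em in endmembers}
    missing = set(by_name) - set(fields)
    if missing:
        raise ValueError(f"fields missing for endmembers: {sorted(missing)}")
    shape = (config.n_rows, config.n_cols)
    grid = make_wavelength_grid(config)

    absorbance = np.zeros(shape + (config.n_bands,))
    for name, em in by_name.items():
        vals = fields[name].values
        if vals.shape != shape:
            raise ValueError(f"field {name!r} shape {vals.shape} != scene shape {shape}")
        absorbance += vals[:, :, None] * em.absorptivity[None, None, :]
    reflectance = np.exp(-absorbance)
    if foreground is not None:
        reflectance = np.where(foreground[:, :, None], reflectance, background_reflectance)
    if config.scatter_cv > 0:
        # smooth multiplicative illumination/surface-orientation field
        g = ndimage.gaussian_filter(rng.standard_normal(shape), config.field_smoothness, mode="reflect")
        g = (g - g.mean()) / g.std()
        reflectance = reflectance * np.exp(config.scatter_cv * g - 0.5 * config.scatter_cv**2)[:, :, None]
    reflectance = np.clip(reflectance, np.finfo(float).tiny, 1.0)

    dark = np.full((1, config.n_cols, config.n_bands), config.dark_level)
    white = np.full((1, config.n_cols, config.n_bands), config.white_level)
    if np.any(white <= dark):
        raise ValueError("white frame must exceed dark frame everywhere")
    raw = dark + reflectance * (white - dark)
    if config.noise_sd > 0:
        raw = raw + rng.normal(0.0, config.noise_sd, raw.shape)
    return SyntheticScene(
        raw_cube=Hypercube(raw, grid, kind="raw"),
        dark_frame=ReferenceFrame(dark, role="black"),
        white_frame=ReferenceFrame(white, role="white"),
        true_reflectance=Hypercube(reflectance, grid, kind="reflectance"),
        fields=list(fields.values()),
        record=record,
        foreground=foreground,
    )


# ---------------------------------------------------------------------------
# Label schedules
# ---------------------------------------------------------------------------

def _anchored(analyte: str, fiber_factor: float) -> tuple[float, float]:
    lo, hi = _ANCHORS[analyte][0.0], _ANCHORS[analyte][0.5]
    f = fiber_factor / 0.5
    return (lo[0] + (hi[0] - lo[0]) * f, lo[1] + (hi[1] - lo[1]) * f)


def label_schedule(analyte: str, bread_fiber_factor: float, chew_time: float, t_max: float = 18.0) -> float:
    """Saturating trajectory anchored at the formulation's start/end values.

    Hydration (and starch breakdown) is slower for fibrous formulations, so
    the time constant grows with fiber_factor. Curves are exact at t = 0 and
    t = t_max and strictly monotone in between.
    """
    v0, v_end = _anchored(analyte, bread_fiber_factor)
    tau = 6.0 * (1.0 + bread_fiber_factor)
    if t_max <= 0:
        return v0
    frac = (1.0 - np.exp(-chew_time / tau)) / (1.0 - np.exp(-t_max / tau))
    return float(v0 + (v_end - v0) * frac)


def heterogeneity_schedule(analyte: str, bread_fiber_factor: float, chew_time: float, t_max: float = 18.0) -> float:
    """Spatial CV over chew time: unimodal for mc/chewiness, decreasing for rs."""
    u = chew_time / t_max if t_max > 0 else 0.0
    if analyte == "rs":
        cv = 0.25 - 0.15 * u
    else:
        cv = 0.08 + 0.12 * np.sin(np.pi * u)
    return float(max(0.02, cv * (1.0 + bread_fiber_factor)))


def field_mean_to_label(analyte: str, field_mean: float) -> float:
    """Invert the optical-concentration link: label = mean / scale."""
    return field_mean / OPTICAL_SCALE[analyte]


def label_to_field_mean(analyte: str, label: float) -> float:
    return label * OPTICAL_SCALE[analyte]


def make_sample_table(config: GeneratorConfig) -> list[SampleRecord]:
    """One record per bread x chew time x panelist x replicate.

    Labels follow the anchored schedules with multiplicative lognormal
    panelist/replicate variation (mean-1, CV = ``label_noise_cv``).
    Deterministic under the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5AB1E]))
    t_max = max(config.chew_times)
    records = []
    for bread, ff in config.bread_types.items():
        for t in config.chew_times:
            for p in range(config.n_panelists):
                for r in range(config.n_replicates):
                    labels = {}
                    for analyte in ANALYTES:
                        base = label_schedule(analyte, ff, t, t_max)
                        if config.label_noise_cv > 0:
                            sd = np.sqrt(np.log1p(config.label_noise_cv**2))
                            base *= rng.lognormal(-0.5 * sd**2, sd)
                        labels[analyte] = base
                    records.append(
                        SampleRecord(
                            sample_id=f"{bread}_t{t:g}_p{p}_r{r}",
                            bread_type=bread,
                            chew_time=float(t),
                            panelist=p,
                            replicate=r,
                            mc=labels["mc"],
                            rs=labels["rs"],
                            chewiness=labels["chewiness"],
                        )
                    )
    return records


def make_scene_for_record(
    config: GeneratorConfig,
    record: SampleRecord,
    endmembers: list[EndmemberSpectrum] | None = None,
    foreground: np.ndarray | None = None,
    heterogeneity_override: float | None = None,
) -> SyntheticScene:
    """Build the full scene whose analyte fields average to the record's labels."""
    endmembers = endmembers or make_endmembers(make_wavelength_grid(config))
    ff = config.bread_types[record.bread_type]
    t_max = max(config.chew_times)
    # per-record RNG: independent of enumeration order, stable across processes
    digest = hashlib.blake2s(record.sample_id.encode()).digest()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, int.from_bytes(digest[:4], "little")])
    )
    shape = (config.n_rows, config.n_cols)
    fields: dict[str, ConcentrationField] = {}
    for analyte, em_name in ANALYTE_ENDMEMBER.items():
        het = (
            heterogeneity_override
            if heterogeneity_override is not None
            else heterogeneity_schedule(analyte, ff, record.chew_time, t_max)
        )
        f = make_field(
            shape,
            label_to_field_mean(analyte, getattr(record, analyte)),
            het,
            smoothness=config.field_smoothness,
            seed=rng,
        )
        f.analyte = analyte
        fields[em_name] = f
    fat = ConcentrationField("fat", np.full(shape, FAT_CONCENTRATION), FAT_CONCENTRATION)
    fields["fat"] = fat
    return assemble_scene(config, record, fields, endmembers, rng=rng, foreground=foreground)


def sample_table_to_frame(records: list[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "bread_type": [r.bread_type for r in records],
            "chew_time_s": [r.chew_time for r in records],
            "panelist": [r.panelist for r in records],
            "replicate": [r.replicate for r in records],
            "mc": [r.mc for r in records],
            "rs_mg_per_g": [r.rs for r in records],
            "chewiness_N": [r.chewiness for r in records],
        }
    )


def frame_to_sample_table(df: pd.DataFrame) -> list[SampleRecord]:
    return [
        SampleRecord(
            sample_id=row.sample_id,
            bread_type=row.bread_type,
            chew_time=float(row.chew_time_s),
            panelist=int(row.panelist),
            replicate=int(row.replicate),
            mc=float(row.mc),
            rs=float(row.rs_mg_per_g),
            chewiness=float(row.chewiness_N),
        )
        for row in df.itertuples(index=False)
    ]


def noise_free(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of the config with every stochastic nuisance switched off."""
    return replace(config, noise_sd=0.0, scatter_cv=0.0, label_noise_cv=0.0)
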