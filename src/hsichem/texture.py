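"""Uniformity statistics (GLCM contrast), Spearman correlation, and the
wet-lab arithmetic: gravimetric moisture and the reducing-sugar standard curve.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import DistributionMap

#: offsets (drow, dcol) at distance 1 for 0, 45, 90, 135 degrees
FOUR_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

DEFAULT_LEVELS = 64


@dataclass
class GLCM:
    matrix: np.ndarray  # L x L, normalized to sum 1
    levels: int
    offset: tuple[int, int]
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.levels, self.levels):
            raise ValueError("GLCM must be levels x levels")
        if abs(self.matrix.sum() - 1.0) > 1e-12:
            raise ValueError("GLCM must be normalized to sum 1")
        if self.symmetric and not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("symmetric GLCM must equal its transpose")


@dataclass
class MoistureWeighing:
    m1: float  # chewed bolus mass, g
    m2: float  # dried bolus mass, g

    def __post_init__(self) -> None:
        if self.m2 <= 0:
            raise ValueError("dried mass m2 must be > 0")
        if self.m1 < self.m2:
            raise ValueError("chewed mass m1 must be >= dried mass m2")


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r2: float
    analyte: str = "glucose"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be > 0 (invalid assay)")


@dataclass
class CorrelationMatrix:
    variables: list[str]
    rho: np.ndarray
    p: np.ndarray
    stars: np.ndarray  # '' | '*' | '**'
    n: np.ndarray  # pairwise sample counts

    def to_frames(self) -> dict[str, pd.DataFrame]:
        idx = self.variables
        return {
            "rho": pd.DataFrame(self.rho, index=idx, columns=idx),
            "p": pd.DataFrame(self.p, index=idx, columns=idx),
            "stars": pd.DataFrame(self.stars, index=idx, columns=idx),
        }


# ---------------------------------------------------------------------------
# Wet-lab arithmetic
# ---------------------------------------------------------------------------

def moisture_content(w: MoistureWeighing, basis: str = "dry") -> float:
    """Gravimetric moisture from chewed (m1) and dried (m2) masses.

    ``basis='dry'`` is (m1 - m2)/m2; ``basis='wet'`` is (m1 - m2)/m1.
    The returned value carries no unit conversion — multiply by 100 for %.
    """
    if basis == "dry":
        return (w.m1 - w.m2) / w.m2
    if basis == "wet":
        return (w.m1 - w.m2) / w.m1
    raise ValueError("basis must be 'dry' or 'wet'")


def fit_standard_curve(concentrations: np.ndarray, absorbances: np.ndarray) -> StandardCurve:
    """OLS line A = slope * c + intercept through >= 3 standards."""
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if len(c) != len(a) or len(c) < 3:
        raise ValueError("need at least 3 matched standards")
    if np.ptp(c) == 0:
        raise ValueError("standard concentrations must not be constant")
    slope, intercept = np.polyfit(c, a, 1)
    pred = slope * c + intercept
    ss_tot = np.sum((a - a.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((a - pred) ** 2) / ss_tot)
    return StandardCurve(float(slope), float(intercept), r2)


def rs_from_absorbance(curve: StandardCurve, a540: float, dilution: float = 1.0) -> float:
    """Invert the standard curve: c = (A - intercept)/slope, scaled by dilution."""
    return (a540 - curve.intercept) / curve.slope * dilution


# ---------------------------------------------------------------------------
# GLCM contrast
# ---------------------------------------------------------------------------

def quantize(
    dmap: DistributionMap,
    levels: int = DEFAULT_LEVELS,
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Linear binning of masked values into 0..levels-1.

    The default range is the map's own masked [min, max]; pass a shared
    ``value_range`` when comparing maps, so bin width is common (values
    outside clamp to the end bins). Background pixels get -1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    vals = dmap.masked_values
    lo, hi = value_range if value_range is not None else (vals.min(), vals.max())
    out = np.full(dmap.values.shape, -1, dtype=np.int64)
    if hi <= lo:
        warnings.warn("constant map: all pixels quantized to level 0")
        out[dmap.mask] = 0
        return out
    scaled = (dmap.values[dmap.mask] - lo) / (hi - lo) * levels
    out[dmap.mask] = np.clip(scaled.astype(np.int64), 0, levels - 1)
    return out


def glcm_compute(
    img: np.ndarray,
    offset: tuple[int, int],
    levels: int | None = None,
    mask: np.ndarray | None = None,
    symmetric: bool = True,
) -> GLCM:
    """Co-occurrence counts at one (drow, dcol) offset, symmetrized, normalized.

    Pairs are counted only when both endpoints lie inside the image and the
    mask. Implemented directly (no image-processing library) so it can be
    cross-checked against an exhaustive pair enumeration.
    """
    img = np.asarray(img)
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError("image must be integer-valued (use quantize first)")
    di, dj = offset
    if (di, dj) == (0, 0):
        raise ValueError("offset must be nonzero")
    if mask is None:
        mask = img >= 0
    mask = np.asarray(mask, dtype=bool) & (img >= 0)
    if levels is None:
        levels = int(img[mask].max()) + 1 if mask.any() else 1
    rows, cols = img.shape

    r0a, r0b = max(0, -di), min(rows, rows - di)
    c0a, c0b = max(0, -dj), min(cols, cols - dj)
    src = np.s_[r0a:r0b, c0a:c0b]
    dst = np.s_[r0a + di : r0b + di, c0a + dj : c0b + dj]
    valid = mask[src] & mask[dst]
    i = img[src][valid].ravel()
    j = img[dst][valid].ravel()
    if i.size == 0:
        raise ValueError(f"no valid pixel pairs at offset {offset}")
    counts = np.zeros((levels, levels))
    np.add.at(counts, (i, j), 1.0)
    if symmetric:
        counts = counts + counts.T
    return GLCM(counts / counts.sum(), levels, (di, dj), symmetric=symmetric)


def contrast(glcm: GLCM) -> float:
    """Moment of inertia about the GLCM diagonal: sum_ij (i - j)^2 P(i, j)."""
    idx = np.arange(glcm.levels)
    return float(((idx[:, None] - idx[None, :]) ** 2 * glcm.matrix).sum())


def map_contrast(
    dmap: DistributionMap,
    levels: int = DEFAULT_LEVELS,
    value_range: tuple[float, float] | None = None,
    offsets: tuple = FOUR_DIRECTIONS,
) -> float:
    """Mean GLCM contrast over the four distance-1 directions."""
    img = quantize(dmap, levels, value_range)
    return float(
        np.mean([contrast(glcm_compute(img, off, levels=levels)) for off in offsets])
    )


# ---------------------------------------------------------------------------
# Spearman correlation matrix
# ---------------------------------------------------------------------------

def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks (average ranks on ties)."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant variable: Spearman rho undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def _spearman_p(rho: float, n: int, exact_max_n: int = 0) -> float:
    """Two-sided p-value: t-approximation, or exact permutation for small n."""
    if n <= exact_max_n:
        # exact null distribution by full permutation of one ranking
        from itertools import permutations

        ranks = np.arange(1, n + 1, dtype=float)
        base = np.arange(1, n + 1, dtype=float)
        count = 0
        total = 0
        for perm in permutations(ranks):
            r = np.corrcoef(base, perm)[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return count / total
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman_matrix(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    exact_max_n: int = 0,
    alpha: tuple[float, float] = (0.05, 0.01),
) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations with significance stars.

    Stars: '*' for p <= alpha[0], '**' for p <= alpha[1]. A constant variable
    yields NaN rho with star label 'x' (flagged, not silent).
    """
    variables = variables or list(table.columns)
    k = len(variables)
    rho = np.eye(k)
    p = np.zeros((k, k))
    n_mat = np.zeros((k, k), dtype=int)
    stars = np.full((k, k), "", dtype=object)
    for a in range(k):
        n_mat[a, a] = table[variables[a]].notna().sum()
        for b in range(a + 1, k):
            pair = table[[variables[a], variables[b]]].dropna()
            n = len(pair)
            n_mat[a, b] = n_mat[b, a] = n
            if n < 5:
                raise ValueError(
                    f"need >= 5 complete pairs for {variables[a]!r} vs {variables[b]!r}, got {n}"
                )
            x = pair.iloc[:, 0].to_numpy(dtype=float)
            y = pair.iloc[:, 1].to_numpy(dtype=float)
            try:
                r = spearman_rho(x, y)
            except ValueError:
                rho[a, b] = rho[b, a] = np.nan
                p[a, b] = p[b, a] = np.nan
                stars[a, b] = stars[b, a] = "x"
                continue
            pv = _spearman_p(r, n, exact_max_n=exact_max_n)
            rho[a, b] = rho[b, a] = r
            p[a, b] = p[b, a] = pv
            if pv <= alpha[1]:
                stars[a, b] = stars[b, a] = "**"
            elif pv <= alpha[0]:
                stars[a, b] = stars[b, a] = "*"
    return CorrelationMatrix(list(variables), rho, p, stars, n_mat)
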