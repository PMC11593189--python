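"""Latent-variable regression for spectra: NIPALS PLS1 and PCR, from scratch.

One model per analyte (univariate y). X and y are mean-centered, never
variance-scaled. Cross-validation, Kennard-Stone splitting, component
selection and the six calibration/CV/prediction metrics live here too.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import PreprocessSpec, apply_chain

MAX_COMPONENTS_DEFAULT = 15


@dataclass
class RegressionModel:
    kind: str  # "PLSR" | "PCR"
    preprocess: PreprocessSpec
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coefficients: np.ndarray  # per-band b on centered data
    n_cal: int = 0
    seed: int | None = None
    scores: np.ndarray | None = None  # training component scores, diagnostics
    analyte: str = ""

    @property
    def n_bands(self) -> int:
        return len(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "analyte": self.analyte,
            "preprocess": self.preprocess.to_dict(),
            "n_components": int(self.n_components),
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "coefficients": self.coefficients.tolist(),
            "n_cal": int(self.n_cal),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        return cls(
            kind=d["kind"],
            analyte=d.get("analyte", ""),
            preprocess=PreprocessSpec.from_dict(d["preprocess"]),
            n_components=d["n_components"],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            n_cal=d.get("n_cal", 0),
            seed=d.get("seed"),
        )


@dataclass
class ModelMetrics:
    rc2: float
    rmsec: float
    rcv2: float
    rmsecv: float
    rp2: float
    rmsep: float


@dataclass
class SplitSpec:
    method: str = "kennard_stone"
    cal_fraction: float = 0.75
    seed: int = 0
    cv_folds: int = 10
    leave_one_out: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("kennard_stone", "random"):
            raise ValueError("split method must be 'kennard_stone' or 'random'")
        if not 0 < self.cal_fraction < 1:
            raise ValueError("cal_fraction must be in (0, 1)")
        if not self.leave_one_out and self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Max-min Euclidean selection, seeded with the two most distant samples."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n_select < 2 or n_select > n:
        raise ValueError(f"n_select must be in [2, {n}]")
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(d2, -np.inf)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    selected = [min(i, j), max(i, j)]
    np.fill_diagonal(d2, np.inf)
    min_d = np.minimum(d2[:, selected[0]], d2[:, selected[1]])
    min_d[selected] = -np.inf
    while len(selected) < n_select:
        nxt = int(np.argmax(min_d))
        selected.append(nxt)
        min_d = np.minimum(min_d, d2[:, nxt])
        min_d[nxt] = -np.inf
    return np.array(sorted(selected))


def split_calibration_prediction(
    X: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive calibration/prediction split; deterministic given spec."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    n_cal = int(np.floor(spec.cal_fraction * n))
    n_cal = max(2, min(n - 1, n_cal))
    if spec.method == "kennard_stone":
        cal = kennard_stone(X, n_cal)
    else:
        rng = np.random.default_rng(spec.seed)
        cal = np.sort(rng.permutation(n)[:n_cal])
    pred = np.setdiff1d(np.arange(n), cal)
    return cal, pred


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _validate_xy(X: np.ndarray, y: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x bands)")
    n, p = X.shape
    if len(y) != n:
        raise ValueError(f"X has {n} rows but y has {len(y)} values")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("X/y contain NaN or inf")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {n_components}"
        )
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    return X, y


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    preprocess: PreprocessSpec | None = None,
    analyte: str = "",
    seed: int | None = None,
) -> RegressionModel:
    """PLS1 by NIPALS with X/y mean-centering and X deflation.

    Per component: w = X'y / ||X'y||, t = Xw, p = X't/(t't), q = y't/(t't),
    then X <- X - t p'. The per-band coefficient vector is
    b = W (P'W)^{-1} q so that y_hat = y_mean + (x - x_mean) b.
    """
    X, y = _validate_xy(X, y, n_components)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W, P, Q, T = [], [], [], []
    Xd = Xc.copy()
    yd = yc.copy()
    for _ in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            warnings.warn("NIPALS: residual covariance vanished; stopping early")
            break
        w = w / nw
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-24 or np.sqrt(tt) < 1e-12:
            warnings.warn("NIPALS: degenerate score; stopping early")
            break
        p = Xd.T @ t / tt
        q = float(yd @ t / tt)
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
        T.append(t)
    if not W:
        raise ValueError("no PLS components could be extracted")
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.array(Q)
    b = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    return RegressionModel(
        kind="PLSR",
        preprocess=preprocess or PreprocessSpec(method="none"),
        n_components=len(W),
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=b,
        n_cal=len(y),
        seed=seed,
        scores=np.column_stack(T),
        analyte=analyte,
    )


def fit_pcr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    preprocess: PreprocessSpec | None = None,
    analyte: str = "",
    seed: int | None = None,
) -> RegressionModel:
    """PCA (SVD of centered X) followed by OLS of y on the leading scores."""
    X, y = _validate_xy(X, y, n_components)
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(f"PCR: rank deficiency, using {k} of {n_components} components")
    if k == 0:
        raise ValueError("X has zero rank after centering")
    # scores T = U_k s_k; regression of yc on orthogonal scores is elementwise
    gamma = (U[:, :k].T @ yc) / s[:k]
    b = Vt[:k].T @ gamma
    return RegressionModel(
        kind="PCR",
        preprocess=preprocess or PreprocessSpec(method="none"),
        n_components=k,
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=b,
        n_cal=len(y),
        seed=seed,
        scores=U[:, :k] * s[:k],
        analyte=analyte,
    )


_FITTERS = {"PLSR": fit_plsr, "PCR": fit_pcr}


def predict(model: RegressionModel, X: np.ndarray) -> np.ndarray:
    """y_hat = y_mean + (X - x_mean) b, vectorized over rows."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X2 = np.atleast_2d(X)
    if X2.shape[1] != model.n_bands:
        raise ValueError(f"X has {X2.shape[1]} bands, model expects {model.n_bands}")
    yhat = model.y_mean + (X2 - model.x_mean) @ model.coefficients
    return float(yhat[0]) if single else yhat


# ---------------------------------------------------------------------------
# Metrics and validation
# ---------------------------------------------------------------------------

def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """Return (r2, rmse): r2 = 1 - SS_res/SS_tot, rmse = sqrt(mean sq. error)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred) or len(y_true) < 2:
        raise ValueError("need equal-length vectors with at least 2 values")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true is constant; R^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    return 1.0 - ss_res / ss_tot, rmse


def _fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [perm[i::folds] for i in range(folds)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    n_components: int,
    spec: SplitSpec | None = None,
) -> tuple[float, float]:
    """Seeded k-fold (or leave-one-out) CV; returns (rcv2, rmsecv) on pooled predictions."""
    spec = spec or SplitSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    folds = n if spec.leave_one_out else min(spec.cv_folds, n)
    if folds > n:
        raise ValueError(f"cannot make {folds} folds from {n} samples")
    fit = _FITTERS[kind]
    y_pred = np.empty(n)
    for test_idx in _fold_indices(n, folds, spec.seed):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(train_idx) < 2:
            raise ValueError("a CV fold leaves fewer than 2 calibration samples")
        k = min(n_components, len(train_idx) - 1, X.shape[1])
        model = fit(X[train_idx], y[train_idx], k)
        y_pred[test_idx] = predict(model, X[test_idx])
    return compute_metrics(y, y_pred)


def select_n_components(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    max_k: int = MAX_COMPONENTS_DEFAULT,
    spec: SplitSpec | None = None,
    tolerance: float = 0.02,
) -> int:
    """Smallest k whose RMSECV is within ``tolerance`` of the global minimum."""
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    max_k = min(max_k, len(y) - 2, X.shape[1])
    rmsecvs = np.array(
        [cross_validate(X, y, kind, k, spec)[1] for k in range(1, max_k + 1)]
    )
    best = rmsecvs.min()
    within = np.where(rmsecvs <= best * (1.0 + tolerance))[0]
    return int(within[0]) + 1


# ---------------------------------------------------------------------------
# Table-2-style model comparison
# ---------------------------------------------------------------------------

def evaluate_model(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    preprocess: PreprocessSpec,
    split: SplitSpec | None = None,
    n_components: int | None = None,
    max_k: int = MAX_COMPONENTS_DEFAULT,
    analyte: str = "",
) -> tuple[RegressionModel, ModelMetrics]:
    """Preprocess, split, select components, fit, and report all six metrics."""
    split = split or SplitSpec()
    Xp = apply_chain(np.asarray(X, dtype=float), preprocess)
    y = np.asarray(y, dtype=float).ravel()
    cal, pred = split_calibration_prediction(Xp, split)
    Xc, yc = Xp[cal], y[cal]
    Xt, yt = Xp[pred], y[pred]
    if n_components is None:
        n_components = select_n_components(Xc, yc, kind, max_k=max_k, spec=split)
    model = _FITTERS[kind](
        Xc, yc, n_components, preprocess=preprocess, analyte=analyte, seed=split.seed
    )
    rc2, rmsec = compute_metrics(yc, predict(model, Xc))
    rcv2, rmsecv = cross_validate(Xc, yc, kind, model.n_components, split)
    rp2, rmsep = compute_metrics(yt, predict(model, Xt))
    return model, ModelMetrics(rc2, rmsec, rcv2, rmsecv, rp2, rmsep)


def model_comparison_table(
    X: np.ndarray,
    labels: dict[str, np.ndarray],
    preprocess_specs: list[PreprocessSpec] | None = None,
    model_kinds: tuple[str, ...] = ("PLSR", "PCR"),
    split: SplitSpec | None = None,
    max_k: int = MAX_COMPONENTS_DEFAULT,
) -> pd.DataFrame:
    """Cross every pretreatment with every model for every analyte.

    Returns one row per (analyte, pretreatment, model) with the six metrics;
    the best model per analyte (max RP2) is flagged.
    """
    if preprocess_specs is None:
        preprocess_specs = [
            PreprocessSpec(method="SG"),
            PreprocessSpec(method="GF"),
            PreprocessSpec(method="N"),
        ]
    rows = []
    for analyte, y in labels.items():
        for pp in preprocess_specs:
            for kind in model_kinds:
                model, m = evaluate_model(
                    X, y, kind, pp, split=split, max_k=max_k, analyte=analyte
                )
                rows.append(
                    {
                        "analyte": analyte,
                        "preprocess": pp.tag,
                        "model": kind,
                        "n_components": model.n_components,
                        "RC2": m.rc2,
                        "RMSEC": m.rmsec,
                        "RCV2": m.rcv2,
                        "RMSECV": m.rmsecv,
                        "RP2": m.rp2,
                        "RMSEP": m.rmsep,
                    }
                )
    table = pd.DataFrame(rows)
    table["best"] = False
    for analyte in labels:
        sub = table[table["analyte"] == analyte]
        table.loc[sub["RP2"].idxmax(), "best"] = True
    return table
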