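"""PLS1 and modified-PLS calibration with cross-validated factor selection.

The calibration engine is a mean-centred NIPALS PLS1.  The "modified"
variant — the default, matching the commercial NIRS convention — additionally
standardizes the X- and y-residuals after each factor is extracted and
deflated: every wavelength's residual column, and the y residual, is divided
by its standard deviation before the next factor is sought.  This weights
later factors toward wavelengths whose residual variance is otherwise
drowned out, and typically yields slightly more parsimonious models on
spectra.  With a single factor the two variants coincide.

All fitted quantities are linear in the (preprocessed) spectrum, so the
model also exposes a plain coefficient vector + intercept in original
preprocessed spectral space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CalibrationModel",
    "fit_pls1",
    "predict",
    "cross_validate",
    "CVResult",
    "split_calibration_validation",
    "save_model",
    "load_model",
]


@dataclass
class CalibrationModel:
    """A fitted PLS1/MPLS calibration.

    Stores the NIPALS weights/loadings per factor together with the residual
    scaling vectors of the modified variant, the equivalent linear
    coefficients in preprocessed spectral space, and calibration statistics.
    """

    variant: str
    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray        # (n_factors, p) NIPALS weight vectors
    x_loadings: np.ndarray     # (n_factors, p)
    y_loadings: np.ndarray     # (n_factors,) in scaled-residual units
    x_scales: np.ndarray       # (n_factors, p) residual sds applied after each factor
    y_scales: np.ndarray       # (n_factors,)
    coefficients: np.ndarray   # (p,) original preprocessed-space slope
    intercept: float
    scores: np.ndarray | None = None   # (n, n_factors) training scores
    fitted: np.ndarray | None = None
    sec: float | None = None
    r2_cal: float | None = None
    secv: float | None = None
    r2_cv: float | None = None
    recipe: str | None = None
    outlier_log: dict | None = None
    seed: int | None = None

    @property
    def n_wavelengths(self) -> int:
        return self.x_mean.size


def _nipals_pls1(
    X: np.ndarray, y: np.ndarray, n_factors: int, variant: str, strict: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core NIPALS loop; returns (W, P, q, x_scales, y_scales, T).

    With ``strict=False`` an exhausted residual (zero weight or score norm)
    stops extraction early; the remaining factors are left as zero vectors,
    which contribute nothing at prediction time.
    """
    n, p = X.shape
    Xr = X.copy()
    yr = y.copy()
    W = np.zeros((n_factors, p))
    P = np.zeros((n_factors, p))
    q = np.zeros(n_factors)
    x_scales = np.ones((n_factors, p))
    y_scales = np.ones(n_factors)
    T = np.zeros((n, n_factors))

    for k in range(n_factors):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw == 0:
            if not strict:
                break
            raise np.linalg.LinAlgError(
                f"X residual orthogonal to y residual at factor {k + 1}; "
                "reduce n_factors"
            )
        w /= nw
        t = Xr @ w
        tt = t @ t
        if tt == 0:
            if not strict:
                break
            raise np.linalg.LinAlgError(f"zero-variance score at factor {k + 1}")
        pk = Xr.T @ t / tt
        qk = yr @ t / tt
        Xr -= np.outer(t, pk)
        yr = yr - qk * t
        W[k], P[k], q[k], T[:, k] = w, pk, qk, t

        if variant == "modified" and k < n_factors - 1:
            sx = Xr.std(axis=0, ddof=1)
            sx[sx == 0] = 1.0  # exhausted wavelengths stay unscaled
            sy = yr.std(ddof=1)
            if sy == 0:
                sy = 1.0  # y fully explained; later factors contribute nothing
            Xr /= sx
            yr = yr / sy
            x_scales[k] = sx
            y_scales[k] = sy
    return W, P, q, x_scales, y_scales, T


def _replay(model: CalibrationModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run new centred data through the stored factor sequence.

    Returns (scores, predictions).  Predictions accumulate each factor's y
    contribution rescaled back to original units by the product of y-scales
    applied before that factor.
    """
    Xr = np.atleast_2d(np.asarray(X, dtype=float)) - model.x_mean
    n = Xr.shape[0]
    T = np.zeros((n, model.n_factors))
    yhat = np.full(n, model.y_mean, dtype=float)
    y_unit = 1.0  # original-units value of one scaled-residual unit
    for k in range(model.n_factors):
        t = Xr @ model.weights[k]
        T[:, k] = t
        yhat += y_unit * model.y_loadings[k] * t
        Xr = Xr - np.outer(t, model.x_loadings[k])
        Xr = Xr / model.x_scales[k]
        y_unit *= model.y_scales[k]
    return T, yhat


def fit_pls1(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    variant: str = "modified",
    recipe: str | None = None,
    seed: int | None = None,
    strict: bool = True,
) -> CalibrationModel:
    """Fit a mean-centred PLS1 (or modified-PLS) calibration.

    Parameters
    ----------
    X : (n_samples, n_wavelengths) preprocessed spectra
    y : (n_samples,) analyte values
    n_factors : number of latent factors, 1 <= n_factors <= min(n-1, p)
    variant : "standard" (plain NIPALS PLS1) or "modified" (residuals
        standardized between factor extractions)
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size} values")
    if variant not in ("standard", "modified"):
        raise ValueError(f"variant must be 'standard' or 'modified', got {variant!r}")
    if not (1 <= n_factors <= min(n - 1, p)):
        raise ValueError(
            f"n_factors must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {n_factors}"
        )
    if np.std(y) == 0:
        raise ValueError("y has zero variance; nothing to calibrate")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, x_scales, y_scales, T = _nipals_pls1(
        X - x_mean, y - y_mean, n_factors, variant, strict=strict
    )

    model = CalibrationModel(
        variant=variant,
        n_factors=n_factors,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scales=x_scales,
        y_scales=y_scales,
        coefficients=np.zeros(p),
        intercept=0.0,
        recipe=recipe,
        seed=seed,
    )
    # the prediction map is linear; extract slope/intercept by probing it
    _, y0 = _replay(model, x_mean[None, :])
    B_rows, _ = _replay_linear(model)
    model.coefficients = B_rows
    model.intercept = float(y0[0] - x_mean @ B_rows)

    model.scores = T
    _, fitted = _replay(model, X)
    model.fitted = fitted
    resid = fitted - y
    dof = max(n - n_factors - 1, 1)
    model.sec = float(np.sqrt(np.sum(resid**2) / dof))
    sst = float(np.sum((y - y_mean) ** 2))
    model.r2_cal = float(1.0 - np.sum(resid**2) / sst)
    return model


def _replay_linear(model: CalibrationModel) -> tuple[np.ndarray, float]:
    """Coefficient vector of the (linear) centred prediction map."""
    p = model.n_wavelengths
    Xr = np.eye(p)
    B = np.zeros(p)
    y_unit = 1.0
    for k in range(model.n_factors):
        t = Xr @ model.weights[k]
        B += y_unit * model.y_loadings[k] * t
        Xr = Xr - np.outer(t, model.x_loadings[k])
        Xr = Xr / model.x_scales[k]
        y_unit *= model.y_scales[k]
    return B, 0.0


def predict(model: CalibrationModel, X_new: np.ndarray) -> np.ndarray:
    """Predict analyte values for spectra preprocessed with the model's recipe."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_wavelengths:
        raise ValueError(
            f"grid mismatch: model expects {model.n_wavelengths} wavelengths, "
            f"got {X_new.shape[1]}"
        )
    _, yhat = _replay(model, X_new)
    return yhat


@dataclass
class CVResult:
    """Cross-validation curve and the factor count it selects."""

    secv_by_factors: np.ndarray     # (max_factors,) SECV per factor count
    r2_cv_by_factors: np.ndarray
    selected_factors: int
    folds: list[np.ndarray]
    seed: int

    @property
    def secv(self) -> float:
        return float(self.secv_by_factors[self.selected_factors - 1])

    @property
    def r2_cv(self) -> float:
        return float(self.r2_cv_by_factors[self.selected_factors - 1])


def _make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks over a seeded shuffle; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, k)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 6,
    max_factors: int = 10,
    variant: str = "modified",
    seed: int = 0,
    parsimony: float = 1.02,
) -> CVResult:
    """k-fold cross-validation of the factor count.

    SECV for a factor count m is sqrt(mean squared out-of-fold residual)
    using m-factor fits.  The selected count is the smallest m whose SECV is
    within ``parsimony`` (default 2%) of the minimum — the fewest factors
    near the optimum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    if k < 2:
        raise ValueError("need at least 2 folds")
    folds = _make_folds(n, k, seed)
    smallest_train = n - max(f.size for f in folds)
    max_factors = min(max_factors, smallest_train - 1, X.shape[1])
    if max_factors < 1:
        raise ValueError("too few samples per fold for even one factor")

    press = np.zeros(max_factors)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Xtr, ytr = X[mask], y[mask]
        Xte, yte = X[fold], y[fold]
        model = fit_pls1(Xtr, ytr, max_factors, variant=variant, strict=False)
        # truncating the factor sequence reproduces the smaller fits exactly
        for m in range(1, max_factors + 1):
            sub = _truncate(model, m)
            resid = predict(sub, Xte) - yte
            press[m - 1] += np.sum(resid**2)

    secv = np.sqrt(press / n)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - press / sst
    threshold = parsimony * secv.min()
    selected = int(np.argmax(secv <= threshold)) + 1
    return CVResult(secv, r2, selected, folds, seed)


def _truncate(model: CalibrationModel, m: int) -> CalibrationModel:
    """View of the first m factors of a fitted model (NIPALS is sequential)."""
    if m == model.n_factors:
        return model
    return CalibrationModel(
        variant=model.variant,
        n_factors=m,
        x_mean=model.x_mean,
        y_mean=model.y_mean,
        weights=model.weights[:m],
        x_loadings=model.x_loadings[:m],
        y_loadings=model.y_loadings[:m],
        x_scales=model.x_scales[:m],
        y_scales=model.y_scales[:m],
        coefficients=model.coefficients,  # not rebuilt for truncated views
        intercept=model.intercept,
    )


def split_calibration_validation(
    sample_ids: list,
    y: np.ndarray | None = None,
    fraction: float = 0.75,
    seed: int = 0,
    strategy: str = "rank-stratified",
) -> tuple[list, list]:
    """Split sample ids into calibration and validation sets.

    ``strategy='rank-stratified'`` (default) sorts samples by analyte value
    and sends every ceil(1/(1-fraction))-th rank to validation, preserving
    range coverage; ``'random'`` draws a seeded random subset.  Returns
    (calibration_ids, validation_ids), disjoint and exhaustive.
    """
    ids = list(sample_ids)
    n = len(ids)
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if strategy == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_cal = int(round(fraction * n))
        cal_idx = np.sort(perm[:n_cal])
        val_idx = np.sort(perm[n_cal:])
    elif strategy == "rank-stratified":
        if y is None:
            raise ValueError("rank-stratified splitting needs analyte values y")
        y = np.asarray(y, dtype=float).ravel()
        if y.size != n:
            raise ValueError("y must have one value per sample id")
        every = int(round(1.0 / (1.0 - fraction)))
        if every < 2:
            raise ValueError("fraction too small for rank stratification")
        order = np.argsort(y, kind="stable")
        # start inside the range so the extremes anchor the calibration set
        val_pos = order[every // 2::every]
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_pos] = True
        cal_idx = np.flatnonzero(~val_mask)
        val_idx = np.flatnonzero(val_mask)
    else:
        raise ValueError(f"unknown split strategy {strategy!r}")
    return [ids[i] for i in cal_idx], [ids[i] for i in val_idx]


def save_model(model: CalibrationModel, path) -> None:
    """Serialize a model as JSON scalars plus a companion .npz for arrays."""
    path = Path(path)
    arrays = {
        "x_mean": model.x_mean,
        "weights": model.weights,
        "x_loadings": model.x_loadings,
        "y_loadings": model.y_loadings,
        "x_scales": model.x_scales,
        "y_scales": model.y_scales,
        "coefficients": model.coefficients,
    }
    npz_path = path.with_suffix(".npz")
    np.savez(npz_path, **arrays)
    scalars = {
        "variant": model.variant,
        "n_factors": model.n_factors,
        "y_mean": model.y_mean,
        "intercept": model.intercept,
        "sec": model.sec,
        "r2_cal": model.r2_cal,
        "secv": model.secv,
        "r2_cv": model.r2_cv,
        "recipe": model.recipe,
        "outlier_log": model.outlier_log,
        "seed": model.seed,
        "arrays": npz_path.name,
    }
    path.write_text(json.dumps(scalars, indent=2))


def load_model(path) -> CalibrationModel:
    path = Path(path)
    scalars = json.loads(path.read_text())
    arrays = np.load(path.parent / scalars["arrays"])
    return CalibrationModel(
        variant=scalars["variant"],
        n_factors=scalars["n_factors"],
        x_mean=arrays["x_mean"],
        y_mean=scalars["y_mean"],
        weights=arrays["weights"],
        x_loadings=arrays["x_loadings"],
        y_loadings=arrays["y_loadings"],
        x_scales=arrays["x_scales"],
        y_scales=arrays["y_scales"],
        coefficients=arrays["coefficients"],
        intercept=scalars["intercept"],
        sec=scalars["sec"],
        r2_cal=scalars["r2_cal"],
        secv=scalars["secv"],
        r2_cv=scalars["r2_cv"],
        recipe=scalars["recipe"],
        outlier_log=scalars["outlier_log"],
        seed=scalars["seed"],
    )
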