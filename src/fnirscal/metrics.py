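"""Figures of merit, model-quality classification, and the recipe grid search.

Definitions follow standard NIRS reporting:

- SEC   = sqrt(SSE / (n - n_factors - 1)), calibration standard error
- SECV  = sqrt(mean squared cross-validated residual)
- bias  = mean(yhat - y) on the validation set
- SEP   = sqrt(sum((yhat - y - bias)^2) / (n - 1)), bias-corrected; the
  uncorrected RMSEP is also reported since conventions differ
- slope = least-squares slope of the reference regressed on the prediction
  (the alternate prediction-on-reference slope is logged too)
- RPD   = sd(y_val) / SEP;  RER = range(y_val) / SEP

Quality classes: RPD >= 3 with RER >= 10 supports quantitative use; RPD in
[2, 3) supports screening (with 2.0–2.5 flagged as acceptable quantitative
per the Saeys convention); anything lower is unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fnirscal.outliers import eliminate_outliers
from fnirscal.preprocessing import Recipe
from fnirscal.regression import (
    cross_validate,
    fit_pls1,
    predict,
    split_calibration_validation,
)
from fnirscal.spectra_io import ReferenceTable, SpectraSet

__all__ = [
    "ValidationReport",
    "calibration_stats",
    "validation_stats",
    "classify_model",
    "grid_search",
    "DEFAULT_SCATTER_SET",
    "DEFAULT_TREATMENT_SET",
]

#: the scatter corrections and math treatments screened during model selection
DEFAULT_SCATTER_SET = ("SNV", "D", "SNV+D", "MSC")
DEFAULT_TREATMENT_SET = ("1.4.4.1", "2.4.4.1", "1.5.5.1", "2.5.5.1")


def calibration_stats(y: np.ndarray, y_hat: np.ndarray, n_factors: int) -> tuple[float, float]:
    """(SEC, R²_CAL) with SEC on n - n_factors - 1 degrees of freedom."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    n = y.size
    if n <= n_factors + 1:
        raise ValueError(f"need n > n_factors + 1 = {n_factors + 1}, got n = {n}")
    sse = float(np.sum((y_hat - y) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("reference values have zero variance")
    sec = np.sqrt(sse / (n - n_factors - 1))
    return float(sec), float(1.0 - sse / sst)


@dataclass
class ValidationReport:
    """External-validation figures of merit and the quality class they imply."""

    n: int
    r2_val: float
    sep: float
    rmsep: float
    bias: float
    slope: float
    slope_alt: float
    rpd: float
    rer: float
    quality: str = ""

    def __post_init__(self) -> None:
        if not self.quality:
            self.quality = classify_model(self)


def validation_stats(y: np.ndarray, y_hat: np.ndarray) -> ValidationReport:
    """Validation report for reference values y against predictions y_hat.

    SEP is bias-corrected; RPD and RER divide the validation-set standard
    deviation and range by SEP.  A zero SEP yields infinite RPD/RER with a
    warning rather than an error.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("validation needs at least 3 samples")
    err = y_hat - y
    bias = float(err.mean())
    sep = float(np.sqrt(np.sum((err - bias) ** 2) / (n - 1)))
    rmsep = float(np.sqrt(np.mean(err**2)))
    sd = float(np.std(y, ddof=1))
    rng = float(y.max() - y.min())
    if sd == 0:
        raise ValueError("validation reference values have zero variance")
    # slope of reference on predicted (reported), and the alternate direction
    vh = float(np.var(y_hat))
    cov = float(np.mean((y - y.mean()) * (y_hat - y_hat.mean())))
    slope = cov / vh if vh > 0 else np.nan
    slope_alt = cov / float(np.var(y))
    r = np.corrcoef(y, y_hat)[0, 1] if vh > 0 else np.nan
    r2 = float(r**2) if np.isfinite(r) else np.nan
    if sep == 0:
        warnings.warn("SEP is zero; RPD and RER reported as +inf", RuntimeWarning)
        rpd = rer = np.inf
    else:
        rpd = sd / sep
        rer = rng / sep
    return ValidationReport(
        n=n, r2_val=r2, sep=sep, rmsep=rmsep, bias=bias,
        slope=float(slope), slope_alt=float(slope_alt), rpd=float(rpd), rer=float(rer),
    )


def classify_model(report: "ValidationReport | None" = None,
                   rpd: float | None = None, rer: float | None = None) -> str:
    """Classify model quality from RPD (and RER).

    Returns ``"quantitative"`` (RPD >= 3 and RER >= 10),
    ``"acceptable quantitative"`` (2.0 <= RPD <= 2.5, Saeys rule),
    ``"screening"`` (otherwise RPD >= 2), or ``"unreliable"``.
    """
    if report is not None:
        rpd, rer = report.rpd, report.rer
    if rpd is None or rer is None:
        raise ValueError("need either a report or explicit rpd/rer")
    if rpd >= 3 and rer >= 10:
        return "quantitative"
    if 2.0 <= rpd <= 2.5:
        return "acceptable quantitative"
    if rpd >= 2.0:
        return "screening"
    return "unreliable"


GRID_COLUMNS = [
    "recipe", "n_factors", "variant",
    "n_cal", "n_val", "n_outliers", "outlier_fraction",
    "r2_cal", "sec", "r2_cv", "secv",
    "r2_val", "sep", "bias", "slope", "rpd", "rer", "quality", "error",
]


def grid_search(
    spectra: SpectraSet,
    reference: ReferenceTable,
    analyte: str,
    scatter_set: tuple[str, ...] = DEFAULT_SCATTER_SET,
    treatment_set: tuple[str, ...] = DEFAULT_TREATMENT_SET,
    variant: str = "modified",
    split_fraction: float = 0.75,
    split_strategy: str = "rank-stratified",
    cv_folds: int = 6,
    max_factors: int = 10,
    outlier_passes: int = 2,
    t_crit: float = 2.5,
    h_crit: float = 10.0,
    outlier_cap: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Screen every scatter x treatment recipe the way model selection does.

    For each recipe: rank-stratified 75/25 split, two outlier-elimination
    passes on the calibration set, cross-validated factor selection, final
    fit, and external validation on the held-out quarter.  Rows are ranked
    by (R²_CV desc, SECV asc, n_factors asc).  A recipe that fails raises
    nothing: its row carries the error message.

    Returns ``(table, models)`` with ``models`` mapping recipe string to the
    fitted :class:`~fnirscal.regression.CalibrationModel` and its report.
    """
    reference = reference.aligned_to(spectra)
    y_all = reference.column(analyte)
    cal_ids, val_ids = split_calibration_validation(
        spectra.sample_ids, y=y_all, fraction=split_fraction,
        seed=seed, strategy=split_strategy,
    )
    pos = {sid: i for i, sid in enumerate(spectra.sample_ids)}
    cal_idx = [pos[s] for s in cal_ids]
    val_idx = [pos[s] for s in val_ids]

    rows = []
    models: dict[str, dict] = {}
    for sc in scatter_set:
        for tr in treatment_set:
            recipe_name = f"{sc}/{tr}"
            try:
                row, bundle = _evaluate_recipe(
                    recipe_name, spectra, y_all, cal_idx, val_idx,
                    variant=variant, cv_folds=cv_folds, max_factors=max_factors,
                    outlier_passes=outlier_passes, t_crit=t_crit, h_crit=h_crit,
                    outlier_cap=outlier_cap, seed=seed,
                )
                models[recipe_name] = bundle
            except Exception as exc:  # a failing recipe becomes a row, not a crash
                row = dict.fromkeys(GRID_COLUMNS, np.nan)
                row.update(recipe=recipe_name, variant=variant, error=str(exc))
            rows.append(row)

    table = pd.DataFrame(rows, columns=GRID_COLUMNS)
    table = table.sort_values(
        by=["r2_cv", "secv", "n_factors"],
        ascending=[False, True, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    return table, models


def _evaluate_recipe(
    recipe_name, spectra, y_all, cal_idx, val_idx, *,
    variant, cv_folds, max_factors, outlier_passes,
    t_crit, h_crit, outlier_cap, seed,
) -> tuple[dict, dict]:
    recipe = Recipe.parse(recipe_name)
    cal_raw = spectra.select(cal_idx)
    val_raw = spectra.select(val_idx)
    recipe.fit(cal_raw)  # MSC reference = calibration mean
    cal = recipe.apply(cal_raw)
    val = recipe.apply(val_raw)
    y_cal = y_all[cal_idx]
    y_val = y_all[val_idx]

    kept, olog = eliminate_outliers(
        cal.absorbance, y_cal, sample_ids=cal.sample_ids,
        variant=variant, passes=outlier_passes,
        t_crit=t_crit, h_crit=h_crit, cap=outlier_cap,
        cv_folds=cv_folds, max_factors=max_factors, seed=seed,
    )
    Xc, yc = cal.absorbance[kept], y_cal[kept]
    cv = cross_validate(Xc, yc, k=min(cv_folds, len(yc)),
                        max_factors=max_factors, variant=variant, seed=seed)
    model = fit_pls1(Xc, yc, cv.selected_factors, variant=variant,
                     recipe=recipe_name, seed=seed)
    model.secv = cv.secv
    model.r2_cv = cv.r2_cv
    model.outlier_log = olog.to_dict()

    report = validation_stats(y_val, predict(model, val.absorbance))
    row = {
        "recipe": recipe_name,
        "n_factors": model.n_factors,
        "variant": variant,
        "n_cal": len(yc),
        "n_val": len(y_val),
        "n_outliers": olog.n_removed,
        "outlier_fraction": olog.fraction_removed,
        "r2_cal": model.r2_cal,
        "sec": model.sec,
        "r2_cv": model.r2_cv,
        "secv": model.secv,
        "r2_val": report.r2_val,
        "sep": report.sep,
        "bias": report.bias,
        "slope": report.slope,
        "rpd": report.rpd,
        "rer": report.rer,
        "quality": report.quality,
        "error": "",
    }
    bundle = {
        "model": model,
        "report": report,
        "recipe": recipe,
        "y_val": y_val,
        "y_val_hat": predict(model, val.absorbance),
        "cv": cv,
    }
    return row, bundle
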