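"""Two-pass chemical (t) and spectral (GH) outlier elimination.

Chemical outliers have a large standardized prediction residual,
t = |yhat - y| / SEC >= 2.5 by default.  Spectral outliers sit far from the
calibration cloud in PLS score space: GH is the squared Mahalanobis distance
of a sample's score vector from the score centroid divided by the number of
factors, flagged at GH >= 10 by default.  Up to two fit/flag/remove passes
are run, and cumulative removals are capped (default 10% of the samples),
dropping the worst offenders first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fnirscal.regression import CalibrationModel, cross_validate, fit_pls1, predict

__all__ = ["OutlierLog", "t_statistic", "gh_statistic", "eliminate_outliers"]


@dataclass
class OutlierPass:
    removed_ids: list
    reasons: list[str]          # "t", "H", or "t+H" per removed sample
    statistics: list[float]     # the offending statistic value (max of scaled t/GH)


@dataclass
class OutlierLog:
    """Record of which samples each elimination pass removed and why."""

    passes: list[OutlierPass] = field(default_factory=list)
    n_total: int = 0
    cap: float = 0.10

    @property
    def removed_ids(self) -> list:
        return [sid for p in self.passes for sid in p.removed_ids]

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_removed": self.n_removed,
            "fraction_removed": self.fraction_removed,
            "cap": self.cap,
            "passes": [
                {
                    "removed_ids": [str(s) for s in p.removed_ids],
                    "reasons": p.reasons,
                    "statistics": [float(v) for v in p.statistics],
                }
                for p in self.passes
            ],
        }


def t_statistic(residuals: np.ndarray, sec: float) -> np.ndarray:
    """Standardized residual t_i = |yhat_i - y_i| / SEC."""
    residuals = np.asarray(residuals, dtype=float)
    if sec <= 0:
        if np.any(residuals != 0):
            raise ValueError("SEC is zero but residuals are nonzero")
        return np.zeros_like(residuals)
    return np.abs(residuals) / sec


def gh_statistic(scores: np.ndarray) -> np.ndarray:
    """Global H: squared Mahalanobis distance in score space over n_factors.

    The covariance of the scores (ddof=1) defines the metric; with a single
    factor GH reduces to the squared standardized score.
    """
    T = np.atleast_2d(np.asarray(scores, dtype=float))
    n, k = T.shape
    if n < 2:
        raise ValueError("GH needs at least 2 samples")
    centred = T - T.mean(axis=0)
    cov = centred.T @ centred / (n - 1)
    cov = np.atleast_2d(cov)
    if np.linalg.matrix_rank(cov) < k:
        raise np.linalg.LinAlgError("singular score covariance; reduce n_factors")
    sol = np.linalg.solve(cov, centred.T)
    d2 = np.einsum("ij,ji->i", centred, sol)
    return d2 / k


def eliminate_outliers(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: list | None = None,
    n_factors: int | None = None,
    variant: str = "modified",
    passes: int = 2,
    t_crit: float = 2.5,
    h_crit: float = 10.0,
    cap: float = 0.10,
    cv_folds: int = 6,
    max_factors: int = 10,
    seed: int = 0,
    use_secv: bool = False,
) -> tuple[np.ndarray, OutlierLog]:
    """Iteratively remove chemical (t) and spectral (GH) outliers.

    Each pass fits a calibration on the currently kept samples (selecting the
    factor count by cross-validation unless ``n_factors`` is given), flags
    samples with t >= t_crit or GH >= h_crit, and removes them worst-first —
    ranked by max(t/t_crit, GH/h_crit) — without letting cumulative removals
    exceed ``cap`` times the original sample count.  Stops early when a pass
    flags nothing.

    ``use_secv=True`` standardizes residuals by SECV instead of SEC.

    Returns ``(kept_indices_into_X, OutlierLog)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    ids = list(sample_ids) if sample_ids is not None else list(range(n))
    if len(ids) != n:
        raise ValueError("sample_ids must match X rows")

    log = OutlierLog(n_total=n, cap=cap)
    kept = np.arange(n)
    budget = int(np.floor(cap * n))

    for _ in range(passes):
        if n_factors is None:
            cv = cross_validate(
                X[kept], y[kept], k=min(cv_folds, kept.size),
                max_factors=max_factors, variant=variant, seed=seed,
            )
            m = cv.selected_factors
            denom_cv = cv.secv
        else:
            m = n_factors
            denom_cv = None
        if kept.size < 2 * m:
            raise ValueError(
                f"only {kept.size} samples left for a {m}-factor fit; refusing to proceed"
            )
        model = fit_pls1(X[kept], y[kept], m, variant=variant)
        resid = predict(model, X[kept]) - y[kept]
        denom = denom_cv if (use_secv and denom_cv) else model.sec
        t = t_statistic(resid, denom)
        gh = gh_statistic(model.scores)
        severity = np.maximum(t / t_crit, gh / h_crit)
        flagged = np.flatnonzero((t >= t_crit) | (gh >= h_crit))
        if flagged.size == 0:
            break
        room = budget - log.n_removed
        if room <= 0:
            break
        order = flagged[np.argsort(-severity[flagged], kind="stable")]
        drop_local = order[:room]
        reasons = [
            ("t+H" if (t[i] >= t_crit and gh[i] >= h_crit)
             else ("t" if t[i] >= t_crit else "H"))
            for i in drop_local
        ]
        log.passes.append(
            OutlierPass(
                removed_ids=[ids[kept[i]] for i in drop_local],
                reasons=reasons,
                statistics=[float(severity[i]) for i in drop_local],
            )
        )
        keep_mask = np.ones(kept.size, dtype=bool)
        keep_mask[drop_local] = False
        kept = kept[keep_mask]

    return kept, log
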