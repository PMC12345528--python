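"""Scatter corrections and WinISI-style derivative math treatments.

A preprocessing recipe is a scatter correction (none, SNV, detrend, SNV+D,
or MSC) followed by a four-digit gap-segment derivative code "d.g.s1.s2":
derivative order, gap in data points, and two running-average smoothing
widths.  Recipes render as strings such as ``"SNV/1.4.4.1"`` and are the
rows of the model-selection grid.

Conventions, since the commercial software that popularised these codes does
not document its internals:

- SNV uses the sample standard deviation (ddof=1).
- Detrend removes a degree-2 polynomial baseline (the standard SNV-D form);
  the degree is an argument.
- The derivative is the Norris gap difference applied to a spectrum smoothed
  by two successive centred running means (smooth first, then difference;
  a flag reverses the order).  First-derivative offsets for odd gaps use
  floor(g/2)/ceil(g/2).
- Points whose smoothing or difference window is incomplete are dropped and
  the wavelength grid shortened — no padding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from fnirscal.spectra_io import SpectraSet

__all__ = [
    "MathTreatment",
    "ScatterCorrection",
    "Recipe",
    "snv",
    "detrend",
    "msc",
    "gap_segment_derivative",
    "SCATTER_KINDS",
]

SCATTER_KINDS = ("none", "SNV", "D", "SNV+D", "MSC")


@dataclass(frozen=True)
class MathTreatment:
    """Four-digit derivative code d.g.s1.s2 (all counts in data points)."""

    derivative: int
    gap: int
    smooth1: int
    smooth2: int

    def __post_init__(self) -> None:
        if self.derivative not in (0, 1, 2):
            raise ValueError(f"derivative order must be 0, 1 or 2, got {self.derivative}")
        if self.gap < 1 or self.smooth1 < 1 or self.smooth2 < 1:
            raise ValueError("gap and smoothing widths must be >= 1")

    @classmethod
    def parse(cls, code: str) -> "MathTreatment":
        parts = code.strip().split(".")
        if len(parts) != 4 or not all(p.isdigit() for p in parts):
            raise ValueError(f"math treatment must be 'd.g.s1.s2' with integer digits, got {code!r}")
        return cls(*(int(p) for p in parts))

    def __str__(self) -> str:
        return f"{self.derivative}.{self.gap}.{self.smooth1}.{self.smooth2}"

    @property
    def min_length(self) -> int:
        """Minimum spectrum length that leaves at least one output point."""
        smooth_loss = (self.smooth1 - 1) + (self.smooth2 - 1)
        if self.derivative == 0:
            deriv_loss = 0
        elif self.derivative == 1:
            deriv_loss = self.gap
        else:
            deriv_loss = 2 * self.gap
        return smooth_loss + deriv_loss + 1


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to sd 1.

    Accepts a single spectrum or a (samples x wavelengths) batch; uses the
    sample standard deviation (ddof=1).  Constant spectra are degenerate.
    """
    X = np.asarray(spectra, dtype=float)
    one_dim = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] < 2:
        raise ValueError("SNV needs at least 2 wavelengths")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        i = int(np.argwhere(sd.ravel() == 0)[0][0])
        raise ValueError(f"degenerate (constant) spectrum at row {i}: SNV undefined")
    out = (X - mu) / sd
    return out[0] if one_dim else out


def detrend(spectra: np.ndarray, wavelengths: np.ndarray, order: int = 2) -> np.ndarray:
    """Residual after least-squares polynomial baseline fit on wavelength."""
    X = np.asarray(spectra, dtype=float)
    one_dim = X.ndim == 1
    X = np.atleast_2d(X)
    wl = np.asarray(wavelengths, dtype=float)
    if X.shape[1] != wl.size:
        raise ValueError("spectra and wavelength grid disagree in length")
    if wl.size <= order + 1:
        raise ValueError(f"need more than {order + 1} points to detrend at order {order}")
    # scale wavelengths to [-1, 1] for conditioning; residuals are unchanged
    w = 2 * (wl - wl.min()) / (wl.max() - wl.min()) - 1
    basis = np.vander(w, order + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(basis, X.T, rcond=None)
    if rank < order + 1:
        raise ValueError("rank-deficient polynomial basis in detrend")
    out = X - (basis @ coef).T
    return out[0] if one_dim else out


def msc(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a fixed reference spectrum.

    Each spectrum x is regressed as x = a + b*reference and returned as
    (x - a)/b, undoing per-sample affine scatter.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    ref = np.asarray(reference, dtype=float)
    if X.shape[1] != ref.size:
        raise ValueError("spectra and MSC reference disagree in length")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(np.abs(b) < 1e-8):
        i = int(np.argwhere(np.abs(b) < 1e-8)[0][0])
        raise ValueError(f"degenerate spectrum at row {i}: MSC slope ~ 0")
    a = X.mean(axis=1) - b * ref.mean()
    out = (X - a[:, None]) / b[:, None]
    return out[0] if np.asarray(spectra).ndim == 1 else out


def _running_mean(X: np.ndarray, width: int) -> np.ndarray:
    """Centred running mean of odd or even width; 'valid' truncation."""
    if width == 1:
        return X
    kernel = np.full(width, 1.0 / width)
    n = X.shape[1] - width + 1
    out = np.empty((X.shape[0], n))
    for i in range(X.shape[0]):
        out[i] = np.convolve(X[i], kernel, mode="valid")
    return out


def gap_segment_derivative(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    treatment: MathTreatment,
    smooth_first: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Norris gap-segment derivative per the four-digit treatment code.

    The spectrum is smoothed by running means of widths s1 then s2, and the
    derivative taken as a gap difference in point units: first derivative
    a(i + ceil(g/2)) - a(i - floor(g/2)); second derivative
    a(i-g) - 2 a(i) + a(i+g).  Edge points without a complete window are
    dropped; the returned grid is shortened (and shifted by half a step when
    a smoothing width is even).

    Returns ``(derived_spectra, derived_wavelengths)``.
    """
    X = np.asarray(spectra, dtype=float)
    one_dim = X.ndim == 1
    X = np.atleast_2d(X)
    wl = np.asarray(wavelengths, dtype=float)
    if X.shape[1] != wl.size:
        raise ValueError("spectra and wavelength grid disagree in length")
    if X.shape[1] < treatment.min_length:
        raise ValueError(
            f"treatment {treatment} needs at least {treatment.min_length} points, "
            f"got {X.shape[1]}"
        )
    step = wl[1] - wl[0]

    def _smooth(mat: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        for width in (treatment.smooth1, treatment.smooth2):
            mat = _running_mean(mat, width)
            # centre of a width-w window sits (w-1)/2 points into the grid
            off = (width - 1) / 2.0
            grid = grid[: mat.shape[1]] + off * step
        return mat, grid

    def _difference(mat: np.ndarray, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = treatment.gap
        d = treatment.derivative
        if d == 0:
            return mat, grid
        if d == 1:
            lo, hi = g // 2, g - g // 2  # floor/ceil split for odd gaps
            out = mat[:, lo + hi:] - mat[:, : mat.shape[1] - lo - hi]
            grid = grid[lo : lo + out.shape[1]] + (hi - lo) / 2.0 * step
            return out, grid
        out = mat[:, 2 * g:] - 2 * mat[:, g:-g] + mat[:, : -2 * g]
        return out, grid[g : g + out.shape[1]]

    if smooth_first:
        X, wl = _smooth(X, wl)
        X, wl = _difference(X, wl)
    else:
        X, wl = _difference(X, wl)
        X, wl = _smooth(X, wl)
    return (X[0], wl) if one_dim else (X, wl)


@dataclass
class ScatterCorrection:
    """One of {none, SNV, D, SNV+D, MSC}; MSC stores its reference at fit time.

    The MSC reference is the calibration-set mean spectrum, fixed by
    :meth:`fit` and reused unchanged for any later (validation) spectra.
    """

    kind: str = "none"
    detrend_order: int = 2
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCATTER_KINDS:
            raise ValueError(f"unknown scatter correction {self.kind!r}; choose from {SCATTER_KINDS}")

    def fit(self, spectra: np.ndarray) -> "ScatterCorrection":
        if self.kind == "MSC" and self.reference is None:
            self.reference = np.atleast_2d(np.asarray(spectra, dtype=float)).mean(axis=0)
        return self

    def transform(self, spectra: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.atleast_2d(np.asarray(spectra, dtype=float))
        if self.kind == "SNV":
            return np.atleast_2d(snv(spectra))
        if self.kind == "D":
            return np.atleast_2d(detrend(spectra, wavelengths, self.detrend_order))
        if self.kind == "SNV+D":
            return np.atleast_2d(detrend(snv(spectra), wavelengths, self.detrend_order))
        if self.reference is None:
            raise RuntimeError("MSC correction used before fit(); reference spectrum unset")
        return np.atleast_2d(msc(spectra, self.reference))


_RECIPE_RE = re.compile(r"^\s*(?P<scatter>[^/]+?)\s*/\s*(?P<code>\d+\.\d+\.\d+\.\d+)\s*$")


@dataclass
class Recipe:
    """A named preprocessing recipe: scatter correction then math treatment.

    Renders as e.g. ``"SNV+D/2.4.4.1"``.  The scatter step runs first
    (SNV+D = SNV then detrend), then the gap-segment derivative; set
    ``scatter_first=False`` to reverse.
    """

    scatter: ScatterCorrection
    treatment: MathTreatment
    scatter_first: bool = True
    smooth_first: bool = True

    @classmethod
    def parse(cls, text: str, **kwargs) -> "Recipe":
        m = _RECIPE_RE.match(text)
        if not m:
            raise ValueError(f"recipe must look like 'SNV/1.4.4.1', got {text!r}")
        return cls(
            scatter=ScatterCorrection(kind=m.group("scatter")),
            treatment=MathTreatment.parse(m.group("code")),
            **kwargs,
        )

    def __str__(self) -> str:
        return f"{self.scatter.kind}/{self.treatment}"

    def fit(self, spectra: SpectraSet | np.ndarray) -> "Recipe":
        """Fix any data-dependent state (the MSC reference) on calibration data."""
        A = spectra.absorbance if isinstance(spectra, SpectraSet) else np.asarray(spectra)
        self.scatter.fit(A)
        return self

    def apply(self, spectra: SpectraSet) -> SpectraSet:
        """Apply the full recipe, returning a new SpectraSet on the shortened grid."""
        A, wl = spectra.absorbance, spectra.wavelengths
        if self.scatter_first:
            A = self.scatter.transform(A, wl)
            A, wl = gap_segment_derivative(A, wl, self.treatment, self.smooth_first)
        else:
            A, wl = gap_segment_derivative(A, wl, self.treatment, self.smooth_first)
            A = self.scatter.transform(A, wl)
        meta = spectra.meta.copy() if spectra.meta is not None else None
        return SpectraSet(list(spectra.sample_ids), wl, A, meta)
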