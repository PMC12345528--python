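"""Marker-based dry-matter digestibility and cross-marker agreement.

An indigestible marker fed at a known dietary concentration concentrates in
excreta as dry matter disappears; the mass balance gives

    DMD = 1 - (marker concentration in diet) / (marker concentration in excreta)

with both concentrations on the same basis (element or oxide) and in the
same units.  Dietary oxides (TiO2, Yb2O3) are converted to element basis
with standard atomic masses before the ratio is formed; the ratio of
mixed-basis concentrations is refused.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMeasurement",
    "oxide_to_element",
    "element_mass_fraction",
    "dmd_from_marker",
    "marker_agreement",
]

# standard atomic masses (u), 4-decimal precision
_ATOMIC_MASS = {"Ti": 47.8670, "Yb": 173.0450, "O": 15.9994}

#: element mass fraction of each supported oxide species
_OXIDE_FRACTIONS = {
    "TiO2": _ATOMIC_MASS["Ti"] / (_ATOMIC_MASS["Ti"] + 2 * _ATOMIC_MASS["O"]),
    "Yb2O3": 2 * _ATOMIC_MASS["Yb"] / (2 * _ATOMIC_MASS["Yb"] + 3 * _ATOMIC_MASS["O"]),
}


def element_mass_fraction(species: str) -> float:
    """Element mass fraction of an oxide species (Ti/TiO2, 2·Yb/Yb2O3)."""
    try:
        return _OXIDE_FRACTIONS[species]
    except KeyError:
        raise ValueError(
            f"unknown oxide species {species!r}; supported: {sorted(_OXIDE_FRACTIONS)}"
        ) from None


def oxide_to_element(amount, species: str):
    """Convert an oxide amount to the contained element amount (same units).

    Linear, so it commutes with addition and applies elementwise to arrays.
    """
    amount = np.asarray(amount, dtype=float)
    if np.any(amount < 0):
        raise ValueError("oxide amount must be >= 0")
    out = amount * element_mass_fraction(species)
    return float(out) if out.ndim == 0 else out


@dataclass
class MarkerMeasurement:
    """Diet and excreta concentrations of one marker, unit- and basis-tagged."""

    marker: str                  # Yb | Ti | PEG | ADF
    diet_concentration: float    # same units as excreta_concentration
    excreta_concentration: float | np.ndarray
    basis: str = "element"       # element | oxide

    def __post_init__(self) -> None:
        if self.basis not in ("element", "oxide"):
            raise ValueError(f"basis must be 'element' or 'oxide', got {self.basis!r}")
        if self.diet_concentration < 0 or np.any(np.asarray(self.excreta_concentration) < 0):
            raise ValueError("marker concentrations must be >= 0")


def dmd_from_marker(measurement: MarkerMeasurement):
    """Dry-matter digestibility fraction from the marker mass balance.

    DMD = 1 - diet/excreta.  A negative result (excreta concentration below
    the diet's, impossible for a fully recovered indigestible marker) is
    returned with a warning — it usually signals a unit or recovery problem.
    """
    excreta = np.asarray(measurement.excreta_concentration, dtype=float)
    if np.any(excreta == 0):
        raise ZeroDivisionError(
            f"excreta {measurement.marker} concentration is zero; DMD undefined"
        )
    dmd = 1.0 - measurement.diet_concentration / excreta
    if np.any(dmd < 0):
        warnings.warn(
            f"negative DMD for marker {measurement.marker}: excreta concentration "
            "below dietary level suggests marker dilution or a unit error",
            RuntimeWarning,
        )
    return float(dmd) if dmd.ndim == 0 else dmd


def marker_agreement(dmd_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise squared Pearson correlation of per-sample DMD across markers.

    Columns are markers, rows samples.  Pairs are evaluated on their complete
    cases (>= 3 required); a zero-variance column makes its pairs NaN.
    Returns a symmetric matrix with unit diagonal.
    """
    cols = list(dmd_table.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        pair = dmd_table[[a, b]].dropna()
        if len(pair) < 3:
            raise ValueError(f"markers {a}/{b} share fewer than 3 complete samples")
        x = pair[a].to_numpy(dtype=float)
        y = pair[b].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        out.loc[a, b] = out.loc[b, a] = r2
    return out
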