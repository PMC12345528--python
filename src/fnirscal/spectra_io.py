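"""Containers and CSV I/O for NIR spectra and per-sample reference analytes.

Spectra follow scanning-monochromator conventions: a uniform wavelength grid
(default 1100–2498 nm at 2 nm, 700 points; the grid is configurable and
never hard-coded), absorbance stored as log10(1/R), and duplicate cup
fillings averaged into one spectrum per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "ReferenceTable",
    "reflectance_to_absorbance",
    "average_duplicates",
    "read_spectra_table",
    "write_spectra_table",
    "read_reference_table",
    "write_reference_table",
    "default_grid",
]

#: relative tolerance used to decide whether a wavelength grid is uniform
_GRID_RTOL = 1e-9


def default_grid(start: float = 1100.0, stop: float = 2498.0, step: float = 2.0) -> np.ndarray:
    """Uniform wavelength grid in nm, endpoints inclusive."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def _check_grid(wavelengths: np.ndarray) -> float:
    """Validate strict monotone increase and uniform spacing; return the step."""
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2:
        raise ValueError("wavelength grid must be a 1-D array with at least 2 points")
    steps = np.diff(wl)
    if np.any(steps <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    step = steps[0]
    if not np.allclose(steps, step, rtol=_GRID_RTOL, atol=_GRID_RTOL * max(abs(step), 1.0)):
        raise ValueError(
            "wavelength grid is not uniformly spaced: observed spacings range "
            f"from {steps.min():.6g} to {steps.max():.6g} nm"
        )
    return float(step)


@dataclass
class SpectraSet:
    """A set of NIR spectra on a shared uniform wavelength grid.

    Parameters
    ----------
    sample_ids:
        One identifier per row of ``absorbance``.  Duplicate ids are allowed
        only while the set still holds un-averaged scan replicates; after
        :func:`average_duplicates` each id appears once.
    wavelengths:
        Strictly increasing, uniformly spaced grid in nm.
    absorbance:
        ``(n_samples, n_wavelengths)`` matrix of log10(1/R) values.
    meta:
        Optional per-sample metadata (diet, cereal, enzyme, replicate count…),
        one row per spectrum, aligned positionally with ``sample_ids``.
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        _check_grid(self.wavelengths)
        n, p = self.absorbance.shape
        if p != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {p} columns but the grid has {self.wavelengths.size} points"
            )
        if n != len(self.sample_ids):
            raise ValueError(
                f"absorbance has {n} rows but {len(self.sample_ids)} sample ids were given"
            )
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise ValueError(
                f"non-finite absorbance at sample '{self.sample_ids[bad[0]]}', "
                f"wavelength {self.wavelengths[bad[1]]:g} nm"
            )
        if self.meta is not None and len(self.meta) != n:
            raise ValueError("meta must have one row per spectrum")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    @property
    def step(self) -> float:
        """Grid spacing in nm."""
        return float(self.wavelengths[1] - self.wavelengths[0])

    def has_duplicate_ids(self) -> bool:
        return len(set(self.sample_ids)) != len(self.sample_ids)

    def select(self, indices) -> "SpectraSet":
        """Row-subset by integer positions, keeping grid and metadata aligned."""
        idx = np.asarray(indices)
        meta = self.meta.iloc[idx].reset_index(drop=True) if self.meta is not None else None
        return SpectraSet(
            sample_ids=[self.sample_ids[i] for i in idx],
            wavelengths=self.wavelengths,
            absorbance=self.absorbance[idx],
            meta=meta,
        )

    def subset_wavelengths(self, mask) -> "SpectraSet":
        """Column-subset to a contiguous-grid selection of wavelengths."""
        mask = np.asarray(mask)
        meta = self.meta.copy() if self.meta is not None else None
        return SpectraSet(
            sample_ids=list(self.sample_ids),
            wavelengths=self.wavelengths[mask],
            absorbance=self.absorbance[:, mask],
            meta=meta,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraSet):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.absorbance, other.absorbance)
        )


@dataclass
class ReferenceTable:
    """Per-sample analyte values (marker concentrations, DMD) keyed by id.

    ``analytes`` is a DataFrame with one row per sample; column names carry
    units by convention, e.g. ``Yb_g_kg``, ``Ti_g_kg``, ``PEG_pct``,
    ``DMD`` (fraction of dry matter).
    """

    sample_ids: list[str]
    analytes: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.analytes) != len(self.sample_ids):
            raise ValueError("analytes must have one row per sample id")
        self.analytes = self.analytes.reset_index(drop=True)

    def column(self, name: str) -> np.ndarray:
        return self.analytes[name].to_numpy(dtype=float)

    def aligned_to(self, spectra: SpectraSet) -> "ReferenceTable":
        """Reorder rows to match the sample order of ``spectra``.

        Raises if any spectrum id has no reference row.
        """
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [sid for sid in spectra.sample_ids if sid not in pos]
        if missing:
            raise KeyError(f"reference table missing sample ids: {missing[:5]}")
        order = [pos[sid] for sid in spectra.sample_ids]
        return ReferenceTable(
            sample_ids=list(spectra.sample_ids),
            analytes=self.analytes.iloc[order].reset_index(drop=True),
        )


def reflectance_to_absorbance(reflectance: np.ndarray,
                              sample_ids: list[str] | None = None,
                              wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Convert reflectance R in (0, 1] to absorbance log10(1/R), elementwise.

    Raises ``ValueError`` naming the offending sample/wavelength when any
    R <= 0 (log undefined).
    """
    R = np.asarray(reflectance, dtype=float)
    if np.any(R <= 0):
        bad = np.argwhere(np.atleast_2d(R) <= 0)[0]
        sid = sample_ids[bad[0]] if sample_ids is not None else f"row {bad[0]}"
        wl = (
            f"{wavelengths[bad[-1]]:g} nm"
            if wavelengths is not None
            else f"column {bad[-1]}"
        )
        raise ValueError(f"reflectance must be > 0; offending value at sample '{sid}', {wl}")
    return -np.log10(R)


def average_duplicates(spectra: SpectraSet) -> SpectraSet:
    """Average scan replicates (duplicate sample ids) into one row per sample.

    Each wavelength becomes the arithmetic mean over replicates.  The output
    preserves first-appearance order of the ids and records the replicate
    count in ``meta['n_replicates']``.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(spectra.sample_ids):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)

    rows = np.empty((len(order), spectra.n_wavelengths))
    counts = np.empty(len(order), dtype=int)
    for j, sid in enumerate(order):
        idx = groups[sid]
        rows[j] = spectra.absorbance[idx].mean(axis=0)
        counts[j] = len(idx)

    meta = pd.DataFrame({"n_replicates": counts})
    if spectra.meta is not None:
        first = [groups[sid][0] for sid in order]
        base = spectra.meta.iloc[first].reset_index(drop=True)
        base = base.drop(columns=["n_replicates"], errors="ignore")
        meta = pd.concat([base, meta], axis=1)
    return SpectraSet(order, spectra.wavelengths, rows, meta)


def write_spectra_table(spectra: SpectraSet, path) -> None:
    """Write a wide CSV: first column ``sample_id``, then one column per nm."""
    df = pd.DataFrame(spectra.absorbance, columns=[f"{w:.10g}" for w in spectra.wavelengths])
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_table(path) -> SpectraSet:
    """Read a wide spectra CSV (sample_id, then wavelength-in-nm headers).

    The wavelength headers must parse as numbers on a strictly increasing,
    uniformly spaced grid; otherwise the error reports the observed spacings.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"cannot parse spectra table {path!s}: file is empty") from exc
    if df.shape[1] < 3:
        raise ValueError(f"spectra table {path!s} needs a sample-id column and >=2 wavelengths")
    try:
        wl = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header in {path!s}: {exc}") from exc
    _check_grid(wl)
    return SpectraSet(
        sample_ids=df.iloc[:, 0].astype(str).tolist(),
        wavelengths=wl,
        absorbance=df.iloc[:, 1:].to_numpy(dtype=float),
    )


def write_reference_table(table: ReferenceTable, path) -> None:
    df = table.analytes.copy()
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_reference_table(path) -> ReferenceTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"cannot parse reference table {path!s}: file is empty") from exc
    if "sample_id" not in df.columns:
        raise ValueError(f"reference table {path!s} must contain a 'sample_id' column")
    ids = df["sample_id"].astype(str).tolist()
    return ReferenceTable(sample_ids=ids, analytes=df.drop(columns=["sample_id"]))
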