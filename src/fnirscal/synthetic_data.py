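"""Synthetic broiler-excreta NIR spectra with marker/digestibility structure.

The generator emulates the statistical structure a fecal-NIRS calibration
study relies on, without pretending to be a radiative-transfer model:

- Each sample draws a true dry-matter digestibility (DMD) from a truncated
  normal (default mean 0.74, sd 0.03 on (0, 0.95)); indigestible-marker
  concentrations in excreta follow exactly from the mass balance
  ``excreta = diet / (1 - DMD)``.  With these defaults the induced
  coefficient of variation of marker concentrations is ~11%.
- A spectrum is a Beer–Lambert mixture: an organic excreta matrix profile
  (Gaussian absorption bands over 1100–2500 nm plus a gentle baseline)
  whose amount varies between samples, plus each marker's organo-complex
  signature bands scaled by its concentration.  Free mineral ions barely
  absorb in the NIR; detectability comes from the complexes they form with
  organic ligands, which is what the signature bands stand for.
- Measured spectra are warped by per-sample affine scatter artifacts
  (multiplicative gain, additive offset, linear tilt) — the distortions SNV,
  detrend and MSC are designed to remove — and white absorbance noise last,
  mirroring the physical measurement order.

A second generator reproduces the ad hoc PEG calibration design: a pooled
base excreta spectrum spiked with PEG at 0–15% of dry matter in 1%
increments, duplicated at the low levels to reach 27 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fnirscal.digestibility import oxide_to_element
from fnirscal.spectra_io import ReferenceTable, SpectraSet, default_grid

__all__ = [
    "Band",
    "DietSpec",
    "SyntheticConfig",
    "component_profile",
    "simulate_excreta_dataset",
    "spike_peg_design",
    "pooled_base_spectrum",
]


@dataclass(frozen=True)
class Band:
    """A Gaussian absorption band: centre (nm), width (nm, sd), peak height."""

    center: float
    width: float
    height: float


def component_profile(bands: tuple[Band, ...], wavelengths: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bands evaluated on the grid (unit-concentration profile)."""
    wl = np.asarray(wavelengths, dtype=float)
    prof = np.zeros_like(wl)
    for b in bands:
        prof += b.height * np.exp(-0.5 * ((wl - b.center) / b.width) ** 2)
    return prof


@dataclass
class DietSpec:
    """Dietary inclusion rates of the external markers, as-fed basis.

    Oxide doses (TiO2 2 g/kg, Yb2O3 50 mg/kg) are the standard broiler
    supplementation levels; PEG is dosed as-is at 5 g/kg.
    """

    tio2_g_kg: float = 2.0
    yb2o3_mg_kg: float = 50.0
    peg_g_kg: float = 5.0
    report_as: str = "element"

    def __post_init__(self) -> None:
        if min(self.tio2_g_kg, self.yb2o3_mg_kg, self.peg_g_kg) <= 0:
            raise ValueError("marker inclusion rates must be > 0")
        if self.report_as not in ("element", "oxide"):
            raise ValueError("report_as must be 'element' or 'oxide'")

    @property
    def ti_g_kg(self) -> float:
        """Dietary titanium, element basis, g/kg."""
        return oxide_to_element(self.tio2_g_kg, "TiO2")

    @property
    def yb_mg_kg(self) -> float:
        """Dietary ytterbium, element basis, mg/kg."""
        return oxide_to_element(self.yb2o3_mg_kg, "Yb2O3")


# NIR band assignments (approximate literature positions):
# 1210 nm C-H 2nd overtone, 1450/1940 nm O-H (water), 1730 nm C-H 1st
# overtone, 2100 nm starch/protein combination, 2310 nm C-H combination.
_ORGANIC_BANDS = (
    Band(1210.0, 45.0, 0.10),
    Band(1450.0, 55.0, 0.35),
    Band(1730.0, 40.0, 0.18),
    Band(1940.0, 60.0, 0.45),
    Band(2100.0, 50.0, 0.30),
    Band(2310.0, 35.0, 0.22),
)

# PEG: a pure crystalline polymer, so its C-H / O-H combination bands are
# sharp and intense compared with the broad excreta matrix.
_PEG_BANDS = (
    Band(1190.0, 18.0, 0.30),
    Band(1730.0, 16.0, 1.10),
    Band(1935.0, 20.0, 0.45),
    Band(2270.0, 16.0, 1.25),
)

# Organo-complex signatures of the mineral markers (per g/kg element).
_TI_BANDS = (Band(1680.0, 28.0, 0.010), Band(2180.0, 32.0, 0.012))
_YB_BANDS = (Band(1560.0, 26.0, 0.009), Band(2050.0, 30.0, 0.011))


@dataclass
class SyntheticConfig:
    """Knobs of the excreta-spectra generator.

    Defaults encode the study conditions the pipeline is meant to face:
    192 excreta samples, DMD ~ N(0.74, 0.03) truncated to (0, 0.95),
    mild affine scatter, and low instrument noise.
    """

    n_samples: int = 192
    seed: int = 0
    wavelengths: np.ndarray = field(default_factory=default_grid)
    dmd_mean: float = 0.74
    dmd_sd: float = 0.03
    dmd_bounds: tuple[float, float] = (0.0, 0.95)
    organic_bands: tuple[Band, ...] = _ORGANIC_BANDS
    peg_bands: tuple[Band, ...] = _PEG_BANDS
    ti_bands: tuple[Band, ...] = _TI_BANDS
    yb_bands: tuple[Band, ...] = _YB_BANDS
    baseline: float = 0.30
    baseline_slope: float = 0.10       # absorbance rise across the full grid
    organic_amount_sd: float = 0.05    # per-sample matrix amount ~ N(1, sd)
    scatter_gain: float = 0.05         # gain ~ U(1 +- this)
    scatter_offset: float = 0.02       # offset ~ U(+- this)
    scatter_tilt: float = 0.01         # linear tilt across grid ~ U(+- this)
    noise_sd: float = 5e-4             # white absorbance noise

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        lo, hi = self.dmd_bounds
        if not (0.0 <= lo < hi < 1.0):
            raise ValueError("DMD bounds must satisfy 0 <= lo < hi < 1")
        wl_lo, wl_hi = self.wavelengths.min(), self.wavelengths.max()
        for bands in (self.organic_bands, self.peg_bands, self.ti_bands, self.yb_bands):
            for b in bands:
                if not (wl_lo <= b.center <= wl_hi):
                    raise ValueError(f"band centre {b.center} nm outside grid "
                                     f"[{wl_lo}, {wl_hi}] nm")


def _truncated_normal(rng, mean, sd, bounds, size, reject_warn=0.01):
    lo, hi = bounds
    draws = rng.normal(mean, sd, size)
    n_rejected = 0
    bad = (draws <= lo) | (draws >= hi)
    while np.any(bad):
        n_rejected += int(bad.sum())
        draws[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (draws <= lo) | (draws >= hi)
    if n_rejected > reject_warn * size:
        warnings.warn(
            f"{n_rejected} of {size + n_rejected} DMD draws fell outside "
            f"({lo}, {hi}) and were redrawn", RuntimeWarning,
        )
    return draws


def _apply_scatter_and_noise(clean: np.ndarray, cfg: SyntheticConfig, rng) -> np.ndarray:
    n, p = clean.shape
    u = np.linspace(0.0, 1.0, p)
    gain = rng.uniform(1 - cfg.scatter_gain, 1 + cfg.scatter_gain, n)
    offset = rng.uniform(-cfg.scatter_offset, cfg.scatter_offset, n)
    tilt = rng.uniform(-cfg.scatter_tilt, cfg.scatter_tilt, n)
    out = clean * gain[:, None] + offset[:, None] + tilt[:, None] * u[None, :]
    if cfg.noise_sd > 0:
        out = out + rng.normal(0.0, cfg.noise_sd, (n, p))
    return out


def clean_excreta_spectrum(
    cfg: SyntheticConfig,
    organic_amount: float,
    ti_g_kg: float,
    yb_g_kg: float,
    peg_pct: float,
) -> np.ndarray:
    """Exact Beer–Lambert mixture for one sample, no scatter or noise."""
    wl = cfg.wavelengths
    u = (wl - wl.min()) / (wl.max() - wl.min())
    spec = cfg.baseline + cfg.baseline_slope * u
    spec = spec + organic_amount * component_profile(cfg.organic_bands, wl)
    spec = spec + ti_g_kg * component_profile(cfg.ti_bands, wl)
    spec = spec + yb_g_kg * component_profile(cfg.yb_bands, wl)
    spec = spec + (peg_pct / 100.0) * component_profile(cfg.peg_bands, wl)
    return spec


def simulate_excreta_dataset(
    cfg: SyntheticConfig | None = None,
    diet: DietSpec | None = None,
) -> tuple[SpectraSet, ReferenceTable]:
    """Generate an excreta dataset with exact marker mass balance.

    The reference table carries element-basis marker concentrations
    (``Ti_g_kg``, ``Yb_g_kg``, ``PEG_pct`` of DM) satisfying
    ``excreta = diet / (1 - DMD)`` exactly, plus the true ``DMD`` fraction.
    The same seed reproduces the dataset bit for bit.
    """
    cfg = cfg or SyntheticConfig()
    diet = diet or DietSpec()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    dmd = _truncated_normal(rng, cfg.dmd_mean, cfg.dmd_sd, cfg.dmd_bounds, n)
    conc_factor = 1.0 / (1.0 - dmd)
    ti = diet.ti_g_kg * conc_factor                      # g/kg element
    yb = diet.yb_mg_kg * conc_factor / 1000.0            # g/kg element
    peg = diet.peg_g_kg * conc_factor / 10.0             # % of DM
    organic = rng.normal(1.0, cfg.organic_amount_sd, n)

    clean = np.empty((n, cfg.wavelengths.size))
    for i in range(n):
        clean[i] = clean_excreta_spectrum(cfg, organic[i], ti[i], yb[i], peg[i])
    A = _apply_scatter_and_noise(clean, cfg, rng)

    ids = [f"ex{i:03d}" for i in range(n)]
    meta = pd.DataFrame({"organic_amount": organic})
    spectra = SpectraSet(ids, cfg.wavelengths, A, meta)
    reference = ReferenceTable(
        ids,
        pd.DataFrame({
            "Ti_g_kg": ti,
            "Yb_g_kg": yb,
            "PEG_pct": peg,
            "DMD": dmd,
        }),
    )
    return spectra, reference


def pooled_base_spectrum(cfg: SyntheticConfig | None = None) -> np.ndarray:
    """A pooled pre-treatment excreta profile: the matrix at nominal amount."""
    cfg = cfg or SyntheticConfig()
    return clean_excreta_spectrum(cfg, organic_amount=1.0,
                                  ti_g_kg=0.0, yb_g_kg=0.0, peg_pct=0.0)


def default_replicate_plan(levels: tuple[int, ...], n_total: int = 27) -> list[float]:
    """Duplicate the lowest levels until n_total samples are reached.

    With the standard 16 levels (0–15%) and n_total 27, levels 0–10 appear
    twice — densest support at low PEG, where excreta predictions live.
    """
    plan = list(levels)
    if n_total < len(plan):
        raise ValueError(f"n_total {n_total} smaller than the number of levels {len(plan)}")
    i = 0
    while len(plan) < n_total:  # cycle through the levels, lowest first
        plan.append(levels[i % len(levels)])
        i += 1
    return sorted(float(v) for v in plan)


def spike_peg_design(
    base: np.ndarray | None = None,
    levels: tuple[float, ...] | None = None,
    n_total: int = 27,
    cfg: SyntheticConfig | None = None,
) -> tuple[SpectraSet, ReferenceTable]:
    """Fortified-sample design: base excreta spiked with PEG at known levels.

    Each sample's clean spectrum is ``(1 - w) * base + w * peg_profile`` with
    ``w`` the PEG mass fraction, then scatter artifacts and noise are applied
    per the config.  The reference column ``PEG_pct`` records the level.
    """
    cfg = cfg or SyntheticConfig()
    if base is None:
        base = pooled_base_spectrum(cfg)
    base = np.asarray(base, dtype=float)
    if base.size != cfg.wavelengths.size:
        raise ValueError("base spectrum does not match the configured grid")
    if levels is None:
        levels = tuple(range(0, 16))  # 0..15% in 1% increments
    for lv in levels:
        if not (0 <= lv < 100):
            raise ValueError(f"PEG level {lv}% outside [0, 100)")
    plan = default_replicate_plan(tuple(levels), n_total)

    rng = np.random.default_rng(cfg.seed)
    peg_profile = component_profile(cfg.peg_bands, cfg.wavelengths)
    # a pure-PEG spectrum still sits on the instrument baseline
    peg_full = cfg.baseline + peg_profile

    w = np.array(plan) / 100.0
    clean = (1 - w)[:, None] * base[None, :] + w[:, None] * peg_full[None, :]
    A = _apply_scatter_and_noise(clean, cfg, rng)

    ids = [f"peg{i:02d}" for i in range(len(plan))]
    meta = pd.DataFrame({"peg_level_pct": plan})
    spectra = SpectraSet(ids, cfg.wavelengths, A, meta)
    reference = ReferenceTable(ids, pd.DataFrame({"PEG_pct": plan}))
    return spectra, reference
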