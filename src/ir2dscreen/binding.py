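"""Binding quantification on the cefazolin verification series.

The univariate readout is the amplitude ratio of the preprocessed 0.25 ps
map at two fixed (pump, probe) coordinates — the high-frequency point
(1656, 1649 cm^-1) against the low-frequency point (1635, 1632 cm^-1) that
anchor the cefazolin signature.  Tracked along the dilution ladder the
ratio reports on the concentration dependence of drug binding; a
dose-dependent (two-regime) bound fraction produces a decline-then-rise
profile with an interior extremum near the regime crossover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridmap import SpectrumMap2D
from .pls import PLSModel, fit_pls

__all__ = [
    "BindingCurve",
    "PT_HIGH",
    "PT_LOW",
    "amplitude_ratio",
    "pls_regression_conc",
    "binding_curve",
    "conc_convert",
]

#: Default measurement coordinates (pump, probe) in cm^-1.
PT_HIGH = (1656.0, 1649.0)
PT_LOW = (1635.0, 1632.0)


@dataclass
class BindingCurve:
    conc: np.ndarray  # mM, strictly increasing
    ratio_mean: np.ndarray
    ratio_sd: np.ndarray
    n: np.ndarray
    extremum: tuple | None  # (conc, ratio) of the interior minimum, if any
    u_shaped: bool

    def __post_init__(self) -> None:
        if np.any(np.diff(self.conc) <= 0):
            raise ValueError("aggregated concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.ratio_mean)):
            raise ValueError("ratios must be finite")


def amplitude_ratio(
    map_: SpectrumMap2D,
    pt_high: tuple = PT_HIGH,
    pt_low: tuple = PT_LOW,
    interpolate: bool = False,
) -> float:
    """Map value at ``pt_high`` divided by the value at ``pt_low``.

    Values are taken at the nearest grid cell (ties toward the lower
    wavenumber); set ``interpolate`` for bilinear interpolation instead.
    """
    read = map_.value_at_interp if interpolate else map_.value_at
    hi = read(*pt_high)
    lo = read(*pt_low)
    if lo == 0:
        raise ZeroDivisionError("degenerate ratio: denominator cell is zero")
    return hi / lo


def pls_regression_conc(
    X: np.ndarray, conc: np.ndarray, n_lv: int, centered: bool = False
) -> PLSModel:
    """PLS regression of spectra on drug concentration.

    The LV1/LV2 loadings of this model are the regression analogues of the
    classification model's serum and drug signatures and can be compared to
    them directly (for an uncentered fit LV1 tracks the mean spectrum).
    """
    conc = np.asarray(conc, dtype=float)
    if np.unique(conc).size < 3:
        raise ValueError("need at least three distinct concentrations")
    return fit_pls(X, conc[:, None], n_lv, centered=centered)


def binding_curve(
    maps: list,
    concs: list,
    pt_high: tuple = PT_HIGH,
    pt_low: tuple = PT_LOW,
    rise_sds: float = 2.0,
) -> BindingCurve:
    """Aggregate per-sample amplitude ratios into a concentration profile.

    Replicates at each concentration are averaged (mean +/- sd); the interior
    extremum is the discrete minimum of the mean ratio over the ladder with
    both endpoints excluded.  The profile is flagged U-shaped iff an interior
    minimum exists and both arms rise at least ``rise_sds`` pooled standard
    deviations above it.
    """
    concs = np.asarray(concs, dtype=float)
    ratios = np.array([amplitude_ratio(m, pt_high, pt_low) for m in maps])
    levels = np.unique(concs)
    if levels.size < 4:
        raise ValueError("extremum analysis needs at least four concentration levels")
    mean = np.empty(levels.size)
    sd = np.empty(levels.size)
    n = np.empty(levels.size, dtype=int)
    for i, c in enumerate(levels):
        r = ratios[concs == c]
        n[i] = r.size
        mean[i] = r.mean()
        sd[i] = r.std(ddof=1) if r.size > 1 else 0.0
    interior = slice(1, levels.size - 1)
    k = int(np.argmin(mean[interior]) + 1)
    pooled = float(np.sqrt(np.mean(sd**2)))
    left_rise = float(np.max(mean[:k]) - mean[k])
    right_rise = float(np.max(mean[k + 1 :]) - mean[k])
    u_shaped = bool(left_rise >= rise_sds * pooled and right_rise >= rise_sds * pooled)
    extremum = (float(levels[k]), float(mean[k])) if u_shaped else None
    return BindingCurve(
        conc=levels, ratio_mean=mean, ratio_sd=sd, n=n,
        extremum=extremum, u_shaped=u_shaped,
    )


def conc_convert(value: float, mode: str, molar_mass: float) -> float:
    """Convert between molar (mM) and mass (ug/mL for molar->mass input,
    mg/mL for mass->molar input) concentration units.

    molar->mass: ug/mL = mM x g/mol / 1000 x 1000 = mM x g/mol ... i.e.
    1 mM of a 454.5 g/mol compound is 454.5 ug/mL.  mass->molar: mM =
    mg/mL x 1000 / (g/mol).  No rounding: presentation layers round.
    """
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if value < 0:
        raise ValueError("concentration must be non-negative")
    if mode == "molar->mass":
        return value * molar_mass  # mM * g/mol -> ug/mL
    if mode == "mass->molar":
        return value * 1000.0 / molar_mass  # mg/mL -> mM
    raise ValueError("mode must be 'molar->mass' or 'mass->molar'")
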