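"""Synthetic 2D-IR serum spectra emulating the drug-screening study designs.

The generator builds pump x probe amide I maps of pooled human serum — a
dominant, largely alpha-helical HSA band near 1660 cm^-1 and a weaker
beta-sheet-rich globulin band near 1640 cm^-1, each a negative fundamental
on the diagonal paired with a positive, anharmonically red-shifted overtone
— and superimposes low-amplitude, drug-specific perturbation patterns whose
strength follows a two-regime protein-binding model.  Each sample yields two
maps: the structured protein response at a 0.25 ps waiting time and a broad,
pump-independent thermal-water reference at 5 ps that downstream
preprocessing uses for baseline correction and normalisation.

Every map is a deterministic function of (record, config, seed), which makes
the generator its own oracle: the exact injected perturbation of any sample
is available through :func:`injected_signal`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import DRUGS, BindingConfig, RunConfig
from .gridmap import AxisGrid, SpectrumMap2D, default_grid

__all__ = [
    "PeakSpec",
    "PerturbationPattern",
    "SampleRecord",
    "Dataset",
    "gaussian2d_peak",
    "amide_doublet",
    "serum_base_map",
    "drug_pattern",
    "pattern_map",
    "thermal_water_map",
    "bound_fraction",
    "drug_signal_scale",
    "secondary_signal_scale",
    "secondary_pattern",
    "injected_signal",
    "synth_sample",
    "generate_screening_set",
    "generate_verification_set",
    "VERIFICATION_CONCENTRATIONS",
]


@dataclass(frozen=True)
class PeakSpec:
    """One amide I doublet: negative fundamental + positive shifted overtone."""

    center: float  # cm^-1, on the diagonal
    amplitude: float  # positive; fundamental is -amplitude
    sigma_diag: float = 18.0
    sigma_anti: float = 8.0
    anharmonic_shift: float = 16.0
    overtone_ratio: float = 0.85

    def __post_init__(self) -> None:
        if self.sigma_diag <= 0 or self.sigma_anti <= 0:
            raise ValueError("peak widths must be positive")
        if self.anharmonic_shift <= 0:
            raise ValueError("anharmonic_shift must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class PerturbationPattern:
    """Drug-specific spectral signature.

    ``components`` are (center_pump, center_probe, fraction, sigma_diag,
    sigma_anti) tuples; ``fraction`` is the signed amplitude relative to the
    HSA fundamental and is small (|fraction| <= 0.5) because bound drugs
    perturb, rather than replace, the protein response.
    """

    drug_id: str
    components: tuple

    def __post_init__(self) -> None:
        if self.drug_id not in DRUGS:
            raise ValueError(f"unknown drug {self.drug_id!r}; valid: {sorted(DRUGS)}")
        for c in self.components:
            if abs(c[2]) > 0.5:
                raise ValueError("pattern amplitude fraction must satisfy |f| <= 0.5")
            if c[3] <= 0 or c[4] <= 0:
                raise ValueError("pattern widths must be positive")


@dataclass(frozen=True)
class SampleRecord:
    """Design metadata tying one measured map pair to the experiment."""

    sample_id: str
    class_label: str  # Serum, Serum+<Drug>, or DrugOnly:<drug>
    drug_conc: float  # mM
    replicate_index: int
    path_length_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.path_length_factor <= 0:
            raise ValueError("path_length_factor must be positive")
        if self.class_label == "Serum" and self.drug_conc != 0:
            raise ValueError("Serum samples must have zero drug concentration")
        if self.class_label.startswith("Serum+") and self.drug_conc <= 0:
            raise ValueError("drug-spiked samples need a positive concentration")

    @property
    def drug(self) -> str | None:
        if self.class_label.startswith("Serum+"):
            return self.class_label.split("+", 1)[1].lower()
        if self.class_label.startswith("DrugOnly:"):
            return self.class_label.split(":", 1)[1].lower()
        return None


@dataclass
class Dataset:
    """A list of samples: records aligned with their 0.25 ps / 5 ps map pairs."""

    records: list
    maps_250fs: list
    maps_5ps: list
    config: RunConfig

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list:
        return [r.class_label for r in self.records]


# ---------------------------------------------------------------------------
# lineshape primitives


def gaussian2d_peak(
    center_pump: float,
    center_probe: float,
    amplitude: float,
    sigma_diag: float,
    sigma_anti: float,
    grid: AxisGrid,
) -> SpectrumMap2D:
    """A 2D Gaussian rotated 45 degrees, elongated along the spectrum diagonal.

    The diagonal elongation mimics the inhomogeneous broadening seen at short
    waiting times: pump and probe frequencies stay correlated before spectral
    diffusion scrambles them.  ``sigma_diag`` is the 1-sigma width along the
    pump=probe diagonal, ``sigma_anti`` across it.
    """
    if sigma_diag <= 0 or sigma_anti <= 0:
        raise ValueError("sigma_diag and sigma_anti must be positive")
    pump, probe = grid.mesh()
    dp = pump - center_pump
    dw = probe - center_probe
    u = (dp + dw) / math.sqrt(2.0)  # along the diagonal
    v = (dw - dp) / math.sqrt(2.0)  # across the diagonal
    amps = amplitude * np.exp(-(u**2) / (2 * sigma_diag**2) - (v**2) / (2 * sigma_anti**2))
    return SpectrumMap2D(grid=grid, amplitudes=amps, waiting_time=0.25)


def amide_doublet(peak: PeakSpec, grid: AxisGrid) -> SpectrumMap2D:
    """Fundamental/overtone pair of one amide I band.

    The v=0-1 bleach appears as a negative band on the diagonal; the v=1-2
    induced absorption appears positive at a probe frequency lowered by the
    anharmonic shift, with reduced amplitude.
    """
    fund = gaussian2d_peak(
        peak.center, peak.center, -peak.amplitude, peak.sigma_diag, peak.sigma_anti, grid
    )
    over = gaussian2d_peak(
        peak.center,
        peak.center - peak.anharmonic_shift,
        peak.overtone_ratio * peak.amplitude,
        peak.sigma_diag,
        peak.sigma_anti,
        grid,
    )
    return fund + over


def _peak_from_config(pc) -> PeakSpec:
    return PeakSpec(
        center=pc.center,
        amplitude=pc.amplitude,
        sigma_diag=pc.sigma_diag,
        sigma_anti=pc.sigma_anti,
        anharmonic_shift=pc.anharmonic_shift,
        overtone_ratio=pc.overtone_ratio,
    )


def serum_base_map(config: RunConfig, grid: AxisGrid) -> SpectrumMap2D:
    """Neat-serum amide I response: HSA doublet at 1660 cm^-1 plus the weaker
    globulin doublet at 1640 cm^-1.  Deterministic given the config."""
    hsa = amide_doublet(_peak_from_config(config.hsa), grid)
    glob = amide_doublet(_peak_from_config(config.globulin), grid)
    return hsa + glob


# ---------------------------------------------------------------------------
# drug signatures

# Component geometry (centers cm^-1, relative sign, widths cm^-1).  Cefazolin
# anchors the two coordinates later used for amplitude-ratio quantification;
# warfarin shares the motif displaced +6 cm^-1 in pump (similar site-I
# chemistry, slightly different frequencies); ibuprofen is a single positive
# feature below the diagonal; paracetamol is a diagonal-elongated change at
# the HSA position covering a wide frequency range.
_PATTERN_GEOMETRY = {
    "cefazolin": ((1635.0, 1632.0, -1.0, 12.0, 7.0), (1656.0, 1649.0, +1.0, 12.0, 7.0)),
    "warfarin": ((1641.0, 1632.0, -1.0, 9.0, 5.0), (1662.0, 1649.0, +1.0, 9.0, 5.0)),
    "ibuprofen": ((1660.0, 1644.0, +1.0, 20.0, 10.0),),
    "paracetamol": ((1660.0, 1660.0, -1.0, 54.0, 6.0),),
}


def drug_pattern(drug_id: str, amplitude: float = 0.06) -> PerturbationPattern:
    """Built-in perturbation pattern for one of the four screened drugs.

    ``amplitude`` scales every component and is expressed as a fraction of
    the HSA fundamental amplitude (default 0.06: the drug signatures are
    subtle relative to the protein response).
    """
    drug_id = drug_id.lower()
    if drug_id not in _PATTERN_GEOMETRY:
        raise ValueError(f"unknown drug {drug_id!r}; valid: {sorted(_PATTERN_GEOMETRY)}")
    comps = tuple(
        (cp, cw, sign * amplitude, sd, sa)
        for cp, cw, sign, sd, sa in _PATTERN_GEOMETRY[drug_id]
    )
    return PerturbationPattern(drug_id=drug_id, components=comps)


def pattern_map(pattern: PerturbationPattern, grid: AxisGrid, hsa_amplitude: float = 1.0) -> SpectrumMap2D:
    """Render a perturbation pattern onto the grid, in absolute amplitude
    units (component fractions times the HSA fundamental amplitude)."""
    total = np.zeros(grid.shape)
    for cp, cw, frac, sd, sa in pattern.components:
        total += gaussian2d_peak(cp, cw, frac * hsa_amplitude, sd, sa, grid).amplitudes
    return SpectrumMap2D(grid=grid, amplitudes=total, waiting_time=0.25)


def thermal_water_map(grid: AxisGrid, scale: float, center_probe: float = 1640.0,
                      sigma_probe: float = 70.0) -> SpectrumMap2D:
    """Thermal water response dominating the 5 ps waiting time: a broad,
    pump-independent probe profile whose maximum equals ``scale``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if sigma_probe < 60:
        raise ValueError("thermal profile must be broad (sigma >= 60 cm^-1)")
    profile = np.exp(-((grid.probe_axis - center_probe) ** 2) / (2 * sigma_probe**2))
    profile = profile / profile.max()  # max over the map equals scale exactly
    amps = scale * np.tile(profile, (grid.pump_axis.size, 1))
    return SpectrumMap2D(grid=grid, amplitudes=amps, waiting_time=5.0)


# ---------------------------------------------------------------------------
# binding model


def bound_fraction(conc: float, params: BindingConfig) -> float:
    """Fraction of drug bound in the primary (spectroscopically active) mode.

    Logistic in log-concentration: f(c) = f_high + (f_low - f_high) /
    (1 + (c / c_crossover)^steepness).  Flat at f_low for trace doses,
    declining through c_crossover to f_high — the dose-dependent regime in
    which additional drug partitions away from the primary site.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if conc == 0:
        return params.f_low
    x = (conc / params.c_crossover) ** params.steepness
    return params.f_high + (params.f_low - params.f_high) / (1.0 + x)


def drug_signal_scale(conc: float, params: BindingConfig) -> float:
    """Amplitude scale of the injected primary drug signature at ``conc``.

    The protein-side 2D-IR signal tracks how much protein carries bound drug,
    so the pattern amplitude is the product of a site-occupancy ramp
    min(c / c_saturation, 1) — the site fills from zero drug and saturates —
    and the primary-mode bound fraction f(c).  The product is non-monotone
    for a two-regime f: it rises on the occupancy ramp and falls once f
    declines past the crossover, which is what gives the verification series
    its concentration extremum.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    occupancy = min(conc / params.c_saturation, 1.0)
    return occupancy * bound_fraction(conc, params)


def secondary_signal_scale(conc: float, params: BindingConfig) -> float:
    """Amplitude scale of the secondary (weak, high-dose) binding mode:
    secondary_weight times a logistic occupancy rising through
    secondary_midpoint.  Zero at zero concentration and whenever the weight
    is zero."""
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if conc == 0 or params.secondary_weight == 0:
        return 0.0
    x = (params.secondary_midpoint / conc) ** params.secondary_steepness
    return params.secondary_weight / (1.0 + x)


# ---------------------------------------------------------------------------
# sample synthesis

# Drug-only DMSO controls sit below the protein amide I window so that their
# band positions are separated from the serum proteins.
_DRUG_ONLY_CENTERS = {
    "cefazolin": 1600.0,
    "ibuprofen": 1592.0,
    "paracetamol": 1608.0,
    "warfarin": 1612.0,
}


# Secondary binding mode: a doublet-shaped change at pump frequencies below
# the protein bands (amide I response of a weaker, high-dose binding site)
# that only populates at mM doses.
_SECONDARY_GEOMETRY = ((1628.0, 1628.0, +1.0, 18.0, 10.0), (1628.0, 1612.0, -0.85, 18.0, 10.0))


def secondary_pattern(drug_id: str, amplitude: float = 0.06) -> PerturbationPattern:
    """Spectral signature of the secondary high-dose binding mode."""
    comps = tuple(
        (cp, cw, sign * amplitude, sd, sa) for cp, cw, sign, sd, sa in _SECONDARY_GEOMETRY
    )
    return PerturbationPattern(drug_id=drug_id, components=comps)


def injected_signal(record: SampleRecord, config: RunConfig, grid: AxisGrid) -> SpectrumMap2D:
    """The exact drug perturbation added to this sample's 0.25 ps map, before
    the path-length factor and noise.  Zero map for neat serum.

    The signal is the primary drug pattern scaled by occupancy times bound
    fraction, plus (for drugs with a nonzero secondary weight) the secondary
    globulin-region pattern scaled by the high-dose occupancy.
    """
    drug = record.drug
    if drug is None or record.class_label.startswith("DrugOnly"):
        return SpectrumMap2D(grid=grid, amplitudes=np.zeros(grid.shape), waiting_time=0.25)
    params = config.binding[drug]
    scale = drug_signal_scale(record.drug_conc, params)
    pat = drug_pattern(drug, amplitude=config.pattern_amplitude)
    total = scale * pattern_map(pat, grid, hsa_amplitude=config.hsa.amplitude)
    s2 = secondary_signal_scale(record.drug_conc, params)
    if s2 > 0:
        pat2 = secondary_pattern(drug, amplitude=config.pattern_amplitude)
        total = total + s2 * pattern_map(pat2, grid, hsa_amplitude=config.hsa.amplitude)
    return total


def synth_sample(
    record: SampleRecord,
    config: RunConfig,
    rng: np.random.Generator,
    grid: AxisGrid | None = None,
) -> tuple[SpectrumMap2D, SpectrumMap2D]:
    """Generate the (0.25 ps, 5 ps) map pair for one sample.

    0.25 ps map: path_factor * (serum base + injected drug signature +
    residual thermal leak) + iid Gaussian noise.  5 ps map: path_factor *
    thermal water reference + noise.  DrugOnly controls replace the serum
    response by an isolated doublet at a drug-specific position outside the
    protein window.
    """
    if grid is None:
        grid = default_grid(**vars(config.grid))
    thermal = thermal_water_map(
        grid, config.thermal.scale, config.thermal.center_probe, config.thermal.sigma_probe
    )
    if record.class_label.startswith("DrugOnly"):
        drug = record.drug
        spec = PeakSpec(center=_DRUG_ONLY_CENTERS[drug], amplitude=0.5 * config.hsa.amplitude,
                        sigma_diag=12.0, sigma_anti=6.0)
        signal = amide_doublet(spec, grid)
    else:
        signal = serum_base_map(config, grid) + injected_signal(record, config, grid)
    pf = record.path_length_factor
    m250 = pf * (signal + config.thermal.leak * thermal)
    m5 = pf * thermal
    if config.noise_sigma > 0:
        m250 = m250.copy_with(
            m250.amplitudes + rng.normal(0.0, config.noise_sigma, grid.shape)
        )
        m5 = m5.copy_with(m5.amplitudes + rng.normal(0.0, config.noise_sigma, grid.shape))
    m250.sample_id = m5.sample_id = record.sample_id
    m250.waiting_time = 0.25
    m5.waiting_time = 5.0
    return m250, m5


def _draw_path_factor(rng: np.random.Generator, sigma_log: float) -> float:
    return float(np.exp(rng.normal(0.0, sigma_log))) if sigma_log > 0 else 1.0


def _build(records: list, config: RunConfig, seed: int) -> Dataset:
    grid = default_grid(**vars(config.grid))
    rng = np.random.default_rng(seed)
    # path factors first so that the manifest is seed-reproducible in one pass
    recs = [
        SampleRecord(
            sample_id=r.sample_id,
            class_label=r.class_label,
            drug_conc=r.drug_conc,
            replicate_index=r.replicate_index,
            path_length_factor=_draw_path_factor(rng, config.path_sigma_log),
        )
        for r in records
    ]
    m250s, m5s = [], []
    for rec in recs:
        a, b = synth_sample(rec, config, rng, grid)
        m250s.append(a)
        m5s.append(b)
    return Dataset(records=recs, maps_250fs=m250s, maps_5ps=m5s, config=config)


# Screening design: 12 neat serum measurements against three replicates of
# each drug at its clinical spike level — 1.2 mM (2:1 molar ratio to the
# 0.6 mM HSA) for cefazolin, ibuprofen and paracetamol, 0.03 mM for warfarin
# whose clinical dosing is far lower.
_SCREENING_CONCS = {"cefazolin": 1.2, "ibuprofen": 1.2, "paracetamol": 1.2, "warfarin": 0.03}


def generate_screening_set(config: RunConfig, seed: int) -> Dataset:
    """The 24-sample screening design: 12 serum + 3 replicates x 4 drugs."""
    records = []
    for i in range(12):
        records.append(SampleRecord(f"serum_{i+1:02d}", "Serum", 0.0, i + 1))
    for drug in DRUGS:
        conc = _SCREENING_CONCS[drug]
        for i in range(3):
            records.append(
                SampleRecord(f"{drug}_{i+1:02d}", f"Serum+{drug.capitalize()}", conc, i + 1)
            )
    return _build(records, config, seed)


def _verification_ladder() -> np.ndarray:
    """13 cefazolin concentrations log-spaced from 6 mM down to 0.6 uM."""
    return np.geomspace(6.0, 0.0006, 13)


#: The 14 concentration levels (mM) of the verification series: the 13-step
#: dilution ladder plus neat serum.
VERIFICATION_CONCENTRATIONS = tuple(np.r_[_verification_ladder(), 0.0])


def generate_verification_set(config: RunConfig, seed: int) -> Dataset:
    """The cefazolin verification series: 13 dilutions (6 mM - 0.6 uM) plus
    neat serum, each in triplicate (42 map pairs)."""
    records = []
    for level, conc in enumerate(VERIFICATION_CONCENTRATIONS):
        for i in range(3):
            if conc == 0:
                records.append(SampleRecord(f"ver_serum_r{i+1}", "Serum", 0.0, i + 1))
            else:
                records.append(
                    SampleRecord(
                        f"ver_c{level:02d}_r{i+1}", "Serum+Cefazolin", float(conc), i + 1
                    )
                )
    return _build(records, config, seed)
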