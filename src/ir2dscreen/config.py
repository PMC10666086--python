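"""Run configuration: generator, preprocessing and model parameters.

The configuration is a nested, YAML-serialisable record.  Loading is strict:
unknown keys are rejected so that a typo in a config file fails loudly
instead of silently falling back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from typing import Any

import yaml

__all__ = [
    "GridConfig",
    "PeakConfig",
    "ThermalConfig",
    "BindingConfig",
    "PreprocessConfig",
    "ModelConfig",
    "RunConfig",
    "config_hash",
]

DRUGS = ("cefazolin", "ibuprofen", "paracetamol", "warfarin")


@dataclass
class GridConfig:
    pump_min: float = 1580.0
    pump_max: float = 1720.0
    probe_min: float = 1560.0
    probe_max: float = 1720.0
    step: float = 2.0

    def validate(self) -> None:
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        if self.pump_min >= self.pump_max or self.probe_min >= self.probe_max:
            raise ValueError("axis bounds must be increasing")


@dataclass
class PeakConfig:
    """One amide I band: fundamental position/amplitude plus doublet shape."""

    center: float = 1660.0
    amplitude: float = 1.0
    sigma_diag: float = 18.0
    sigma_anti: float = 8.0
    anharmonic_shift: float = 16.0
    overtone_ratio: float = 0.85

    def validate(self) -> None:
        if self.sigma_diag <= 0 or self.sigma_anti <= 0:
            raise ValueError("peak widths must be positive")
        if self.anharmonic_shift <= 0:
            raise ValueError("anharmonic shift must be positive")
        if not 0 < self.overtone_ratio <= 1:
            raise ValueError("overtone_ratio must lie in (0, 1]")


@dataclass
class ThermalConfig:
    """Thermal water response measured at the 5 ps waiting time."""

    center_probe: float = 1640.0
    sigma_probe: float = 70.0
    scale: float = 1.0
    leak: float = 0.05  # residual thermal fraction present in the 250 fs map

    def validate(self) -> None:
        if self.sigma_probe < 60:
            raise ValueError("thermal profile must be broad (sigma >= 60 cm^-1)")
        if self.scale <= 0:
            raise ValueError("thermal scale must be positive")
        if self.leak < 0:
            raise ValueError("thermal leak must be non-negative")


@dataclass
class BindingConfig:
    """Two-regime bound-fraction model plus site-occupancy scales.

    f_low is the low-concentration plateau of the primary-site bound
    fraction, f_high the limiting fraction once the dose-dependent regime
    takes over above c_crossover; steepness is the Hill-type exponent of the
    logistic-in-log-concentration transition (f_high may equal f_low for a
    single-regime drug).  c_saturation sets how quickly the primary protein
    site fills from zero drug (signal ramp at trace doses).  The secondary_*
    fields describe a weak secondary binding mode that only populates at
    high (mM) doses and perturbs the globulin spectral region;
    secondary_weight 0 disables it.
    """

    f_low: float = 0.8
    f_high: float = 0.3
    c_crossover: float = 0.2  # mM
    steepness: float = 3.0
    c_saturation: float = 0.1  # mM
    secondary_weight: float = 0.0  # relative to the primary pattern amplitude
    secondary_midpoint: float = 0.5  # mM
    secondary_steepness: float = 2.0

    def validate(self) -> None:
        if not (0 <= self.f_high <= self.f_low <= 1):
            raise ValueError("require 0 <= f_high <= f_low <= 1")
        if self.c_crossover <= 0 or self.c_saturation <= 0:
            raise ValueError("concentration scales must be positive")
        if self.steepness <= 0 or self.secondary_steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.secondary_weight < 0 or self.secondary_midpoint <= 0:
            raise ValueError("secondary mode parameters must be non-negative")


def _default_binding() -> dict:
    # Cefazolin carries the dose-dependent two-regime curve probed by the
    # verification series, plus the weak secondary mode that repopulates the
    # protein signal at mM doses.  The other drugs show no documented dose
    # dependence across their clinical range, so their crossover sits far
    # above the screening dose; warfarin's ~uM site-I affinity makes it
    # effectively fully bound and site-saturated at its 0.03 mM dose.
    return {
        "cefazolin": BindingConfig(secondary_weight=2.0),
        "ibuprofen": BindingConfig(f_low=1.0, f_high=0.5, c_crossover=10.0,
                                   c_saturation=0.01),
        "paracetamol": BindingConfig(f_low=0.65, f_high=0.325, c_crossover=10.0,
                                     c_saturation=0.01),
        "warfarin": BindingConfig(f_low=1.0, f_high=0.5, c_crossover=10.0,
                                  c_saturation=0.003),
    }


@dataclass
class PreprocessConfig:
    mask_low: float = 1600.0  # off-amide region: probe < mask_low
    mask_high: float = 1700.0  # or probe > mask_high
    sg_window: int = 7
    sg_order: int = 3
    pca_variance: float = 0.99

    def validate(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("Savitzky-Golay window must be odd and > order")
        if not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must lie in (0, 1]")


@dataclass
class ModelConfig:
    n_lv_binary: int = 7
    n_lv_multiclass: int = 9
    centered: bool = False

    def validate(self) -> None:
        if self.n_lv_binary < 1 or self.n_lv_multiclass < 1:
            raise ValueError("latent-variable counts must be >= 1")


@dataclass
class RunConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    hsa: PeakConfig = field(default_factory=PeakConfig)
    globulin: PeakConfig = field(
        default_factory=lambda: PeakConfig(center=1640.0, amplitude=0.3)
    )
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    binding: dict = field(default_factory=_default_binding)
    pattern_amplitude: float = 0.06  # drug signature, fraction of HSA fundamental
    noise_sigma: float = 0.01  # additive iid noise, fraction of HSA fundamental
    path_sigma_log: float = 0.1  # lognormal sigma of the path-length factor
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 1

    def validate(self) -> "RunConfig":
        for sub in (self.grid, self.hsa, self.globulin, self.thermal,
                    self.preprocess, self.model):
            sub.validate()
        if set(self.binding) - set(DRUGS):
            raise ValueError(f"unknown drug in binding config: {set(self.binding) - set(DRUGS)}")
        for b in self.binding.values():
            b.validate()
        if self.pattern_amplitude < 0 or self.noise_sigma < 0 or self.path_sigma_log < 0:
            raise ValueError("amplitude/noise/path parameters must be non-negative")
        return self


def _to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_dict(v) for k, v in obj.items()}
    return obj


def _from_dict(cls, data: dict, path: str = ""):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if name == "binding":
            kwargs[name] = {
                drug: _from_dict(BindingConfig, v, f"{path}binding.{drug}.")
                for drug, v in value.items()
            }
        elif dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[name] = _from_dict(f.type, value, f"{path}{name}.")
        elif isinstance(value, dict):
            sub_cls = {
                "grid": GridConfig, "hsa": PeakConfig, "globulin": PeakConfig,
                "thermal": ThermalConfig, "preprocess": PreprocessConfig,
                "model": ModelConfig,
            }[name]
            kwargs[name] = _from_dict(sub_cls, value, f"{path}{name}.")
        else:
            kwargs[name] = value
    return cls(**kwargs)


def to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(_to_dict(config), sort_keys=True)


def from_yaml(text: str) -> RunConfig:
    data = yaml.safe_load(text) or {}
    return _from_dict(RunConfig, data).validate()


def config_hash(config: RunConfig) -> str:
    """Short provenance hash embedded in every written artifact."""
    return hashlib.sha256(to_yaml(config).encode()).hexdigest()[:12]
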