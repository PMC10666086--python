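"""Core containers for 2D-IR spectral maps.

A 2D-IR measurement correlates an excitation (pump) wavenumber with a
detection (probe) wavenumber; a single acquisition is therefore a signed
amplitude grid over (pump, probe).  These containers are shared by the
generator, the preprocessing stages and the analysis layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AxisGrid", "SpectrumMap2D", "nearest_index", "default_grid"]


def _check_axis(axis: np.ndarray, name: str) -> None:
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError(f"{name} must be a 1-D array with at least two points")
    steps = np.diff(axis)
    if np.any(steps <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    if np.max(np.abs(steps - steps[0])) > 1e-9:
        raise ValueError(f"{name} must be uniformly spaced to within 1e-9")


@dataclass(frozen=True)
class AxisGrid:
    """Pump and probe wavenumber axes (cm^-1), ascending and uniform."""

    pump_axis: np.ndarray
    probe_axis: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pump_axis", np.asarray(self.pump_axis, dtype=float))
        object.__setattr__(self, "probe_axis", np.asarray(self.probe_axis, dtype=float))
        _check_axis(self.pump_axis, "pump_axis")
        _check_axis(self.probe_axis, "probe_axis")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pump_axis.size, self.probe_axis.size

    @property
    def n_pixels(self) -> int:
        return self.pump_axis.size * self.probe_axis.size

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Pump/probe coordinate matrices with map orientation (rows = pump)."""
        return np.meshgrid(self.pump_axis, self.probe_axis, indexing="ij")

    def same_as(self, other: "AxisGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.pump_axis, other.pump_axis, atol=tol)
            and np.allclose(self.probe_axis, other.probe_axis, atol=tol)
        )


def nearest_index(axis: np.ndarray, value: float) -> int:
    """Index of the grid point nearest ``value``; ties resolve to the lower
    wavenumber (the first minimal distance)."""
    axis = np.asarray(axis, dtype=float)
    if value < axis[0] or value > axis[-1]:
        raise ValueError(f"value {value} outside axis range [{axis[0]}, {axis[-1]}]")
    return int(np.argmin(np.abs(axis - value)))


@dataclass
class SpectrumMap2D:
    """A signed pump x probe amplitude grid at one waiting time.

    Amplitudes are in arbitrary dOD-like units: negative on the diagonal for
    the v=0-1 ground-state bleach, positive for the anharmonically shifted
    v=1-2 induced absorption.
    """

    grid: AxisGrid
    amplitudes: np.ndarray
    waiting_time: float  # ps
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != self.grid.shape:
            raise ValueError(
                f"amplitude shape {self.amplitudes.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")

    def value_at(self, pump: float, probe: float) -> float:
        """Amplitude at the grid cell nearest to (pump, probe)."""
        i = nearest_index(self.grid.pump_axis, pump)
        j = nearest_index(self.grid.probe_axis, probe)
        return float(self.amplitudes[i, j])

    def value_at_interp(self, pump: float, probe: float) -> float:
        """Bilinear interpolation at (pump, probe)."""
        from scipy.interpolate import RegularGridInterpolator

        f = RegularGridInterpolator(
            (self.grid.pump_axis, self.grid.probe_axis), self.amplitudes
        )
        return float(f([[pump, probe]])[0])

    def flatten(self) -> np.ndarray:
        """Row-major flatten: pump outer, probe inner."""
        return self.amplitudes.reshape(-1)

    def copy_with(self, amplitudes: np.ndarray, **kw) -> "SpectrumMap2D":
        return SpectrumMap2D(
            grid=self.grid,
            amplitudes=amplitudes,
            waiting_time=kw.get("waiting_time", self.waiting_time),
            sample_id=kw.get("sample_id", self.sample_id),
        )

    def __add__(self, other: "SpectrumMap2D") -> "SpectrumMap2D":
        if not self.grid.same_as(other.grid):
            raise ValueError("grid mismatch")
        return self.copy_with(self.amplitudes + other.amplitudes)

    def __sub__(self, other: "SpectrumMap2D") -> "SpectrumMap2D":
        if not self.grid.same_as(other.grid):
            raise ValueError("grid mismatch")
        return self.copy_with(self.amplitudes - other.amplitudes)

    def __mul__(self, c: float) -> "SpectrumMap2D":
        return self.copy_with(self.amplitudes * float(c))

    __rmul__ = __mul__


def default_grid(
    pump_min: float = 1580.0,
    pump_max: float = 1720.0,
    probe_min: float = 1560.0,
    probe_max: float = 1720.0,
    step: float = 2.0,
) -> AxisGrid:
    """The default acquisition grid: 2 cm^-1 steps over the amide I window,
    71 pump x 81 probe points (~5.8k pixels)."""
    pump = np.arange(pump_min, pump_max + step / 2, step, dtype=float)
    probe = np.arange(probe_min, probe_max + step / 2, step, dtype=float)
    return AxisGrid(pump, probe)
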