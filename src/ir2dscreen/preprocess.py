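"""Chemometric preprocessing of 2D-IR map pairs.

Stage order is fixed: thermal-reference baseline correction and
normalisation, Savitzky-Golay smoothing along the probe axis, PCA noise
reduction across samples, then flattening into the analysis matrix.  The
first stage is what makes spectra from different samples comparable: the
broad thermal water response at the 5 ps waiting time scales with the
sample path length exactly as the protein signal does, so fitting and
removing it, then dividing by its magnitude, cancels path-length and
intensity variation between measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .config import PreprocessConfig, RunConfig, config_hash
from .gridmap import AxisGrid, SpectrumMap2D
from .synth import Dataset

__all__ = [
    "ProcessedDataset",
    "correct_and_normalize",
    "smooth_sg",
    "pca_denoise",
    "build_design_matrix",
    "preprocess_dataset",
]


@dataclass
class ProcessedDataset:
    """Flattened spectra ready for multivariate analysis.

    X rows follow the manifest sample order; columns are pixels in row-major
    order (pump outer, probe inner).  ``pixel_index`` maps a column back to
    its (pump, probe) wavenumbers; ``unflatten`` restores the 2D map.
    """

    X: np.ndarray  # n_samples x n_pixels
    labels: list
    grid: AxisGrid
    records: list
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.X.shape[1] != self.grid.n_pixels:
            raise ValueError("X column count does not match the grid pixel count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X must be finite")

    def pixel_index(self, column: int) -> tuple[float, float]:
        n_probe = self.grid.probe_axis.size
        if not 0 <= column < self.grid.n_pixels:
            raise IndexError(f"pixel column {column} out of range")
        return (
            float(self.grid.pump_axis[column // n_probe]),
            float(self.grid.probe_axis[column % n_probe]),
        )

    def column_of(self, pump: float, probe: float) -> int:
        from .gridmap import nearest_index

        i = nearest_index(self.grid.pump_axis, pump)
        j = nearest_index(self.grid.probe_axis, probe)
        return i * self.grid.probe_axis.size + j

    def unflatten(self, row: np.ndarray) -> SpectrumMap2D:
        return SpectrumMap2D(
            grid=self.grid,
            amplitudes=np.asarray(row, dtype=float).reshape(self.grid.shape),
            waiting_time=0.25,
        )


def correct_and_normalize(
    map250: SpectrumMap2D, map5ps: SpectrumMap2D, config: PreprocessConfig | None = None
) -> SpectrumMap2D:
    """Thermal-reference baseline correction and normalisation.

    The 5 ps map is taken as the thermal water reference.  Its maximum
    absolute amplitude s sets the normalisation scale; the unit-scaled
    reference profile is least-squares fitted to the 0.25 ps map over
    off-amide cells (probe outside the band window) and subtracted, removing
    the residual thermal leak; the result is divided by s.  Dividing the
    reference by the same s maps it to a maximum of exactly 1, and because s
    is proportional to the sample path length the output is invariant to
    path-length and intensity scaling of the raw pair.
    """
    config = config or PreprocessConfig()
    if not map250.grid.same_as(map5ps.grid):
        raise ValueError("the two waiting-time maps must share one grid")
    # The thermal response is pump-independent, so the pump-averaged probe
    # profile estimates the reference bandwidth with ~sqrt(n_pump) less
    # noise than any single cell; its peak sets the normalisation scale.
    profile = map5ps.amplitudes.mean(axis=0)
    s = float(np.max(np.abs(profile)))
    if s == 0:
        raise ValueError("degenerate thermal reference: 5 ps map is identically zero")
    ref = np.tile(profile / s, (map5ps.grid.pump_axis.size, 1))
    probe = map250.grid.probe_axis
    mask = (probe < config.mask_low) | (probe > config.mask_high)
    if not np.any(mask):
        raise ValueError("off-amide mask is empty; widen the mask bounds")
    r = ref[:, mask].ravel()
    m = map250.amplitudes[:, mask].ravel()
    alpha = float(r @ m) / float(r @ r)
    corrected = (map250.amplitudes - alpha * ref) / s
    return map250.copy_with(corrected)


def smooth_sg(map_: SpectrumMap2D, window: int = 7, order: int = 3) -> SpectrumMap2D:
    """Savitzky-Golay smoothing along the probe (read-out) axis of each pump
    row.  Edges are handled by evaluating the polynomial fitted to the last
    full window.  Smoothing is 1D only: 2D kernels would blur the diagonal
    fundamental/overtone structure across the anharmonic shift.
    """
    if window % 2 == 0 or window <= order or order < 0:
        raise ValueError("window must be odd and greater than order >= 0")
    if window > map_.grid.probe_axis.size:
        raise ValueError("window exceeds probe axis length")
    sm = savgol_filter(map_.amplitudes, window, order, axis=1, mode="interp")
    return map_.copy_with(sm)


def pca_denoise(maps: list, k: int | float = 0.99) -> list:
    """PCA noise reduction across samples.

    Flattened maps are stacked (samples x pixels), pixel means removed, and
    each spectrum reconstructed from the leading principal components: an
    integer ``k`` keeps exactly k components, a fraction keeps the smallest
    number explaining at least that share of variance.
    """
    if len(maps) < 2:
        raise ValueError("PCA noise reduction needs at least two maps")
    grid = maps[0].grid
    if not all(m.grid.same_as(grid) for m in maps):
        raise ValueError("all maps must share one grid")
    X = np.stack([m.flatten() for m in maps])
    mean = X.mean(axis=0)
    Xc = X - mean
    # n_samples << n_pixels: SVD of the thin matrix
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if isinstance(k, (int, np.integer)) and not isinstance(k, bool):
        if not 1 <= k <= len(maps):
            raise ValueError(f"k={k} out of range [1, {len(maps)}]")
        keep = int(k)
    else:
        if not 0 < k <= 1:
            raise ValueError("variance fraction must lie in (0, 1]")
        var = S**2
        total = var.sum()
        if total == 0:
            keep = 1
        else:
            frac = np.cumsum(var) / total
            keep = int(np.searchsorted(frac, k - 1e-12) + 1)
    recon = U[:, :keep] @ np.diag(S[:keep]) @ Vt[:keep] + mean
    return [m.copy_with(recon[i].reshape(grid.shape)) for i, m in enumerate(maps)]


def build_design_matrix(maps: list, records: list, provenance: str = "") -> ProcessedDataset:
    """Flatten preprocessed maps into the analysis matrix, preserving the
    manifest sample order and recording the pixel <-> (pump, probe) bijection."""
    if len(maps) != len(records):
        raise ValueError("one map per record required")
    grid = maps[0].grid
    if not all(m.grid.same_as(grid) for m in maps):
        raise ValueError("all maps must share one grid")
    X = np.stack([m.flatten() for m in maps])
    return ProcessedDataset(
        X=X,
        labels=[r.class_label for r in records],
        grid=grid,
        records=list(records),
        provenance=provenance,
    )


def preprocess_dataset(dataset: Dataset, config: RunConfig | None = None) -> ProcessedDataset:
    """Run the full fixed-order pipeline on a generated or loaded dataset."""
    config = config or dataset.config
    pp = config.preprocess
    corrected = [
        correct_and_normalize(a, b, pp)
        for a, b in zip(dataset.maps_250fs, dataset.maps_5ps)
    ]
    smoothed = [smooth_sg(m, pp.sg_window, pp.sg_order) for m in corrected]
    denoised = pca_denoise(smoothed, pp.pca_variance)
    return build_design_matrix(denoised, dataset.records, provenance=config_hash(config))
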