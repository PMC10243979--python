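"""Energy calibration and per-pixel batch fitting of spectrum cubes.

The fit is linear: each element contributes a fixed unit-amount spectrum
(Gaussians at its excitable line energies, detector-width), plus optional
constant and linear baseline columns, solved per pixel by non-negative
least squares.  Channels in the scatter region near the excitation energy
are masked by default because scatter is not part of the emission model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize

from .errors import CatalogueError, DegenerateDataError, InsufficientDataError
from .line_physics import BeamConfig, DetectorModel, LineCatalogue
from .spectrum_sim import simulate

__all__ = [
    "SpectrumCube",
    "ElementMapSet",
    "EnergyCalibration",
    "calibrate_energy",
    "build_design_matrix",
    "fit_pixel",
    "batch_fit",
]

logger = logging.getLogger(__name__)

BASELINE_COMPONENTS = ("baseline_const", "baseline_slope")


@dataclass(frozen=True)
class EnergyCalibration:
    """Linear channel -> energy map: E = gain * channel + offset."""

    gain: float
    offset: float
    residuals_keV: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        object.__setattr__(self, "residuals_keV",
                           np.asarray(self.residuals_keV, dtype=float))

    def energy(self, channels: np.ndarray) -> np.ndarray:
        return self.gain * np.asarray(channels, dtype=float) + self.offset

    def grid(self, n_channels: int) -> np.ndarray:
        return self.energy(np.arange(n_channels))


@dataclass
class SpectrumCube:
    """(rows x cols x channels) counts with linear energy calibration."""

    counts: np.ndarray
    gain: float
    offset: float
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be rows x cols x channels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def energy_grid(self) -> np.ndarray:
        return self.offset + self.gain * np.arange(self.counts.shape[2])


@dataclass
class ElementMapSet:
    """Per-element amplitude maps plus the per-pixel residual norm."""

    maps: dict[str, np.ndarray]
    residual_norm: np.ndarray
    elements: tuple[str, ...]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()} | {self.residual_norm.shape}
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")
        for el, m in self.maps.items():
            if np.any(m < 0):
                raise ValueError(f"negative amplitudes in map for {el}")

    def __getitem__(self, element: str) -> np.ndarray:
        return self.maps[element]


def calibrate_energy(observed_peak_channels: Sequence[float],
                     known_energies_keV: Sequence[float]) -> EnergyCalibration:
    """Least-squares line through (channel, energy) pairs."""
    channels = np.asarray(observed_peak_channels, dtype=float)
    energies = np.asarray(known_energies_keV, dtype=float)
    if channels.shape != energies.shape or channels.ndim != 1:
        raise ValueError("channel and energy lists must be 1-D and equal length")
    if len(channels) < 2:
        raise InsufficientDataError(
            f"energy calibration needs >= 2 pairs, got {len(channels)}")
    if np.ptp(channels) == 0:
        raise DegenerateDataError("zero spread in peak channels")
    design = np.column_stack([channels, np.ones_like(channels)])
    (gain, offset), *_ = np.linalg.lstsq(design, energies, rcond=None)
    residuals = energies - (gain * channels + offset)
    return EnergyCalibration(gain=float(gain), offset=float(offset),
                             residuals_keV=residuals)


def scatter_mask(grid: np.ndarray, beam: BeamConfig,
                 detector: DetectorModel) -> np.ndarray:
    """Boolean mask of channels to KEEP: energies below the scatter region
    starting 3 FWHM under the excitation energy."""
    cutoff = beam.excitation_keV - 3.0 * detector.fwhm_at(beam.excitation_keV) / 1e3
    return grid < cutoff


def build_design_matrix(elements: Sequence[str], calibration: EnergyCalibration,
                        detector: DetectorModel, beam: BeamConfig,
                        n_channels: int, include_baseline: bool = False,
                        channel_mask: np.ndarray | None = None,
                        catalogue: LineCatalogue | None = None,
                        ) -> tuple[np.ndarray, tuple[str, ...]]:
    """Channels x components matrix: one unit-amount simulated spectrum per
    element, in the given order, plus optional constant + linear baseline
    columns.  Raises :class:`CatalogueError` naming any element with no
    excitable line under ``beam``."""
    cat = catalogue or LineCatalogue.default()
    grid = calibration.grid(n_channels)
    if channel_mask is not None:
        channel_mask = np.asarray(channel_mask, dtype=bool)
        grid = grid[channel_mask]
    columns, names = [], []
    for element in elements:
        if not cat.get_lines(element, beam=beam):
            raise CatalogueError(
                f"element {element!r} has no line excitable at "
                f"{beam.excitation_keV:g} keV")
        spectrum = simulate({element: 1.0}, beam, detector, grid=grid,
                            catalogue=cat, require_coverage=False)
        columns.append(spectrum.counts)
        names.append(element)
    if include_baseline:
        columns.append(np.ones_like(grid))
        columns.append(np.linspace(0.0, 1.0, len(grid)))
        names.extend(BASELINE_COMPONENTS)
    return np.column_stack(columns), tuple(names)


def fit_pixel(spectrum: np.ndarray, design: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve min ||design @ a - spectrum||^2 subject to a >= 0."""
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1 or design.ndim != 2 or design.shape[0] != len(spectrum):
        raise ValueError(
            f"shape mismatch: design {design.shape} vs spectrum {spectrum.shape}")
    amplitudes, residual = scipy.optimize.nnls(design, spectrum)
    return amplitudes, float(residual)


def batch_fit(cube: SpectrumCube, elements: Sequence[str],
              detector: DetectorModel, beam: BeamConfig,
              include_baseline: bool = False, mask_scatter: bool = True,
              catalogue: LineCatalogue | None = None) -> ElementMapSet:
    """Apply :func:`fit_pixel` to every pixel of the cube.

    An unconstrained least-squares solve covers all pixels at once; only
    pixels whose unconstrained solution leaves the feasible region are
    re-solved with NNLS (identical optimum, much faster on clean data).
    """
    rows, cols, n_channels = cube.shape
    calibration = EnergyCalibration(gain=cube.gain, offset=cube.offset)
    keep = None
    if mask_scatter:
        keep = scatter_mask(cube.energy_grid, beam, detector)
    design, names = build_design_matrix(
        elements, calibration, detector, beam, n_channels,
        include_baseline=include_baseline, channel_mask=keep,
        catalogue=catalogue)
    data = cube.counts.reshape(rows * cols, n_channels)
    if keep is not None:
        data = data[:, keep]

    solution, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    solution = solution.T  # pixels x components
    refit = np.flatnonzero(np.any(solution < 0, axis=1))
    logger.info("batch_fit: %d pixels, %d NNLS refits (%s)",
                rows * cols, len(refit), ", ".join(names))
    for idx in refit:
        try:
            solution[idx], _ = fit_pixel(data[idx], design)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"fit failed at pixel (row={idx // cols}, col={idx % cols}): {exc}"
            ) from exc
    solution = np.clip(solution, 0.0, None)  # clear float round-off
    residual = np.linalg.norm(design @ solution.T - data.T, axis=0)

    maps = {
        name: solution[:, j].reshape(rows, cols)
        for j, name in enumerate(names) if name not in BASELINE_COMPONENTS
    }
    return ElementMapSet(maps=maps, residual_norm=residual.reshape(rows, cols),
                         elements=tuple(elements),
                         pixel_size_um=cube.pixel_size_um)
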