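"""Forward simulation of XRF spectra from element amounts.

Emission-only model: each excitable line contributes a Gaussian whose area
equals ``amount * rel_intensity`` and whose width is set by the detector
resolution at the line energy.  No pile-up, escape, scatter or background
components are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .errors import CoverageError
from .line_physics import BeamConfig, DetectorModel, LineCatalogue

__all__ = [
    "ElementAmounts",
    "SimulatedSpectrum",
    "default_grid",
    "simulate",
    "add_poisson_noise",
]

DEFAULT_STEP_KEV = 0.010


class ElementAmounts(Mapping):
    """Mapping element symbol -> amount in linear peak-area units.

    Amounts must be non-negative and every symbol must exist in the line
    catalogue; unknown symbols are rejected at construction.
    """

    def __init__(self, amounts: Mapping[str, float],
                 catalogue: LineCatalogue | None = None):
        cat = catalogue or LineCatalogue.default()
        clean: dict[str, float] = {}
        for element, value in amounts.items():
            if element not in cat:
                cat.lines(element)  # raises CatalogueError naming the symbol
            value = float(value)
            if value < 0:
                raise ValueError(f"negative amount for {element}: {value}")
            clean[element] = value
        self._amounts = clean

    def __getitem__(self, element: str) -> float:
        return self._amounts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._amounts)

    def __len__(self) -> int:
        return len(self._amounts)

    def __repr__(self) -> str:
        return f"ElementAmounts({self._amounts!r})"


@dataclass(frozen=True)
class SimulatedSpectrum:
    """Counts-per-keV values on a uniform ascending energy grid."""

    energy_keV: np.ndarray
    counts: np.ndarray
    gain: float
    offset: float

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_keV, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if e.ndim != 1 or c.shape != e.shape:
            raise ValueError("energy grid and counts must be 1-D and equal length")
        if len(e) >= 2 and not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly ascending")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "energy_keV", e)
        object.__setattr__(self, "counts", c)

    def __len__(self) -> int:
        return len(self.energy_keV)


def default_grid(beam: BeamConfig, step_keV: float = DEFAULT_STEP_KEV,
                 start_keV: float = 0.0) -> np.ndarray:
    """Uniform grid from ``start_keV`` to the excitation energy inclusive."""
    if step_keV <= 0:
        raise ValueError("step_keV must be positive")
    n = int(np.floor((beam.excitation_keV - start_keV) / step_keV)) + 1
    return start_keV + step_keV * np.arange(n)


def simulate(amounts: Mapping[str, float], beam: BeamConfig,
             detector: DetectorModel, grid: np.ndarray | None = None,
             catalogue: LineCatalogue | None = None,
             require_coverage: bool = True) -> SimulatedSpectrum:
    """Simulate the emission spectrum of ``amounts`` under ``beam``.

    The grid must cover every excitable line of every element with a
    positive amount; a line outside the grid raises :class:`CoverageError`
    naming it.  Elements whose every shell edge lies above the excitation
    energy contribute nothing.  ``require_coverage=False`` evaluates
    out-of-grid lines anyway (their tails still contribute) — used when
    fitting on a deliberately truncated channel range.
    """
    cat = catalogue or LineCatalogue.default()
    if not isinstance(amounts, ElementAmounts):
        amounts = ElementAmounts(amounts, catalogue=cat)
    if grid is None:
        grid = default_grid(beam)
    grid = np.asarray(grid, dtype=float)
    counts = np.zeros_like(grid)
    for element, amount in amounts.items():
        if amount == 0:
            continue
        for line in cat.get_lines(element, beam=beam):
            if require_coverage and not grid[0] <= line.energy_keV <= grid[-1]:
                raise CoverageError(
                    f"grid [{grid[0]:g}, {grid[-1]:g}] keV does not cover "
                    f"{element} {line.transition} at {line.energy_keV:g} keV"
                )
            sigma = detector.sigma_keV(line.energy_keV)
            area = amount * line.rel_intensity
            counts += area * np.exp(
                -0.5 * ((grid - line.energy_keV) / sigma) ** 2
            ) / (sigma * np.sqrt(2.0 * np.pi))
    step = float(grid[1] - grid[0]) if len(grid) > 1 else 1.0
    return SimulatedSpectrum(energy_keV=grid, counts=counts,
                             gain=step, offset=float(grid[0]))


def add_poisson_noise(spectrum: SimulatedSpectrum, seed: int) -> SimulatedSpectrum:
    """Replace every value by a Poisson draw with that mean (reproducible)."""
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(spectrum.counts).astype(float)
    return SimulatedSpectrum(energy_keV=spectrum.energy_keV, counts=noisy,
                             gain=spectrum.gain, offset=spectrum.offset)
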