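"""X-ray emission-line catalogue and silicon-drift-detector resolution model.

The catalogue is a static table embedded with the package
(``data/emission_lines.csv``), covering the K series of the light elements
relevant to soft tissue and common exogenous metals, and the L series of the
lanthanides.  Relative intensities are normalized within each
(element, series) group so the principal line carries ``rel_intensity = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import pandas as pd

from .errors import CatalogueError

__all__ = [
    "EmissionLine",
    "DetectorModel",
    "BeamConfig",
    "LineCatalogue",
    "get_lines",
    "principal_line",
    "fwhm_at",
    "ATOMIC_NUMBER",
    "LANTHANIDES",
    "STABLE_LANTHANIDES",
    "DEFAULT_ENDOGENOUS",
    "GAUSS_FWHM_FACTOR",
]

#: 2 * sqrt(2 * ln 2) — converts a Gaussian sigma to its FWHM.
GAUSS_FWHM_FACTOR = 2.3548200450309493

ATOMIC_NUMBER = {
    "P": 15, "S": 16, "Cl": 17, "K": 19, "Ca": 20, "Ti": 22, "V": 23,
    "Cr": 24, "Mn": 25, "Fe": 26, "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30,
    "La": 57, "Ce": 58, "Pr": 59, "Nd": 60, "Pm": 61, "Sm": 62, "Eu": 63,
    "Gd": 64, "Tb": 65, "Dy": 66, "Ho": 67, "Er": 68, "Tm": 69, "Yb": 70,
    "Lu": 71,
}

LANTHANIDES = ("La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb", "Dy",
               "Ho", "Er", "Tm", "Yb", "Lu")

#: The 14 stable lanthanides (Pm has no stable isotope) — the default
#: candidate-label panel.
STABLE_LANTHANIDES = tuple(el for el in LANTHANIDES if el != "Pm")

#: Default soft-tissue endogenous panel (high signal-to-noise K emitters).
DEFAULT_ENDOGENOUS = ("Cl", "K", "Ca", "Fe", "Zn")


@dataclass(frozen=True)
class EmissionLine:
    """One radiative transition of one element.

    ``rel_intensity`` is the emission probability relative to the principal
    line of the same (element, series) group, in (0, 1].
    """

    element: str
    transition: str
    energy_keV: float
    rel_intensity: float
    edge_keV: float
    series: str

    def __post_init__(self) -> None:
        if self.energy_keV <= 0:
            raise ValueError(f"non-positive line energy: {self.energy_keV}")
        if not self.energy_keV < self.edge_keV:
            raise ValueError(
                f"{self.element} {self.transition}: emitted photon energy "
                f"{self.energy_keV} keV must lie below the ionized-shell edge "
                f"{self.edge_keV} keV"
            )
        if not 0 < self.rel_intensity <= 1:
            raise ValueError(f"rel_intensity outside (0, 1]: {self.rel_intensity}")
        if self.series not in ("K", "L"):
            raise ValueError(f"unknown series: {self.series!r}")

    @property
    def subshell(self) -> str:
        """Ionized subshell implied by the IUPAC transition code."""
        return self.transition[:2] if self.series == "L" else "K"


@dataclass(frozen=True)
class BeamConfig:
    """Monochromatic incident beam; only shells with an edge below
    ``excitation_keV`` fluoresce."""

    excitation_keV: float

    def __post_init__(self) -> None:
        if self.excitation_keV <= 0:
            raise ValueError("excitation_keV must be positive")

    def excites(self, line: EmissionLine) -> bool:
        return line.edge_keV < self.excitation_keV


@dataclass(frozen=True)
class DetectorModel:
    """Energy-dependent resolution of a Si drift detector.

    FWHM(E) = sqrt(noise^2 + (2.3548^2) * fano * pair_creation * E)
    with every energy in eV.
    """

    electronic_noise_eV: float
    fano: float = 0.115
    pair_creation_eV: float = 3.85

    def __post_init__(self) -> None:
        if self.electronic_noise_eV < 0 or self.fano < 0 or self.pair_creation_eV <= 0:
            raise ValueError("detector parameters must be non-negative (pair energy positive)")

    def fwhm_at(self, energy_keV: float) -> float:
        """Resolution FWHM in eV at the given photon energy."""
        if energy_keV <= 0:
            raise ValueError(f"energy must be positive, got {energy_keV}")
        return math.sqrt(
            self.electronic_noise_eV ** 2
            + GAUSS_FWHM_FACTOR ** 2 * self.fano * self.pair_creation_eV * energy_keV * 1e3
        )

    def sigma_keV(self, energy_keV: float) -> float:
        """Gaussian sigma (keV) of a peak centred at ``energy_keV``."""
        return self.fwhm_at(energy_keV) / GAUSS_FWHM_FACTOR / 1e3

    @classmethod
    def default(cls, reference_fwhm_eV: float = 140.0,
                reference_energy_keV: float = 5.895) -> "DetectorModel":
        """Detector whose electronic noise is solved so FWHM at the reference
        energy (Mn Ka by default) equals ``reference_fwhm_eV`` exactly."""
        fano, pair = 0.115, 3.85
        statistical = GAUSS_FWHM_FACTOR ** 2 * fano * pair * reference_energy_keV * 1e3
        noise_sq = reference_fwhm_eV ** 2 - statistical
        if noise_sq < 0:
            raise ValueError("reference resolution below the statistical limit")
        return cls(electronic_noise_eV=math.sqrt(noise_sq), fano=fano, pair_creation_eV=pair)


class LineCatalogue:
    """In-memory view of the embedded emission-line table."""

    def __init__(self, table: pd.DataFrame):
        required = {"element", "transition", "energy_keV", "rel_intensity",
                    "edge_keV", "series"}
        missing = required - set(table.columns)
        if missing:
            raise CatalogueError(f"catalogue table missing columns: {sorted(missing)}")
        self._table = table.reset_index(drop=True)
        self._by_element: dict[str, tuple[EmissionLine, ...]] = {}
        for el, group in table.groupby("element", sort=False):
            lines = tuple(
                EmissionLine(row.element, row.transition, row.energy_keV,
                             row.rel_intensity, row.edge_keV, row.series)
                for row in group.itertuples(index=False)
            )
            self._by_element[el] = tuple(
                sorted(lines, key=lambda l: (-l.rel_intensity, l.energy_keV))
            )

    @classmethod
    def from_csv(cls, path) -> "LineCatalogue":
        return cls(pd.read_csv(path))

    @classmethod
    def default(cls) -> "LineCatalogue":
        return _load_default_catalogue()

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self._by_element)

    def __contains__(self, element: str) -> bool:
        return element in self._by_element

    def lines(self, element: str) -> tuple[EmissionLine, ...]:
        try:
            return self._by_element[element]
        except KeyError:
            raise CatalogueError(
                f"element {element!r} not in catalogue (known: {', '.join(self.elements)})"
            ) from None

    def get_lines(self, element: str, beam: BeamConfig | None = None,
                  min_rel_intensity: float = 0.0) -> list[EmissionLine]:
        """Lines of ``element`` excitable under ``beam`` (no gating when
        ``beam`` is None) with ``rel_intensity >= min_rel_intensity``,
        sorted by descending relative intensity.

        An element with no excitable shell yields an empty list.
        """
        if not 0 <= min_rel_intensity <= 1:
            raise ValueError("min_rel_intensity must lie in [0, 1]")
        out = [l for l in self.lines(element) if l.rel_intensity >= min_rel_intensity]
        if beam is not None:
            out = [l for l in out if beam.excites(l)]
        return out

    def principal_line(self, element: str, series: str) -> EmissionLine:
        """The maximal-``rel_intensity`` line of the requested series
        (L3M5 for lanthanide L, KL3 for K emitters)."""
        candidates = [l for l in self.lines(element) if l.series == series]
        if not candidates:
            raise CatalogueError(f"element {element!r} has no {series}-series lines")
        return max(candidates, key=lambda l: l.rel_intensity)

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()


@lru_cache(maxsize=1)
def _load_default_catalogue() -> LineCatalogue:
    ref = resources.files("xrflabel").joinpath("data/emission_lines.csv")
    with resources.as_file(ref) as path:
        return LineCatalogue.from_csv(path)


def get_lines(element: str, beam: BeamConfig | None = None,
              min_rel_intensity: float = 0.0,
              catalogue: LineCatalogue | None = None) -> list[EmissionLine]:
    cat = catalogue or LineCatalogue.default()
    return cat.get_lines(element, beam, min_rel_intensity)


def principal_line(element: str, series: str,
                   catalogue: LineCatalogue | None = None) -> EmissionLine:
    cat = catalogue or LineCatalogue.default()
    return cat.principal_line(element, series)


def fwhm_at(detector: DetectorModel, energy_keV: float) -> float:
    """Detector FWHM in eV at ``energy_keV`` (> 0)."""
    return detector.fwhm_at(energy_keV)
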