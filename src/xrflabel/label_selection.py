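"""Selection of lanthanide antibody tags free of fluorescence-peak overlap.

Two elements clash when a line of one falls within a resolution-scaled
energy window of a line of the other.  Candidate labels are screened against
the endogenous tissue panel (disqualifying) and against any expected
exogenous elements (advisory: reported, but the label stays usable).

Default criterion
-----------------
* endogenous test: the label's principal line only
  (``label_line_cutoff = 1.0``) against endogenous Ka lines
  (``endo_line_cutoff = 0.2`` keeps KL3/KL2, drops Kb), window
  1.0 x FWHM at the pair midpoint;
* exogenous advisory test: the label's principal line against interferer
  lines with ``rel_intensity >= 0.10`` (Ka and Kb), window 1.8 x FWHM
  (about 250 eV in the 5-6 keV region).

With the default soft-tissue panel this leaves 12 of the 14 stable
lanthanides usable (Tb and Dy fall on Fe Ka) and flags Nd, Sm, Eu and Gd
when Cr is expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError
from .line_physics import (
    ATOMIC_NUMBER,
    DEFAULT_ENDOGENOUS,
    STABLE_LANTHANIDES,
    BeamConfig,
    DetectorModel,
    EmissionLine,
    LineCatalogue,
)

__all__ = [
    "ConvolutionCriterion",
    "Clash",
    "ConvolutionReport",
    "find_clashes",
    "select_labels",
    "report_to_table",
]

PILEUP_WARNING = ("Pile-up peaks may be a source of convolution: "
                  "2x {source} {source_line} ({pileup_keV:.3f} keV) lies within "
                  "{window_eV:.0f} eV of {label} {label_line} ({label_keV:.3f} keV)")


@dataclass(frozen=True)
class ConvolutionCriterion:
    """Windows and line cutoffs defining a peak clash.

    Windows are multiples of the detector FWHM evaluated at the midpoint of
    the two line energies; cutoffs are minimum relative intensities for a
    line to participate in the comparison.
    """

    endogenous_window_multiplier: float = 1.0
    exogenous_window_multiplier: float = 1.8
    endo_line_cutoff: float = 0.2
    exo_line_cutoff: float = 0.10
    label_line_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.endogenous_window_multiplier <= 0 or self.exogenous_window_multiplier <= 0:
            raise ValueError("window multipliers must be positive")
        for name in ("endo_line_cutoff", "exo_line_cutoff", "label_line_cutoff"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class Clash:
    """A pair of lines from two elements closer than the applicable window."""

    label: str
    interferer: str
    label_line: EmissionLine
    interferer_line: EmissionLine
    delta_eV: float
    window_eV: float

    def __post_init__(self) -> None:
        if not self.delta_eV < self.window_eV:
            raise ValueError("clash recorded outside its window")


@dataclass
class ConvolutionReport:
    """Outcome of screening candidate labels against element panels."""

    candidates: tuple[str, ...]
    usable: tuple[str, ...]
    endogenous_clashes: list[Clash] = field(default_factory=list)
    exogenous_clashes: list[Clash] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.usable) <= set(self.candidates):
            raise ValueError("usable labels must be a subset of candidates")

    @property
    def clashes(self) -> dict[tuple[str, str], list[Clash]]:
        """All clashes keyed by (label, interfering element)."""
        out: dict[tuple[str, str], list[Clash]] = {}
        for clash in [*self.endogenous_clashes, *self.exogenous_clashes]:
            out.setdefault((clash.label, clash.interferer), []).append(clash)
        return out

    @property
    def advisory_exclusions(self) -> tuple[str, ...]:
        """Labels flagged by at least one exogenous clash."""
        flagged = {c.label for c in self.exogenous_clashes}
        return tuple(el for el in self.candidates if el in flagged)


def _pair_clashes(lines_a: Sequence[EmissionLine], lines_b: Sequence[EmissionLine],
                  detector: DetectorModel, window_multiplier: float) -> list[Clash]:
    out = []
    for la in lines_a:
        for lb in lines_b:
            midpoint = 0.5 * (la.energy_keV + lb.energy_keV)
            window = window_multiplier * detector.fwhm_at(midpoint)
            delta = abs(la.energy_keV - lb.energy_keV) * 1e3
            if delta < window:
                out.append(Clash(la.element, lb.element, la, lb, delta, window))
    return out


def find_clashes(panel_a: Sequence[str], panel_b: Sequence[str],
                 detector: DetectorModel, beam: BeamConfig | None = None,
                 criterion: ConvolutionCriterion | None = None,
                 catalogue: LineCatalogue | None = None) -> list[Clash]:
    """Exhaustive pairwise line comparison between two disjoint panels.

    Every line of an element in ``panel_a`` passing the exogenous cutoff is
    compared against every such line of ``panel_b``; the result is symmetric
    in panel order up to swapping the roles in each :class:`Clash`.
    ``beam=None`` disables excitation gating (panel-design mode).
    """
    if not panel_a or not panel_b:
        raise ConfigurationError("panels must be non-empty")
    overlap = set(panel_a) & set(panel_b)
    if overlap:
        raise ConfigurationError(f"panels overlap: {sorted(overlap)}")
    crit = criterion or ConvolutionCriterion()
    cat = catalogue or LineCatalogue.default()
    clashes: list[Clash] = []
    for el_a in panel_a:
        lines_a = cat.get_lines(el_a, beam=beam, min_rel_intensity=crit.exo_line_cutoff)
        for el_b in panel_b:
            lines_b = cat.get_lines(el_b, beam=beam,
                                    min_rel_intensity=crit.exo_line_cutoff)
            clashes.extend(
                _pair_clashes(lines_a, lines_b, detector,
                              crit.exogenous_window_multiplier)
            )
    return clashes


def _pileup_warnings(labels: Iterable[str], sources: Iterable[str],
                     detector: DetectorModel, crit: ConvolutionCriterion,
                     cat: LineCatalogue) -> list[str]:
    """Flag doubled principal-Ka energies of light elements landing on a
    label line (sum-peak pile-up is otherwise outside the model)."""
    out = []
    for source in sources:
        k_lines = [l for l in cat.lines(source) if l.series == "K"]
        if not k_lines:
            continue
        ka = max(k_lines, key=lambda l: l.rel_intensity)
        pileup_keV = 2.0 * ka.energy_keV
        for label in labels:
            for line in cat.get_lines(label, min_rel_intensity=crit.label_line_cutoff):
                midpoint = 0.5 * (pileup_keV + line.energy_keV)
                window = crit.endogenous_window_multiplier * detector.fwhm_at(midpoint)
                if abs(pileup_keV - line.energy_keV) * 1e3 < window:
                    out.append(PILEUP_WARNING.format(
                        source=source, source_line=ka.transition,
                        pileup_keV=pileup_keV, window_eV=window,
                        label=label, label_line=line.transition,
                        label_keV=line.energy_keV))
    return out


def select_labels(endogenous: Sequence[str] = DEFAULT_ENDOGENOUS,
                  exogenous: Sequence[str] = (),
                  candidates: Sequence[str] = STABLE_LANTHANIDES,
                  detector: DetectorModel | None = None,
                  beam: BeamConfig | None = None,
                  criterion: ConvolutionCriterion | None = None,
                  catalogue: LineCatalogue | None = None) -> ConvolutionReport:
    """Screen candidate labels against endogenous and exogenous panels.

    Endogenous clashes remove a candidate from ``usable``; exogenous clashes
    are advisory only.  ``beam=None`` (the default) screens the full
    catalogue irrespective of a particular acquisition energy.
    """
    if set(candidates) & set(endogenous):
        raise ConfigurationError(
            f"candidates also listed as endogenous: "
            f"{sorted(set(candidates) & set(endogenous))}"
        )
    detector = detector or DetectorModel.default()
    crit = criterion or ConvolutionCriterion()
    cat = catalogue or LineCatalogue.default()
    if not candidates:
        return ConvolutionReport(candidates=(), usable=())

    endo_clashes: list[Clash] = []
    exo_clashes: list[Clash] = []
    for label in candidates:
        label_lines = cat.get_lines(label, beam=beam,
                                    min_rel_intensity=crit.label_line_cutoff)
        for el in endogenous:
            endo_lines = cat.get_lines(el, beam=beam,
                                       min_rel_intensity=crit.endo_line_cutoff)
            endo_clashes.extend(_pair_clashes(
                label_lines, endo_lines, detector,
                crit.endogenous_window_multiplier))
        for el in exogenous:
            exo_lines = cat.get_lines(el, beam=beam,
                                      min_rel_intensity=crit.exo_line_cutoff)
            exo_clashes.extend(_pair_clashes(
                label_lines, exo_lines, detector,
                crit.exogenous_window_multiplier))

    blocked = {c.label for c in endo_clashes}
    usable = tuple(el for el in candidates if el not in blocked)
    warnings = _pileup_warnings(candidates, [*endogenous, *exogenous],
                                detector, crit, cat)
    return ConvolutionReport(
        candidates=tuple(candidates), usable=usable,
        endogenous_clashes=endo_clashes, exogenous_clashes=exo_clashes,
        warnings=warnings,
    )


def report_to_table(report: ConvolutionReport) -> pd.DataFrame:
    """One row per clashing line pair, ordered by label atomic number then
    interferer; the usable-label list travels in ``DataFrame.attrs``."""
    rows = []
    for kind, clashes in (("endogenous", report.endogenous_clashes),
                          ("exogenous", report.exogenous_clashes)):
        for c in clashes:
            rows.append({
                "kind": kind,
                "label": c.label,
                "interferer": c.interferer,
                "label_line": c.label_line.transition,
                "label_keV": c.label_line.energy_keV,
                "interferer_line": c.interferer_line.transition,
                "interferer_keV": c.interferer_line.energy_keV,
                "delta_eV": round(c.delta_eV, 2),
                "window_eV": round(c.window_eV, 2),
            })
    columns = ["kind", "label", "interferer", "label_line", "label_keV",
               "interferer_line", "interferer_keV", "delta_eV", "window_eV"]
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        table = table.sort_values(
            by=["label", "interferer", "delta_eV"],
            key=lambda col: col.map(ATOMIC_NUMBER) if col.name in ("label", "interferer") else col,
        ).reset_index(drop=True)
    table.attrs["usable"] = list(report.usable)
    table.attrs["warnings"] = list(report.warnings)
    return table
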