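"""Pipeline configuration: one JSON document with validated fields."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

from .errors import ConfigurationError
from .label_selection import ConvolutionCriterion
from .line_physics import (
    DEFAULT_ENDOGENOUS,
    STABLE_LANTHANIDES,
    BeamConfig,
    DetectorModel,
    LineCatalogue,
)

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Validated parameters shared across pipeline stages.

    Unknown keys are rejected so typos cannot silently fall back to
    defaults; every referenced element must exist in the line catalogue.
    """

    excitation_keV: float = 7.7
    detector_fwhm_eV: float = 140.0
    detector_reference_keV: float = 5.895
    endogenous: tuple[str, ...] = DEFAULT_ENDOGENOUS
    exogenous: tuple[str, ...] = ()
    candidates: tuple[str, ...] = STABLE_LANTHANIDES
    criterion: ConvolutionCriterion = field(default_factory=ConvolutionCriterion)
    threshold_factor: float = 10.0
    geometry_angle_deg: float = 45.0
    depth_step_um: float = 15.0
    pixel_size_um: float = 1.0
    min_cell_area_um2: float = 20.0
    max_cell_area_um2: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        catalogue = LineCatalogue.default()
        for panel_name in ("endogenous", "exogenous", "candidates"):
            panel = tuple(getattr(self, panel_name))
            setattr(self, panel_name, panel)
            for element in panel:
                if element not in catalogue:
                    raise ConfigurationError(
                        f"{panel_name}: unknown element {element!r}")
        if self.excitation_keV <= 0:
            raise ConfigurationError("excitation_keV must be positive")
        if self.threshold_factor <= 0:
            raise ConfigurationError("threshold_factor must be positive")
        if not 0 < self.geometry_angle_deg < 90:
            raise ConfigurationError("geometry_angle_deg must lie in (0, 90)")
        if not self.min_cell_area_um2 < self.max_cell_area_um2:
            raise ConfigurationError(
                "min_cell_area_um2 must be below max_cell_area_um2")

    @property
    def beam(self) -> BeamConfig:
        return BeamConfig(excitation_keV=self.excitation_keV)

    @property
    def detector(self) -> DetectorModel:
        return DetectorModel.default(
            reference_fwhm_eV=self.detector_fwhm_eV,
            reference_energy_keV=self.detector_reference_keV)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {sorted(unknown)}")
        payload = dict(payload)
        if "criterion" in payload and isinstance(payload["criterion"], dict):
            crit_fields = {f.name for f in fields(ConvolutionCriterion)}
            bad = set(payload["criterion"]) - crit_fields
            if bad:
                raise ConfigurationError(f"unknown criterion keys: {sorted(bad)}")
            payload["criterion"] = ConvolutionCriterion(**payload["criterion"])
        return cls(**payload)

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["endogenous"] = list(self.endogenous)
        payload["exogenous"] = list(self.exogenous)
        payload["candidates"] = list(self.candidates)
        return payload
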