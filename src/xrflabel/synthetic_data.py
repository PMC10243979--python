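"""Tissue phantoms with ground truth for every pipeline stage.

A map phantom is a circular tissue field (ECM class) on a low-signal
substrate (background class), carrying non-overlapping disk "cells", a
labelled CD45+ subset with imperfect per-pixel binding, sparse bright
exogenous Ti particles and Poisson counting noise.  A confocal phantom
stacks depth planes of particles whose persistence through depth grows
with their size, with the oblique-geometry lateral skew applied so the
shift correction has a known truth.

All randomness flows from the mandatory seed through one
``numpy.random.default_rng`` generator, so phantoms are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import scipy.ndimage

from .errors import ConfigurationError, PackingError
from .confocal_stack import ConfocalStack
from .line_physics import BeamConfig, DetectorModel, LineCatalogue
from .spectral_fit import SpectrumCube
from .spectrum_sim import default_grid, simulate

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "ConfocalPhantomConfig",
    "ConfocalTruth",
    "make_map_phantom",
    "make_spectrum_cube",
    "make_confocal_phantom",
]

#: Order-of-magnitude per-class mean amounts; real tissue concentrations are
#: not available, only the class contrast structure matters.
DEFAULT_ELEMENT_MEANS: dict[str, dict[str, float]] = {
    "background": {"Cl": 2.0, "K": 2.0, "P": 1.0, "Ca": 1.0,
                   "Fe": 0.5, "Zn": 0.5},
    "ecm":        {"Cl": 40.0, "K": 50.0, "P": 20.0, "Ca": 10.0,
                   "Fe": 5.0, "Zn": 3.0},
    "cell":       {"Cl": 60.0, "K": 80.0, "P": 200.0, "Ca": 15.0,
                   "Fe": 30.0, "Zn": 8.0},
}

TI_BASELINE = 10.0  # instrumental Ti baseline, identical in every class


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of a 2-D map phantom.  ``seed`` is mandatory."""

    seed: int
    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.0
    n_cells: int = 40
    cell_diameter_log_mu: float = 2.3   # lognormal of diameter in um (~10 um)
    cell_diameter_log_sigma: float = 0.2
    cd45_fraction: float = 0.7
    binding_efficiency: float = 0.98    # beta: P(label | CD45+ cell pixel)
    nonspecific_rate: float = 0.01      # gamma: P(label | background pixel)
    sm_amplitude: float = 50.0
    element_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_ELEMENT_MEANS)
    n_ti_particles: int = 8
    ti_diameter_log_mu: float = 1.2     # lognormal of diameter in um (~3.3 um)
    ti_diameter_log_sigma: float = 0.5
    ti_intensity_multiple: float = 50.0  # particle amplitude as multiple of baseline
    tissue_radius_fraction: float = 0.42
    counts_scale: float = 1.0
    noise: bool = True

    def __post_init__(self) -> None:
        for name in ("cd45_fraction", "binding_efficiency", "nonspecific_rate"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.cell_diameter_log_sigma <= 0 or self.ti_diameter_log_sigma <= 0:
            raise ConfigurationError("diameter distribution sigmas must be positive")
        if self.counts_scale <= 0 or self.pixel_size_um <= 0:
            raise ConfigurationError("scales must be positive")
        if not 0 < self.tissue_radius_fraction < 0.5:
            raise ConfigurationError("tissue_radius_fraction must lie in (0, 0.5)")


@dataclass
class PhantomTruth:
    """Ground truth emitted with every map phantom."""

    class_mask: np.ndarray          # 0 background, 1 ECM, 2 cell
    cell_id_map: np.ndarray         # 0 where no cell, ids from 2
    cell_diameters_um: dict[int, float]
    cd45_ids: frozenset[int]
    label_mask: np.ndarray          # true label-positive pixels
    ti_particles: list[dict]        # center, diameter_um, pixel index arrays
    background_levels: dict[str, float]
    mean_maps: dict[str, np.ndarray]  # pre-noise per-element amounts

    def __post_init__(self) -> None:
        if not self.cd45_ids <= set(self.cell_diameters_um):
            raise ValueError("CD45+ ids must exist in the cell id set")


def _disk_mask(shape: tuple[int, int], center: tuple[float, float],
               radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _place_disks(rng: np.random.Generator, allowed: np.ndarray,
                 radii_px: np.ndarray, gap_px: float = 1.0,
                 max_tries: int = 500) -> list[tuple[float, float]]:
    """Non-overlapping disk centers inside ``allowed`` (rejection sampling)."""
    shape = allowed.shape
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for radius in radii_px:
        for _ in range(max_tries):
            r = rng.uniform(radius, shape[0] - radius)
            c = rng.uniform(radius, shape[1] - radius)
            ir, ic = int(round(r)), int(round(c))
            if not allowed[ir, ic]:
                continue
            if all((r - pr) ** 2 + (c - pc) ** 2
                   > (radius + rr_ + gap_px) ** 2
                   for (pr, pc), rr_ in zip(centers, placed_r)):
                centers.append((r, c))
                placed_r.append(radius)
                break
        else:
            raise PackingError(
                f"could not place disk of radius {radius:.1f} px after "
                f"{max_tries} tries ({len(centers)} placed)")
    return centers


def make_map_phantom(config: PhantomConfig,
                     ) -> tuple[dict[str, np.ndarray], PhantomTruth]:
    """Generate per-element maps and their ground truth.

    Returned maps cover the configured endogenous elements plus ``Ti`` and
    ``Sm``; values are amounts (Poisson-noised when ``config.noise``).
    """
    rng = np.random.default_rng(config.seed)
    shape = config.shape
    center = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    tissue = _disk_mask(shape, center,
                        config.tissue_radius_fraction * min(shape))

    # --- cells ---------------------------------------------------------
    diameters_um = rng.lognormal(config.cell_diameter_log_mu,
                                 config.cell_diameter_log_sigma,
                                 config.n_cells)
    radii_px = diameters_um / 2 / config.pixel_size_um
    interior = _erode(tissue, int(np.ceil(radii_px.max())) + 1)
    centers = _place_disks(rng, interior, radii_px)
    class_mask = tissue.astype(np.uint8)  # 1 = ECM
    cell_id_map = np.zeros(shape, dtype=np.uint16)
    cell_diameters: dict[int, float] = {}
    for i, ((r, c), radius) in enumerate(zip(centers, radii_px)):
        cid = i + 2
        disk = _disk_mask(shape, (r, c), radius)
        cell_id_map[disk] = cid
        class_mask[disk] = 2
        cell_diameters[cid] = diameters_um[i]

    n_cd45 = int(round(config.cd45_fraction * config.n_cells))
    cd45_ids = frozenset(
        int(i) for i in rng.choice(sorted(cell_diameters), size=n_cd45,
                                   replace=False)) if n_cd45 else frozenset()

    # --- label deposition ---------------------------------------------
    label_mask = np.zeros(shape, dtype=bool)
    cd45_px = np.isin(cell_id_map, sorted(cd45_ids))
    label_mask[cd45_px] = rng.random(int(cd45_px.sum())) < config.binding_efficiency
    bg_px = class_mask == 0
    label_mask[bg_px] = rng.random(int(bg_px.sum())) < config.nonspecific_rate

    # --- Ti particles --------------------------------------------------
    ti_map = np.full(shape, TI_BASELINE * config.counts_scale)
    ti_particles: list[dict] = []
    if config.n_ti_particles:
        ti_diam_um = rng.lognormal(config.ti_diameter_log_mu,
                                   config.ti_diameter_log_sigma,
                                   config.n_ti_particles)
        ti_radii = np.maximum(ti_diam_um / 2 / config.pixel_size_um, 0.5)
        ti_centers = _place_disks(rng, tissue, ti_radii)
        amplitude = (config.ti_intensity_multiple * TI_BASELINE
                     * config.counts_scale)
        for (r, c), radius, diam in zip(ti_centers, ti_radii, ti_diam_um):
            disk = _disk_mask(shape, (r, c), radius)
            ti_map[disk] += amplitude
            ti_particles.append({
                "center": (float(r), float(c)),
                "diameter_um": float(diam),
                "pixels": np.argwhere(disk),
            })

    # --- element maps --------------------------------------------------
    means = {key: dict(val) for key, val in config.element_means.items()}
    class_names = {0: "background", 1: "ecm", 2: "cell"}
    elements = sorted({el for table in means.values() for el in table})
    mean_maps: dict[str, np.ndarray] = {}
    for el in elements:
        out = np.zeros(shape)
        for cls, name in class_names.items():
            out[class_mask == cls] = means[name].get(el, 0.0) * config.counts_scale
        mean_maps[el] = out
    mean_maps["Ti"] = ti_map
    mean_maps["Sm"] = (label_mask * config.sm_amplitude * config.counts_scale)

    maps = {
        el: (rng.poisson(m).astype(float) if config.noise else m.copy())
        for el, m in mean_maps.items()
    }
    background_levels = {
        el: float(np.mean(mean_maps[el][class_mask == 0])) for el in mean_maps
    }
    truth = PhantomTruth(
        class_mask=class_mask, cell_id_map=cell_id_map,
        cell_diameters_um=cell_diameters, cd45_ids=cd45_ids,
        label_mask=label_mask, ti_particles=ti_particles,
        background_levels=background_levels, mean_maps=mean_maps)
    return maps, truth


def _erode(mask: np.ndarray, margin_px: int) -> np.ndarray:
    """Shrink a boolean mask by ``margin_px`` (keeps disks fully inside)."""
    if margin_px <= 0:
        return mask
    return scipy.ndimage.binary_erosion(mask, iterations=margin_px)


def make_spectrum_cube(mean_maps: Mapping[str, np.ndarray], beam: BeamConfig,
                       detector: DetectorModel, seed: int | None = None,
                       step_keV: float = 0.010, pixel_size_um: float = 1.0,
                       catalogue: LineCatalogue | None = None) -> SpectrumCube:
    """Forward-simulate a spectrum cube from per-element amount maps.

    Elements with no line excitable under ``beam`` are skipped (they emit
    nothing).  With ``seed`` the cube is Poisson-noised.
    """
    cat = catalogue or LineCatalogue.default()
    grid = default_grid(beam, step_keV=step_keV)
    contributing = [el for el in mean_maps if cat.get_lines(el, beam=beam)]
    if not contributing:
        raise ConfigurationError("no element in the maps is excitable under the beam")
    unit = np.column_stack([
        simulate({el: 1.0}, beam, detector, grid=grid, catalogue=cat).counts
        for el in contributing
    ])  # channels x elements
    amounts = np.stack([np.asarray(mean_maps[el], dtype=float)
                        for el in contributing], axis=-1)
    counts = amounts @ unit.T  # rows x cols x channels
    if seed is not None:
        counts = np.random.default_rng(seed).poisson(counts).astype(float)
    return SpectrumCube(counts=counts, gain=step_keV, offset=float(grid[0]),
                        pixel_size_um=pixel_size_um)


@dataclass(frozen=True)
class ConfocalPhantomConfig:
    """Parameters of a skewed confocal depth-stack phantom."""

    seed: int
    shape: tuple[int, int] = (96, 96)
    n_planes: int = 5
    depth_step_um: float = 15.0
    geometry_angle_deg: float = 45.0
    pixel_size_um: float = 5.0
    n_particles: int = 10
    particle_diameter_log_mu: float = 2.6   # lognormal diameter in um
    particle_diameter_log_sigma: float = 0.6
    intensity_multiple: float = 50.0
    background_mean: float = 10.0
    persistence_per_um: float = 0.08  # mean extra planes per um of extent
    noise: bool = True

    def __post_init__(self) -> None:
        if self.n_planes < 2:
            raise ConfigurationError("confocal phantom needs >= 2 planes")
        if self.background_mean < 0 or self.intensity_multiple <= 0:
            raise ConfigurationError("intensities must be positive")


@dataclass
class ConfocalTruth:
    """Ground truth of a confocal phantom (pre-skew geometry)."""

    particles: list[dict]  # center, diameter_um, start_plane, depth_span
    background_mean: float
    shift_px_per_plane: float


def make_confocal_phantom(config: ConfocalPhantomConfig,
                          ) -> tuple[ConfocalStack, ConfocalTruth]:
    """Generate a skewed particle stack with size-dependent depth persistence.

    Particle depth span grows stochastically with particle extent
    (``1 + Poisson(persistence_per_um * diameter)``, clipped to the plane
    count), guaranteeing a positive size-persistence association.  Each
    plane is drawn with the particle center displaced by the geometric skew,
    so :func:`confocal_stack.shift_correct` has an exact known inverse.
    """
    rng = np.random.default_rng(config.seed)
    shape, n_planes = config.shape, config.n_planes
    shift_px = (config.depth_step_um
                * np.tan(np.radians(config.geometry_angle_deg))
                / config.pixel_size_um)
    max_skew = shift_px * (n_planes - 1)

    diam_um = rng.lognormal(config.particle_diameter_log_mu,
                            config.particle_diameter_log_sigma,
                            config.n_particles)
    radii_px = np.maximum(diam_um / 2 / config.pixel_size_um, 0.6)
    spans = np.minimum(
        1 + rng.poisson(config.persistence_per_um * diam_um), n_planes)
    starts = np.array([rng.integers(0, n_planes - s + 1) for s in spans])

    margin = int(np.ceil(radii_px.max() + max_skew)) + 1
    if 2 * margin >= min(shape):
        raise ConfigurationError("image too small for particle size plus skew")
    allowed = np.zeros(shape, dtype=bool)
    allowed[margin:-margin, margin:-margin] = True
    centers = _place_disks(rng, allowed, radii_px, gap_px=2.0)

    amplitude = config.intensity_multiple * config.background_mean
    planes = np.full((n_planes, *shape), config.background_mean, dtype=float)
    particles = []
    for (r, c), radius, diam, start, span in zip(
            centers, radii_px, diam_um, starts, spans):
        for k in range(start, start + span):
            skewed = (r + shift_px * k, c)
            planes[k][_disk_mask(shape, skewed, radius)] += amplitude
        particles.append({
            "center": (float(r), float(c)), "diameter_um": float(diam),
            "radius_px": float(radius),
            "start_plane": int(start), "depth_span": int(span),
        })
    if config.noise:
        planes = rng.poisson(planes).astype(float)

    stack = ConfocalStack(
        planes=planes, depth_step_um=config.depth_step_um,
        geometry_angle_deg=config.geometry_angle_deg,
        pixel_size_um=config.pixel_size_um,
        probe_depth_um=30.0, shift_axis=0, shift_sign=1)
    truth = ConfocalTruth(particles=particles,
                          background_mean=config.background_mean,
                          shift_px_per_plane=shift_px)
    return stack, truth
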