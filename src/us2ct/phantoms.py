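"""Random lesion phantoms with stochastic material properties.

A phantom is a rectangular slab of soft-tissue-like background material
containing up to three non-overlapping spherical inclusions (rasterized on
the elevational mid-plane, so inclusions appear as disks).  Every pixel is
assigned a density and sound speed drawn from a Gaussian whose mean and
relative SD depend on the owning material.  Two dataset flavours exist:

``ct_invisible``
    Background mean density equals the water-inclusion mean density
    (1000 kg/m³), so anechoic (water) inclusions are invisible in CT while
    remaining visible (dark) in B-mode — the cyst-like case.
``ct_visible``
    Background density is 1030 kg/m³, so every inclusion, water included,
    carries CT contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FLAVOURS = ("ct_invisible", "ct_visible")
ECHO_CLASSES = ("anechoic", "hyperechoic")

# material → echogenicity class: homogeneous water returns no speckle
# (anechoic); muscle and kidney have large relative SD (hyperechoic).
_ECHO_CLASS = {"water": "anechoic", "muscle": "hyperechoic", "kidney": "hyperechoic"}
INCLUSION_MATERIALS = ("water", "muscle", "kidney")


@dataclass(frozen=True)
class MaterialSpec:
    """Acoustic material: mean sound speed c0 (m/s), mean density rho0
    (kg/m³) and relative standard deviation sigma (dimensionless)."""

    c0: float
    rho0: float
    sigma: float

    def __post_init__(self) -> None:
        if self.c0 <= 0 or self.rho0 <= 0 or self.sigma < 0:
            raise ValueError("require c0 > 0, rho0 > 0, sigma >= 0")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and sampling configuration for one phantom.

    Extents are physical lengths in mm; ``grid_spacing`` is the raster pitch
    in mm/pixel (0.1 mm at full scale → 400 × 584 pixels; coarser presets
    are used for fast tests).  The 10 mm elevation extent is recorded for
    provenance but the raster is the 2-D elevational mid-plane.
    """

    axial_extent: float = 40.0
    transverse_extent: float = 58.4
    elevation_extent: float = 10.0
    grid_spacing: float = 0.1
    inclusion_radius_min: float = 1.0
    inclusion_radius_max: float = 8.0
    max_inclusions: int = 3
    flavour: str = "ct_invisible"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.inclusion_radius_min <= self.inclusion_radius_max):
            raise ValueError("require 0 < radius_min <= radius_max")
        if min(self.axial_extent, self.transverse_extent, self.grid_spacing) <= 0:
            raise ValueError("extents and grid spacing must be positive")
        if self.flavour not in FLAVOURS:
            raise ValueError(f"unknown flavour {self.flavour!r}")

    @property
    def shape(self) -> tuple[int, int]:
        """(axial, transverse) raster shape."""
        return (
            int(round(self.axial_extent / self.grid_spacing)),
            int(round(self.transverse_extent / self.grid_spacing)),
        )


@dataclass(frozen=True)
class Inclusion:
    """One spherical inclusion: centre/radius in mm (axial, transverse),
    material name, echogenicity class and CT visibility."""

    centre: tuple[float, float]
    radius: float
    material: str
    echo_class: str
    ct_visible: bool


@dataclass
class Phantom:
    density_map: np.ndarray          # kg/m³, shape (axial, transverse)
    sound_speed_map: np.ndarray      # m/s, same shape
    inclusions: list[Inclusion]
    masks: list[np.ndarray]          # per-inclusion boolean rasters, disjoint
    flavour: str
    config: PhantomConfig = field(repr=False, default=None)

    @property
    def background(self) -> MaterialSpec:
        return material_table(self.flavour)["background"]

    def background_mask(self) -> np.ndarray:
        out = np.ones(self.density_map.shape, dtype=bool)
        for m in self.masks:
            out &= ~m
        return out


def material_table(flavour: str) -> dict[str, MaterialSpec]:
    """Material properties per dataset flavour.

    The two flavours differ only in the background: the ``ct_invisible``
    background shares the water mean density (1000 kg/m³) so water
    inclusions carry no CT contrast.
    """
    if flavour == "ct_invisible":
        background = MaterialSpec(1540.0, 1000.0, 0.008)
    elif flavour == "ct_visible":
        background = MaterialSpec(1520.0, 1030.0, 0.008)
    else:
        raise ValueError(f"unknown flavour {flavour!r}")
    return {
        "background": background,
        "water": MaterialSpec(1480.0, 1000.0, 0.0),
        "muscle": MaterialSpec(1575.0, 1065.0, 0.08),
        "kidney": MaterialSpec(1570.0, 1050.0, 0.05),
    }


def sample_inclusions(
    config: PhantomConfig,
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> list[Inclusion]:
    """Draw 0..max_inclusions non-overlapping spheres fully inside the slab.

    The inclusion count is uniform over {0, …, max_inclusions}, radii are
    uniform in [radius_min, radius_max] mm and materials uniform over
    water/muscle/kidney.  Non-overlap (centre distance > r1 + r2) is
    enforced by rejection sampling; a geometrically infeasible
    configuration raises ``RuntimeError`` after ``max_retries`` attempts.
    """
    table = material_table(config.flavour)
    bg_rho = table["background"].rho0
    n = int(rng.integers(0, config.max_inclusions + 1))
    out: list[Inclusion] = []
    for _ in range(n):
        for _attempt in range(max_retries):
            radius = float(rng.uniform(config.inclusion_radius_min, config.inclusion_radius_max))
            if 2 * radius >= min(config.axial_extent, config.transverse_extent):
                continue  # sphere cannot fit; count as a failed attempt
            ax = float(rng.uniform(radius, config.axial_extent - radius))
            tr = float(rng.uniform(radius, config.transverse_extent - radius))
            if all(
                np.hypot(ax - inc.centre[0], tr - inc.centre[1]) > radius + inc.radius
                for inc in out
            ):
                material = INCLUSION_MATERIALS[int(rng.integers(0, 3))]
                out.append(
                    Inclusion(
                        centre=(ax, tr),
                        radius=radius,
                        material=material,
                        echo_class=_ECHO_CLASS[material],
                        ct_visible=table[material].rho0 != bg_rho,
                    )
                )
                break
        else:
            raise RuntimeError(
                f"could not place inclusion after {max_retries} retries; "
                "config geometrically infeasible"
            )
    return out


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, n_sd: float = 4.0
) -> np.ndarray:
    draws = rng.normal(mean, sd, size=size)
    # clip at ±4 SD: forbids non-physical negative densities without
    # perturbing the first two moments measurably
    return np.clip(draws, mean - n_sd * sd, mean + n_sd * sd)


def realize_phantom(
    config: PhantomConfig,
    inclusions: list[Inclusion],
    rng: np.random.Generator,
) -> Phantom:
    """Rasterize material ownership and draw per-pixel density/sound-speed.

    Each pixel's density ~ N(rho0, sigma·rho0) and sound speed
    ~ N(c0, sigma·c0) of the owning material (truncated at ±4 SD); the
    water material has sigma 0 and is therefore exactly homogeneous.
    """
    table = material_table(config.flavour)
    shape = config.shape
    ax_coords = (np.arange(shape[0]) + 0.5) * config.grid_spacing
    tr_coords = (np.arange(shape[1]) + 0.5) * config.grid_spacing
    axg, trg = np.meshgrid(ax_coords, tr_coords, indexing="ij")

    masks = []
    for inc in inclusions:
        masks.append((axg - inc.centre[0]) ** 2 + (trg - inc.centre[1]) ** 2 <= inc.radius**2)

    density = np.empty(shape, dtype=np.float64)
    speed = np.empty(shape, dtype=np.float64)
    owner = np.full(shape, -1, dtype=np.int32)  # -1 = background
    for i, m in enumerate(masks):
        owner[m] = i

    bg = table["background"]
    sel = owner == -1
    density[sel] = _truncated_normal(rng, bg.rho0, bg.sigma * bg.rho0, int(sel.sum()))
    speed[sel] = _truncated_normal(rng, bg.c0, bg.sigma * bg.c0, int(sel.sum()))
    for i, inc in enumerate(inclusions):
        spec = table[inc.material]
        sel = owner == i
        k = int(sel.sum())
        if spec.sigma == 0.0:
            density[sel] = spec.rho0
            speed[sel] = spec.c0
        else:
            density[sel] = _truncated_normal(rng, spec.rho0, spec.sigma * spec.rho0, k)
            speed[sel] = _truncated_normal(rng, spec.c0, spec.sigma * spec.c0, k)

    return Phantom(
        density_map=density,
        sound_speed_map=speed,
        inclusions=list(inclusions),
        masks=masks,
        flavour=config.flavour,
        config=config,
    )


def generate_phantom(config: PhantomConfig, seed: int | None = None) -> Phantom:
    """Convenience wrapper: sample inclusions and realize in one call."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    inclusions = sample_inclusions(config, rng)
    return realize_phantom(config, inclusions, rng)


def combined_mask(phantom: Phantom, echo_class: str) -> np.ndarray:
    """Union of all inclusion masks of one echogenicity class.

    Used to stratify gCNR regions of interest into anechoic versus
    hyperechoic inclusions.  Returns an all-False raster when the phantom
    has no inclusion of that class.
    """
    if echo_class not in ECHO_CLASSES:
        raise ValueError(f"unknown echo class {echo_class!r}")
    out = np.zeros(phantom.density_map.shape, dtype=bool)
    for inc, m in zip(phantom.inclusions, phantom.masks):
        if inc.echo_class == echo_class:
            out |= m
    return out


def coarse_config(flavour: str = "ct_invisible", **kw) -> PhantomConfig:
    """0.4 mm/pixel preset (100 × 146 raster) used by tests and the
    scaled-down desk experiments."""
    defaults = dict(grid_spacing=0.4, flavour=flavour)
    defaults.update(kw)
    return PhantomConfig(**defaults)
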