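"""2-D dielectric breast phantoms.

A phantom is a pair of cell-centred maps (relative permittivity and
conductivity) on a uniform square grid, built from nested regions:
background (coupling medium, air by default), a circular breast-fat
disc, a thin skin shell on its rim, and one or more circular tumors.
Later regions overwrite earlier ones, so the nesting order is total and
rebuilding with tumors listed in any order gives identical maps (tumors
are assumed disjoint).

Tissue dielectric values are frequency-independent defaults typical of
the microwave-imaging literature; malignant tissue is several times
more polarisable than fat, which is the contrast the radar exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as C0

from .arraypulse import PulseSpec

__all__ = [
    "TissueSpec",
    "TumorSpec",
    "Phantom",
    "DEFAULT_TISSUES",
    "build_phantom",
    "scenario_catalogue",
    "SCENARIO_NAMES",
    "GeometryError",
    "ResolutionError",
]


class GeometryError(ValueError):
    """A region does not fit where it must (e.g. tumor outside breast)."""


class ResolutionError(ValueError):
    """The grid is too coarse for the shortest in-tissue wavelength."""


@dataclass(frozen=True)
class TissueSpec:
    """Homogeneous tissue: name, relative permittivity, conductivity (S/m)."""

    name: str
    eps_r: float
    sigma: float

    def __post_init__(self):
        if self.eps_r < 1.0:
            raise ValueError(f"{self.name}: eps_r must be >= 1, got {self.eps_r}")
        if self.sigma < 0.0:
            raise ValueError(f"{self.name}: sigma must be >= 0, got {self.sigma}")

    @property
    def speed(self) -> float:
        """Phase speed c / sqrt(eps_r) in m/s (non-magnetic media)."""
        return C0 / np.sqrt(self.eps_r)


@dataclass(frozen=True)
class TumorSpec:
    """Circular tumor: centre (x, y) in metres and radius in metres."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"tumor radius must be positive, got {self.radius}")


#: Literature-typical dielectric values around the 2-4 GHz band.  The
#: tumor/fat permittivity contrast (50 / 5.1 ~ 9.8) sits inside the
#: 2-10x band reported for healthy vs malignant tissue.
DEFAULT_TISSUES: dict[str, TissueSpec] = {
    "background": TissueSpec("background", 1.0, 0.0),
    "fat": TissueSpec("fat", 5.1, 0.14),
    "skin": TissueSpec("skin", 36.0, 4.0),
    "tumor": TissueSpec("tumor", 50.0, 7.0),
}

#: Acceptable tumor/fat permittivity contrast band.
CONTRAST_BAND = (2.0, 10.0)


@dataclass(frozen=True)
class Phantom:
    """Discretised 2-D dielectric map.

    ``eps_map`` and ``sigma_map`` are (nx, ny) arrays indexed row-major;
    the cell (i, j) is centred at ``x = -half + (i + 0.5) dx`` and
    likewise in y, with the origin at the breast centre.
    """

    grid_spacing: float
    eps_map: np.ndarray = field(repr=False)
    sigma_map: np.ndarray = field(repr=False)
    regions: tuple = ()
    breast_radius: float = 0.0
    skin_thickness: float = 0.0
    tumors: tuple[TumorSpec, ...] = ()
    tissues: dict[str, TissueSpec] = field(default_factory=lambda: dict(DEFAULT_TISSUES))

    @property
    def shape(self) -> tuple[int, int]:
        return self.eps_map.shape

    @property
    def half_extent(self) -> float:
        """Half-width of the square domain in metres."""
        return self.eps_map.shape[0] * self.grid_spacing / 2.0

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D x and y coordinates of cell centres (m)."""
        nx, ny = self.eps_map.shape
        dx = self.grid_spacing
        x = (np.arange(nx) + 0.5) * dx - nx * dx / 2.0
        y = (np.arange(ny) + 0.5) * dx - ny * dx / 2.0
        return x, y

    def point_to_cell(self, p) -> tuple[int, int]:
        """Grid cell containing the physical point ``p = (x, y)``."""
        nx, ny = self.eps_map.shape
        dx = self.grid_spacing
        i = int(np.floor(p[0] / dx + nx / 2.0))
        j = int(np.floor(p[1] / dx + ny / 2.0))
        if not (0 <= i < nx and 0 <= j < ny):
            raise GeometryError(f"point {p} lies outside the computational domain")
        return i, j


def _disc_mask(x: np.ndarray, y: np.ndarray, center, radius: float) -> np.ndarray:
    xx = x[:, None] - center[0]
    yy = y[None, :] - center[1]
    return xx**2 + yy**2 <= radius**2


def min_wavelength(tissues: dict[str, TissueSpec], pulse: PulseSpec) -> float:
    """Shortest in-tissue wavelength at the pulse's upper band edge (m)."""
    f_hi = pulse.upper_band_edge()
    eps_max = max(t.eps_r for t in tissues.values())
    return C0 / (f_hi * np.sqrt(eps_max))


def build_phantom(
    breast_radius: float,
    skin_thickness: float = 2e-3,
    tumors: list[TumorSpec] | tuple[TumorSpec, ...] = (),
    tissues: dict[str, TissueSpec] | None = None,
    grid_spacing: float = 1e-3,
    *,
    domain_margin: float = 30e-3,
    pulse: PulseSpec | None = None,
    check_resolution: bool = True,
    contrast_band: tuple[float, float] | None = CONTRAST_BAND,
) -> Phantom:
    """Rasterise a breast phantom: fat disc + skin shell + tumors.

    Parameters
    ----------
    breast_radius, skin_thickness : float
        Outer breast radius and skin-shell thickness in metres.  The
        skin occupies the outermost ``skin_thickness`` of the disc.
    tumors : sequence of TumorSpec
        Circular inclusions; each must lie entirely inside the breast.
    tissues : mapping, optional
        Overrides for the default tissue table (keys ``background``,
        ``fat``, ``skin``, ``tumor``).
    grid_spacing : float
        Cell size in metres.
    domain_margin : float
        Padding beyond the breast radius; must leave room for the 5 mm
        antenna standoff, the ring itself and the absorbing boundary.
    pulse : PulseSpec, optional
        Used for the wavelength-resolution check (default pulse if not
        given).

    Raises
    ------
    GeometryError
        If a tumor pokes outside the breast.
    ResolutionError
        If fewer than 10 cells resolve the shortest in-tissue
        wavelength at the pulse's upper half-power band edge.
    """
    tissues = dict(DEFAULT_TISSUES) if tissues is None else {**DEFAULT_TISSUES, **tissues}
    if tumors and contrast_band is not None:
        lo, hi = contrast_band
        contrast = tissues["tumor"].eps_r / tissues["fat"].eps_r
        if not (lo <= contrast <= hi):
            raise ValueError(
                f"tumor/fat permittivity contrast {contrast:.2f} outside the [{lo}, {hi}] band"
            )
    if skin_thickness < 0 or skin_thickness >= breast_radius:
        raise GeometryError("skin thickness must lie in [0, breast_radius)")
    for tm in tumors:
        if np.hypot(*tm.center) + tm.radius > breast_radius:
            raise GeometryError(
                f"tumor at {tm.center} with radius {tm.radius * 1e3:.2f} mm "
                "extends outside the breast"
            )
    if check_resolution:
        lam = min_wavelength(tissues, pulse or PulseSpec())
        if grid_spacing > lam / 10.0:
            raise ResolutionError(
                f"grid spacing {grid_spacing * 1e3:.2f} mm does not resolve the "
                f"shortest in-tissue wavelength {lam * 1e3:.2f} mm by >= 10 cells"
            )

    half = breast_radius + domain_margin
    n = int(np.ceil(2.0 * half / grid_spacing))
    n += n % 2  # even cell count keeps the origin on a cell corner
    x = (np.arange(n) + 0.5) * grid_spacing - n * grid_spacing / 2.0
    y = x.copy()

    bg = tissues["background"]
    eps = np.full((n, n), bg.eps_r, dtype=float)
    sig = np.full((n, n), bg.sigma, dtype=float)
    regions: list[tuple[str, TissueSpec]] = [("background", bg)]

    fat = _disc_mask(x, y, (0.0, 0.0), breast_radius)
    eps[fat] = tissues["fat"].eps_r
    sig[fat] = tissues["fat"].sigma
    regions.append(("fat", tissues["fat"]))

    if skin_thickness > 0:
        inner = _disc_mask(x, y, (0.0, 0.0), breast_radius - skin_thickness)
        shell = fat & ~inner
        eps[shell] = tissues["skin"].eps_r
        sig[shell] = tissues["skin"].sigma
        regions.append(("skin", tissues["skin"]))

    for tm in tumors:
        m = _disc_mask(x, y, tm.center, tm.radius)
        eps[m] = tissues["tumor"].eps_r
        sig[m] = tissues["tumor"].sigma
        regions.append(("tumor", tissues["tumor"]))

    return Phantom(
        grid_spacing=grid_spacing,
        eps_map=eps,
        sigma_map=sig,
        regions=tuple(regions),
        breast_radius=breast_radius,
        skin_thickness=skin_thickness,
        tumors=tuple(tumors),
        tissues=tissues,
    )


@dataclass(frozen=True)
class Scenario:
    """A fully specified imaging trial: phantom + array + pulse."""

    name: str
    phantom: Phantom
    n_antennas: int
    r_max: float
    d: float
    pulse: PulseSpec


# Single-tumor trials place the tumor off-centre (the measured phantom
# had it at x = 35 mm); a strictly centred target is degenerate for the
# cross-channel mean-removal stage because every monostatic channel
# then records the identical echo.
_SCENARIOS: dict[str, dict] = {
    "three_antennas": dict(n=3, R=50e-3, tumors=[TumorSpec((20e-3, 0.0), 2e-3)]),
    "six_antennas": dict(n=6, R=50e-3, tumors=[TumorSpec((20e-3, 0.0), 2e-3)]),
    "nine_antennas": dict(n=9, R=50e-3, tumors=[TumorSpec((20e-3, 0.0), 2e-3)]),
    "small_tumor": dict(n=9, R=50e-3, tumors=[TumorSpec((20e-3, 0.0), 1.5e-3)]),
    "two_tumors": dict(
        n=9, R=50e-3, tumors=[TumorSpec((-10e-3, 0.0), 2e-3), TumorSpec((10e-3, 0.0), 2e-3)]
    ),
    "three_tumors": dict(
        n=9,
        R=50e-3,
        tumors=[
            TumorSpec((0.0, 15e-3), 2e-3),
            TumorSpec((-13e-3, -7.5e-3), 2e-3),
            TumorSpec((13e-3, -7.5e-3), 2e-3),
        ],
    ),
    "large_breast": dict(n=9, R=80e-3, tumors=[TumorSpec((30e-3, 0.0), 2e-3)]),
}

SCENARIO_NAMES = tuple(_SCENARIOS)


def scenario_catalogue(name: str, grid_spacing: float = 1e-3) -> Scenario:
    """Return one of the packaged imaging trials.

    Trials: 3/6/9-element rings around a 50 mm breast with one 2 mm
    tumor, a smaller (1.5 mm) tumor, two and three tumors, and a larger
    breast of 16 cm diameter.
    """
    try:
        p = _SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}") from None
    pulse = PulseSpec()
    phantom = build_phantom(
        breast_radius=p["R"],
        skin_thickness=2e-3,
        tumors=p["tumors"],
        grid_spacing=grid_spacing,
        pulse=pulse,
    )
    return Scenario(
        name=name,
        phantom=phantom,
        n_antennas=p["n"],
        r_max=p["R"] + 10e-3,
        d=0.0,
        pulse=pulse,
    )
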