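"""Scenario configuration (YAML) and signal/image containers (HDF5, PNG).

All config files use millimetres, GHz and picoseconds for readability;
values are converted to SI on load and everything in memory is SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .arraypulse import ArrayLayout, PulseSpec, place_antennas
from .forward import SignalSet, SolverConfig
from .phantom import (
    DEFAULT_TISSUES,
    Phantom,
    TissueSpec,
    TumorSpec,
    build_phantom,
    scenario_catalogue,
)
from .preprocess import ChainParams
from .reconstruct import ImageGrid

__all__ = [
    "ScenarioConfig",
    "load_scenario",
    "save_scenario",
    "save_signalset",
    "load_signalset",
    "save_image",
    "load_image",
    "render_png",
]


@dataclass
class ScenarioConfig:
    """Everything needed to run one imaging trial."""

    name: str = "custom"
    breast_radius_mm: float = 50.0
    skin_thickness_mm: float = 2.0
    grid_spacing_mm: float = 1.0
    tumors: list[dict] = field(default_factory=list)  # {x_mm, y_mm, radius_mm}
    tissues: dict[str, dict] = field(default_factory=dict)  # {name: {eps_r, sigma}}
    n_antennas: int = 9
    r_max_mm: float = 60.0
    d_mm: float = 0.0
    slot_mode: str = "contiguous"
    f_r_ghz: float = 2.4
    omega_ps: float = 78.1
    courant_factor: float = 0.5
    pml_cells: int = 10
    n_timesteps: int = 4096
    weight: float = 1.0
    mean_removal: bool = True
    smoothing_kernel: int | None = None
    noise_std: float = 0.0  # additive receiver noise relative to trace max; 0 = off
    pixel_mm: float = 1.0

    @classmethod
    def from_catalogue(cls, name: str) -> "ScenarioConfig":
        sc = scenario_catalogue(name)
        return cls(
            name=name,
            breast_radius_mm=sc.phantom.breast_radius * 1e3,
            skin_thickness_mm=sc.phantom.skin_thickness * 1e3,
            grid_spacing_mm=sc.phantom.grid_spacing * 1e3,
            tumors=[
                {"x_mm": t.center[0] * 1e3, "y_mm": t.center[1] * 1e3, "radius_mm": t.radius * 1e3}
                for t in sc.phantom.tumors
            ],
            n_antennas=sc.n_antennas,
            r_max_mm=sc.r_max * 1e3,
            d_mm=sc.d * 1e3,
            f_r_ghz=sc.pulse.f_r / 1e9,
            omega_ps=sc.pulse.omega * 1e12,
        )

    # -- builders ----------------------------------------------------
    def tumor_specs(self) -> list[TumorSpec]:
        return [
            TumorSpec((t["x_mm"] * 1e-3, t["y_mm"] * 1e-3), t["radius_mm"] * 1e-3)
            for t in self.tumors
        ]

    def tissue_table(self) -> dict[str, TissueSpec]:
        table = dict(DEFAULT_TISSUES)
        for name, d in self.tissues.items():
            table[name] = TissueSpec(name, d["eps_r"], d["sigma"])
        return table

    def pulse(self) -> PulseSpec:
        return PulseSpec(f_r=self.f_r_ghz * 1e9, omega=self.omega_ps * 1e-12)

    def phantom(self, with_tumors: bool = True) -> Phantom:
        return build_phantom(
            breast_radius=self.breast_radius_mm * 1e-3,
            skin_thickness=self.skin_thickness_mm * 1e-3,
            tumors=self.tumor_specs() if with_tumors else [],
            tissues=self.tissue_table(),
            grid_spacing=self.grid_spacing_mm * 1e-3,
            pulse=self.pulse(),
        )

    def empty_phantom(self) -> Phantom:
        """Domain with the coupling medium only (the E1 acquisition)."""
        ph = self.phantom(with_tumors=False)
        bg = self.tissue_table()["background"]
        return Phantom(
            grid_spacing=ph.grid_spacing,
            eps_map=np.full(ph.shape, bg.eps_r),
            sigma_map=np.full(ph.shape, bg.sigma),
            tissues=ph.tissues,
        )

    def layout(self) -> ArrayLayout:
        return place_antennas(
            self.n_antennas,
            self.r_max_mm * 1e-3,
            self.d_mm * 1e-3,
            breast_radius=self.breast_radius_mm * 1e-3,
            slot_mode=self.slot_mode,
        )

    def solver(self) -> SolverConfig:
        return SolverConfig(
            courant_factor=self.courant_factor,
            pml_cells=self.pml_cells,
            n_timesteps=self.n_timesteps,
        )

    def chain(self) -> ChainParams:
        return ChainParams(
            weight=self.weight,
            mean_removal=self.mean_removal,
            smoothing_kernel=self.smoothing_kernel,
        )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_scenario(path: str | Path) -> ScenarioConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    known = {f.name for f in ScenarioConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ScenarioConfig(**raw)


def save_scenario(cfg: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg.to_dict(), f, sort_keys=False)


# -- HDF5 containers -------------------------------------------------

def save_signalset(ss: SignalSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ss.data, compression="gzip", compression_opts=4)
        f.create_dataset("t", data=ss.t)
        f.attrs["role"] = ss.role
        if ss.layout is not None:
            f.attrs["n_antennas"] = ss.layout.n_antennas
            f.attrs["r_max"] = ss.layout.r_max
            f.attrs["d"] = ss.layout.d
            f.create_dataset("positions", data=ss.layout.positions)
        if ss.pulse is not None:
            f.attrs["f_r"] = ss.pulse.f_r
            f.attrs["omega"] = ss.pulse.omega
            f.attrs["t0"] = ss.pulse.t0


def load_signalset(path: str | Path) -> SignalSet:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        t = f["t"][...]
        role = f.attrs.get("role", "total")
        layout = None
        if "positions" in f:
            pos = f["positions"][...]
            layout = ArrayLayout(
                n_antennas=int(f.attrs["n_antennas"]),
                r_max=float(f.attrs["r_max"]),
                d=float(f.attrs["d"]),
                positions=pos,
                thetas=np.arctan2(pos[:, 1], pos[:, 0]),
            )
        pulse = None
        if "f_r" in f.attrs:
            pulse = PulseSpec(
                f_r=float(f.attrs["f_r"]),
                omega=float(f.attrs["omega"]),
                t0=float(f.attrs["t0"]),
            )
    return SignalSet(data=data, t=t, role=str(role), layout=layout, pulse=pulse)


def save_image(img: ImageGrid, path: str | Path, **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensity", data=img.intensity, compression="gzip")
        f.attrs["extent"] = img.extent
        f.attrs["pixel"] = img.pixel
        for k, v in attrs.items():
            f.attrs[k] = v


def load_image(path: str | Path) -> ImageGrid:
    with h5py.File(path, "r") as f:
        return ImageGrid(
            intensity=f["intensity"][...],
            extent=tuple(f.attrs["extent"]),
            pixel=float(f.attrs["pixel"]),
        )


def render_png(img: ImageGrid, path: str | Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    ext_mm = [v * 1e3 for v in (img.extent[2], img.extent[3], img.extent[0], img.extent[1])]
    # intensity[i, j] has x along axis 0; transpose for imshow's row=y
    im = ax.imshow(
        img.intensity.T, origin="lower", extent=[e * 1e3 for e in img.extent], cmap="inferno"
    )
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="normalised intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
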