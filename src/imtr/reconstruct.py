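"""Image formation: MWDAS, FDMAS, time reversal, and IMTR backprojection.

All four imagers share the same skeleton: a focal grid over the breast,
per-antenna propagation delays from a :class:`DelayModel`, and
time-domain traces sampled at the focal delays.

* MWDAS — weighted delay-and-sum: coherent sum of delayed channel
  samples (weights default to tx+rx path-length compensation for the
  cylindrical spreading loss), envelope via the analytic signal,
  squared and integrated over a pulse-length window.
* FDMAS — delay-multiply-and-sum: products of every pair of delayed
  channel samples with the sign-preserving square root, which keeps the
  dimensionality of field amplitude while rewarding cross-channel
  coherence.
* TR — time reversal, either numeric (re-inject the time-reversed
  traces into the background phantom with the FDTD solver and
  accumulate field energy) or synthetic (phase-conjugate
  backprojection, an unweighted envelope-DAS fast path).
* IMTR — pair-delay backprojection of the preprocessed E7 pair traces:
  pair (i, j) is sampled at the summed one-way delays
  tau_i(r) + tau_j(r), where the product of the two round-trip echoes
  peaks.

Images are non-negative and max-normalised to 1 (unless identically
zero).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
from scipy.constants import c as C0
from scipy.signal import hilbert

from .arraypulse import ArrayLayout
from .forward import SolverConfig, run_fdtd
from .phantom import Phantom
from .preprocess import ProcessedSignals

__all__ = [
    "ImageGrid",
    "DelayModel",
    "make_image_grid",
    "focal_delays",
    "mwdas_image",
    "fdmas_image",
    "tr_image",
    "imtr_image",
]


@dataclass
class ImageGrid:
    """2-D intensity map with physical extent.

    ``intensity[i, j]`` corresponds to the pixel centred at
    ``x = extent[0] + (i + 0.5) * pixel``,
    ``y = extent[2] + (j + 0.5) * pixel``.
    """

    intensity: np.ndarray
    extent: tuple[float, float, float, float]
    pixel: float

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.intensity.shape
        x = self.extent[0] + (np.arange(nx) + 0.5) * self.pixel
        y = self.extent[2] + (np.arange(ny) + 0.5) * self.pixel
        return x, y

    def argmax_point(self) -> tuple[float, float]:
        """Physical coordinates of the intensity maximum."""
        i, j = np.unravel_index(int(np.argmax(self.intensity)), self.shape)
        x, y = self.pixel_centers()
        return float(x[i]), float(y[j])

    def blank_like(self) -> "ImageGrid":
        return ImageGrid(np.zeros(self.shape), self.extent, self.pixel)


def make_image_grid(half_extent: float, pixel: float = 1e-3) -> ImageGrid:
    """Square focal grid of +-``half_extent`` metres around the origin."""
    n = int(np.ceil(2.0 * half_extent / pixel))
    return ImageGrid(
        intensity=np.zeros((n, n)),
        extent=(-half_extent, -half_extent + n * pixel, -half_extent, -half_extent + n * pixel),
        pixel=pixel,
    )


@dataclass(frozen=True)
class DelayModel:
    """Propagation-delay model for focusing.

    ``homogeneous`` uses one ``speed`` everywhere.  ``two_speed`` and
    ``layered`` follow the straight ray antenna -> focal point with the
    background speed outside the breast disc and slower in-tissue
    speeds inside (``layered`` distinguishes the skin shell from fat).
    """

    mode: str = "homogeneous"
    speed: float = C0
    breast_radius: float = 0.0
    skin_thickness: float = 0.0
    eps_fat: float = 1.0
    eps_skin: float = 1.0

    def __post_init__(self):
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.mode not in ("homogeneous", "two_speed", "layered"):
            raise ValueError(f"unknown delay mode {self.mode!r}")

    @classmethod
    def from_phantom(cls, phantom: Phantom, mode: str = "layered") -> "DelayModel":
        if mode == "homogeneous":
            # area-weighted mean permittivity over the breast disc
            R, ts = phantom.breast_radius, phantom.skin_thickness
            f_skin = 1.0 - ((R - ts) / R) ** 2
            eps_eff = (1 - f_skin) * phantom.tissues["fat"].eps_r + f_skin * phantom.tissues[
                "skin"
            ].eps_r
            return cls(mode="homogeneous", speed=C0 / np.sqrt(eps_eff))
        return cls(
            mode=mode,
            speed=C0 / np.sqrt(phantom.tissues["background"].eps_r),
            breast_radius=phantom.breast_radius,
            skin_thickness=phantom.skin_thickness,
            eps_fat=phantom.tissues["fat"].eps_r,
            eps_skin=phantom.tissues["skin"].eps_r,
        )


def _chord_inside(a: np.ndarray, px: np.ndarray, py: np.ndarray, R: float) -> np.ndarray:
    """Length of the segment antenna ``a`` -> pixels inside the origin-
    centred circle of radius ``R`` (vectorised over pixels)."""
    dx = px - a[0]
    dy = py - a[1]
    L2 = dx * dx + dy * dy
    L = np.sqrt(L2)
    safe = np.maximum(L2, 1e-30)
    # parametrise p(s) = a + s*(r-a), s in [0,1]
    b = 2.0 * (a[0] * dx + a[1] * dy)
    c_ = a[0] ** 2 + a[1] ** 2 - R * R
    disc = b * b - 4.0 * safe * c_
    hit = disc > 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    s1 = np.clip((-b - sq) / (2.0 * safe), 0.0, 1.0)
    s2 = np.clip((-b + sq) / (2.0 * safe), 0.0, 1.0)
    return np.where(hit, (s2 - s1) * L, 0.0)


def focal_delays(layout: ArrayLayout, grid: ImageGrid, dm: DelayModel) -> np.ndarray:
    """One-way delays tau_i(r) in seconds, shape (n_antennas, nx, ny)."""
    x, y = grid.pixel_centers()
    px = np.repeat(x, y.size)
    py = np.tile(y, x.size)
    out = np.empty((layout.n_antennas, px.size))
    for k, a in enumerate(layout.positions):
        d = np.hypot(px - a[0], py - a[1])
        if dm.mode == "homogeneous":
            out[k] = d / dm.speed
        else:
            inside_outer = _chord_inside(a, px, py, dm.breast_radius)
            if dm.mode == "layered" and dm.skin_thickness > 0:
                inside_inner = _chord_inside(
                    a, px, py, dm.breast_radius - dm.skin_thickness
                )
                skin = inside_outer - inside_inner
                fat = inside_inner
            else:
                skin = 0.0
                fat = inside_outer
            v_fat = C0 / np.sqrt(dm.eps_fat)
            v_skin = C0 / np.sqrt(dm.eps_skin)
            out[k] = (d - inside_outer) / dm.speed + np.asarray(fat) / v_fat + np.asarray(
                skin
            ) / v_skin
    return out.reshape(layout.n_antennas, *grid.shape)


def _normalize(img: np.ndarray) -> np.ndarray:
    m = img.max()
    return img / m if m > 0 else img


def _channel_delay_maps(
    signals: ProcessedSignals, layout: ArrayLayout, grid: ImageGrid, dm: DelayModel
) -> np.ndarray:
    """Per-channel focusing delays tau_tx + tau_rx, shape (n_ch, npix)."""
    tau = focal_delays(layout, grid, dm).reshape(layout.n_antennas, -1)
    maps = np.empty((signals.n_channels, tau.shape[1]))
    for row, ch in enumerate(signals.channel_index):
        i, j = ch if isinstance(ch, tuple) else (ch, ch)
        maps[row] = tau[i] + tau[j]
    return maps


def _interp_rows(data: np.ndarray, t: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Sample ``data[row]`` at ``times[row]`` with linear interpolation;
    out-of-record times contribute zero."""
    out = np.empty_like(times)
    for row in range(data.shape[0]):
        out[row] = np.interp(times[row], t, data[row], left=0.0, right=0.0)
    return out


def _window_offsets(signals: ProcessedSignals, n: int = 25) -> np.ndarray:
    """Integration window of about one pulse length, centred on the
    nominal arrival so the estimate carries no radial bias."""
    omega = signals.pulse.omega if signals.pulse is not None else 78.1e-12
    return np.linspace(-2.0 * omega, 2.0 * omega, n)


def _t0(signals: ProcessedSignals) -> float:
    return signals.pulse.t0 if signals.pulse is not None else 0.0


def mwdas_image(
    e3: ProcessedSignals,
    layout: ArrayLayout,
    grid: ImageGrid,
    dm: DelayModel,
    weights: np.ndarray | str = "path",
) -> ImageGrid:
    """Modified weighted delay-and-sum on channel-stage signals.

    I(r) = sum_k | sum_ch w_ch a_ch(t0 + tau_ch(r) + k dt) |^2 with
    a_ch the analytic signal; ``weights="path"`` compensates the
    cylindrical spreading with w_ch proportional to the tx+rx path
    length at each focal point, ``"uniform"`` uses 1.
    """
    tau_ch = _channel_delay_maps(e3, layout, grid, dm)
    analytic = hilbert(e3.data, axis=1)
    t0 = _t0(e3)
    acc = np.zeros(tau_ch.shape[1])
    if isinstance(weights, str):
        if weights == "path":
            w = tau_ch / tau_ch.mean()
        elif weights == "uniform":
            w = np.ones_like(tau_ch)
        else:
            raise ValueError(f"unknown weight rule {weights!r}")
    else:
        w = np.asarray(weights, dtype=float)[:, None] * np.ones_like(tau_ch)
    for k in _window_offsets(e3):
        re = _interp_rows(analytic.real, e3.t, tau_ch + (t0 + k))
        im = _interp_rows(analytic.imag, e3.t, tau_ch + (t0 + k))
        s_re = (w * re).sum(axis=0)
        s_im = (w * im).sum(axis=0)
        acc += s_re**2 + s_im**2
    return ImageGrid(_normalize(acc.reshape(grid.shape)), grid.extent, grid.pixel)


def fdmas_image(
    e3: ProcessedSignals, layout: ArrayLayout, grid: ImageGrid, dm: DelayModel
) -> ImageGrid:
    """Delay-multiply-and-sum with the sign-preserving square root.

    For delayed samples s_ch the per-offset statistic is
    sum_{a<b} g_a g_b with g = sign(s) sqrt(|s|), evaluated via the
    square-of-sum identity over a pulse-length window centred on the
    nominal arrival.  The window mean is then removed — the
    multiplication shifts coherent signal content to twice the carrier
    while incoherent clutter piles up near DC, and rejecting that
    baseband component is the algorithm's clutter-suppression step —
    before envelope detection and integration.
    """
    if e3.n_channels < 2:
        warnings.warn("FDMAS needs >= 2 channels; falling back to a DAS image")
        return mwdas_image(e3, layout, grid, dm, weights="uniform")
    tau_ch = _channel_delay_maps(e3, layout, grid, dm)
    t0 = _t0(e3)
    omega = e3.pulse.omega if e3.pulse is not None else 78.1e-12
    offsets = np.linspace(-3.0 * omega, 3.0 * omega, 49)
    q = np.empty((tau_ch.shape[1], offsets.size))
    for kk, k in enumerate(offsets):
        s = _interp_rows(e3.data, e3.t, tau_ch + (t0 + k))
        g = np.sign(s) * np.sqrt(np.abs(s))
        q[:, kk] = 0.5 * (g.sum(axis=0) ** 2 - (g**2).sum(axis=0))
    q -= q.mean(axis=1, keepdims=True)
    env = np.abs(hilbert(q, axis=1))
    img = (env**2).sum(axis=1)
    return ImageGrid(_normalize(img.reshape(grid.shape)), grid.extent, grid.pixel)


def tr_image(
    e3: ProcessedSignals,
    layout: ArrayLayout,
    grid: ImageGrid,
    phantom_background: Phantom | None = None,
    mode: str = "numeric",
    *,
    dm: DelayModel | None = None,
    cfg: SolverConfig | None = None,
    antenna_exclusion: float = 8e-3,
    accumulate: str = "energy",
) -> ImageGrid:
    """Time-reversal image.

    ``numeric`` re-emits the time-reversed calibrated signals into the
    tumor-free background phantom with the FDTD solver: each antenna
    injects the reverse of the coherent sum of every trace it received
    across the acquisition (by linearity this equals the coherent
    superposition of re-emitting each transmit experiment separately),
    and the per-pixel field statistic — ``sum_t Ez^2`` ("energy",
    default) or squared ``max_t |Ez|`` ("peak") — is accumulated; the
    field refocuses where the scattered wave originated.  Pixels closer
    than ``antenna_exclusion`` to an antenna are blanked, since
    injection energy trivially dominates there.  ``synthetic`` is the
    fast phase-conjugate backprojection equivalent (envelope DAS with
    uniform weights).
    """
    if not np.any(e3.data):
        return grid.blank_like()
    if mode == "synthetic":
        if dm is None:
            raise ValueError("synthetic TR needs a DelayModel")
        return mwdas_image(e3, layout, grid, dm, weights="uniform")
    if mode != "numeric":
        raise ValueError(f"unknown TR mode {mode!r}")
    if phantom_background is None:
        raise ValueError("numeric TR needs the background phantom")
    if accumulate not in ("energy", "peak"):
        raise ValueError(f"unknown accumulation {accumulate!r}")
    ph = phantom_background
    cells = [ph.point_to_cell(p) for p in layout.positions]

    # coherent re-emission: per receiver, sum the traces it recorded
    # over all transmit experiments, then time-reverse
    waveforms: dict[int, np.ndarray] = {}
    for row, ch in enumerate(e3.channel_index):
        _, rx = ch if isinstance(ch, tuple) else (ch, ch)
        waveforms.setdefault(rx, np.zeros(e3.t.size))
        waveforms[rx] = waveforms[rx] + e3.data[row]

    cfg = cfg or SolverConfig(n_timesteps=e3.t.size)
    cfg = replace(cfg, n_timesteps=e3.t.size)
    sources = [(cells[rx], w[::-1].copy()) for rx, w in waveforms.items()]
    _, fm = run_fdtd(ph, sources, [cells[0]], cfg, accumulate=accumulate)
    energy = fm**2 if accumulate == "peak" else fm

    # resample the phantom-grid energy onto the image grid
    xs, ys = ph.cell_centers()
    gx, gy = grid.pixel_centers()
    from scipy.interpolate import RegularGridInterpolator

    itp = RegularGridInterpolator((xs, ys), energy, bounds_error=False, fill_value=0.0)
    pts = np.stack(np.meshgrid(gx, gy, indexing="ij"), axis=-1).reshape(-1, 2)
    img = itp(pts).reshape(grid.shape)

    if antenna_exclusion > 0:
        d2 = np.full(grid.shape, np.inf)
        for a in layout.positions:
            d2 = np.minimum(
                d2, (gx[:, None] - a[0]) ** 2 + (gy[None, :] - a[1]) ** 2
            )
        img = np.where(d2 < antenna_exclusion**2, 0.0, img)
    return ImageGrid(_normalize(img), grid.extent, grid.pixel)


def imtr_image(
    e7: ProcessedSignals, layout: ArrayLayout, grid: ImageGrid, dm: DelayModel
) -> ImageGrid:
    """Pair-delay backprojection of the preprocessed pair traces.

    I(r) = [sum_{(i,j)} yhat_(i,j)(t0 + tau_i(r) + tau_j(r))]^2 with
    yhat the envelope (analytic-signal magnitude) of each E7 pair
    trace; the final intensity is the squared magnitude, consistent
    with the other imagers.
    """
    if not np.any(e7.data):
        return grid.blank_like()
    tau = focal_delays(layout, grid, dm).reshape(layout.n_antennas, -1)
    env = np.abs(hilbert(e7.data, axis=1))
    t0 = _t0(e7)
    times = np.empty((e7.n_channels, tau.shape[1]))
    for row, (i, j) in enumerate(e7.channel_index):
        times[row] = t0 + tau[i] + tau[j]
    img = _interp_rows(env, e7.t, times).sum(axis=0) ** 2
    return ImageGrid(_normalize(img.reshape(grid.shape)), grid.extent, grid.pixel)
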