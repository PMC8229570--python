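"""Antenna ring geometry and the UWB excitation pulse.

The acquisition geometry is a single ring of ideal point transceivers
surrounding the breast.  Antennas occupy angular slots on a circle of
radius ``gamma = r_max - d``; with the default 9 slots consecutive
elements are 40 degrees apart.  The excitation is a Gaussian-enveloped
sinusoid (a "modulated Gaussian"), the standard UWB radar pulse: a
carrier at ``f_r`` under an envelope of width ``omega``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArrayLayout",
    "PulseSpec",
    "place_antennas",
    "arc_layout",
    "gaussian_modulated_pulse",
    "pulse_bandwidth",
]


class GeometryError(ValueError):
    """Raised when an antenna layout violates the standoff requirement."""


@dataclass(frozen=True)
class ArrayLayout:
    """Ring array of point transceivers.

    Attributes
    ----------
    n_antennas : int
        Number of active elements.
    r_max : float
        Maximum system radius in metres.
    d : float
        Radial displacement; elements sit on a circle of radius
        ``r_max - d``.
    positions : (n, 2) ndarray
        Cartesian element positions in metres, breast-centred frame.
    thetas : (n,) ndarray
        Element angles in radians.
    """

    n_antennas: int
    r_max: float
    d: float
    positions: np.ndarray = field(repr=False)
    thetas: np.ndarray = field(repr=False)

    @property
    def radius(self) -> float:
        """Ring radius gamma = r_max - d (m)."""
        return self.r_max - self.d


@dataclass(frozen=True)
class PulseSpec:
    """Modulated Gaussian excitation pulse.

    Parameters
    ----------
    f_r : float
        Modulation (carrier) frequency in Hz.  Default 2.4 GHz.
    omega : float
        Gaussian envelope width in seconds.  Default 78.1 ps, which
        makes the pulse ultra-wideband.
    t0 : float, optional
        Envelope centre in seconds.  Defaults to ``5 * omega`` so the
        pulse switches on smoothly from (numerically) zero amplitude.
    """

    f_r: float = 2.4e9
    omega: float = 78.1e-12
    t0: float | None = None

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError(f"pulse width omega must be positive, got {self.omega}")
        if self.f_r <= 0:
            raise ValueError(f"modulation frequency must be positive, got {self.f_r}")
        if self.t0 is None:
            object.__setattr__(self, "t0", 5.0 * self.omega)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return gaussian_modulated_pulse(self, t)

    def upper_band_edge(self) -> float:
        """Upper half-power (-3 dB) band edge of the amplitude spectrum (Hz).

        The analytic amplitude spectrum of the pulse is a Gaussian
        centred on ``f_r``; its half-power half-width is
        ``sqrt(ln 2) / (2 pi omega)``.
        """
        return self.f_r + np.sqrt(np.log(2.0)) / (2.0 * np.pi * self.omega)


def place_antennas(
    n: int,
    r_max: float,
    d: float = 0.0,
    angular_slots: int = 9,
    *,
    breast_radius: float | None = None,
    standoff: float = 5e-3,
    slot_mode: str = "contiguous",
) -> ArrayLayout:
    """Place ``n`` antennas on the polar ring ``gamma = r_max - d``.

    Slot angles follow ``theta_A = (A - 1) * 2 pi / angular_slots`` for
    A = 1..n, i.e. 40 degree spacing on the default 9-slot ring.  With
    ``slot_mode="contiguous"`` the first ``n`` slots are used; with
    ``"uniform"`` ``n`` equally spaced angles are used instead (for
    sub-arrays that should still surround the target).

    Parameters are in metres.  If ``breast_radius`` is given the ring is
    checked against the required antenna standoff (default 5 mm).
    """
    if n < 1:
        raise ValueError(f"need at least one antenna, got n={n}")
    if n > angular_slots and slot_mode == "contiguous":
        raise ValueError(f"n={n} exceeds the {angular_slots} available slots")
    gamma = r_max - d
    if gamma <= 0:
        raise GeometryError(f"ring radius r_max - d = {gamma:.4g} m is not positive")
    if breast_radius is not None and gamma < breast_radius + standoff:
        raise GeometryError(
            f"ring radius {gamma * 1e3:.1f} mm violates the "
            f"{standoff * 1e3:.0f} mm standoff from the breast surface "
            f"(needs >= {(breast_radius + standoff) * 1e3:.1f} mm)"
        )
    if slot_mode == "contiguous":
        a = np.arange(n)
        thetas = a * 2.0 * np.pi / angular_slots
    elif slot_mode == "uniform":
        thetas = np.arange(n) * 2.0 * np.pi / n
    else:
        raise ValueError(f"unknown slot_mode {slot_mode!r}")
    positions = gamma * np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    return ArrayLayout(n_antennas=n, r_max=r_max, d=d, positions=positions, thetas=thetas)


def arc_layout(n: int, radius: float, span: float) -> ArrayLayout:
    """``n`` elements spread over an arc of ``span`` radians centred on
    the +x direction — the one-sided aperture used for point-spread
    (resolution) measurements."""
    if n < 1:
        raise ValueError("need at least one antenna")
    thetas = np.linspace(-span / 2.0, span / 2.0, n)
    positions = radius * np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    return ArrayLayout(n_antennas=n, r_max=radius, d=0.0, positions=positions, thetas=thetas)


def gaussian_modulated_pulse(spec: PulseSpec, t: np.ndarray) -> np.ndarray:
    """Sample S(t) = exp(-(t - t0)^2 / (2 omega^2)) * cos(2 pi f_r t)."""
    t = np.asarray(t, dtype=float)
    env = np.exp(-((t - spec.t0) ** 2) / (2.0 * spec.omega**2))
    return env * np.cos(2.0 * np.pi * spec.f_r * t)


def pulse_bandwidth(spec: PulseSpec, dt: float, n: int = 8192, level_db: float = -3.0) -> tuple[float, float]:
    """Measure the pulse band edges at ``level_db`` below the spectral peak.

    Returns ``(f_lo, f_hi)`` in Hz from an FFT of the sampled pulse;
    used for logging the realised UWB band.
    """
    t = np.arange(n) * dt
    s = gaussian_modulated_pulse(spec, t)
    spec_amp = np.abs(np.fft.rfft(s))
    f = np.fft.rfftfreq(n, dt)
    thresh = spec_amp.max() * 10.0 ** (level_db / 20.0)
    above = np.nonzero(spec_amp >= thresh)[0]
    return float(f[above[0]]), float(f[above[-1]])
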