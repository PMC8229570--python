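"""The IMTR preprocessing chain.

Starting from a background acquisition E1 (no tumor) and a total
acquisition E2 (with tumor), the chain produces progressively cleaner
per-channel traces:

E3  calibration            E3 = E2 - E1 (background subtraction)
E4  early-content removal  weighted channels minus their cross-channel
                           mean, removing residual early arrivals that
                           are common to all channels
y   pairwise products      y_(i,j)(t) = S_i(t) * S_j(t) for i < j
E5  averaging              per-pair temporal moving average, smoothing
                           the products toward their envelopes
E6  time gating            zero outside the (tE, tL) window bracketing
                           physically possible tumor returns
E7  Gaussian window        taper E6 with exp(-((t - tp)/tau)^2)

E7 is the input to the pair-delay backprojection imager.  The chain
operates on one trace per antenna; by default these are the monostatic
(tx == rx) channels of the multistatic matrix, so channel i carries
round-trip delays 2*tau_i and the product of channels i and j peaks at
the summed one-way delay tau_i + tau_j.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import warnings

import numpy as np
from scipy.constants import c as C0
from scipy.ndimage import uniform_filter1d

from .arraypulse import ArrayLayout, PulseSpec
from .forward import SignalSet
from .phantom import Phantom

__all__ = [
    "GateWindow",
    "WindowSpec",
    "ProcessedSignals",
    "ChainParams",
    "calibrate",
    "early_content_removal",
    "pair_multiply",
    "average_pairs",
    "estimate_gate",
    "time_gate",
    "gaussian_window",
    "imtr_chain",
]

_STAGE_ORDER = {"E3": 0, "E4": 1, "pairs": 2, "E5": 3, "E6": 4, "E7": 5}


@dataclass(frozen=True)
class GateWindow:
    """Time gate (tE, tL) in seconds."""

    tE: float
    tL: float

    def __post_init__(self):
        if not (0 <= self.tE <= self.tL):
            raise ValueError(f"need 0 <= tE <= tL, got ({self.tE}, {self.tL})")


@dataclass(frozen=True)
class WindowSpec:
    """Gaussian taper: apex time ``tp`` and tapering factor ``tau`` (s)."""

    tp: float
    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError(f"tapering factor tau must be positive, got {self.tau}")


@dataclass
class ProcessedSignals:
    """Per-channel (or per-pair) traces at one chain stage.

    ``channel_index`` identifies each row: antenna indices for channel
    stages, ``(i, j)`` antenna pairs for pair stages.
    """

    stage: str
    data: np.ndarray
    t: np.ndarray
    channel_index: tuple = ()
    layout: ArrayLayout | None = None
    pulse: PulseSpec | None = None

    def __post_init__(self):
        if self.stage not in _STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage!r}")
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.t = np.asarray(self.t, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def _advance(self, stage: str, data: np.ndarray, channel_index=None) -> "ProcessedSignals":
        if _STAGE_ORDER[stage] < _STAGE_ORDER[self.stage]:
            raise ValueError(f"cannot move from stage {self.stage} back to {stage}")
        return ProcessedSignals(
            stage=stage,
            data=data,
            t=self.t,
            channel_index=self.channel_index if channel_index is None else channel_index,
            layout=self.layout,
            pulse=self.pulse,
        )


class AlignmentError(ValueError):
    pass


def calibrate(
    total: SignalSet, background: SignalSet, *, channels: str = "monostatic"
) -> ProcessedSignals:
    """Background subtraction: E3 = E2 - E1, flattened to a channel list.

    ``channels`` selects which multistatic entries become chain
    channels: ``"monostatic"`` keeps the tx == rx diagonal (one trace
    per antenna, the default for the pairing chain), ``"all"`` keeps
    every ordered (tx, rx) entry (used by the channel-domain
    beamformers and numeric time reversal).
    """
    if total.data.shape != background.data.shape:
        raise AlignmentError(
            f"total shape {total.data.shape} != background shape {background.data.shape}"
        )
    if total.t.size != background.t.size or not np.allclose(
        total.t, background.t, rtol=1e-9, atol=1e-15
    ):
        raise AlignmentError("total and background time axes differ")
    diff = total.data - background.data
    n = diff.shape[0]
    if channels == "monostatic":
        idx = tuple((i, i) for i in range(n))
        data = np.stack([diff[i, i] for i in range(n)])
    elif channels == "all":
        idx = tuple((i, j) for i in range(n) for j in range(n))
        data = diff.reshape(n * n, -1)
    else:
        raise ValueError(f"unknown channel selection {channels!r}")
    return ProcessedSignals(
        stage="E3",
        data=data,
        t=total.t.copy(),
        channel_index=idx,
        layout=total.layout,
        pulse=total.pulse,
    )


def early_content_removal(e3: ProcessedSignals, weight: float = 1.0) -> ProcessedSignals:
    """Weight the channels and subtract their cross-channel average.

    Residual early-time content (source breakthrough, skin interface
    leakage) is nearly identical across channels, so removing the
    per-sample channel mean suppresses it while leaving the
    target-dependent arrivals mostly intact.
    """
    if weight <= 0:
        raise ValueError(f"weighting factor must be positive, got {weight}")
    if e3.n_channels < 2:
        warnings.warn("early-content removal with a single channel yields all zeros")
    w = weight * e3.data
    return e3._advance("E4", w - w.mean(axis=0, keepdims=True))


def pair_multiply(e4: ProcessedSignals) -> ProcessedSignals:
    """Elementwise products over all unordered channel pairs.

    For channels S_1..S_n this yields C(n, 2) traces
    y_(i,j)(t) = S_i(t) S_j(t) in lexicographic pair order
    (y1 = S1 S2, y2 = S1 S3, ..., last = S_{n-1} S_n).
    """
    n = e4.n_channels
    if n < 2:
        raise ValueError(f"pair multiplication needs >= 2 channels, got {n}")
    pairs = list(combinations(range(n), 2))
    data = np.stack([e4.data[i] * e4.data[j] for i, j in pairs])
    # map row positions back to antenna labels where available
    labels = [c[0] if isinstance(c, tuple) else c for c in e4.channel_index] or list(range(n))
    idx = tuple((labels[i], labels[j]) for i, j in pairs)
    return e4._advance("pairs", data, channel_index=idx)


def average_pairs(pairs: ProcessedSignals, kernel: int | None = None) -> ProcessedSignals:
    """Per-pair moving-average smoothing (E5).

    The pair products oscillate at twice the carrier; averaging over
    roughly one pulse width (the default kernel) keeps their
    slowly-varying overlap envelope, which is what the backprojector
    needs.  ``kernel=1`` is the identity.
    """
    if pairs.n_channels < 1:
        raise ValueError("no pair traces to average")
    if kernel is None:
        omega = pairs.pulse.omega if pairs.pulse is not None else 78.1e-12
        kernel = max(1, int(round(omega / pairs.dt)))
    if kernel < 1:
        raise ValueError("kernel length must be >= 1")
    data = (
        uniform_filter1d(pairs.data, size=kernel, axis=1, mode="nearest")
        if kernel > 1
        else pairs.data.copy()
    )
    return pairs._advance("E5", data)


def _front_back_times(layout: ArrayLayout, phantom: Phantom) -> tuple[np.ndarray, float]:
    """Per-antenna one-way time to the breast front wall, and the one-way
    transit time of the breast diameter (skin crossed twice)."""
    r = np.hypot(layout.positions[:, 0], layout.positions[:, 1])
    front = (r - phantom.breast_radius) / C0
    ts = phantom.skin_thickness
    eps_skin = phantom.tissues["skin"].eps_r
    eps_fat = phantom.tissues["fat"].eps_r
    diam = 2.0 * phantom.breast_radius
    t_diam = (2.0 * ts * np.sqrt(eps_skin) + (diam - 2.0 * ts) * np.sqrt(eps_fat)) / C0
    return front, t_diam


def estimate_gate(
    layout: ArrayLayout,
    phantom: Phantom,
    pulse: PulseSpec,
    *,
    guard: float | None = None,
) -> GateWindow:
    """Geometric gate for the pair-product time base.

    Straight rays at per-segment speeds c/sqrt(eps_r) give, per antenna
    i, the one-way front-wall time f_i and the back-wall transit.  A
    pair trace (i, j) carries the summed one-way delays, so its
    physically possible tumor content lies between
    ``t0 + min(f_i + f_j)`` (the front-wall arrival) and
    ``t0 + max(f_i + f_j) + 2 * t_diam`` (round trips grazing the back
    wall).

    ``guard`` shifts the gate opening past tE so that the front-wall
    (skin) echo itself — the clutter the gate exists to reject — has
    cleared; the default is the skin-shell round trip plus three pulse
    widths (the echo's envelope support).
    """
    front, t_diam = _front_back_times(layout, phantom)
    s = front[:, None] + front[None, :]
    if guard is None:
        ts = phantom.skin_thickness
        eps_bg = phantom.tissues["background"].eps_r
        eps_surface = phantom.tissues["skin" if ts > 0 else "fat"].eps_r
        if np.isclose(eps_surface, eps_bg):
            guard = 0.0  # contrast-free surface: no front-wall echo to reject
        else:
            eps_skin = phantom.tissues["skin"].eps_r
            guard = 2.0 * ts * np.sqrt(eps_skin) / C0 + 3.0 * pulse.omega
    tE = pulse.t0 + float(s.min()) + guard
    tL = pulse.t0 + float(s.max()) + 2.0 * t_diam
    return GateWindow(tE=tE, tL=tL)


def time_gate(e5: ProcessedSignals, gate: GateWindow) -> ProcessedSignals:
    """Zero all samples outside the open interval (tE, tL)."""
    if gate.tE > e5.t[-1]:
        warnings.warn("gate lies entirely beyond the record; output is all zero")
    mask = (e5.t > gate.tE) & (e5.t < gate.tL)
    if not mask.any():
        warnings.warn("empty time gate; output is all zero")
    return e5._advance("E6", e5.data * mask[None, :])


def gaussian_window(e6: ProcessedSignals, w: WindowSpec) -> ProcessedSignals:
    """Taper with exp(-((t - tp)/tau)^2); the result is the E7 output."""
    taper = np.exp(-(((e6.t - w.tp) / w.tau) ** 2))
    return e6._advance("E7", e6.data * taper[None, :])


@dataclass(frozen=True)
class ChainParams:
    """Tunables of the preprocessing chain (all optional).

    ``mean_removal=False`` keeps the weighting of the early-content
    stage but skips the cross-channel mean subtraction; appropriate for
    data that contain no common-mode early content (e.g. analytic
    single-scattering traces), where the subtraction only injects
    cross-channel leakage into the pair products.
    """

    weight: float = 1.0
    mean_removal: bool = True
    smoothing_kernel: int | None = None
    gate: GateWindow | None = None
    window: WindowSpec | None = None
    channels: str = "monostatic"


def imtr_chain(
    total: SignalSet,
    background: SignalSet,
    phantom: Phantom,
    params: ChainParams | None = None,
    *,
    trace: dict | None = None,
) -> ProcessedSignals:
    """Run the full E1/E2 -> E7 chain.

    ``phantom`` supplies the geometry for the gate estimate when
    ``params.gate`` is not given; the Gaussian window defaults to
    ``tp = (tE + tL)/2`` and ``tau = (tL - tE)/4``.  Pass a dict as
    ``trace`` to collect the per-stage intermediates.
    """
    params = params or ChainParams()
    pulse = total.pulse
    layout = total.layout
    e3 = calibrate(total, background, channels=params.channels)
    if params.mean_removal:
        e4 = early_content_removal(e3, weight=params.weight)
    else:
        e4 = e3._advance("E4", params.weight * e3.data)
    prs = pair_multiply(e4)
    e5 = average_pairs(prs, kernel=params.smoothing_kernel)
    gate = params.gate
    if gate is None:
        if layout is None or pulse is None:
            raise ValueError("gate estimation needs the layout and pulse on the SignalSet")
        gate = estimate_gate(layout, phantom, pulse)
    gate = GateWindow(tE=gate.tE, tL=min(gate.tL, float(e5.t[-1])))
    e6 = time_gate(e5, gate)
    # window defaults: apex at the peak of the summed gated envelope
    # (the strongest coherent return), taper over half the gate span
    w = params.window
    if w is None:
        from scipy.signal import hilbert

        env = np.abs(hilbert(e6.data, axis=1)).sum(axis=0)
        tp = float(e6.t[np.argmax(env)]) if env.max() > 0 else 0.5 * (gate.tE + gate.tL)
        w = WindowSpec(tp=tp, tau=0.5 * (gate.tL - gate.tE))
    e7 = gaussian_window(e6, w)
    if trace is not None:
        trace.update({"E3": e3, "E4": e4, "pairs": prs, "E5": e5, "E6": e6, "E7": e7,
                      "gate": gate, "window": w})
    return e7
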