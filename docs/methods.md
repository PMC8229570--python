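# Methods

`imtr` is a hermetic software model of an ultra-wideband (UWB) microwave
radar system for detecting small tumors in breast/skin tissue: a 2-D
electromagnetic forward simulator generates multistatic acquisitions from
synthetic dielectric phantoms, a six-stage preprocessing chain isolates the
tumor response, and four image-formation algorithms (MWDAS, FDMAS, time
reversal, IMTR) turn the traces into intensity maps that are scored against
a clutter-free reference. This note records the model, its assumptions, the
tunable parameters, and the design choices made where the problem was
genuinely open.

## Physical model

**Geometry.** Everything lives in a 2-D slice through the equatorial plane
of the breast: a circular fat disc (default radius 50 mm), a thin skin
shell (2 mm), and one or more circular tumors. Antennas are ideal point
transceivers on a ring of radius `r_max − d` (default 60 mm, i.e. a 5 mm
working gap plus clearance beyond the 5 mm minimum standoff), occupying
angular slots spaced 2π/9 (40°). Coordinates are metres, origin at the
breast centre.

**Tissues.** Media are linear, isotropic, non-magnetic and
frequency-independent, characterised by (ε_r, σ). Defaults: fat
ε_r = 5.1, σ = 0.14 S/m; skin 36, 4; tumor 50, 7 — literature-typical
values chosen to respect the reported 2–10× permittivity contrast between
healthy and malignant tissue (tumor/fat ≈ 9.8). Dispersion (Debye) is
deliberately omitted: constant media keep the analytic oracles exact, at
the cost of ignoring pulse distortion that real tissue would add.

**Excitation.** A modulated Gaussian `S(t) = exp(−(t−t0)²/2ω²)·cos(2πf_r t)`
with carrier f_r = 2.4 GHz and envelope width ω = 78.1 ps (t0 = 5ω so the
record starts silent). The measured −10 dB band spans several GHz, so the
pulse is UWB. The phantom grid must resolve the shortest in-tissue
wavelength at the pulse's upper half-power band edge (≈4.1 GHz; ≈10.3 mm
in tumor tissue) by at least 10 cells, which the default 1 mm grid just
satisfies.

**Forward solver.** A 2-D TMz FDTD scheme on the Yee grid: one
out-of-plane electric component Ez, lossy-medium update coefficients, and
Berenger split-field PML (10 cells, cubic grading, target reflection
1e-6 design / ≤1e-2 accepted; measured ≈2e-5). Time step
`dt = 0.5·dx/c` (Courant factor 0.5 < 1/√2). Sources are soft additive
currents at single cells; receivers record Ez. On orthogonal grids this
is the same discretisation family as the finite integration technique, so
it is a faithful stand-in for a commercial 2-D FIT solve. Known 2-D
artefact: the cylindrical-wave Green function has a 1/√(t−r/c) tail, so
the *absolute* envelope peak of a received pulse lags the geometric
arrival by ≈3%. The tail shape is range-invariant, so arrival-time
validation uses the envelope-peak *difference* between two probes on one
ray, which agrees with distance/c to better than 1%.

**Analytic oracle.** `born_point_scatterer` implements single scattering
in a homogeneous medium: each scatterer contributes a delayed copy of the
pulse attenuated by 1/√(d_tx·d_rx), with exact arrival times by
construction. Every beamformer is validated against it.

## Acquisition protocol

Each antenna transmits in turn while all antennas record, giving an
n×n×n_t multistatic matrix. Two acquisitions are made per trial:

* **E1 (background)** — the empty chamber: coupling medium only, no
  phantom. This matches the measurement practice the system emulates and
  means E3 = E2 − E1 removes the direct antenna-to-antenna wave but *not*
  the skin reflection: all reconstruction algorithms face the same
  clutter, and the preprocessing chain's clutter-removal stages do real
  work. (Calibrating against a tumor-free phantom instead makes E3
  clutter-free and flattens the differences between algorithms; the
  functions accept either.)
* **E2 (total)** — the phantom with tumors in place.

Optional i.i.d. receiver noise (relative to the acquisition maximum) can
be enabled per config; it is off by default and seeded when on.

## The IMTR preprocessing chain

Operating on one trace per antenna — the monostatic (tx = rx) diagonal,
the only channel choice consistent with the pair-delay imaging rule
below — the chain is:

1. **E3 calibration**: E2 − E1 per channel.
2. **E4 early-content removal**: multiply by a scalar weight (default 1)
   and subtract the cross-channel mean at each time sample. The skin
   echo is nearly identical across channels of a concentric ring, so the
   mean captures and removes it (measured ≈9× suppression on the default
   scenario). Side effect: 1/n of every channel leaks into every other,
   which matters only when the input is already clutter-free;
   `mean_removal=False` is provided for that case.
3. **Pair products**: y_(i,j)(t) = S_i(t)·S_j(t) for all C(n,2) unordered
   pairs in lexicographic order. A product of two round-trip echoes peaks
   at the *mean* of their arrival times, i.e. at the summed one-way delay
   τ_i + τ_j of the scatterer.
4. **E5 averaging**: per-pair moving average over one pulse width
   (kernel = ω/dt samples), smoothing the double-carrier component of the
   products toward their overlap envelope.
5. **E6 time gating**: zero outside (tE, tL). tE/tL come from straight-ray
   geometry at per-segment speeds c/√ε_r: tE is the earliest pair
   front-wall sum **plus a guard** (skin-shell round trip + 3ω) so the
   front-wall echo itself has cleared; tL is the latest pair sum through
   the back wall. The guard is what separates residual skin clutter from
   tumor returns: without it the gated traces are still skin-dominated.
6. **E7 Gaussian window**: multiply by exp(−((t−tp)/τ_w)²). Defaults:
   tp = the apex (time of the summed gated-envelope peak) and
   τ_w = (tL − tE)/2. A gate-midpoint apex was rejected because the
   midpoint time equals the ring-centre lookup time exactly, which
   systematically highlights the array centre.

## Image formation

All imagers share a focal grid (breast bounding box + 10 mm, 1 mm pixels)
and a delay model; the packaged default is `layered`: straight rays with
the background speed outside the breast and c/√ε_r segments through skin
and fat (a homogeneous effective-speed mode is available). Final images
are squared magnitudes, max-normalised, and masked to the breast interior
(the imaging domain) before scoring.

* **MWDAS** — weighted delay-and-sum: coherent sum of delayed
  analytic-signal samples with path-length weights, integrated over a
  pulse-length window *centred* on the nominal arrival (an asymmetric
  window biases the peak radially inward ~5% of range; centring removes
  the bias exactly).
* **FDMAS** — delay-multiply-and-sum with the sign-preserving square
  root, computed via the square-of-sum identity over the same centred
  window. The window mean is removed before envelope detection:
  multiplication shifts coherent signal content to twice the carrier
  while incoherent clutter accumulates near DC, and rejecting that
  baseband term is the algorithm's distinguishing clutter-suppression
  step.
* **TR** — time reversal. Numeric mode re-emits the time-reversed
  calibrated signals into the tumor-free phantom with the FDTD solver:
  each antenna injects the reverse of the coherent sum of all traces it
  received across the acquisition (by linearity, the coherent
  superposition of re-emitting each transmit experiment separately) and
  the per-pixel field energy Σ_t Ez² is accumulated; pixels within 8 mm
  of an antenna are blanked because injection amplitude trivially
  dominates there. Synthetic mode is phase-conjugate backprojection
  (unweighted envelope DAS), the fast cross-check.
* **IMTR** — pair-delay backprojection of the preprocessed pair traces:
  I(r) = [Σ_(i,j) ŷ_(i,j)(t0 + τ_i(r) + τ_j(r))]², ŷ the envelope of
  each E7 trace.

## Known limitations

* **Multi-target ambiguity of pair-delay backprojection.** Multiplying
  *unaligned* traces discards which arrival belongs to which antenna.
  With two targets A and B, each pair trace contains cross blobs at
  (τ_iA + τ_jB) with the same amplitude law as the true blobs; for a
  symmetric target pair those 36 cross blobs backproject coherently to
  the midpoint, which becomes the global maximum. For off-centre targets
  the true blobs survive in only the ~10 of 36 pairs whose two distances
  differ by less than a pulse width. Consequence: a single tumor is
  localised to ≈1.6 mm end-to-end, but with two tumors 20 mm apart the
  strongest image peaks land on the inter-tumor ghost and residual
  clutter rather than on the tumors (matching errors from several mm
  up to tens of mm); the two-tumor scenario is packaged and scored
  honestly with this behaviour. Channel-domain imagers (which delay
  before combining) do not share this ambiguity.
* A tumor exactly at the array centre is degenerate for the
  mean-removal stage (all monostatic channels identical); packaged
  single-tumor scenarios therefore place the tumor at (20, 0) mm.
* The resolution probe uses a one-sided arc aperture: for a closed ring
  the coherent point response is carrier-wavelength-limited and nearly
  independent of pulse bandwidth and aperture, so the classical
  range/cross-range sweeps are only meaningful for an arc.
* 2-D slice physics: out-of-plane spreading, antenna patterns,
  dispersion and mutual coupling are not modelled; SSIM values are
  therefore comparable within this package, not directly to measured
  systems.

## Problem sizes and determinism

Packaged scenario runs use a 1 mm grid (160×160 cells for the 50 mm
breast, 220×220 for the 16 cm variant), 9 transmitters, and 3072–4096
time steps of ≈1.67 ps; one acquisition pair plus all four
reconstructions completes in about a minute on one core. The pipeline is
deterministic for a fixed config and seed; the only stochastic element
(receiver noise) is off by default and seeded when enabled.
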