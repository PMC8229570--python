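"""The E1..E7 preprocessing chain: stage contracts and invariants."""

import numpy as np
import pytest
from scipy.constants import c as C0

from imtr.arraypulse import PulseSpec, place_antennas
from imtr.forward import SignalSet
from imtr.preprocess import (
    AlignmentError,
    ChainParams,
    GateWindow,
    ProcessedSignals,
    WindowSpec,
    average_pairs,
    calibrate,
    early_content_removal,
    estimate_gate,
    gaussian_window,
    imtr_chain,
    pair_multiply,
    time_gate,
)
from imtr.preprocess import _front_back_times


def make_sets(n=4, nt=256, seed=0):
    rng = np.random.default_rng(seed)
    lay = place_antennas(n, 60e-3)
    pulse = PulseSpec()
    t = np.arange(nt) * 2e-12
    total = SignalSet(rng.normal(size=(n, n, nt)), t, "total", lay, pulse)
    background = SignalSet(rng.normal(size=(n, n, nt)), t, "background", lay, pulse)
    return total, background


def channels(data, t=None, stage="E4"):
    data = np.atleast_2d(data)
    t = np.arange(data.shape[1]) * 2e-12 if t is None else t
    idx = tuple((i, i) for i in range(data.shape[0]))
    return ProcessedSignals(stage, data, t, idx)


class TestCalibrate:
    def test_identical_sets_cancel(self):
        total, _ = make_sets()
        e3 = calibrate(total, total)
        assert not np.any(e3.data)

    def test_zero_background_is_identity(self):
        total, background = make_sets()
        background.data = np.zeros_like(background.data)
        e3 = calibrate(total, background, channels="all")
        assert np.array_equal(e3.data, total.data.reshape(16, -1))

    def test_elementwise_subtraction_oracle(self):
        total, background = make_sets()
        e3 = calibrate(total, background, channels="monostatic")
        for k in range(4):
            assert np.array_equal(e3.data[k], total.data[k, k] - background.data[k, k])

    def test_mismatched_shapes_raise(self):
        total, _ = make_sets(n=4)
        other, _ = make_sets(n=3)
        with pytest.raises(AlignmentError):
            calibrate(total, other)

    def test_mismatched_time_axes_raise(self):
        total, background = make_sets()
        background.t = background.t * 2.0
        with pytest.raises(AlignmentError):
            calibrate(total, background)


class TestEarlyContentRemoval:
    def test_identical_channels_vanish(self):
        e = channels(np.tile(np.sin(np.arange(64.0)), (5, 1)), stage="E3")
        out = early_content_removal(e)
        assert np.allclose(out.data, 0.0)

    def test_antisymmetric_pair_is_preserved(self):
        s = np.sin(np.arange(64.0))
        e = channels(np.stack([s, -s]), stage="E3")
        out = early_content_removal(e, weight=1.0)
        assert np.allclose(out.data, np.stack([s, -s]))

    def test_weighted_mean_removal_oracle(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=(6, 128))
        out = early_content_removal(channels(d, stage="E3"), weight=2.0)
        assert np.allclose(out.data, 2.0 * (d - d.mean(axis=0)))

    def test_single_channel_warns(self):
        with pytest.warns(UserWarning):
            early_content_removal(channels(np.ones((1, 16)), stage="E3"))


class TestPairStage:
    def test_four_channels_give_six_products_in_printed_order(self):
        d = np.arange(4.0)[:, None] + np.ones((4, 8))
        out = pair_multiply(channels(d))
        assert out.n_channels == 6
        assert out.channel_index == ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

    def test_two_channels_give_single_product(self):
        d = np.stack([np.arange(8.0), np.arange(8.0) + 1])
        out = pair_multiply(channels(d))
        assert out.n_channels == 1
        assert np.array_equal(out.data[0], d[0] * d[1])

    def test_nine_channels_give_36_elementwise_products(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(9, 64))
        out = pair_multiply(channels(d))
        assert out.n_channels == 36
        for row, (i, j) in enumerate(out.channel_index):
            assert np.array_equal(out.data[row], d[i] * d[j])

    def test_single_channel_cannot_pair(self):
        with pytest.raises(ValueError):
            pair_multiply(channels(np.ones((1, 8))))

    def test_bilinearity_scaling(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=(4, 32))
        a = pair_multiply(channels(d))
        b = pair_multiply(channels(3.0 * d))
        assert np.allclose(b.data, 9.0 * a.data)


class TestAveraging:
    def test_constant_traces_unchanged(self):
        prs = pair_multiply(channels(np.ones((3, 64))))
        out = average_pairs(prs, kernel=9)
        assert np.allclose(out.data, 1.0)

    def test_impulse_becomes_rectangle(self):
        d = np.zeros((2, 64))
        d[:, 32] = 1.0
        prs = channels(d, stage="pairs")
        out = average_pairs(prs, kernel=5)
        assert np.allclose(out.data[0][30:35], 0.2)
        assert out.data[0].sum() == pytest.approx(1.0)

    def test_kernel_one_is_identity(self):
        rng = np.random.default_rng(4)
        prs = channels(rng.normal(size=(2, 64)), stage="pairs")
        out = average_pairs(prs, kernel=1)
        assert np.array_equal(out.data, prs.data)


class TestGate:
    def test_vacuum_front_wall_leg(self, vacuum_phantom_50mm):
        lay = place_antennas(9, 60e-3)
        front, t_diam = _front_back_times(lay, vacuum_phantom_50mm)
        assert np.allclose(front, 10e-3 / C0)
        assert t_diam == pytest.approx(100e-3 / C0)

    def test_gate_ordering_and_fat_slowdown(self, vacuum_phantom_50mm):
        lay = place_antennas(9, 60e-3)
        pulse = PulseSpec()
        g_vac = estimate_gate(lay, vacuum_phantom_50mm, pulse)
        assert g_vac.tE < g_vac.tL
        from imtr.phantom import build_phantom

        fat = build_phantom(50e-3, 0.0, [])
        # in-breast diameter legs slower by sqrt(eps_fat)
        _, t_vac = _front_back_times(lay, vacuum_phantom_50mm)
        _, t_fat = _front_back_times(lay, fat)
        assert t_fat / t_vac == pytest.approx(np.sqrt(5.1), rel=1e-9)
        g_fat = estimate_gate(lay, fat, pulse)
        assert g_fat.tL > g_vac.tL

    def test_full_record_gate_is_identity(self):
        e5 = channels(np.random.default_rng(5).normal(size=(3, 64)), stage="E5")
        out = time_gate(e5, GateWindow(0.0, 1.0))
        # open interval: the t=0 sample is excluded, all others kept
        assert np.array_equal(out.data[:, 1:], e5.data[:, 1:])
        assert np.all(out.data[:, 0] == 0.0)

    def test_zero_width_gate_silences(self):
        e5 = channels(np.ones((2, 32)), stage="E5")
        with pytest.warns(UserWarning):
            out = time_gate(e5, GateWindow(1e-11, 1e-11))
        assert not np.any(out.data)

    def test_toy_trace_index_arithmetic(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        e5 = ProcessedSignals("E5", np.array([[1.0, 2.0, 3.0, 4.0]]), t, ((0, 0),))
        out = time_gate(e5, GateWindow(0.5, 2.5))
        assert np.array_equal(out.data[0], [0.0, 2.0, 3.0, 0.0])

    def test_gating_is_idempotent(self):
        e5 = channels(np.random.default_rng(6).normal(size=(2, 64)), stage="E5")
        g = GateWindow(20e-12, 90e-12)
        once = time_gate(e5, g)
        twice = time_gate(ProcessedSignals("E5", once.data, once.t, once.channel_index), g)
        assert np.array_equal(once.data, twice.data)


class TestWindow:
    def test_identity_at_apex_and_e_fold_at_tau(self):
        t = np.arange(64) * 2e-12
        e6 = ProcessedSignals("E6", np.ones((1, 64)), t, ((0, 0),))
        w = WindowSpec(tp=t[32], tau=t[10])
        out = gaussian_window(e6, w)
        assert out.data[0, 32] == pytest.approx(1.0)
        assert out.data[0, 42] == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_huge_tau_approaches_identity(self):
        t = np.arange(64) * 2e-12
        d = np.random.default_rng(7).normal(size=(2, 64))
        e6 = ProcessedSignals("E6", d, t, ((0, 0), (1, 1)))
        out = gaussian_window(e6, WindowSpec(tp=t[32], tau=100 * t[-1]))
        assert np.allclose(out.data, d, rtol=1e-4, atol=1e-12)

    def test_window_commutes_with_gate(self):
        t = np.arange(64) * 2e-12
        d = np.random.default_rng(8).normal(size=(2, 64))
        g = GateWindow(t[10], t[50])
        w = WindowSpec(tp=t[30], tau=t[15])
        a = gaussian_window(time_gate(channels(d, t, "E5"), g), w)
        b = time_gate(
            ProcessedSignals("E5", gaussian_window(channels(d, t, "E5")._advance("E6", d), w).data, t,
                             a.channel_index),
            g,
        )
        assert np.allclose(a.data, b.data)

    def test_energy_never_increases_through_masks(self):
        t = np.arange(128) * 2e-12
        d = np.random.default_rng(9).normal(size=(3, 128))
        e5 = channels(d, t, "E5")
        gated = time_gate(e5, GateWindow(t[10], t[100]))
        windowed = gaussian_window(gated, WindowSpec(tp=t[50], tau=t[20]))
        assert (gated.data**2).sum() <= (d**2).sum()
        assert (windowed.data**2).sum() <= (gated.data**2).sum()


class TestChain:
    def test_null_input_propagates_to_silence(self, vacuum_phantom_50mm):
        total, _ = make_sets(n=9, nt=512)
        e7 = imtr_chain(total, total, vacuum_phantom_50mm)
        assert not np.any(e7.data)

    def test_chain_matches_manual_composition(self, vacuum_phantom_50mm):
        total, background = make_sets(n=4, nt=512)
        trace = {}
        params = ChainParams(
            gate=GateWindow(1e-10, 8e-10), window=WindowSpec(tp=4e-10, tau=2e-10)
        )
        e7 = imtr_chain(total, background, vacuum_phantom_50mm, params, trace=trace)
        manual = calibrate(total, background)
        manual = early_content_removal(manual, 1.0)
        manual = average_pairs(pair_multiply(manual))
        manual = time_gate(manual, GateWindow(1e-10, min(8e-10, total.t[-1])))
        manual = gaussian_window(manual, WindowSpec(tp=4e-10, tau=2e-10))
        assert np.allclose(e7.data, manual.data)

    def test_doubling_weight_quadruples_output(self, vacuum_phantom_50mm):
        total, background = make_sets(n=4, nt=512)
        e7a = imtr_chain(total, background, vacuum_phantom_50mm, ChainParams(weight=1.0))
        e7b = imtr_chain(total, background, vacuum_phantom_50mm, ChainParams(weight=2.0))
        assert np.allclose(e7b.data, 4.0 * e7a.data)

    def test_stage_order_is_enforced(self):
        e7 = channels(np.ones((2, 16)), stage="E7")
        with pytest.raises(ValueError):
            e7._advance("E4", e7.data)
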