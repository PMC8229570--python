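"""Image formation: delays, the four imagers, and shared invariants."""

import numpy as np
import pytest
from scipy.constants import c as C0

from imtr.arraypulse import PulseSpec
from imtr.forward import SignalSet, born_point_scatterer
from imtr.phantom import Phantom
from imtr.preprocess import calibrate, imtr_chain
from imtr.reconstruct import (
    DelayModel,
    ImageGrid,
    fdmas_image,
    focal_delays,
    imtr_image,
    make_image_grid,
    mwdas_image,
    tr_image,
)

DM_VAC = DelayModel(mode="homogeneous", speed=C0)


def zero_like(ss):
    return SignalSet(np.zeros_like(ss.data), ss.t, "background", ss.layout, ss.pulse)


def err_mm(img, truth):
    p = img.argmax_point()
    return np.hypot(p[0] - truth[0], p[1] - truth[1]) * 1e3


@pytest.fixture(scope="module")
def born_e3(ring9, pulse):
    truth = (10e-3, 5e-3)
    ss = born_point_scatterer(ring9, [(truth, 1.0)], pulse, v=C0, dt=8e-12)
    return truth, calibrate(ss, zero_like(ss), channels="all")


class TestFocalDelays:
    def test_delay_vanishes_at_antenna(self, ring9):
        grid = make_image_grid(61e-3, 1e-3)
        tau = focal_delays(ring9, grid, DM_VAC)
        x, y = grid.pixel_centers()
        i = np.argmin(np.abs(x - ring9.positions[0, 0]))
        j = np.argmin(np.abs(y - ring9.positions[0, 1]))
        assert tau[0, i, j] < 1.5e-3 / C0  # sub-pixel residual

    def test_center_delay_is_radius_over_c(self, ring9):
        grid = make_image_grid(50e-3, 1e-3)
        tau = focal_delays(ring9, grid, DM_VAC)
        n = grid.shape[0] // 2
        assert tau[0, n, n] == pytest.approx(60e-3 / C0, rel=1e-2)

    def test_slow_breast_increases_delay(self, ring9):
        grid = make_image_grid(50e-3, 1e-3)
        slow = DelayModel(mode="two_speed", speed=C0, breast_radius=50e-3, eps_fat=5.1)
        tau_h = focal_delays(ring9, grid, DM_VAC)
        tau_s = focal_delays(ring9, grid, slow)
        assert np.all(tau_s >= tau_h - 1e-15)
        assert tau_s.max() > tau_h.max()

    def test_from_phantom_modes(self, vacuum_phantom_50mm):
        dm = DelayModel.from_phantom(vacuum_phantom_50mm, "homogeneous")
        assert dm.speed == pytest.approx(C0)


class TestImagers:
    def test_all_zero_signals_give_blank_images(self, ring9, pulse, vacuum_phantom_50mm):
        nt = 512
        t = np.arange(nt) * 8e-12
        ss = SignalSet(np.zeros((9, 9, nt)), t, "total", ring9, pulse)
        e3 = calibrate(ss, ss, channels="all")
        grid = make_image_grid(50e-3, 1e-3)
        assert not np.any(mwdas_image(e3, ring9, grid, DM_VAC).intensity)
        assert not np.any(fdmas_image(e3, ring9, grid, DM_VAC).intensity)
        assert not np.any(tr_image(e3, ring9, grid, mode="synthetic", dm=DM_VAC).intensity)

    @pytest.mark.parametrize("imager", ["mwdas", "fdmas", "tr_synthetic"])
    def test_born_scatterer_within_one_pixel(self, born_e3, ring9, imager):
        truth, e3 = born_e3
        grid = make_image_grid(50e-3, 1e-3)
        if imager == "mwdas":
            img = mwdas_image(e3, ring9, grid, DM_VAC)
        elif imager == "fdmas":
            img = fdmas_image(e3, ring9, grid, DM_VAC)
        else:
            img = tr_image(e3, ring9, grid, mode="synthetic", dm=DM_VAC)
        assert err_mm(img, truth) <= 1.5  # within one 1 mm pixel of the corner point

    def test_fdmas_mainlobe_not_wider_than_das(self, born_e3, ring9):
        truth, e3 = born_e3
        grid = make_image_grid(50e-3, 1e-3)
        das = mwdas_image(e3, ring9, grid, DM_VAC, weights="uniform")
        dmas = fdmas_image(e3, ring9, grid, DM_VAC)

        def lobe_area(img):
            return np.count_nonzero(img.intensity >= 0.5)

        assert lobe_area(dmas) <= lobe_area(das)

    def test_fdmas_single_channel_falls_back(self, ring9, pulse):
        nt = 256
        t = np.arange(nt) * 8e-12
        data = np.zeros((9, 9, nt))
        data[0, 0, 100] = 1.0
        ss = SignalSet(data, t, "total", ring9, pulse)
        e3 = calibrate(ss, zero_like(ss), channels="monostatic")
        one = type(e3)("E3", e3.data[:1], e3.t, (e3.channel_index[0],), ring9, pulse)
        grid = make_image_grid(30e-3, 2e-3)
        with pytest.warns(UserWarning):
            fdmas_image(one, ring9, grid, DM_VAC)

    def test_mirror_symmetric_scene_gives_mirror_symmetric_image(self, ring9, pulse):
        # scatterer pair symmetric about the x-axis; the 9-slot ring is too
        ss = born_point_scatterer(
            ring9, [((10e-3, 15e-3), 1.0), ((10e-3, -15e-3), 1.0)], pulse, v=C0, dt=8e-12
        )
        e3 = calibrate(ss, zero_like(ss), channels="all")
        grid = make_image_grid(50e-3, 1e-3)
        img = mwdas_image(e3, ring9, grid, DM_VAC, weights="uniform").intensity
        assert np.allclose(img, img[:, ::-1], atol=1e-6 * img.max())

    def test_imtr_blank_on_silent_pairs(self, ring9, pulse):
        from imtr.preprocess import ProcessedSignals

        t = np.arange(256) * 8e-12
        e7 = ProcessedSignals("E7", np.zeros((36, 256)), t,
                              tuple((i, j) for i in range(9) for j in range(i + 1, 9)),
                              ring9, pulse)
        grid = make_image_grid(50e-3, 1e-3)
        assert not np.any(imtr_image(e7, ring9, grid, DM_VAC).intensity)

    def test_imtr_born_scatterer_recovery(self, born_single, ring9, vacuum_phantom_50mm):
        truth, total, background = born_single
        e7 = imtr_chain(total, background, vacuum_phantom_50mm)
        grid = make_image_grid(50e-3, 1e-3)
        img = imtr_image(e7, ring9, grid, DM_VAC)
        assert err_mm(img, truth) <= 1.5

    def test_tr_numeric_matches_synthetic_argmax(self, born_single, ring9):
        truth, total, background = born_single
        from imtr.forward import SolverConfig

        # resample Born data onto the FDTD time step for re-injection
        cfg = SolverConfig()
        dt = cfg.dt(1e-3)
        nt = 1500
        t = np.arange(nt) * dt
        data = np.empty((9, 9, nt))
        for i in range(9):
            for j in range(9):
                data[i, j] = np.interp(t, total.t, total.data[i, j], left=0, right=0)
        ss = SignalSet(data, t, "total", ring9, total.pulse)
        e3 = calibrate(ss, zero_like(ss), channels="all")
        n = 160
        vac = Phantom(grid_spacing=1e-3, eps_map=np.ones((n, n)), sigma_map=np.zeros((n, n)))
        grid = make_image_grid(50e-3, 1e-3)
        num = tr_image(e3, ring9, grid, phantom_background=vac, mode="numeric")
        syn = tr_image(e3, ring9, grid, mode="synthetic", dm=DM_VAC)
        pn, ps = num.argmax_point(), syn.argmax_point()
        assert np.hypot(pn[0] - ps[0], pn[1] - ps[1]) <= 2.1e-3


class TestInvariances:
    def test_translation_consistency(self, ring9, pulse):
        grid = make_image_grid(50e-3, 1e-3)
        shifts = []
        for truth in [(10e-3, 5e-3), (13e-3, 5e-3)]:
            ss = born_point_scatterer(ring9, [(truth, 1.0)], pulse, v=C0, dt=8e-12)
            e3 = calibrate(ss, zero_like(ss), channels="all")
            img = mwdas_image(e3, ring9, grid, DM_VAC)
            shifts.append(img.argmax_point())
        dx = (shifts[1][0] - shifts[0][0]) * 1e3
        dy = (shifts[1][1] - shifts[0][1]) * 1e3
        assert dx == pytest.approx(3.0, abs=1.0)
        assert dy == pytest.approx(0.0, abs=1.0)

    def test_global_time_shift_invariance(self, ring9, pulse):
        """Shifting every trace and the time axis together leaves the
        image unchanged (t0 compensation)."""
        truth = (10e-3, 5e-3)
        ss = born_point_scatterer(ring9, [(truth, 1.0)], pulse, v=C0, dt=8e-12)
        shifted = SignalSet(ss.data, ss.t + 3e-10, "total", ring9,
                            PulseSpec(t0=pulse.t0 + 3e-10))
        grid = make_image_grid(50e-3, 1e-3)
        a = mwdas_image(calibrate(ss, zero_like(ss), channels="all"), ring9, grid, DM_VAC)
        b = mwdas_image(calibrate(shifted, zero_like(shifted), channels="all"), ring9, grid, DM_VAC)
        assert np.allclose(a.intensity, b.intensity, atol=1e-7)

    def test_image_grid_validation(self):
        with pytest.raises(ValueError):
            ImageGrid(np.zeros(5), (0, 1, 0, 1), 1e-3)
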