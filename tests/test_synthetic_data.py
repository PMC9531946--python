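import numpy as np
import pandas as pd
import pytest

import papa_spt as p
from papa_spt import BLEACHED, BRIGHT, DARK
from papa_spt.illumination import Channel


def _labeling(n, fdl=0.0):
    return p.LabelingModel(n_molecules=n, fraction_double_labeled=fdl)


class TestPhotophysics:
    def test_all_rates_zero_keeps_everything_bright(self, quiet_photophysics):
        proto = p.parse_protocol(
            "2 cycles of 10 R [2 ms], 1 V [7 ms], 10 R [2 ms], 1 G [7 ms]"
        )
        res = p.simulate_photophysics(quiet_photophysics, _labeling(50), proto, 0)
        assert (res.states == BRIGHT).all()

    def test_saturation_limit(self):
        # infinitely fast shelving, saturating violet at frame 250
        proto = p.parse_protocol("1 cycle of 250 R [2 ms], 1 V [7 ms], 50 R [2 ms]")
        model = p.PhotophysicsModel(
            p_shelve_per_ms_red=1e3,
            p_bleach_per_ms_red=0.0,
            shelvable_fraction=1.0,
            k_dr_per_ms_violet=1e3,
            k_papa_per_ms_green=0.0,
            k_papa_background_per_ms_green=0.0,
            p_spont_per_frame=0.0,
        )
        res = p.simulate_photophysics(model, _labeling(200), proto, 1)
        assert (res.states[:, 249] == DARK).all()
        assert (res.states[:, 251] == BRIGHT).all()

    def test_competing_risks_closed_form(self):
        # fraction ever-dark = shelvable_fraction * ks/(ks+kb) after long red
        proto = p.parse_protocol("1 cycle of 2000 R [7 ms]")
        model = p.PhotophysicsModel(
            p_shelve_per_ms_red=0.002,
            p_bleach_per_ms_red=0.001,
            shelvable_fraction=0.5,
            k_dr_per_ms_violet=0.0,
            k_papa_per_ms_green=0.0,
            k_papa_background_per_ms_green=0.0,
            p_spont_per_frame=0.0,
        )
        n = 200_000
        res = p.simulate_photophysics(model, _labeling(n), proto, 2)
        ever_dark = (res.states == DARK).any(axis=1).mean()
        expected = 0.5 * 0.002 / 0.003
        assert ever_dark == pytest.approx(expected, abs=3 * np.sqrt(expected / n))

    def test_occupancy_conservation(self, standard_protocol):
        model = p.PhotophysicsModel()
        res = p.simulate_photophysics(model, _labeling(500, 0.5), standard_protocol, 3)
        assert set(np.unique(res.states)) <= {BRIGHT, DARK, BLEACHED}
        counts = np.stack([(res.states == s).sum(axis=0) for s in (0, 1, 2)])
        assert (counts.sum(axis=0) == 500).all()

    def test_pre_shelving_applied_before_frame_zero(self):
        proto = p.parse_protocol("1 cycle of 5 R [2 ms]", pre_shelving_s=100.0)
        model = p.PhotophysicsModel(
            p_shelve_per_ms_red=1.0, p_bleach_per_ms_red=0.0, shelvable_fraction=1.0,
            p_spont_per_frame=0.0,
        )
        res = p.simulate_photophysics(model, _labeling(100), proto, 4)
        assert (res.states[:, 0] == DARK).all()

    def test_green_reactivation_monotone_in_double_labeling(self):
        proto = p.parse_protocol(
            "1 cycle of 100 R [2 ms], 1 G [7 ms], 30 R [2 ms]", pre_shelving_s=10.0
        )
        model = p.PhotophysicsModel(
            k_papa_per_ms_green=0.1, k_papa_background_per_ms_green=0.0,
            p_spont_per_frame=0.0, p_sender_bleach_per_ms_green=0.0,
        )
        reactivated = []
        for fdl in (0.0, 0.5, 1.0):
            res = p.simulate_photophysics(model, _labeling(20_000, fdl), proto, 5)
            # green pulse in frame 100; reactivation visible from frame 101
            before = (res.states[:, 100] == BRIGHT).sum()
            after = (res.states[:, 101] == BRIGHT).sum()
            reactivated.append(after - before)
        assert reactivated[0] <= reactivated[1] <= reactivated[2]

    def test_sender_blind_equivalence(self):
        # with k_papa == k_papa_background, labeling cannot matter
        proto = p.parse_protocol(
            "1 cycle of 100 R [2 ms], 1 G [7 ms], 30 R [2 ms]", pre_shelving_s=10.0
        )
        model = p.PhotophysicsModel(
            k_papa_per_ms_green=0.05, k_papa_background_per_ms_green=0.05,
            p_spont_per_frame=0.0, p_sender_bleach_per_ms_green=0.0,
        )
        res0 = p.simulate_photophysics(model, _labeling(50_000, 0.0), proto, 6)
        res1 = p.simulate_photophysics(model, _labeling(50_000, 1.0), proto, 6)

        def green_step(res):
            return (res.states[:, 101] == BRIGHT).sum() - (
                res.states[:, 100] == BRIGHT
            ).sum()

        s0, s1 = green_step(res0), green_step(res1)
        # binomial noise bound on the difference of reactivation counts
        assert abs(s0 - s1) < 6 * np.sqrt(max(s0 + s1, 1))

    def test_bit_reproducibility(self, standard_protocol):
        model = p.PhotophysicsModel()
        a = p.simulate_photophysics(model, _labeling(200, 0.5), standard_protocol, 7)
        b = p.simulate_photophysics(model, _labeling(200, 0.5), standard_protocol, 7)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.sender_alive, b.sender_alive)


class TestTrajectories:
    def _bright_result(self, quiet, n, n_frames):
        proto = p.parse_protocol(f"1 cycle of {n_frames} R [2 ms]")
        return p.simulate_photophysics(quiet, _labeling(n), proto, 8)

    def test_immobile_noiseless_localizations_identical(self, quiet_photophysics):
        res = self._bright_result(quiet_photophysics, 5, 20)
        motion = p.MotionModel(d_bound=0.0, d_free=0.0, f_bound=1.0, sigma_loc=0.0)
        ts = p.simulate_trajectories(motion, res, 9)
        for _, g in ts.df.groupby("trajectory"):
            assert g["x_um"].nunique() == 1
            assert g["y_um"].nunique() == 1

    def test_mean_squared_jump_matches_analytic(self, quiet_photophysics):
        res = self._bright_result(quiet_photophysics, 1000, 101)
        motion = p.MotionModel(
            d_free=1.0, f_bound=0.0, sigma_loc=0.035, fov_um=500.0
        )
        ts = p.simulate_trajectories(motion, res, 10)
        stats = ts.jump_stats()
        msd = stats["sum_r2"].sum() / stats["n_jumps"].sum()
        expected = 4 * (1.0 * 0.00748 + 0.035**2)
        assert msd == pytest.approx(expected, rel=0.02)

    def test_dark_frames_produce_no_localizations(self, quiet_photophysics):
        res = self._bright_result(quiet_photophysics, 3, 20)
        res.states[1, 5:10] = DARK
        motion = p.MotionModel(d_free=0.5, f_bound=0.0)
        ts = p.simulate_trajectories(motion, res, 11)
        mol1 = ts.df[ts.df["molecule"] == 1]
        assert not set(range(5, 10)) & set(mol1["frame"])
        # the dark gap splits molecule 1 into two trajectories
        assert mol1["trajectory"].nunique() == 2

    def test_positions_stay_inside_fov(self, quiet_photophysics):
        res = self._bright_result(quiet_photophysics, 200, 100)
        motion = p.MotionModel(d_free=8.3, f_bound=0.0, fov_um=5.0, sigma_loc=0.0)
        ts = p.simulate_trajectories(motion, res, 12)
        assert ts.df["x_um"].between(0, 5).all()
        assert ts.df["y_um"].between(0, 5).all()


class TestRenderAndTrace:
    def test_zero_molecules_pure_background(self):
        cam = p.CameraModel(background_photons_per_pixel=5.0, n_pixels=40)
        empty = p.TrajectorySet(
            pd.DataFrame(columns=["trajectory", "frame", "x_um", "y_um"])
        )
        movie = p.render_movie(empty, cam, seed=13, n_frames=20)
        assert movie.shape == (20, 40, 40)
        assert movie.mean() == pytest.approx(5.0, rel=0.05)

    def test_single_molecule_centroid(self):
        cam = p.CameraModel(
            photons_per_bright_frame=2000.0,
            background_photons_per_pixel=0.0,
            n_pixels=32,
        )
        x_px, y_px = 15.4, 12.7
        df = pd.DataFrame(
            {
                "trajectory": np.zeros(50, int),
                "frame": np.arange(50),
                "x_um": np.full(50, x_px * cam.pixel_size_um),
                "y_um": np.full(50, y_px * cam.pixel_size_um),
            }
        )
        movie = p.render_movie(p.TrajectorySet(df), cam, seed=14, n_frames=50)
        mean_img = movie.mean(axis=0)
        yy, xx = np.mgrid[0:32, 0:32] + 0.5
        cx = (mean_img * xx).sum() / mean_img.sum()
        cy = (mean_img * yy).sum() / mean_img.sum()
        assert abs(cx - x_px) < 0.1 and abs(cy - y_px) < 0.1

    def test_zero_photons_is_pure_background(self):
        cam = p.CameraModel(
            photons_per_bright_frame=0.0, background_photons_per_pixel=3.0,
            n_pixels=24,
        )
        df = pd.DataFrame(
            {"trajectory": [0], "frame": [0], "x_um": [2.0], "y_um": [2.0]}
        )
        movie = p.render_movie(p.TrajectorySet(df), cam, seed=15, n_frames=1)
        assert movie.sum() == pytest.approx(3.0 * 24 * 24, rel=0.1)

    def test_intensity_trace_step_bookkeeping(self, quiet_photophysics):
        proto = p.parse_protocol("1 cycle of 30 R [2 ms], 1 V [7 ms], 30 R [2 ms]")
        model = p.PhotophysicsModel(
            p_shelve_per_ms_red=1e3, p_bleach_per_ms_red=0.0, shelvable_fraction=1.0,
            k_dr_per_ms_violet=1e3, k_papa_per_ms_green=0.0,
            k_papa_background_per_ms_green=0.0, p_spont_per_frame=0.0,
        )
        res = p.simulate_photophysics(model, _labeling(10_000), proto, 16)
        n_bright = res.n_bright()
        # expected step across the pulse equals photons * delta n_bright
        photons = 100.0
        trace = p.simulate_intensity_trace(res, photons, 0.0, 17)
        d_bright = n_bright[31] - n_bright[29]
        observed_step = trace.values[31] - trace.values[29]
        assert observed_step == pytest.approx(
            photons * d_bright, abs=4 * np.sqrt(photons * max(n_bright[31], 1))
        )
        # more bright emitters after a violet pulse
        assert n_bright[31] > n_bright[29]

    def test_constant_bright_count_gives_flat_trace(self, quiet_photophysics):
        proto = p.parse_protocol("1 cycle of 200 R [2 ms]")
        res = p.simulate_photophysics(quiet_photophysics, _labeling(1000), proto, 18)
        trace = p.simulate_intensity_trace(res, 100.0, 0.0, 19)
        expected = 1000 * 100.0
        assert trace.values.mean() == pytest.approx(expected, rel=0.01)
        assert trace.values.std() < 5 * np.sqrt(expected)

    def test_red_gating_blanks_unexcited_frames(self, quiet_photophysics):
        proto = p.parse_protocol("1 cycle of 5 R [2 ms], 5 off, 5 R [2 ms]")
        res = p.simulate_photophysics(quiet_photophysics, _labeling(100), proto, 20)
        trace = p.simulate_intensity_trace(res, 100.0, 0.0, 21)
        assert (trace.values[5:10] == 0).all()
        assert (trace.values[:5] > 0).all()


class TestFlimDecaySimulation:
    def test_mean_arrival_time_matches_tau(self):
        tau, width, nbins = 2.5, 0.05, 500
        decay = p.simulate_flim_decay(tau, 100_000, width, nbins, seed=22)
        t = decay.midpoints_ns
        mean_t = float((t * decay.counts).sum() / decay.counts.sum())
        # truncation correction for the finite record T
        T = width * nbins
        correction = T * np.exp(-T / tau) / (1 - np.exp(-T / tau))
        assert mean_t + correction == pytest.approx(tau, rel=0.01)

    def test_zero_photons_empty_histogram(self):
        decay = p.simulate_flim_decay(2.5, 0, 0.05, 100, seed=23)
        assert decay.total_photons == 0

    def test_same_seed_identical(self):
        a = p.simulate_flim_decay(3.0, 10_000, 0.05, 200, seed=24)
        b = p.simulate_flim_decay(3.0, 10_000, 0.05, 200, seed=24)
        assert np.array_equal(a.counts, b.counts)
        assert a.n_truncated == b.n_truncated
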