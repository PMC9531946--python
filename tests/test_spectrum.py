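import numpy as np
import pandas as pd
import pytest

import papa_spt as p
from papa_spt.spectrum import (
    DiffusionGrid,
    fit_reduced,
    fraction_bound,
    infer_spectrum,
    jump_loglik,
    local_maxima,
)


def _traj_with_jumps(r2_values):
    """One trajectory whose consecutive squared displacements are given."""
    x = np.concatenate([[0.0], np.cumsum(np.sqrt(r2_values))])
    return pd.DataFrame(
        {
            "trajectory": 0,
            "frame": np.arange(len(x)),
            "x_um": x,
            "y_um": 0.0,
        }
    )


def _d_for_b(b, sigma=0.0, dt_ms=7.48):
    """Diffusion coefficient whose jump-variance parameter equals b."""
    return (b / 4.0 - sigma**2) / (dt_ms / 1000.0)


class TestJumpLoglik:
    def test_zero_displacement_unit_b(self):
        df = _traj_with_jumps([0.0])
        assert jump_loglik(df, _d_for_b(1.0), sigma_loc=0.0) == pytest.approx(0.0)

    def test_unit_displacement_unit_b(self):
        df = _traj_with_jumps([1.0])
        assert jump_loglik(df, _d_for_b(1.0), sigma_loc=0.0) == pytest.approx(-1.0)

    def test_sum_over_jumps(self):
        df = _traj_with_jumps([1.0, 0.0, 2.0])
        assert jump_loglik(df, _d_for_b(1.0), sigma_loc=0.0) == pytest.approx(-3.0)

    def test_gap_jumps_excluded(self):
        df = _traj_with_jumps([1.0, 1.0])
        df.loc[2, "frame"] = 5  # second displacement now spans a gap
        assert jump_loglik(df, _d_for_b(1.0), sigma_loc=0.0) == pytest.approx(-1.0)

    def test_ml_grid_matches_moment_estimator(self):
        motion = p.MotionModel(d_free=2.0, f_bound=0.0)
        ts = p.simulate_two_state_trajectories(
            1500, motion, seed=30, mean_track_length=8.0
        )
        stats = ts.jump_stats()
        mean_r2 = stats["sum_r2"].sum() / stats["n_jumps"].sum()
        d_moment = (mean_r2 / 4 - motion.sigma_loc**2) / 0.00748
        dense = np.linspace(1.0, 3.0, 801)
        lls = [jump_loglik(ts.df, d, motion.sigma_loc) for d in dense]
        d_ml = dense[int(np.argmax(lls))]
        assert d_ml == pytest.approx(2.0, rel=0.05)
        assert d_ml == pytest.approx(d_moment, rel=0.01)


class TestInferSpectrum:
    def test_zero_iterations_returns_uniform_prior(self, bound_free_trajectories):
        spec = infer_spectrum(bound_free_trajectories, max_iter=0)
        assert np.allclose(spec.occupations, 1.0 / spec.grid.n_states)
        assert not spec.converged

    def test_single_state_recovery(self):
        grid = DiffusionGrid()
        d_true = 1.0
        motion = p.MotionModel(d_free=d_true, f_bound=0.0)
        ts = p.simulate_two_state_trajectories(
            1500, motion, seed=31, mean_track_length=8.0
        )
        spec = infer_spectrum(ts, grid)
        idx = int(np.argmin(np.abs(grid.d_values - d_true)))
        mass = spec.occupations[max(idx - 1, 0) : idx + 2].sum()
        assert mass >= 0.80

    def test_immobile_mass_lands_at_grid_minimum(self):
        motion = p.MotionModel(d_bound=0.0, f_bound=1.0, sigma_loc=0.035)
        ts = p.simulate_two_state_trajectories(
            1000, motion, seed=32, mean_track_length=8.0
        )
        spec = infer_spectrum(ts)
        # bulk of the mass in the lowest few states around the 0.01 anchor
        assert spec.occupations[:5].sum() >= 0.8
        assert np.argmax(spec.occupations) == 0

    def test_log_posterior_nondecreasing(self, bound_free_trajectories):
        _, history = infer_spectrum(
            bound_free_trajectories, max_iter=50, return_history=True
        )
        assert np.all(np.diff(history) >= -1e-7)

    def test_occupations_normalized_and_order_invariant(self, bound_free_trajectories):
        spec = infer_spectrum(bound_free_trajectories)
        assert spec.occupations.sum() == pytest.approx(1.0, abs=1e-9)
        assert (spec.occupations >= 0).all()
        shuffled = bound_free_trajectories.df.sample(
            frac=1.0, random_state=0
        ).reset_index(drop=True)
        spec2 = infer_spectrum(p.TrajectorySet(shuffled))
        assert np.allclose(spec.occupations, spec2.occupations, atol=1e-9)

    def test_duplication_invariance(self, bound_free_trajectories):
        spec = infer_spectrum(bound_free_trajectories)
        df = bound_free_trajectories.df
        dup = df.copy()
        dup["trajectory"] = dup["trajectory"] + df["trajectory"].max() + 1
        doubled = p.TrajectorySet(pd.concat([df, dup], ignore_index=True))
        spec2 = infer_spectrum(doubled)
        assert np.allclose(spec.occupations, spec2.occupations, atol=1e-6)

    def test_no_usable_jumps_raises(self):
        df = pd.DataFrame(
            {"trajectory": [0, 1], "frame": [0, 0], "x_um": [0, 1], "y_um": [0, 1]}
        )
        with pytest.raises(ValueError, match="displacement"):
            infer_spectrum(p.TrajectorySet(df))


class TestFitReduced:
    def test_two_state_recovery(self, bound_free_trajectories):
        fit = fit_reduced(bound_free_trajectories, (0.01, 8.3))
        assert fit.fraction_bound() == pytest.approx(0.70, abs=0.05)

    def test_all_free_boundary(self):
        motion = p.MotionModel(d_free=8.3, f_bound=0.0)
        ts = p.simulate_two_state_trajectories(
            800, motion, seed=33, mean_track_length=8.0
        )
        fit = fit_reduced(ts, (0.01, 8.3))
        assert fit.fraction_bound() <= 0.05

    def test_three_state_and_ar_sets_accepted(self, bound_free_trajectories):
        for states in ((0.01, 2.1, 13.2), (0.01, 1.3, 15.8), (0.01, 4.4)):
            fit = fit_reduced(bound_free_trajectories, states)
            assert fit.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fewer_than_two_states_rejected(self, bound_free_trajectories):
        with pytest.raises(ValueError, match="two states"):
            fit_reduced(bound_free_trajectories, (0.01,))


class TestFractionBound:
    def _spectrum_at(self, idx):
        grid = DiffusionGrid()
        occ = np.zeros(grid.n_states)
        occ[idx] = 1.0
        return p.DiffusionSpectrum(grid, occ, 1, 1)

    def test_all_mass_at_minimum(self):
        assert fraction_bound(self._spectrum_at(0)) == 1.0

    def test_all_mass_at_free_peak(self):
        grid = DiffusionGrid()
        idx = int(np.argmin(np.abs(grid.d_values - 8.3)))
        assert fraction_bound(self._spectrum_at(idx)) == 0.0

    def test_sixty_forty_mixture_recovery(self):
        motion = p.MotionModel(d_bound=0.01, d_free=8.3, f_bound=0.60)
        ts = p.simulate_two_state_trajectories(
            2000, motion, seed=34, mean_track_length=8.0
        )
        spec = infer_spectrum(ts)
        assert fraction_bound(spec) == pytest.approx(0.60, abs=0.05)

    def test_threshold_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="grid range"):
            fraction_bound(self._spectrum_at(0), threshold=1000.0)


class TestPeaks:
    def test_two_component_spectrum_has_bound_and_free_peaks(
        self, bound_free_trajectories
    ):
        grid = DiffusionGrid()
        spec = infer_spectrum(bound_free_trajectories, grid)
        peaks = local_maxima(spec, min_occupation=0.02)
        assert grid.d_values[0] in peaks
        free_idx = int(np.argmin(np.abs(grid.d_values - 8.3)))
        idxs = [int(np.argmin(np.abs(grid.d_values - d))) for d in peaks]
        assert any(abs(i - free_idx) <= 2 for i in idxs)
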