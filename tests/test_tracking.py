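import warnings

import numpy as np
import pandas as pd
import pytest

import papa_spt as p
from papa_spt.tracking import detect_spots, link, localize_movie
from papa_spt.trajectories import (
    TrajectorySet,
    read_trajectories,
    write_trajectories,
)


def _render_point(x_px, y_px, photons=2000.0, n_pixels=32, bg=2.0, seed=0):
    cam = p.CameraModel(
        photons_per_bright_frame=photons,
        background_photons_per_pixel=bg,
        n_pixels=n_pixels,
    )
    df = pd.DataFrame(
        {
            "trajectory": [0] * len(x_px),
            "frame": [0] * len(x_px),
            "x_um": np.asarray(x_px) * cam.pixel_size_um,
            "y_um": np.asarray(y_px) * cam.pixel_size_um,
        }
    )
    return p.render_movie(TrajectorySet(df), cam, seed=seed, n_frames=1)[0], cam


class TestDetection:
    def test_single_spot_subpixel_accuracy(self):
        img, _ = _render_point([10.3], [7.8], photons=3000.0)
        det = detect_spots(img.astype(float), psf_sigma_px=1.0, threshold_photons=200)
        assert len(det) == 1
        assert det["x_px"].iloc[0] == pytest.approx(10.3, abs=0.15)
        assert det["y_px"].iloc[0] == pytest.approx(7.8, abs=0.15)

    def test_blank_image_empty(self):
        det = detect_spots(np.zeros((32, 32)), threshold_photons=50)
        assert len(det) == 0

    def test_two_well_separated_spots(self):
        img, _ = _render_point([5.0, 25.0], [5.0, 25.0], photons=3000.0)
        det = detect_spots(img.astype(float), threshold_photons=200)
        assert len(det) == 2

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            detect_spots(np.zeros((3, 4, 5)))

    def test_recall_at_stated_snr(self, quiet_photophysics):
        # localization count should match bright-molecule count at
        # photons >= 300, background <= 10
        rng = np.random.default_rng(50)
        n = 12
        cam = p.CameraModel(
            photons_per_bright_frame=300.0,
            background_photons_per_pixel=10.0,
            n_pixels=64,
        )
        pts = rng.uniform(8, 56, size=(n, 2))
        df = pd.DataFrame(
            {
                "trajectory": np.arange(n),
                "frame": 0,
                "x_um": pts[:, 0] * cam.pixel_size_um,
                "y_um": pts[:, 1] * cam.pixel_size_um,
            }
        )
        movie = p.render_movie(TrajectorySet(df), cam, seed=51, n_frames=1)
        det = detect_spots(movie[0].astype(float), threshold_photons=120)
        matched = 0
        for x, y in pts:
            d = np.hypot(det["x_px"] - x, det["y_px"] - y)
            if len(d) and d.min() < 1.0:
                matched += 1
        assert matched / n >= 0.9


class TestLinking:
    def test_single_molecule_single_trajectory(self):
        locs = pd.DataFrame(
            {"frame": np.arange(20), "x_um": 1.0, "y_um": np.linspace(1, 2, 20)}
        )
        ts = link(locs, max_disp_um=0.5)
        assert ts.n_trajectories == 1
        assert ts.lengths().iloc[0] == 20

    def test_two_distant_molecules_no_swaps(self):
        rows = []
        for f in range(15):
            rows.append((f, 0.0, 0.0))
            rows.append((f, 5.0, 5.0))
        ts = link(pd.DataFrame(rows, columns=["frame", "x_um", "y_um"]), 1.0)
        assert ts.n_trajectories == 2
        for _, g in ts.df.groupby("trajectory"):
            assert g["x_um"].nunique() == 1  # no identity swaps

    def test_displacement_beyond_max_disp_starts_new_track(self):
        locs = pd.DataFrame(
            {"frame": [0, 1], "x_um": [0.0, 3.0], "y_um": [0.0, 0.0]}
        )
        assert link(locs, max_disp_um=1.5).n_trajectories == 2

    def test_gap_bridging(self):
        locs = pd.DataFrame(
            {"frame": [0, 1, 3], "x_um": [0.0, 0.1, 0.2], "y_um": 0.0}
        )
        assert link(locs, 1.0, max_gap_frames=0).n_trajectories == 2
        assert link(locs, 1.0, max_gap_frames=1).n_trajectories == 1

    def test_permutation_invariance(self):
        rng = np.random.default_rng(52)
        rows = []
        for f in range(10):
            for m in range(5):
                rows.append((f, m * 3.0 + rng.normal(0, 0.05), 2.0))
        locs = pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])
        a = link(locs, 1.0)
        b = link(locs.sample(frac=1.0, random_state=7), 1.0)
        key = lambda ts: sorted(
            tuple(sorted(zip(g["frame"], g["x_um"]))) for _, g in ts.df.groupby("trajectory")
        )
        assert key(a) == key(b)

    def test_linking_accuracy_on_rendered_movie(self, quiet_photophysics):
        # paper-like sparse density: >=90% of links correct vs ground truth
        proto = p.parse_protocol("1 cycle of 15 R [2 ms]")
        res = p.simulate_photophysics(
            quiet_photophysics,
            p.LabelingModel(n_molecules=10, fraction_double_labeled=0),
            proto,
            53,
        )
        motion = p.MotionModel(
            d_bound=0.01, d_free=2.0, f_bound=0.5, fov_um=9.6, sigma_loc=0.02
        )
        truth = p.simulate_trajectories(motion, res, 54)
        cam = p.CameraModel(
            photons_per_bright_frame=800.0,
            background_photons_per_pixel=3.0,
            n_pixels=60,
        )
        movie = p.render_movie(truth, cam, seed=55, n_frames=15)
        locs = localize_movie(
            movie.astype(float), cam.pixel_size_um, threshold_photons=200
        )
        linked = link(locs, max_disp_um=1.0)
        # evaluate: each linked localization inherits the nearest true
        # molecule; a link is correct if consecutive localizations in a
        # linked track belong to the same molecule
        correct = total = 0
        tdf = truth.df
        for _, g in linked.df.groupby("trajectory"):
            mols = []
            for _, row in g.iterrows():
                tf = tdf[tdf["frame"] == row["frame"]]
                d = np.hypot(tf["x_um"] - row["x_um"], tf["y_um"] - row["y_um"])
                mols.append(tf["molecule"].iloc[int(np.argmin(d.to_numpy()))])
            total += len(mols) - 1
            correct += sum(a == b for a, b in zip(mols, mols[1:]))
        assert total > 0
        assert correct / total >= 0.9


class TestTrajectoryIO:
    def test_roundtrip_preserves_everything(self, tmp_path, bound_free_trajectories):
        path = tmp_path / "traj.csv"
        write_trajectories(bound_free_trajectories, path)
        back = read_trajectories(path)
        pd.testing.assert_frame_equal(back.df, bound_free_trajectories.df)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("trajectory,frame,x_um,y_um\n")
        assert read_trajectories(path).n_trajectories == 0

    def test_unsorted_frames_sorted_with_warning(self, tmp_path):
        path = tmp_path / "unsorted.csv"
        path.write_text(
            "trajectory,frame,x_um,y_um\n0,2,1.0,1.0\n0,1,0.5,0.5\n0,3,1.5,1.5\n"
        )
        with pytest.warns(UserWarning, match="unsorted"):
            ts = read_trajectories(path)
        assert ts.df["frame"].tolist() == [1, 2, 3]

    def test_missing_columns_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("trajectory,frame,x_um\n0,0,1.0\n")
        with pytest.raises(ValueError, match="y_um"):
            read_trajectories(path)

    def test_unknown_columns_preserved(self, tmp_path):
        path = tmp_path / "extra.csv"
        path.write_text(
            "trajectory,frame,x_um,y_um,cell_id\n0,0,1.0,1.0,cell7\n"
        )
        ts = read_trajectories(path)
        assert ts.df["cell_id"].iloc[0] == "cell7"
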