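"""MSD, diffusion-coefficient and inter-distance analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdactin.synthetic_data import BrownianParams, simulate_monomer_trajectory
from crowdactin.trajectory_analysis import (
    MSDSeries,
    Trajectory,
    barbed_end_group,
    compute_inter_distance,
    compute_msd,
    convert_diffusion_units,
    estimate_diffusion,
)


def make_traj(coords, groups, names=None, dt=1.0):
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    return Trajectory(
        frame_times=np.arange(coords.shape[0]) * dt,
        coords=coords,
        group_ids=np.array(groups, dtype=object),
        atom_names=np.array(names or ["CA"] * n_atoms, dtype=object),
    )


class TestComputeMsd:
    def test_single_atom_hand_example(self):
        # one atom at (0,0,0),(1,0,0),(2,0,0) -> msd [0, 1, 4]
        traj = make_traj([[[0, 0, 0]], [[1, 0, 0]], [[2, 0, 0]]], ["G"])
        msd = compute_msd(traj, "G")
        assert np.allclose(msd.msd, [0.0, 1.0, 4.0])
        assert msd.n_atoms_averaged == 1

    def test_two_atom_average_hand_example(self):
        # static atom + moving atom -> the average halves the moving MSD
        coords = [
            [[0, 0, 0], [5, 5, 5]],
            [[1, 0, 0], [5, 5, 5]],
            [[2, 0, 0], [5, 5, 5]],
        ]
        traj = make_traj(coords, ["G", "G"])
        assert np.allclose(compute_msd(traj, "G").msd, [0.0, 0.5, 2.0])

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.normal(size=(5, 10, 3))
        traj = make_traj(coords, ["G"] * 10)
        msd = compute_msd(traj, "G").msd
        oracle = np.zeros(5)
        for f in range(5):
            acc = 0.0
            for a in range(10):
                d = coords[f, a] - coords[0, a]
                acc += d @ d
            oracle[f] = acc / 10
        assert np.allclose(msd, oracle, atol=1e-12)

    def test_coordinate_scaling_scales_msd_quadratically(self, rng):
        coords = rng.normal(size=(6, 4, 3))
        traj = make_traj(coords, ["G"] * 4)
        scaled = make_traj(3.0 * coords, ["G"] * 4)
        assert np.allclose(
            compute_msd(scaled, "G").msd, 9.0 * compute_msd(traj, "G").msd
        )

    def test_unknown_selection_lists_names(self):
        traj = make_traj([[[0, 0, 0]], [[1, 0, 0]]], ["G"])
        with pytest.raises(ValueError, match="XX"):
            compute_msd(traj, "XX")
        with pytest.raises(ValueError, match="empty"):
            compute_msd(traj, "  ")

    def test_atom_name_filter(self):
        coords = [[[0, 0, 0], [0, 0, 0]], [[1, 0, 0], [3, 0, 0]]]
        traj = make_traj(coords, ["G", "G"], names=["CA", "CB"])
        assert np.allclose(compute_msd(traj, "G:CA").msd, [0.0, 1.0])
        assert np.allclose(compute_msd(traj, "G").msd, [0.0, 5.0])

    def test_lag_averaged_on_linear_motion(self):
        # constant-velocity atom: lag-averaged msd(lag) = lag^2 exactly
        coords = np.zeros((6, 1, 3))
        coords[:, 0, 0] = np.arange(6)
        traj = make_traj(coords, ["G"])
        msd = compute_msd(traj, "G", lag_averaged=True, max_lag=3)
        assert np.allclose(msd.msd, [0.0, 1.0, 4.0, 9.0])


class TestEstimateDiffusion:
    def test_exact_linear_msd_both_methods(self):
        # msd = 6t in A^2/ns -> D = 1 A^2/ns = 10 um^2/s
        t = np.linspace(0, 5, 51)
        msd = MSDSeries(times=t, msd=6.0 * t, atom_selection="G", n_atoms_averaged=1)
        fit = estimate_diffusion(msd, method="linear-fit")
        assert fit.D == pytest.approx(10.0, rel=1e-12)
        assert fit.fit_r2 == pytest.approx(1.0)
        pw = estimate_diffusion(msd, method="pointwise")
        assert pw.D == pytest.approx(10.0, rel=1e-12)
        assert np.allclose(pw.per_time_D[1:], 10.0)

    def test_zero_msd_gives_zero_d(self):
        t = np.linspace(0, 5, 11)
        msd = MSDSeries(times=t, msd=np.zeros_like(t), atom_selection="G",
                        n_atoms_averaged=1)
        assert estimate_diffusion(msd).D == 0.0

    def test_negative_slope_clamped_with_flag(self):
        t = np.linspace(0, 5, 11)
        y = np.concatenate([[0.0], 10.0 - t[1:]])
        msd = MSDSeries(times=t, msd=y, atom_selection="G", n_atoms_averaged=1)
        est = estimate_diffusion(msd)
        assert est.D == 0.0 and est.clamped

    def test_crowded_vs_control_ratio(self):
        # diffusion speed-up of the polymer-crowded condition vs dilute buffer
        d_peg, d_control = 12.4, 5.36
        assert round(d_peg / d_control, 1) == 2.3

    def test_bad_windows_rejected(self):
        t = np.linspace(0, 5, 11)
        msd = MSDSeries(times=t, msd=6 * t, atom_selection="G", n_atoms_averaged=1)
        with pytest.raises(ValueError):
            estimate_diffusion(msd, fit_window=(0.0, 99.0))
        with pytest.raises(ValueError):
            estimate_diffusion(msd, fit_window=(4.9, 5.0))  # <3 points

    def test_median_recovery_on_drift_free_ensembles(self):
        # lag-averaged MSD fit: median fitted D across seeds within 10% of truth
        truth = 10.0  # um^2/s
        fits = []
        for seed in range(100):
            traj = simulate_monomer_trajectory(
                BrownianParams(diffusion_coefficient=truth, time_step=0.01,
                               n_steps=500, n_monomer_atoms=1, seed=seed)
            )
            msd = compute_msd(traj, "G", lag_averaged=True, max_lag=25)
            est = estimate_diffusion(msd, fit_window=(0.0, float(msd.times[-1])))
            fits.append(est.D)
        assert np.median(fits) == pytest.approx(truth, rel=0.10)


class TestUnitConversion:
    @pytest.mark.parametrize(
        "value,src,dst,expected",
        [
            (1.0, "A2/ns", "um2/s", 10.0),
            (0.536, "A2/ns", "um2/s", 5.36),
            (1.0, "nm2/us", "um2/s", 1.0),
            (10.0, "um2/s", "A2/ns", 1.0),
        ],
    )
    def test_known_conversions(self, value, src, dst, expected):
        assert convert_diffusion_units(value, src, dst) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_roundtrip_identity(self, value):
        out = value
        for src, dst in [("A2/ns", "um2/s"), ("um2/s", "nm2/us"), ("nm2/us", "A2/ns")]:
            out = convert_diffusion_units(out, src, dst)
        assert out == pytest.approx(value, rel=1e-12)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="furlong"):
            convert_diffusion_units(1.0, "furlong^2/fortnight", "um2/s")


class TestInterDistance:
    def test_static_trajectory_gives_zero(self, static_trajectory):
        series = compute_inter_distance(static_trajectory, None, "G")
        assert np.allclose(series.delta_L, 0.0)
        assert series.l0 > 0

    def test_rigid_translation_along_separation_axis(self):
        # monomer shifted +5 A along the separation axis at frame 1
        fil = np.zeros((2, 2, 3))
        fil[:, 1, 2] = 1.0  # centroid at z = 0.5
        mono = np.zeros((2, 1, 3))
        mono[0, 0, 2] = 10.0
        mono[1, 0, 2] = 15.0
        coords = np.concatenate([fil, mono], axis=1)
        traj = make_traj(coords, ["F1", "F1", "G"])
        series = compute_inter_distance(traj, "F1", "G")
        assert series.delta_L[1] == pytest.approx(5.0)
        assert series.l0 == pytest.approx(9.5)

    def test_translating_filament_is_symmetric(self):
        fil = np.zeros((2, 1, 3))
        mono = np.zeros((2, 1, 3))
        mono[:, 0, 2] = 10.0
        fil[1, 0, 2] = -5.0  # filament moves away instead
        traj = make_traj(np.concatenate([fil, mono], axis=1), ["F1", "G"])
        series = compute_inter_distance(traj, "F1", "G")
        assert abs(series.delta_L[1]) == pytest.approx(5.0)

    def test_scaling_coordinates_scales_delta_l_linearly(self, rng):
        coords = rng.normal(size=(4, 3, 3))
        coords[:, 2, :] += 20.0  # keep monomer well separated
        traj = make_traj(coords, ["F1", "F1", "G"])
        scaled = make_traj(2.0 * coords, ["F1", "F1", "G"])
        a = compute_inter_distance(traj, "F1", "G").delta_L
        b = compute_inter_distance(scaled, "F1", "G").delta_L
        assert np.allclose(b, 2.0 * a)

    def test_overlapping_selections_rejected(self):
        traj = make_traj(np.zeros((2, 2, 3)) + [[0, 0, 0], [9, 0, 0]], ["G", "G"])
        with pytest.raises(ValueError, match="overlap"):
            compute_inter_distance(traj, "G", "G")

    def test_barbed_end_defaults_to_nearest_terminal_subunit(self, static_trajectory):
        assert barbed_end_group(static_trajectory) == "F5"
        series = compute_inter_distance(static_trajectory, None, "G")
        assert series.filament_selection == "F5"
        # monomer sits 15 A beyond the F5 centroid along the axis
        assert series.l0 == pytest.approx(15.0, abs=0.5)
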