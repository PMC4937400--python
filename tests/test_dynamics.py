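"""Unwrapping, MSD/diffusion and radial distribution functions."""

import numpy as np
import pytest

from sugarglass.dynamics import (
    RDF,
    diffusion_coefficient,
    first_minimum,
    msd,
    rdf,
    select_atoms,
    unwrap,
)
from sugarglass.synthetic import (
    RandomWalkSpec,
    generate_ideal_gas,
    generate_random_walk,
)
from sugarglass.topology import AtomRecord, Topology
from sugarglass.trajio import Box, Frame, Trajectory


def traj_from_array(arr: np.ndarray, box: Box, dt: float = 1.0) -> Trajectory:
    return Trajectory(
        [Frame(arr[i], box, time=i * dt) for i in range(arr.shape[0])]
    )


class TestUnwrap:
    box = Box(10, 10, 10)

    def test_constant_drift_through_boundary(self):
        x = (np.arange(16.0) * 1.0) % 10.0
        arr = np.zeros((16, 1, 3))
        arr[:, 0, 0] = x
        unw = unwrap(traj_from_array(arr, self.box))
        assert np.allclose(unw.positions[:, 0, 0], np.arange(16.0))

    def test_static_identity(self):
        arr = np.tile(np.array([[1.0, 2.0, 3.0]]), (5, 1, 1))
        unw = unwrap(traj_from_array(arr, self.box))
        assert np.allclose(unw.positions, arr)

    def test_round_trip_with_generator(self):
        spec = RandomWalkSpec(
            n_atoms=50, d_target=2e-12, dt=1.0, n_frames=200,
            box=Box(30, 30, 30), seed=4,
        )
        res = generate_random_walk(spec)
        unw = unwrap(res.wrapped)
        # unwrapped trajectory matches the pre-wrap original up to a
        # constant image shift of the starting point (zero here)
        assert np.allclose(unw.positions, res.unwrapped.positions, atol=1e-9)

    def test_large_jump_rejected(self):
        arr = np.zeros((2, 1, 3))
        arr[1, 0, 0] = 5.0  # exactly half the box
        with pytest.raises(ValueError, match="spacing"):
            unwrap(traj_from_array(arr, self.box))


class TestMSD:
    def test_ballistic_quadratic(self):
        v = np.array([0.3, -0.2, 0.1])
        t = np.arange(40.0)
        arr = t[:, None, None] * v[None, None, :]
        series = msd(traj_from_array(arr, Box(100, 100, 100)), np.array([0]))
        for lag in (3, 7, 15):
            assert series.msd[lag] == pytest.approx(np.dot(v, v) * lag**2, rel=1e-9)

    def test_static_zero(self):
        arr = np.tile(np.array([[2.0, 2.0, 2.0]]), (30, 1, 1))
        series = msd(traj_from_array(arr, Box(10, 10, 10)), np.array([0]))
        assert np.allclose(series.msd, 0.0)

    def test_fft_equals_naive_all_origin_average(self):
        rng = np.random.default_rng(8)
        arr = np.cumsum(rng.normal(size=(60, 4, 3)), axis=0)
        series = msd(traj_from_array(arr, Box(1e6, 1e6, 1e6)), np.arange(4))
        T = arr.shape[0]
        for lag in (1, 5, 17, 29):
            disp = arr[lag:] - arr[:-lag]
            naive = (disp**2).sum(axis=2).mean()
            assert series.msd[lag] == pytest.approx(naive, rel=1e-10)

    def test_empty_selection_names_available(self):
        top = Topology(
            [AtomRecord(0, 0, "trehalose", "acceptor_oxygen", "O16", None)]
        )
        with pytest.raises(ValueError, match="O16"):
            select_atoms(top, "O99")

    def test_random_walk_msd_is_6dt(self):
        d = 7.5e-14  # m²/s
        spec = RandomWalkSpec(
            n_atoms=1000, d_target=d, dt=1.0, n_frames=400,
            box=Box(50, 50, 50), seed=9,
        )
        res = generate_random_walk(spec)
        series = msd(unwrap(res.wrapped), np.arange(1000))
        d_aps = d * 1e8
        lags = series.lag_times[1:80]  # tau <= 0.2 T
        expect = 6 * d_aps * lags
        assert np.allclose(series.msd[1:80], expect, rtol=0.05)


class TestDiffusion:
    def test_unit_conversion_on_exact_line(self):
        lags = np.arange(100.0)
        series_msd = 6.0 * lags
        from sugarglass.dynamics import MSDSeries

        est = diffusion_coefficient(
            MSDSeries(lag_times=lags, msd=series_msd, selection="x")
        )
        assert est.d == pytest.approx(1e-8)
        assert est.r2 == pytest.approx(1.0)

    def test_zero_msd_gives_zero_d(self):
        from sugarglass.dynamics import MSDSeries

        est = diffusion_coefficient(
            MSDSeries(lag_times=np.arange(50.0), msd=np.zeros(50), selection="x")
        )
        assert est.d == 0.0

    def test_window_too_narrow_is_error(self):
        from sugarglass.dynamics import MSDSeries

        s = MSDSeries(lag_times=np.arange(3.0), msd=np.array([0.0, 6.0, 12.0]), selection="x")
        with pytest.raises(ValueError, match="window|points"):
            diffusion_coefficient(s, window=(0.9, 0.95))

    def test_translation_invariance(self):
        spec = RandomWalkSpec(
            n_atoms=100, d_target=5e-13, dt=1.0, n_frames=300,
            box=Box(40, 40, 40), seed=2,
        )
        res = generate_random_walk(spec)
        unw = unwrap(res.wrapped)
        est1 = diffusion_coefficient(msd(unw, np.arange(100)))
        shifted = traj_from_array(unw.positions + 13.7, Box(40, 40, 40))
        est2 = diffusion_coefficient(msd(shifted, np.arange(100)))
        assert est2.d == pytest.approx(est1.d, rel=1e-12)

    def test_planted_d_recovery(self):
        d = 7.5e-14
        spec = RandomWalkSpec(
            n_atoms=1000, d_target=d, dt=1.0, n_frames=2000,
            box=Box(50, 50, 50), seed=0,
        )
        res = generate_random_walk(spec)
        est = diffusion_coefficient(msd(unwrap(res.wrapped), np.arange(1000)))
        assert est.d == pytest.approx(d, rel=0.05)


class TestRDF:
    def test_ideal_gas_is_flat(self):
        frames = [generate_ideal_gas(5000, Box(40, 40, 40), seed=s) for s in range(4)]
        idx = np.arange(5000)
        curve = rdf(frames, idx, idx, r_max=10.0, bin_width=0.1)
        sel = curve.r_centers >= 2.0
        assert np.max(np.abs(curve.g[sel] - 1.0)) <= 0.05

    def test_fixed_pair_single_bin(self):
        frame = Frame(np.array([[1.0, 1, 1], [3.75, 1, 1]]), Box(20, 20, 20))
        curve = rdf([frame], np.array([0]), np.array([1]), r_max=5.0, bin_width=0.1)
        nz = np.flatnonzero(curve.g)
        assert len(nz) == 1
        assert curve.r_centers[nz[0]] == pytest.approx(2.75)

    def test_bin_width_conserves_integral(self):
        frames = [generate_ideal_gas(2000, Box(30, 30, 30), seed=s) for s in (5, 6)]
        idx = np.arange(2000)
        rho = 2000 / 30**3
        totals = []
        for bw in (0.05, 0.1):
            curve = rdf(frames, idx, idx, r_max=9.0, bin_width=bw)
            shell = 4 * np.pi * curve.r_centers**2 * bw
            totals.append(np.sum(curve.g * shell * rho))
        assert totals[0] == pytest.approx(totals[1], rel=1e-6)

    def test_r_max_beyond_half_box_rejected(self):
        frame = generate_ideal_gas(10, Box(20, 20, 20), seed=0)
        with pytest.raises(ValueError, match="half"):
            rdf([frame], np.arange(10), np.arange(10), r_max=11.0)


class TestFirstMinimum:
    @staticmethod
    def curve(g, r=None):
        r = np.arange(len(g)) * 0.1 if r is None else r
        return RDF(r_centers=r, g=np.asarray(g, float), pair_spec=("a", "b"),
                   bin_width=0.1, r_max=float(r[-1]))

    def test_peak_then_trough(self):
        r = np.arange(0.0, 6.0, 0.1)
        g = 1 + 1.5 * np.exp(-((r - 2.8) ** 2) / 0.1) - 0.6 * np.exp(-((r - 3.5) ** 2) / 0.02)
        assert first_minimum(self.curve(g, r)) == pytest.approx(3.5, abs=0.1)

    def test_monotone_is_error(self):
        with pytest.raises(ValueError, match="monotone|minimum"):
            first_minimum(self.curve(np.linspace(0, 2, 30)), smooth=False)

    def test_first_trough_not_global_minimum(self):
        r = np.arange(0.0, 8.0, 0.1)
        g = (
            1
            + 2.0 * np.exp(-((r - 2.8) ** 2) / 0.05)
            + 1.0 * np.exp(-((r - 5.0) ** 2) / 0.05)
            - 0.9 * np.exp(-((r - 6.5) ** 2) / 0.05)
        )
        # troughs near 3.9 (shallow) and 6.5 (deep): the first one wins
        got = first_minimum(self.curve(g, r))
        assert got < 5.0
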