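"""Reweighting identities, FES projection, block errors, basins, ΔG."""

import numpy as np
import pandas as pd
import pytest

from lvmetad.constants import kt
from lvmetad.errors import ParameterError, RegionError, ResolutionError, SchemaError
from lvmetad.io import ColvarTable
from lvmetad.reweight_fes import (
    CVGrid,
    FES2D,
    block_error,
    classify_by_ranges,
    compute_ct,
    delta_g,
    find_basins,
    frame_weights,
    grid_from_hills,
    project_fes,
)

KT = kt(298.0)
BETA = 1.0 / KT


def _hills_df(times, centers, heights, sigma=0.3, gamma=10.0):
    n = len(times)
    return pd.DataFrame(
        {
            "time": times,
            "rho": centers,
            "tau": np.zeros(n),
            "theta": np.zeros(n),
            "sigma_rho": np.full(n, sigma),
            "sigma_tau": np.full(n, 0.04),
            "sigma_theta": np.full(n, np.pi / 8),
            "height": heights,
            "biasf": np.full(n, gamma),
        }
    )


def _colvar(time, rho, bias, **extra):
    df = pd.DataFrame({"time": time, "rho": rho, "bias": bias})
    for k, v in extra.items():
        df[k] = v
    return ColvarTable(data=df)


class TestComputeCt:
    def test_zero_bias_gives_zero_offset(self):
        hills = _hills_df([1.0], [0.0], [0.5])
        grid = CVGrid(centers=(np.linspace(-3, 3, 200),), dims=(0,), periodic=(False,))
        state = compute_ct(hills, grid, gamma=10.0, beta=BETA, eval_times=np.array([0.5, 1.0]))
        # both requested times precede or coincide with the first hill: V = 0
        np.testing.assert_allclose(state.ct, 0.0, atol=1e-12)

    def test_constant_bias_returns_the_constant(self):
        # a hill far wider than the grid is constant over it to machine precision
        c0 = 0.8
        hills = _hills_df([1.0], [0.0], [c0], sigma=1e6)
        grid = CVGrid(centers=(np.linspace(-0.01, 0.01, 50),), dims=(0,), periodic=(False,))
        state = compute_ct(hills, grid, gamma=10.0, beta=BETA, eval_times=np.array([2.0]))
        assert state.ct[0] == pytest.approx(c0, rel=1e-9)

    def test_offset_is_nondecreasing_for_positive_hills(self):
        rng = np.random.default_rng(0)
        n = 60
        hills = _hills_df(np.arange(1.0, n + 1), rng.uniform(-2, 2, n), np.full(n, 0.2))
        grid = grid_from_hills(hills, dims=(0,))
        state = compute_ct(hills, grid, gamma=10.0, beta=BETA)
        assert np.all(np.diff(state.ct) >= -1e-10)

    def test_grid_refinement_stability(self):
        rng = np.random.default_rng(1)
        n = 40
        hills = _hills_df(np.arange(1.0, n + 1), rng.uniform(-2, 2, n), np.full(n, 0.15))
        coarse = grid_from_hills(hills, dims=(0,), cells_per_sigma=4)
        fine = grid_from_hills(hills, dims=(0,), cells_per_sigma=8)
        ct_c = compute_ct(hills, coarse, gamma=10.0, beta=BETA).ct
        ct_f = compute_ct(hills, fine, gamma=10.0, beta=BETA).ct
        assert np.max(np.abs(ct_c - ct_f)) < 0.01

    def test_too_coarse_grid_rejected(self):
        hills = _hills_df([1.0], [0.0], [0.5], sigma=0.1)
        grid = CVGrid(centers=(np.linspace(-3, 3, 20),), dims=(0,), periodic=(False,))
        with pytest.raises(ResolutionError):
            compute_ct(hills, grid, gamma=10.0, beta=BETA)

    def test_nearest_preceding_interpolation(self):
        hills = _hills_df([1.0, 2.0], [0.0, 0.0], [0.5, 0.4])
        grid = grid_from_hills(hills, dims=(0,))
        state = compute_ct(hills, grid, gamma=10.0, beta=BETA, eval_times=np.array([1.0, 2.0]))
        at = state.at(np.array([0.5, 1.5, 10.0]))
        assert at[0] == 0.0
        assert at[1] == state.ct[0]
        assert at[2] == state.ct[1]


class TestFrameWeights:
    def test_zero_bias_gives_uniform_weights(self):
        colvar = _colvar(np.arange(10.0), np.zeros(10), np.zeros(10))
        hills = _hills_df([1.0], [50.0], [1e-30])
        grid = CVGrid(centers=(np.linspace(-1, 1, 40),), dims=(0,), periodic=(False,))
        state = compute_ct(hills, grid, gamma=10.0, beta=BETA)
        w = frame_weights(colvar, state, BETA, t_start=0.0)
        np.testing.assert_allclose(w, 0.1, rtol=1e-9)

    def test_constant_shift_gives_uniform_weights(self):
        # all frames share V - c: normalization removes it
        colvar = _colvar(np.arange(5.0), np.zeros(5), np.full(5, 3.0))
        state = compute_ct(
            _hills_df([0.5], [0.0], [1e-30]),
            CVGrid(centers=(np.linspace(-1, 1, 40),), dims=(0,), periodic=(False,)),
            gamma=10.0, beta=BETA,
        )
        w = frame_weights(colvar, state, BETA, t_start=0.0)
        np.testing.assert_allclose(w, 0.2, rtol=1e-9)

    def test_window_start_zeroes_early_frames(self):
        colvar = _colvar(np.arange(10.0), np.zeros(10), np.zeros(10))
        state = compute_ct(
            _hills_df([0.5], [0.0], [1e-30]),
            CVGrid(centers=(np.linspace(-1, 1, 40),), dims=(0,), periodic=(False,)),
            gamma=10.0, beta=BETA,
        )
        w = frame_weights(colvar, state, BETA, t_start=5.0)
        assert np.all(w[:5] == 0)
        np.testing.assert_allclose(w[5:], 0.2, rtol=1e-9)

    def test_missing_bias_column_is_schema_error(self):
        df = pd.DataFrame({"time": [0.0, 1.0], "rho": [0.0, 0.1]})
        colvar = ColvarTable(data=df)
        state = compute_ct(
            _hills_df([0.5], [0.0], [1e-30]),
            CVGrid(centers=(np.linspace(-1, 1, 40),), dims=(0,), periodic=(False,)),
            gamma=10.0, beta=BETA,
        )
        with pytest.raises(SchemaError):
            frame_weights(colvar, state, BETA, t_start=0.0)


class TestProjectFes:
    def test_single_frame_single_cell(self):
        colvar = _colvar([0.0], [0.5], [0.0], d=[0.25], nhb=[1.5])
        fes = project_fes(colvar, np.array([1.0]), "d", "nhb",
                          np.linspace(0, 1, 5), np.linspace(0, 4, 5), kT=KT)
        assert np.nansum(fes.F == 0.0) == 1
        assert fes.sampled.sum() == 1

    def test_unbiased_fes_equals_log_histogram(self, rng):
        n = 4000
        d = rng.uniform(0, 1, n)
        nhb = rng.uniform(0, 4, n)
        colvar = _colvar(np.arange(float(n)), np.zeros(n), np.zeros(n), d=d, nhb=nhb)
        w = np.full(n, 1.0 / n)
        xe, ye = np.linspace(0, 1, 9), np.linspace(0, 4, 7)
        fes = project_fes(colvar, w, "d", "nhb", xe, ye, kT=KT)
        H, _, _ = np.histogram2d(d, nhb, bins=(xe, ye))
        ref = -KT * np.log(H / n)
        ref -= np.nanmin(ref)
        np.testing.assert_allclose(fes.F[fes.sampled], ref[fes.sampled], rtol=1e-12)

    def test_marginalizing_2d_recovers_1d(self, rng):
        n = 3000
        d = rng.uniform(0, 1, n)
        nhb = rng.uniform(0, 4, n)
        w = rng.uniform(0, 1, n)
        w /= w.sum()
        colvar = _colvar(np.arange(float(n)), np.zeros(n), np.zeros(n), d=d, nhb=nhb)
        xe, ye = np.linspace(0, 1, 11), np.linspace(0, 4, 9)
        fes = project_fes(colvar, w, "d", "nhb", xe, ye, kT=KT)
        # marginal over N in probability space
        P = np.where(fes.sampled, np.exp(-fes.F / KT), 0.0)
        marg = -KT * np.log(P.sum(axis=1))
        direct, _ = np.histogram(d, bins=xe, weights=w)
        direct = -KT * np.log(direct)
        np.testing.assert_allclose(marg - marg.min(), direct - direct.min(), atol=1e-10)

    def test_region_free_energy_stable_under_grid_refinement(self, rng):
        """ΔF between two windows changes < 0.1 kT when bins are doubled."""
        n = 20000
        d = np.concatenate([rng.normal(0.3, 0.05, n // 2), rng.normal(0.7, 0.08, n // 2)])
        d = np.clip(d, 0.0, 1.0)
        nhb = rng.uniform(0, 2, n)
        w = rng.uniform(0.5, 1.5, n)
        w /= w.sum()
        colvar = _colvar(np.arange(float(n)), np.zeros(n), np.zeros(n), d=d, nhb=nhb)

        def region_df(nx):
            fes = project_fes(colvar, w, "d", "nhb",
                              np.linspace(0, 1, nx + 1), np.linspace(0, 2, 5), kT=KT)
            P = np.where(fes.sampled, np.exp(-fes.F / KT), 0.0)
            xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
            left = P[xc < 0.5].sum()
            right = P[xc >= 0.5].sum()
            return -KT * np.log(left / right)

        assert abs(region_df(20) - region_df(40)) < 0.1 * KT

    def test_all_zero_weights_rejected(self):
        colvar = _colvar([0.0], [0.5], [0.0], d=[0.25], nhb=[1.5])
        with pytest.raises(RegionError):
            project_fes(colvar, np.array([0.0]), "d", "nhb",
                        np.linspace(0, 1, 5), np.linspace(0, 4, 5), kT=KT)


class TestBlockError:
    def test_identical_blocks_have_zero_error(self):
        # the same ten frames repeated in each of 5 blocks
        base_d = np.tile(np.array([0.1, 0.3, 0.3, 0.7, 0.7, 0.7, 0.9, 0.9, 0.1, 0.3]), 5)
        n = len(base_d)
        colvar = _colvar(np.arange(float(n)), np.zeros(n), np.zeros(n),
                         d=base_d, nhb=np.ones(n))
        w = np.full(n, 1.0 / n)
        err = block_error(colvar, w, "d", "nhb",
                          (np.linspace(0, 1, 6), np.linspace(0, 2, 3)), n_blocks=5, kT=KT)
        assert np.nanmax(err) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_standard_error(self):
        # two equal-mass blocks whose single-cell probabilities differ:
        # err must be |F1 - F2| / 2 in every doubly-sampled cell
        d = np.array([0.1, 0.1, 0.9, 0.9, 0.1, 0.9, 0.9, 0.9])
        n = len(d)
        colvar = _colvar(np.arange(float(n)), np.zeros(n), np.zeros(n), d=d, nhb=np.ones(n))
        w = np.full(n, 1.0 / n)
        edges = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 2.0]))
        err = block_error(colvar, w, "d", "nhb", edges, n_blocks=2, kT=KT)
        f1 = -KT * np.log(np.array([0.5, 0.5]))
        f2 = -KT * np.log(np.array([0.25, 0.75]))
        np.testing.assert_allclose(err[:, 0], np.abs(f1 - f2) / 2, rtol=1e-9)

    def test_error_plateaus_with_block_count(self):
        """Blocks longer than the correlation time: err(5) ≈ err(10)."""
        from lvmetad.fixtures import TEMPERATURE, double_well_system
        from lvmetad.toy_systems import LangevinParams, run_langevin

        pot = double_well_system()
        lang = LangevinParams(timestep=0.004, friction=1.0, temperature=TEMPERATURE,
                              mass=40.0, seed=5, n_steps=400_000)
        xs = run_langevin(pot, lang, start=[-2.0], sample_stride=100)[:, 0]
        n = len(xs)
        df = pd.DataFrame({"time": np.arange(float(n)), "rho": xs,
                           "bias": np.zeros(n), "nhb": np.zeros(n)})
        colvar = ColvarTable(data=df)
        w = np.full(n, 1.0 / n)
        edges = (np.linspace(-3.0, 0.0, 7), np.array([-0.5, 0.5]))  # the well it starts in
        means = {}
        for nb in (5, 10):
            err = block_error(colvar, w, "rho", "nhb", edges, n_blocks=nb, kT=KT)
            means[nb] = np.nanmean(err)
        assert abs(means[10] - means[5]) / means[5] < 0.2

    def test_requires_at_least_two_blocks(self):
        colvar = _colvar(np.arange(4.0), np.zeros(4), np.zeros(4), d=np.ones(4), nhb=np.ones(4))
        with pytest.raises(ParameterError):
            block_error(colvar, np.full(4, 0.25), "d", "nhb",
                        (np.linspace(0, 2, 3), np.linspace(0, 2, 3)), n_blocks=1, kT=KT)


def _grid_fes(F):
    F = np.asarray(F, dtype=float)
    nx, ny = F.shape
    return FES2D(
        x_edges=np.linspace(0, 1, nx + 1),
        y_edges=np.linspace(0, 1, ny + 1),
        F=F - np.nanmin(F),
        err=np.zeros_like(F),
        kT=KT,
        n_eff=np.ones_like(F),
        sampled=np.isfinite(F),
    )


class TestFindBasins:
    def test_single_well_single_basin(self):
        x = np.linspace(-1, 1, 12)
        F = np.add.outer(x**2, x**2)
        basins = find_basins(_grid_fes(F), depth_cutoff=2.0)
        assert len(basins.basins) == 1
        assert (basins.assignment >= 0).all()

    def test_two_separated_wells(self):
        x = np.linspace(0, 1, 24)
        X, Y = np.meshgrid(x, x, indexing="ij")
        F = 5.0 - 4.0 * np.exp(-((X - 0.25) ** 2 + (Y - 0.5) ** 2) / 0.01) \
                - 3.5 * np.exp(-((X - 0.75) ** 2 + (Y - 0.5) ** 2) / 0.01)
        basins = find_basins(_grid_fes(F), depth_cutoff=2.0)
        assert len(basins.basins) == 2
        # deepest basin is labelled 0 and holds the global minimum cell
        gm = np.unravel_index(np.argmin(F), F.shape)
        assert basins.assignment[gm] == 0

    def test_shallow_ripple_merged_by_prominence(self):
        x = np.linspace(0, 2 * np.pi, 80)
        F = np.add.outer(np.zeros(4), 0.2 * (x - np.pi) ** 2 + 0.06 * np.sin(9 * x))
        noisy = find_basins(_grid_fes(F), depth_cutoff=1.5)
        assert len(noisy.basins) > 1  # shallow ripples fragment the well
        merged = find_basins(_grid_fes(F), depth_cutoff=1.5, min_prominence=0.2)
        assert len(merged.basins) == 1

    def test_published_window_classification(self):
        """A frame at (0.85 nm, N=7) falls in the deepest-basin window 0.77-0.95 nm, 5-9."""
        ranges = {
            "I": ((0.77, 0.95), (5.0, 9.0)),
            "II": ((1.1, 1.4), (5.2, 6.7)),
            "III": ((1.5, 1.8), (2.3, 3.5)),
        }
        assert classify_by_ranges(0.85, 7.0, ranges) == "I"
        assert classify_by_ranges(1.25, 6.0, ranges) == "II"
        assert classify_by_ranges(0.5, 1.0, ranges) is None


class TestDeltaG:
    def _uniform_colvar(self, rng, n=6000):
        d = rng.uniform(0.0, 1.0, n)
        return _colvar(np.arange(float(n)), np.zeros(n), np.zeros(n), d=d), np.full(n, 1.0 / n)

    def test_flat_distribution_equal_regions(self, rng):
        colvar, w = self._uniform_colvar(rng)
        dg, err = delta_g(w, colvar, {"d": (0.0, 0.4)}, {"d": (0.6, 1.0)}, kT=KT)
        assert abs(dg) < 3 * err

    def test_swapping_regions_flips_sign(self, rng):
        colvar, w = self._uniform_colvar(rng)
        a, b = {"d": (0.0, 0.3)}, {"d": (0.5, 1.0)}
        fwd, _ = delta_g(w, colvar, a, b, kT=KT)
        rev, _ = delta_g(w, colvar, b, a, kT=KT)
        assert fwd == pytest.approx(-rev, rel=1e-12)

    def test_zero_weight_region_is_error(self, rng):
        colvar, w = self._uniform_colvar(rng)
        with pytest.raises(RegionError):
            delta_g(w, colvar, {"d": (2.0, 3.0)}, {"d": (0.5, 1.0)}, kT=KT)

    def test_overlapping_regions_rejected(self, rng):
        colvar, w = self._uniform_colvar(rng)
        with pytest.raises(RegionError):
            delta_g(w, colvar, {"d": (0.0, 0.6)}, {"d": (0.5, 1.0)}, kT=KT)

    def test_standard_state_correction_shifts_by_volume_ratio(self, rng):
        colvar, w = self._uniform_colvar(rng)
        a, b = {"d": (0.0, 0.3)}, {"d": (0.5, 1.0)}
        plain, _ = delta_g(w, colvar, a, b, kT=KT)
        corrected, _ = delta_g(w, colvar, a, b, kT=KT,
                               standard_volume=1660.0, unbound_volume=3320.0)
        assert corrected - plain == pytest.approx(-KT * np.log(2.0), rel=1e-9)

    def test_volume_correction_requires_unbound_volume(self, rng):
        colvar, w = self._uniform_colvar(rng)
        with pytest.raises(ParameterError):
            delta_g(w, colvar, {"d": (0.0, 0.3)}, {"d": (0.5, 1.0)}, kT=KT,
                    standard_volume=1660.0)
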