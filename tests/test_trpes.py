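"""TRPES assembly, time convolution, energy integration, decomposition."""

import numpy as np
import pytest

from dysonspec import (
    ChannelSeries,
    TrajectoryRecord,
    TRPESGrid,
    assemble_trpes,
    broaden,
    convolve_time,
    decompose,
    integrate_energy,
    step_channel_intensities,
)
from dysonspec.kinetics import emg
from dysonspec.spectra import FWHM_TO_SIGMA
from dysonspec.trpes import (
    StrideError,
    load_ensemble,
    save_ensemble,
)


def _record(
    traj_id="t0",
    tautomer="enol",
    pathway="OOP",
    n_steps=11,
    dt=5.0,
    weights=None,
    v_states=None,
    channels=None,
    t0=0.0,
):
    times = t0 + dt * np.arange(n_steps)
    v_states = v_states or {"A": 4.0, "B": 4.4}
    if weights is None:
        weights = {"A": np.ones(n_steps), "B": np.zeros(n_steps)}
    energies = {s: np.full(n_steps, v) for s, v in v_states.items()}
    if channels is None:
        channels = [("A", "D0", 8.0, 0.7), ("B", "D0", 8.0, 0.5)]
    series = [
        ChannelSeries(src, ion, np.full(n_steps, vi), np.full(n_steps, nm))
        for src, ion, vi, nm in channels
    ]
    return TrajectoryRecord(traj_id, tautomer, pathway, times, weights, energies, series)


class TestStepChannelIntensities:
    def test_closed_channel_empty(self):
        rec = _record(weights={"A": np.ones(5), "B": np.zeros(5)},
                      v_states={"A": 1.0, "B": 4.4}, n_steps=5)
        # binding energy 8.0 - 1.0 = 7.0 eV > 5.4 eV probe
        assert step_channel_intensities(rec, 0, 5.4) == []

    def test_bare_norm_mode_arithmetic(self):
        rec = _record(n_steps=5, v_states={"A": 4.0, "B": 4.4})
        out = step_channel_intensities(rec, 0, 5.4, mode="norm")
        assert out == [pytest.approx((1.4, 0.7, "A"))]

    def test_weighted_sum_oracle(self):
        w = {"A": np.full(5, 0.6), "B": np.full(5, 0.4)}
        rec = _record(weights=w, n_steps=5)
        out = step_channel_intensities(rec, 2, 5.4, mode="W")
        expected = {
            "A": (5.4 - 4.0, 0.6 * 4.0 * 0.7),
            "B": (5.4 - 3.6, 0.4 * 3.6 * 0.5),
        }
        assert len(out) == 2
        for ekin, intensity, state in out:
            want_ekin, want_i = expected[state]
            assert ekin == pytest.approx(want_ekin)
            assert intensity == pytest.approx(want_i)

    def test_open_channel_set_monotone_in_probe(self):
        rec = _record(n_steps=5, v_states={"A": 1.0, "B": 3.0})
        opened = [
            {s for _, _, s in step_channel_intensities(rec, 0, hw)}
            for hw in (4.0, 5.4, 7.5)
        ]
        assert opened[0] <= opened[1] <= opened[2]


class TestAssembleTRPES:
    def test_constant_trajectory_matches_broadened_sticks(self):
        rec = _record(n_steps=6)
        grid = assemble_trpes([rec], 5.4, kinetic_grid=(0.0, 3.0, 0.01),
                              energy_fwhm=0.2)
        sticks = [(e, i) for e, i, _ in step_channel_intensities(rec, 0, 5.4)]
        ref = broaden(sticks, (0.0, 3.0, 0.01), 0.2, axis_kind="kinetic")
        for row in grid.intensity:
            np.testing.assert_allclose(row, ref.intensity, atol=1e-12)

    def test_slices_sum_to_total(self, small_ensemble):
        grid = assemble_trpes(small_ensemble, 5.4, kinetic_grid=(0.0, 3.0, 0.05))
        total = sum(grid.slices.values())
        np.testing.assert_allclose(total, grid.intensity, atol=1e-10)

    def test_union_equals_weighted_subset_assemblies(self, small_ensemble):
        """Linearity: pathway slices of the union match sub-ensemble
        assemblies scaled by the subset fraction."""
        kw = dict(probe_energy=5.4, kinetic_grid=(0.0, 3.0, 0.05), energy_fwhm=0.2)
        union = assemble_trpes(small_ensemble, **kw)
        by_path = decompose(union, "pathway")
        n = len(small_ensemble)
        for label in {r.pathway for r in small_ensemble}:
            subset = [r for r in small_ensemble if r.pathway == label]
            sub = assemble_trpes(subset, **kw)
            np.testing.assert_allclose(
                by_path[label], (len(subset) / n) * sub.intensity, atol=1e-10
            )

    def test_mixed_strides_refused(self):
        a = _record(traj_id="a", dt=5.0)
        b = _record(traj_id="b", dt=2.0)
        with pytest.raises(StrideError):
            assemble_trpes([a, b], 5.4)

    def test_unequal_lengths_contributing_normalization(self):
        """A shorter trajectory contributes only to bins it covers; bins
        beyond its end are normalised by the count still contributing."""
        long = _record(traj_id="long", n_steps=11)
        short = _record(traj_id="short", n_steps=5)
        grid = assemble_trpes([long, short], 5.4, kinetic_grid=(0.0, 3.0, 0.05))
        solo = assemble_trpes([long], 5.4, kinetic_grid=(0.0, 3.0, 0.05))
        # identical constant records: averaging is idempotent where both
        # contribute, and the tail falls back to the long trajectory alone
        np.testing.assert_allclose(grid.intensity, solo.intensity, atol=1e-12)

    def test_tautomer_weights_applied(self):
        keto = _record(traj_id="k", tautomer="keto")
        enol = _record(traj_id="e", tautomer="enol")
        grid = assemble_trpes([keto, enol], 5.4, kinetic_grid=(0.0, 3.0, 0.05))
        by_taut = decompose(grid, "tautomer")
        ratio = by_taut["keto"].sum() / by_taut["enol"].sum()
        assert ratio == pytest.approx(35 / 65, rel=1e-10)


class TestConvolveTime:
    def _impulse_grid(self, n_t=201, dt=5.0):
        times = dt * np.arange(n_t)
        energies = np.array([1.0, 2.0])
        intensity = np.zeros((n_t, 2))
        intensity[n_t // 2, :] = 1.0
        return TRPESGrid(times, energies, intensity,
                         {("enol", "A", "OOP"): intensity.copy()})

    def test_impulse_becomes_gaussian_of_stated_fwhm(self):
        out = convolve_time(self._impulse_grid(), fwhm=160.0)
        profile = out.intensity[:, 0]
        above = out.times[profile >= profile.max() / 2]
        assert above[-1] - above[0] == pytest.approx(160.0, abs=5.0)

    def test_constant_signal_unchanged_in_interior(self):
        n_t = 301
        times = 5.0 * np.arange(n_t)
        intensity = np.ones((n_t, 1))
        grid = TRPESGrid(times, np.array([1.0]), intensity,
                         {("enol", "A", "OOP"): intensity.copy()})
        out = convolve_time(grid, fwhm=160.0)
        sigma_steps = int(np.ceil(5 * 160.0 * FWHM_TO_SIGMA / 5.0))
        interior = out.intensity[sigma_steps:-1, 0]
        np.testing.assert_allclose(interior, 1.0, atol=1e-8)

    def test_conserves_time_integral_for_interior_signal(self):
        n_t = 401
        times = 5.0 * np.arange(n_t)
        intensity = np.zeros((n_t, 1))
        intensity[150:250, 0] = np.hanning(100)
        grid = TRPESGrid(times, np.array([1.0]), intensity,
                         {("enol", "A", "OOP"): intensity.copy()})
        out = convolve_time(grid, fwhm=160.0)
        assert out.intensity.sum() == pytest.approx(intensity.sum(), rel=1e-6)

    def test_exponential_matches_closed_form_emg(self):
        """Gaussian (x) exponential equals the analytic exponentially
        modified Gaussian away from the trailing edge."""
        dt, tau, fwhm = 2.0, 400.0, 160.0
        n_t = 1001
        times = dt * np.arange(n_t)
        signal = np.exp(-times / tau)
        intensity = signal[:, None]
        grid = TRPESGrid(times, np.array([1.0]), intensity,
                         {("enol", "A", "OOP"): intensity.copy()})
        out = convolve_time(grid, fwhm=fwhm)
        sigma = fwhm * FWHM_TO_SIGMA
        expected = emg(times, 1.0, tau, sigma)
        # interior: at least 3 FWHM away from both grid edges, where neither
        # the t=0 onset discretisation nor the trailing edge extension reach
        keep = (times >= 3 * fwhm) & (times <= times[-1] - 3 * fwhm)
        np.testing.assert_allclose(out.intensity[keep, 0], expected[keep], atol=1e-6)


class TestIntegrateEnergy:
    def _grid(self, intensity, emax=5.0, de=0.05):
        energies = np.arange(0.0, emax + de / 2, de)
        n_t = 4
        mat = np.tile(intensity(energies), (n_t, 1))
        return TRPESGrid(5.0 * np.arange(n_t), energies, mat,
                         {("enol", "A", "OOP"): mat.copy()})

    def test_flat_unit_intensity(self):
        grid = self._grid(lambda e: np.ones_like(e))
        _, total, _ = integrate_energy(grid, (0.0, 4.0))
        np.testing.assert_allclose(total, 4.0, atol=1e-12)

    def test_signal_above_window_gives_zero(self):
        grid = self._grid(lambda e: np.where(e > 4.2, 1.0, 0.0))
        _, total, _ = integrate_energy(grid, (0.0, 4.0))
        np.testing.assert_allclose(total, 0.0, atol=1e-12)

    def test_matches_dense_quadrature(self, rng):
        values = rng.uniform(0, 2, size=101)
        grid = self._grid(lambda e: values)
        lo, hi = 0.33, 3.77
        _, total, _ = integrate_energy(grid, (lo, hi))
        fine = np.linspace(lo, hi, 200001)
        dense = np.trapezoid(np.interp(fine, grid.energies, values), fine)
        np.testing.assert_allclose(total, dense, atol=1e-6)

    def test_slice_traces_sum_to_total(self, small_ensemble):
        grid = assemble_trpes(small_ensemble, 5.4, kinetic_grid=(0.0, 3.0, 0.05))
        _, total, traces = integrate_energy(grid, (0.0, 4.0))
        np.testing.assert_allclose(sum(traces.values()), total, atol=1e-10)

    def test_empty_window_raises(self, small_ensemble):
        grid = assemble_trpes(small_ensemble, 5.4, kinetic_grid=(0.0, 3.0, 0.05))
        with pytest.raises(ValueError):
            integrate_energy(grid, (2.0, 2.0))


class TestDecompose:
    def test_single_pathway_slice_is_total(self):
        rec = _record()
        grid = assemble_trpes([rec], 5.4, kinetic_grid=(0.0, 3.0, 0.05))
        slices = decompose(grid, "pathway")
        assert set(slices) == {"OOP"}
        np.testing.assert_allclose(slices["OOP"], grid.intensity, atol=1e-12)

    def test_fractional_state_attribution(self):
        w = {"A": np.full(5, 0.6), "B": np.full(5, 0.4)}
        rec = _record(weights=w, n_steps=5)
        grid = assemble_trpes([rec], 5.4, kinetic_grid=(0.0, 3.0, 0.01))
        by_state = decompose(grid, "state")
        # per-state integrated signal proportional to w_j * W_j
        got = by_state["A"].sum() / by_state["B"].sum()
        expect = (0.6 * 4.0 * 0.7) / (0.4 * 3.6 * 0.5)
        assert got == pytest.approx(expect, rel=1e-6)

    def test_unknown_axis_rejected(self, small_ensemble):
        grid = assemble_trpes(small_ensemble, 5.4, kinetic_grid=(0.0, 3.0, 0.05))
        with pytest.raises(ValueError):
            decompose(grid, "flavour")


class TestTrajectoryIO:
    def test_ensemble_roundtrip(self, tmp_path, small_ensemble):
        subset = small_ensemble[:3]
        save_ensemble(str(tmp_path / "ens"), subset)
        back = load_ensemble(str(tmp_path / "ens"))
        assert [r.traj_id for r in back] == sorted(r.traj_id for r in subset)
        orig = {r.traj_id: r for r in subset}
        for r in back:
            o = orig[r.traj_id]
            assert r.pathway == o.pathway and r.tautomer == o.tautomer
            np.testing.assert_allclose(r.times, o.times)
            for s in o.weights:
                np.testing.assert_allclose(r.weights[s], o.weights[s], atol=1e-12)
            for cb, co in zip(r.channels, o.channels):
                np.testing.assert_allclose(cb.norm, co.norm, atol=1e-12)
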