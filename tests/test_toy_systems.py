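"""Synthetic-system generators: landscapes, propagator, bead model, telegraph."""

import numpy as np
import pytest
from scipy.optimize import minimize, minimize_scalar
from scipy.spatial.transform import Rotation
from scipy.stats import chi2, kstest

from elevatorfep.common import kt
from elevatorfep.toy_systems import (ContactSeries, IntegrationError,
                                     TelegraphParams, analytic_pmf,
                                     free_energy_difference,
                                     generate_telegraph_binding,
                                     make_double_well,
                                     make_elevator_bead_model,
                                     make_two_basin_2d, propagate_langevin)
from elevatorfep.toy_systems import DegenerateAxisError

from .conftest import harmonic_model


class TestDoubleWell:
    def test_barrier_and_asymmetry_definitions(self, double_well):
        e = double_well.energy
        assert e(np.array(0.0)) - e(np.array(-2.0)) == pytest.approx(5.0)
        asym = make_double_well(5.0, 4.0, asymmetry=1.5)
        assert (asym.energy(np.array(2.0))
                - asym.energy(np.array(-2.0))) == pytest.approx(1.5)

    def test_substrate_coupling_lowers_saddle_exactly(self):
        # numeric saddle-find against the closed form barrier - delta
        m = make_double_well(5.0, 4.0, coupling_delta=3.0)
        left = minimize_scalar(lambda x: float(m.energy(np.array(x))),
                               bounds=(-3.0, -1.0), method="bounded")
        saddle = float(m.energy(np.array(0.0)))
        assert saddle - left.fun == pytest.approx(2.0, abs=1e-8)

    def test_reduces_to_base_form_at_zero_coupling(self, double_well):
        m = make_double_well(5.0, 4.0, coupling_delta=0.0)
        x = np.linspace(-3, 3, 50)
        assert np.allclose(m.energy(x), double_well.energy(x))

    @pytest.mark.parametrize("kwargs", [
        {"barrier": -1.0, "separation": 4.0},
        {"barrier": 5.0, "separation": 0.0},
        {"barrier": 5.0, "separation": 4.0, "coupling_delta": 5.0},
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            make_double_well(**kwargs)

    def test_gradient_matches_finite_difference(self, double_well, two_basin):
        rng = np.random.default_rng(0)
        h = 1e-6
        x1 = rng.uniform(-3, 3, 40)
        fd = (double_well.energy(x1 + h) - double_well.energy(x1 - h)) / (2 * h)
        assert np.allclose(fd, double_well.gradient(x1), rtol=1e-5)
        x2 = rng.uniform(-0.3, 1.3, (40, 2))
        for i in range(2):
            e = np.zeros(2)
            e[i] = h
            fd = (two_basin.energy(x2 + e) - two_basin.energy(x2 - e)) / (2 * h)
            assert np.allclose(fd, two_basin.gradient(x2)[:, i], rtol=1e-5,
                               atol=1e-6)


class TestTwoBasin2D:
    def test_saddle_lowered_exactly_by_coupling(self):
        base = make_two_basin_2d()
        coupled = make_two_basin_2d(coupling_delta=3.0)
        s = base.params["saddle"]
        assert (base.energy(s) - coupled.energy(s)).item() == pytest.approx(3.0)

    def test_confinement_raises_saddle_exactly(self):
        base = make_two_basin_2d()
        conf = make_two_basin_2d(confinement=2.0)
        s = base.params["saddle"]
        assert (conf.energy(s) - base.energy(s)).item() == pytest.approx(2.0)

    def test_no_barrier_left_is_an_error(self):
        with pytest.raises(ValueError):
            make_two_basin_2d(barrier=5.0, coupling_delta=5.0)

    def test_basin_hessians_positive_definite(self, two_basin):
        h = 1e-5
        for basin in two_basin.basin_minima():
            hess = np.empty((2, 2))
            for i in range(2):
                e = np.zeros(2)
                e[i] = h
                hess[:, i] = (two_basin.gradient(basin + e)
                              - two_basin.gradient(basin - e)) / (2 * h)
            assert np.all(np.linalg.eigvalsh(0.5 * (hess + hess.T)) > 0)

    def test_symmetric_saddle_on_minimum_energy_path(self):
        # with no coupling the saddle sits on the valley floor midway
        m = make_two_basin_2d(valley_amplitude=0.0)
        s = m.params["saddle"]
        assert np.allclose(s, [0.5, 0.5])
        assert np.allclose(m.gradient(s), 0.0, atol=1e-10)


class TestLangevin:
    def test_equipartition_in_harmonic_well(self):
        # sample variance of overdamped sampling must match kT/k at 310 K
        m = harmonic_model(k=1.0)
        traj = propagate_langevin(m, [0.0], n_steps=1_000_000, dt=0.01, seed=11)
        expected = kt(310.0)  # 0.616 Å² for k = 1 kcal/mol/Å²
        assert traj.frames[2000:].var() == pytest.approx(expected, rel=0.02)

    def test_equipartition_chi2_consistency(self):
        # chi-square test of the sampled variance at the 1% level,
        # using an effective sample size from the OU correlation time
        m = harmonic_model(k=1.0)
        dt, n = 0.01, 400_000
        traj = propagate_langevin(m, [0.0], n_steps=n, dt=dt, seed=13)
        x = traj.frames[2000:, 0]
        tau = 1.0 / (1.0 * dt)  # correlation time in steps (mu*k = 1)
        n_eff = len(x) / (2 * tau)
        stat = n_eff * x.var() / kt(310.0)
        lo, hi = chi2.ppf(0.005, n_eff), chi2.ppf(0.995, n_eff)
        assert lo < stat < hi

    def test_zero_temperature_stays_at_minimum(self):
        m = harmonic_model(k=1.0, temperature=0.0)
        traj = propagate_langevin(m, [0.0], n_steps=100, dt=0.01, seed=0)
        assert np.all(traj.frames == 0.0)

    def test_seed_determinism(self, double_well):
        a = propagate_langevin(double_well, [-2.0], 2000, 0.005, seed=5)
        b = propagate_langevin(double_well, [-2.0], 2000, 0.005, seed=5)
        assert np.array_equal(a.frames, b.frames)

    def test_divergence_error_names_dt(self, double_well):
        with pytest.raises(IntegrationError, match="dt"):
            propagate_langevin(double_well, [-2.0], 5000, 5.0, seed=1)

    def test_frame_count_matches_stride(self, double_well):
        traj = propagate_langevin(double_well, [-2.0], 1000, 0.005, seed=1,
                                  stride=10)
        assert len(traj.frames) == 101  # start frame + 100 records


class TestElevatorBeadModel:
    def test_default_geometry_recovered_by_rigid_fit_oracle(self, bead_system):
        # independent quaternion superposition of TD_OF onto TD_IF
        of = bead_system.td_of - bead_system.td_of.mean(axis=0)
        if_ = bead_system.td_if - bead_system.td_if.mean(axis=0)
        rot, _ = Rotation.align_vectors(if_, of)
        angle = np.degrees(rot.magnitude())
        shift = np.linalg.norm(bead_system.td_if.mean(axis=0)
                               - bead_system.td_of.mean(axis=0))
        assert angle == pytest.approx(19.0, abs=1e-6)
        assert shift == pytest.approx(8.0, abs=1e-6)

    def test_identity_geometry(self):
        bs = make_elevator_bead_model(translation=0.0, rotation=0.0, seed=1)
        assert np.allclose(bs.td_of, bs.td_if)

    @pytest.mark.parametrize("t,r", [(3.5, 7.0), (12.0, 41.0), (0.5, 2.0)])
    def test_arbitrary_rigid_motion_recovered(self, t, r):
        bs = make_elevator_bead_model(translation=t, rotation=r, seed=9)
        of = bs.td_of - bs.td_of.mean(axis=0)
        if_ = bs.td_if - bs.td_if.mean(axis=0)
        rot, rssd = Rotation.align_vectors(if_, of)
        assert np.degrees(rot.magnitude()) == pytest.approx(r, abs=1e-6)
        assert rssd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.norm(bs.td_if.mean(axis=0)
                              - bs.td_of.mean(axis=0)) == pytest.approx(t, abs=1e-6)

    def test_scaffold_identical_in_both_references(self, bead_system):
        assert np.array_equal(bead_system.frame_of()[:bead_system.n_sd],
                              bead_system.frame_if()[:bead_system.n_sd])

    def test_too_few_beads_is_degenerate(self):
        with pytest.raises(DegenerateAxisError):
            make_elevator_bead_model(n_td=2)


class TestTelegraph:
    def test_symmetric_rates_give_half_bound(self):
        p = TelegraphParams(kon_times_conc=0.2, koff=0.2, concentration=18.0,
                            duration=20000.0, dt=0.05)
        series = generate_telegraph_binding(p, seed=2)
        assert series.bound.mean() == pytest.approx(0.5, abs=0.02)

    def test_mean_bound_dwell_matches_rate(self):
        p = TelegraphParams(kon_times_conc=0.1, koff=0.2, concentration=18.0,
                            duration=10000.0, dt=0.02)
        series = generate_telegraph_binding(p, seed=4)
        flags = series.bound.astype(int)
        change = np.flatnonzero(np.diff(flags))
        runs = np.diff(np.concatenate([[0], change + 1, [len(flags)]]))
        states = flags[np.concatenate([[0], change + 1])]
        bound_dwells = runs[states == 1] * p.dt
        assert bound_dwells.mean() == pytest.approx(1.0 / p.koff, rel=0.10)

    def test_dwell_distribution_is_exponential(self):
        # KS test against the exponential with the input rate, n >= 1000
        p = TelegraphParams(kon_times_conc=0.3, koff=0.3, concentration=18.0,
                            duration=20000.0, dt=0.02)
        series = generate_telegraph_binding(p, seed=6)
        flags = series.bound.astype(int)
        change = np.flatnonzero(np.diff(flags))
        runs = np.diff(np.concatenate([[0], change + 1, [len(flags)]]))
        states = flags[np.concatenate([[0], change + 1])]
        dwells = runs[1:-1][states[1:-1] == 1] * p.dt  # interior bound dwells
        assert len(dwells) >= 1000
        assert kstest(dwells, "expon", args=(0, 1.0 / p.koff)).pvalue > 0.01

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            TelegraphParams(kon_times_conc=-1.0, koff=0.2, concentration=18.0,
                            duration=100.0, dt=0.01)
        with pytest.raises(ValueError):  # dt not << 1/rate
            TelegraphParams(kon_times_conc=10.0, koff=10.0, concentration=18.0,
                            duration=100.0, dt=0.1)

    def test_contact_series_requires_increasing_times(self):
        with pytest.raises(ValueError):
            ContactSeries(times=np.array([0.0, 0.0, 1.0]),
                          bound=np.array([True, False, True]))


class TestAnalyticPMF:
    def test_double_well_barrier_exact(self, double_well):
        prof = analytic_pmf(double_well, np.linspace(-3, 3, 601))
        assert prof.barrier() == pytest.approx(5.0, abs=1e-9)
        assert prof.values.min() == 0.0

    def test_flat_potential_is_zero(self):
        from .conftest import flat_model
        m = flat_model(dim=1)
        m.params["basins"] = np.array([[0.0]])
        prof = analytic_pmf(m, np.linspace(-1, 1, 51))
        assert np.allclose(prof.values, 0.0)

    def test_transverse_quadrature_matches_closed_form(self):
        # the transverse integral of the two-basin model is an exact
        # Gaussian, so PMF(s) must equal the quartic + tilt to high accuracy
        m = make_two_basin_2d(asymmetry=1.0, confinement=2.0)
        s = np.linspace(0, 1, 101)
        prof = analytic_pmf(m, s)
        b_eff = m.params["effective_barrier"]
        closed = 16.0 * b_eff * s ** 2 * (1 - s) ** 2 + 1.0 * s
        closed -= closed.min()
        assert np.abs(prof.values - closed).max() < 1e-4

    def test_free_energy_difference_sign(self):
        m = make_double_well(5.0, 4.0, asymmetry=1.5)
        df = free_energy_difference(m)
        assert 0.5 < df < 1.6  # IF-like basin higher
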