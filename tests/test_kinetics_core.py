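import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relaxkin.kinetics_core import (
    MechanismCS,
    MechanismLK,
    ObservableModel,
    RelaxationSpectrum,
    Trace,
    analytic_spectrum,
    cs_relaxations,
    equilibrium_populations,
    lk_relaxation,
    rate_matrix,
    simulate_trace,
)

rates_pos = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)
rates_nonneg = st.floats(0.0, 1e3, allow_nan=False, allow_infinity=False)
ligand = st.floats(0.0, 1e3, allow_nan=False, allow_infinity=False)


class TestMechanismTypes:
    def test_cs_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            MechanismCS(k12=-1.0, k21=1.0, kon=1.0, koff=1.0)

    def test_cs_requires_binding_competence(self):
        with pytest.raises(ValueError):
            MechanismCS(k12=1.0, k21=1.0, kon=0.0, koff=1.0)

    def test_partition_ratio(self):
        m = MechanismCS(k12=2.0, k21=8.0, kon=1.0, koff=5.0)
        assert m.partition_ratio == 4.0

    def test_partition_ratio_undefined_for_zero_k12(self):
        m = MechanismCS(k12=0.0, k21=8.0, kon=1.0, koff=5.0)
        with pytest.raises(ValueError):
            m.partition_ratio

    def test_lk_rejects_nonpositive_kon(self):
        with pytest.raises(ValueError):
            MechanismLK(kon=0.0, koff=1.0)

    def test_spectrum_requires_descending_rates(self):
        with pytest.raises(ValueError):
            RelaxationSpectrum(rates=(1.0, 2.0), amplitudes=(1.0, 1.0), baseline=0.0)

    def test_trace_requires_increasing_time(self):
        t = np.ones(12)
        with pytest.raises(ValueError):
            Trace(time=t, signal=t, ligand_conc=1.0, temperature=288.15)

    def test_observable_needs_distinct_coefficients(self):
        with pytest.raises(ValueError):
            ObservableModel(coefficients=(1.0, 1.0, 1.0))


class TestCsRelaxations:
    def test_zero_ligand_collapses_to_exchange_and_off_rates(self, cs_mech):
        # at L=0 the square root collapses to |koff - k12 - k21|
        a1, a2 = cs_relaxations(cs_mech, 0.0)
        expected = {cs_mech.k12 + cs_mech.k21, cs_mech.koff}
        assert a1 == max(expected)
        assert a2 == min(expected)

    def test_matches_eigenvalues(self, cs_mech):
        # frozen oracle: brute-force eigendecomposition of the generator
        a1, a2 = cs_relaxations(cs_mech, 10.0)
        ev = np.sort(np.abs(np.linalg.eigvals(rate_matrix(cs_mech, 10.0))))
        assert a2 == pytest.approx(ev[1], rel=1e-9)
        assert a1 == pytest.approx(ev[2], rel=1e-9)

    def test_decoupled_when_k21_zero(self):
        m = MechanismCS(k12=2.0, k21=0.0, kon=1.0, koff=5.0)
        L = 10.0  # kon*L + koff > k12
        a1, a2 = cs_relaxations(m, L)
        assert a1 == pytest.approx(m.kon * L + m.koff, rel=1e-12)
        assert a2 == pytest.approx(m.k12, rel=1e-12)

    def test_negative_ligand_rejected(self, cs_mech):
        with pytest.raises(ValueError):
            cs_relaxations(cs_mech, -1.0)

    def test_saturation_limits(self, cs_mech):
        # alpha2 -> k12 and alpha1/L -> kon as L -> infinity
        L = 1e6 * cs_mech.koff / cs_mech.kon
        a1, a2 = cs_relaxations(cs_mech, L)
        assert a2 == pytest.approx(cs_mech.k12, rel=1e-3)
        assert a1 / L == pytest.approx(cs_mech.kon, rel=1e-3)

    def test_reduces_to_lk_when_exchange_frozen(self):
        m = MechanismCS(k12=0.0, k21=0.0, kon=1.6, koff=7.8)
        lk = MechanismLK(kon=1.6, koff=7.8)
        for L in (0.0, 5.0, 20.0):
            a1, a2 = cs_relaxations(m, L)
            assert a1 == pytest.approx(lk_relaxation(lk, L), rel=1e-12)
            assert a2 == pytest.approx(0.0, abs=1e-12)

    @given(
        k12=rates_nonneg, k21=rates_nonneg, kon=rates_pos, koff=rates_pos, L=ligand
    )
    @settings(max_examples=200, deadline=None)
    def test_property_eigenvalue_equivalence(self, k12, k21, kon, koff, L):
        m = MechanismCS(k12=k12, k21=k21, kon=kon, koff=koff)
        a1, a2 = cs_relaxations(m, L)
        ev = np.sort(np.abs(np.linalg.eigvals(rate_matrix(m, L))))
        scale = max(a1, 1.0)
        assert abs(a1 - ev[2]) <= 1e-9 * scale
        assert abs(a2 - ev[1]) <= 1e-9 * scale


class TestLkRelaxation:
    def test_d194a_constants_at_20uM(self, lk_mech):
        assert lk_relaxation(lk_mech, 20.0) == pytest.approx(39.8, rel=1e-12)

    def test_intercept_is_koff(self, lk_mech):
        assert lk_relaxation(lk_mech, 0.0) == lk_mech.koff

    def test_matches_eigenvalue(self, lk_mech):
        ev = np.sort(np.abs(np.linalg.eigvals(rate_matrix(lk_mech, 12.0))))
        assert lk_relaxation(lk_mech, 12.0) == pytest.approx(ev[1], rel=1e-12)


class TestRateMatrix:
    @pytest.mark.parametrize("L", [0.0, 1.0, 25.0])
    def test_columns_sum_to_zero(self, cs_mech, lk_mech, L):
        for m in (cs_mech, lk_mech):
            M = rate_matrix(m, L)
            np.testing.assert_allclose(M.sum(axis=0), 0.0, atol=1e-14)

    def test_off_diagonal_nonnegative(self, cs_mech):
        M = rate_matrix(cs_mech, 10.0)
        off = M[~np.eye(3, dtype=bool)]
        assert np.all(off >= 0)

    def test_lk_zero_ligand_single_nonzero_eigenvalue(self, lk_mech):
        M = rate_matrix(lk_mech, 0.0)
        ev = np.sort(np.abs(np.linalg.eigvals(M)))
        assert ev[0] == pytest.approx(0.0, abs=1e-12)
        assert ev[1] == pytest.approx(lk_mech.koff, rel=1e-12)


class TestEquilibriumPopulations:
    def test_symmetric_exchange_without_ligand(self):
        m = MechanismCS(k12=3.0, k21=3.0, kon=1.0, koff=5.0)
        np.testing.assert_allclose(
            equilibrium_populations(m, 0.0), [0.5, 0.5, 0.0], atol=1e-14
        )

    def test_partition_ratio_at_zero_ligand(self, cs_mech):
        pops = equilibrium_populations(cs_mech, 0.0)
        np.testing.assert_allclose(pops, [0.8, 0.2, 0.0], atol=1e-14)

    def test_matches_null_space(self, cs_mech):
        pops = equilibrium_populations(cs_mech, 10.0)
        M = rate_matrix(cs_mech, 10.0)
        np.testing.assert_allclose(M @ pops, 0.0, atol=1e-12)
        assert pops.sum() == pytest.approx(1.0)
        assert np.all(pops >= 0)

    def test_all_zero_exchange_raises(self):
        m = MechanismCS(k12=0.0, k21=0.0, kon=1.0, koff=5.0)
        with pytest.raises(ValueError):
            equilibrium_populations(m, 10.0)


class TestSimulateTrace:
    def test_stationary_start_gives_constant_signal(self, cs_mech, time_grid):
        # mixing into zero ligand from the zero-ligand pre-equilibrium
        eq = equilibrium_populations(cs_mech, 0.0)
        obs = ObservableModel(initial=(eq[0], eq[1]))
        trace = simulate_trace(cs_mech, obs, 0.0, time_grid)
        assert np.ptp(trace.signal) < 1e-12

    def test_lk_single_exponential_with_closed_form_rate(self, lk_mech, obs, time_grid):
        trace = simulate_trace(lk_mech, obs, 20.0, time_grid, dead_time=1e-3)
        alpha = lk_relaxation(lk_mech, 20.0)
        asymptote = trace.signal[-1]
        resid = trace.signal - asymptote
        # log-linear: residual must decay with exactly the closed-form rate
        sel = np.abs(resid) > 1e-10
        slope = np.polyfit(trace.time[sel], np.log(np.abs(resid[sel])), 1)[0]
        assert -slope == pytest.approx(alpha, rel=1e-3)
        spec = analytic_spectrum(lk_mech, obs, 20.0)
        assert spec.rates == (pytest.approx(alpha, rel=1e-12),)

    def test_cs_two_exponentials_with_closed_form_rates(self, cs_mech, obs):
        spec = analytic_spectrum(cs_mech, obs, 10.0)
        a1, a2 = cs_relaxations(cs_mech, 10.0)
        assert spec.rates[0] == pytest.approx(a1, rel=1e-9)
        assert spec.rates[1] == pytest.approx(a2, rel=1e-9)

    def test_asymptote_is_equilibrium_signal(self, cs_mech, obs):
        grid = np.geomspace(1e-3, 50.0, 400)
        trace = simulate_trace(cs_mech, obs, 10.0, grid)
        eq_signal = equilibrium_populations(cs_mech, 10.0) @ np.array([1.0, 1.0, 0.7])
        assert trace.signal[-1] == pytest.approx(eq_signal, rel=1e-9)

    def test_dead_time_censoring(self, lk_mech, obs):
        grid = np.linspace(1e-4, 1.0, 200)
        trace = simulate_trace(lk_mech, obs, 10.0, grid, dead_time=0.01)
        assert trace.time[0] >= 0.01
        assert len(trace) < 200

    def test_empty_after_censoring_raises(self, lk_mech, obs):
        grid = np.linspace(1e-4, 5e-3, 20)
        with pytest.raises(ValueError):
            simulate_trace(lk_mech, obs, 10.0, grid, dead_time=0.5)

    @given(
        k12=st.floats(0.1, 50), k21=st.floats(0.1, 50),
        kon=st.floats(0.1, 10), koff=st.floats(0.1, 50),
        L=st.floats(0.0, 100),
    )
    @settings(max_examples=30, deadline=None)
    def test_populations_nonnegative_and_normalized(self, k12, k21, kon, koff, L):
        from relaxkin.kinetics_core import _initial_populations, _propagate

        m = MechanismCS(k12=k12, k21=k21, kon=kon, koff=koff)
        p0 = _initial_populations(m, ObservableModel())
        t = np.geomspace(1e-4, 10.0, 50)
        pops = _propagate(rate_matrix(m, L), p0, t)
        assert np.all(pops > -1e-9)
        np.testing.assert_allclose(pops.sum(axis=1), 1.0, atol=1e-9)
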