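"""Mechanistic-core tests against closed-form pharmacokinetic oracles."""

import numpy as np
import pytest

from warfarin_mipd.dynamics import (DosingRegimen, OccasionSeries,
                                    simulate_response, steady_state_inr)

from conftest import bateman_concentration


class TestDomainTypes:
    def test_parameter_invariants_enforced(self, typical_psi):
        with pytest.raises(ValueError):
            typical_psi.with_(ke=-0.1)
        with pytest.raises(ValueError):
            typical_psi.with_(inr_base=0.5)
        with pytest.raises(ValueError):
            typical_psi.with_(n_transit=0)

    def test_regimen_invariants(self):
        with pytest.raises(ValueError):
            DosingRegimen(((5.0, 24.0), (5.0, 0.0)))
        with pytest.raises(ValueError):
            DosingRegimen(((-1.0, 0.0),))
        daily = DosingRegimen.daily([10, 7.5, 5])
        assert daily.times.tolist() == [0.0, 24.0, 48.0]

    def test_occasion_series_positive(self):
        with pytest.raises(ValueError):
            OccasionSeries({0: -0.5})
        assert OccasionSeries({0: 1.2}).eta(3) == 1.0  # absent day -> 1


class TestSimulateResponse:
    def test_zero_dose_stays_at_baseline(self, typical_psi):
        traj = simulate_response(DosingRegimen(), typical_psi,
                                 times=np.linspace(0, 240, 11))
        assert np.allclose(traj.conc_mg_per_L, 0.0)
        assert np.allclose(traj.inr, typical_psi.inr_base)

    def test_single_dose_matches_bateman_oracle(self, typical_psi):
        """ODE concentration equals the closed-form one-compartment
        first-order-absorption solution to <= 1e-6 relative."""
        times = np.linspace(0.5, 120, 40)
        traj = simulate_response(DosingRegimen(((10.0, 0.0),)), typical_psi,
                                 times=times, rtol=1e-10, atol=1e-12)
        oracle = bateman_concentration(10.0, times, typical_psi)
        rel = np.abs(traj.conc_mg_per_L - oracle) / oracle.max()
        assert rel.max() <= 1e-6

    def test_two_doses_superpose_linearly(self, typical_psi):
        """PK linearity: two 5 mg doses equal the sum of shifted
        single-dose closed forms."""
        times = np.linspace(25, 150, 30)
        regimen = DosingRegimen(((5.0, 0.0), (5.0, 24.0)))
        traj = simulate_response(regimen, typical_psi, times=times,
                                 rtol=1e-10, atol=1e-12)
        oracle = (bateman_concentration(5.0, times, typical_psi)
                  + bateman_concentration(5.0, times - 24.0, typical_psi))
        rel = np.abs(traj.conc_mg_per_L - oracle) / oracle.max()
        assert rel.max() <= 1e-6

    def test_inr_peak_lags_concentration_peak(self, typical_psi):
        """The INR response is delayed relative to drug exposure."""
        times = np.linspace(0, 240, 481)
        traj = simulate_response(DosingRegimen(((15.0, 0.0),)), typical_psi,
                                 times=times)
        t_conc = times[np.argmax(traj.conc_mg_per_L)]
        t_inr = times[np.argmax(traj.inr)]
        assert t_inr > t_conc + 12.0

    def test_high_vitamin_k_day_lowers_following_inr(self, typical_psi):
        """A day with more vitamin-K input (eta > 1) partially reverses the
        anticoagulant effect on the following days."""
        regimen = DosingRegimen.daily([7.5] * 10)
        times = np.array([24.0 * d for d in range(4, 10)])
        base = simulate_response(regimen, typical_psi, times=times)
        boosted = simulate_response(regimen, typical_psi, times=times,
                                    occasions=OccasionSeries({3: 1.3}))
        assert np.all(boosted.inr < base.inr)

    def test_solver_tolerance_refinement_stable(self, typical_psi):
        times = np.array([24.0 * d for d in range(1, 8)])
        regimen = DosingRegimen.daily([5.0] * 8)
        coarse = simulate_response(regimen, typical_psi, times=times)
        fine = simulate_response(regimen, typical_psi, times=times,
                                 rtol=1e-8, atol=1e-10)
        assert np.max(np.abs(coarse.inr - fine.inr)) < 1e-4

    def test_empty_grid_rejected(self, typical_psi):
        with pytest.raises(ValueError):
            simulate_response(DosingRegimen(), typical_psi, times=[])

    def test_unsorted_grid_rejected(self, typical_psi):
        with pytest.raises(ValueError):
            simulate_response(DosingRegimen(), typical_psi,
                              times=[10.0, 5.0])


class TestSteadyStateInr:
    def test_zero_dose_returns_baseline(self, typical_psi):
        assert steady_state_inr(0.0, typical_psi) == typical_psi.inr_base

    def test_monotone_in_dose(self, typical_psi):
        doses = [1.0, 3.0, 5.0, 8.0, 12.0]
        inrs = [steady_state_inr(d, typical_psi) for d in doses]
        assert all(a <= b + 1e-9 for a, b in zip(inrs, inrs[1:]))

    def test_reference_patient_on_target_at_calibration_dose(
            self, typical_psi):
        """The default EC50 is calibrated so 5 mg/day puts the reference
        patient inside the therapeutic range."""
        assert 2.0 <= steady_state_inr(5.0, typical_psi) <= 3.0

    def test_negative_dose_rejected(self, typical_psi):
        with pytest.raises(ValueError):
            steady_state_inr(-1.0, typical_psi)


def test_sbml_hook_requires_libsbml():
    from warfarin_mipd.dynamics import load_sbml_model
    with pytest.raises((ImportError, NotImplementedError)):
        load_sbml_model("model.xml")
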