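"""Simple dosing agents: stubs and a parameter-oracle baseline.

The learned agents live in :mod:`warfarin_mipd.regression`,
:mod:`warfarin_mipd.deeprl` and :mod:`warfarin_mipd.pkpd`; the agents here
anchor sanity orderings in tests and demos.
"""

from __future__ import annotations

from scipy.optimize import brentq

from .dynamics import IndividualParameters, steady_state_inr
from .protocols import round_dose


class ZeroDoseAgent:
    """Administers no drug; every INR stays near baseline."""

    name = "stub"

    def propose_dose(self, chi, record, y_star, day, patient_id):
        return 0.0


class ConstantDoseAgent:
    """Administers a fixed daily dose regardless of monitoring data."""

    name = "constant"

    def __init__(self, dose_mg: float):
        self.dose_mg = float(dose_mg)

    def propose_dose(self, chi, record, y_star, day, patient_id):
        return self.dose_mg


class OracleMaintenanceAgent:
    """Upper-bound baseline that reads the true individual parameters.

    Solves ``steady_state_inr(d) = y_star`` for each patient's true psi and
    administers that maintenance dose daily.  This deliberately breaks the
    information barrier of the trial protocols, so it is only suitable as a
    best-case comparator in simulation studies, never as an MIPD method.
    """

    name = "oracle"

    def __init__(self, cohort, dose_max: float = 30.0):
        self._doses = {}
        for i, (_, psi) in enumerate(cohort):
            self._doses[i + 1] = self._maintenance_dose(psi, dose_max)

    def _maintenance_dose(self, psi: IndividualParameters, dose_max,
                          y_star: float = 2.5) -> float:
        lo, hi = 0.0, dose_max
        if steady_state_inr(hi, psi) < y_star:
            return hi

        def f(d):
            return steady_state_inr(d, psi) - y_star

        return round_dose(brentq(f, lo, hi, xtol=0.05), dose_max=dose_max)

    def propose_dose(self, chi, record, y_star, day, patient_id):
        return self._doses[patient_id]
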