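"""Trial-phase protocols, the dose heuristic and the safety-stop rule."""

import numpy as np
import pandas as pd
import pytest

from warfarin_mipd.dataset import maintenance_table, write_dataset
from warfarin_mipd.protocols import (MonitoringRecord, ProtocolError,
                                     heuristic_dose, run_mipd_trial,
                                     run_phase1, run_phase2, run_phase3,
                                     safety_stop)
from warfarin_mipd.population import sample_cohort
from warfarin_mipd.agents import ZeroDoseAgent
from warfarin_mipd.metrics import TherapeuticRange, summarise_trial


class TestHeuristicDose:
    @pytest.mark.parametrize("d_prev, y_j, expected", [
        (10.0, 2.5, 10.0),    # on target: keep the dose
        (10.0, 5.0, 5.0),     # INR twice the target: halve
        (7.5, 1.5, 12.5),     # INR below target: scale up
    ])
    def test_linear_adjustment(self, d_prev, y_j, expected):
        assert heuristic_dose(d_prev, 2.5, y_j) == expected

    def test_rounding_and_cap(self):
        assert heuristic_dose(10.0, 2.5, 2.4) == 10.5  # 10.416 -> 10.5
        assert heuristic_dose(20.0, 2.5, 0.9) == 30.0  # capped

    def test_nonpositive_inr_rejected(self):
        with pytest.raises(ValueError):
            heuristic_dose(10.0, 2.5, 0.0)


class TestSafetyStop:
    @pytest.mark.parametrize("history, expected", [
        ([5.1, 5.2, 5.3], True),
        ([5.1, 4.9, 5.2, 5.3], False),
        ([], False),
        ([6.0, 6.0], False),
        ([2.0, 5.5, 5.1, 5.01, 2.0], True),
    ])
    def test_three_consecutive_above_five(self, history, expected):
        assert safety_stop(history) is expected


class TestPhase1:
    def test_design_counts(self, config):
        ds = run_phase1(config, 123)
        assert ds.n_patients == 60
        assert len(ds.measurements) == 180
        assert len(ds.doses) == 60
        assert set(ds.measurements["Time_h"]) == {10.0, 35.0, 60.0}
        assert (ds.measurements["Observable"] ==
                "warfarin_conc_mg_per_L").all()

    def test_seed_determinism_byte_identical(self, config, tmp_path):
        for sub in ("a", "b"):
            write_dataset(run_phase1(config, 7), tmp_path / sub)
        for name in ("covariates", "measurements", "doses"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == \
                (tmp_path / "b" / f"{name}.csv").read_bytes()

    def test_degenerate_config_collapses_cohort(self, quiet_config):
        """All noise and IIV off: every patient yields the same triple."""
        ds = run_phase1(quiet_config, 5)
        values = ds.measurements.pivot_table(
            index="ID", columns="Time_h", values="Value")
        assert np.allclose(values.std(axis=0), 0.0, atol=1e-12)


class TestPhase2:
    def test_design_counts(self, config):
        ds = run_phase2(config, 11, n=40)
        assert ds.n_patients == 40
        inr = ds.measurements
        assert len(inr) <= 40 * 8
        assert set(inr["Time_h"] / 24.0) <= {0, 1, 2, 3, 5, 7, 13, 20}
        # induction doses fixed for everyone still in the trial
        d0 = ds.doses[ds.doses["Time_h"] == 0.0]["Dose_mg"]
        assert (d0 == 10.0).all()
        d2 = ds.doses[ds.doses["Time_h"] == 48.0]["Dose_mg"]
        assert (d2 == 5.0).all()

    def test_on_target_patient_keeps_dose(self, quiet_config):
        """With all variability off and measurements exactly on target, the
        heuristic reproduces the previous dose."""
        ds = run_phase2(quiet_config, 1, n=3)
        doses = ds.doses[ds.doses["ID"] == 1].sort_values("Time_h")
        by_day = doses.set_index(doses["Time_h"] / 24.0)["Dose_mg"]
        # dose is constant between adjustment days
        assert by_day[4.0] == by_day[3.0]
        assert by_day[20.0] == by_day[13.0]

    def test_stop_rule_truncates_rows(self, config, monkeypatch):
        """Forcing measurements far above 5 stops patients after the third
        consecutive high measurement (day 2)."""
        from warfarin_mipd import protocols

        monkeypatch.setattr(
            protocols, "sample_measurement",
            lambda y, cfg, rng: np.full(np.shape(y), 6.0))
        ds = run_phase2(config, 2, n=5)
        assert ds.measurements["Time_h"].max() == 48.0
        assert sorted(ds.metadata["stopped_patients"]) == [1, 2, 3, 4, 5]


class TestPhase3:
    def test_one_inr_row_and_maintenance_dose_per_survivor(self, config):
        ds = run_phase3(config, 21, n=80)
        survivors = ds.n_patients - len(ds.metadata["stopped_patients"])
        assert len(ds.measurements) == survivors
        assert (ds.measurements["Time_h"] == 24.0 * 55).all()
        assert len(ds.doses) == survivors
        table = maintenance_table(ds)
        assert {"INR", "MaintenanceDose"} <= set(table.columns)

    def test_zero_variability_gives_identical_doses_per_covariate_class(
            self, quiet_config):
        ds = run_phase3(quiet_config, 3, n=40)
        table = maintenance_table(ds)
        grouped = table.groupby(["CYP2C9", "VKORC1", "Age"])
        assert (grouped["MaintenanceDose"].nunique() == 1).all()


class TestMipdTrial:
    def test_row_counts_and_zero_dose_baseline(self, config, theta,
                                               demographics):
        cohort = sample_cohort(theta, demographics, 20, 9)
        ds = run_mipd_trial(config, ZeroDoseAgent(), cohort, 31)
        assert len(ds.measurements) == 20 * 19
        assert len(ds.doses) == 20 * 19
        assert (ds.doses["Dose_mg"] == 0.0).all()
        med = ds.measurements.groupby("ID")["Value"].median()
        assert np.allclose(med, 1.0, atol=0.25)

    def test_invalid_agent_dose_raises_named_error(self, config, theta,
                                                   demographics):
        class BadAgent:
            name = "bad"

            def propose_dose(self, chi, record, y_star, day, patient_id):
                return float("nan")

        cohort = sample_cohort(theta, demographics, 2, 1)
        with pytest.raises(ProtocolError, match="bad.*day 0"):
            run_mipd_trial(config, BadAgent(), cohort, 1)

    def test_agents_see_monitoring_not_parameters(self, config, theta,
                                                  demographics):
        """The agent interface receives covariates and measurements only."""
        seen = []

        class SpyAgent:
            name = "spy"

            def propose_dose(self, chi, record, y_star, day, patient_id):
                seen.append((chi, record, day))
                return 5.0

        cohort = sample_cohort(theta, demographics, 2, 2)
        config.trials.mipd_days = 3
        run_mipd_trial(config, SpyAgent(), cohort, 3)
        assert len(seen) == 2 * 3
        chi, record, _ = seen[-1]
        assert isinstance(record, MonitoringRecord)
        assert len(record.measurements) == 3
        assert not hasattr(chi, "ke")  # covariates, never parameters
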