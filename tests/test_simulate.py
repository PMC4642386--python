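"""Synthetic claims generator: determinism, configured moments, limit
behaviour, effect monotonicity, calibration, CSV round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rxadhere.pdc import compute_pdc_table
from rxadhere.records import Group, read_fills, read_patients
from rxadhere.simulate import (
    CalibrationError, SimulationConfig, calibrate_effect, simulate_fills,
    simulate_roster, simulate_study, _simulated_rates,
)

HTN = "antihypertensive"


def small_config(seed=123, n=400, **kw):
    """One-class, one-subclass config for fast unit checks."""
    defaults = dict(
        seed=seed, n_intervention=n // 3, n_control=n - n // 3,
        class_membership=(0.0, 1.0, 0.0),
        subclass_count_probs=(1.0, 0.0, 0.0),
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestRoster:
    def test_deterministic(self):
        cfg = SimulationConfig(seed=5)
        assert simulate_roster(cfg) == simulate_roster(cfg)

    def test_seed_changes_output(self):
        a = simulate_roster(SimulationConfig(seed=5, n_intervention=50,
                                             n_control=50))
        b = simulate_roster(SimulationConfig(seed=6, n_intervention=50,
                                             n_control=50))
        assert a != b

    def test_exact_group_sizes(self):
        roster = simulate_roster(SimulationConfig(seed=1))
        n_int = sum(p.group is Group.INTERVENTION for p in roster)
        assert n_int == 756
        assert len(roster) - n_int == 1391

    def test_age_mean_matches_truncated_normal(self):
        cfg = SimulationConfig(seed=2, n_intervention=5000, n_control=5000)
        ages = np.array([p.age for p in simulate_roster(cfg)])
        a = (18 - cfg.age_mean) / cfg.age_sd
        b = (89 - cfg.age_mean) / cfg.age_sd
        # floor() shifts the truncated-normal mean down by ~0.5
        expected = stats.truncnorm.mean(a, b, cfg.age_mean, cfg.age_sd) - 0.5
        se = cfg.age_sd / np.sqrt(len(ages))
        assert abs(ages.mean() - expected) < 3.5 * se
        assert ages.min() >= 18 and ages.max() <= 89

    def test_eligible_fraction_trims_enrollment(self):
        cfg = small_config(eligible_fraction=0.5, n=600)
        roster = simulate_roster(cfg)
        fu_end = cfg.windows["follow_up"].end
        short = sum(p.enroll_end < fu_end for p in roster)
        assert 200 < short < 400  # ~half

    @pytest.mark.parametrize(
        "kw", [dict(n_intervention=0), dict(p_low=1.5),
               dict(class_membership=(0.5, 0.2, 0.2)),
               dict(eligible_fraction=2.0)],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, **kw)


class TestFills:
    def test_deterministic(self):
        cfg = small_config()
        roster = simulate_roster(cfg)
        a = simulate_fills(roster, cfg, "baseline")
        b = simulate_fills(roster, cfg, "baseline")
        assert a == b

    @staticmethod
    def _static_dynamics():
        """Freeze period-to-period dynamics so theta keeps its limit value."""
        null = {"antihypertensive": 0.0, "antihyperlipidemic": 0.0}
        return dict(transition_sd=0.0, control_followup_shift=null,
                    intervention_effect_shift=dict(null))

    def test_perfect_adherence_limit(self):
        # degenerate bulk at theta ~ 1 and no start delay -> PDC exactly 1
        cfg = small_config(p_low=0.0, bulk_a=5e8, bulk_b=1.0,
                           first_fill_delay_max=0, n=60,
                           **self._static_dynamics())
        study = simulate_study(cfg)
        table = compute_pdc_table(study.fills, cfg.windows)
        assert np.allclose(table["pdc"], 1.0)

    def test_never_refill_limit(self):
        # theta at floor ~ 0 -> a single initial 90-day fill per stream
        cfg = small_config(p_low=1.0, low_a=1e-3, low_b=1e3,
                           theta_min=1e-9, first_fill_delay_max=0,
                           days_supply_values=(90,), days_supply_probs=(1.0,),
                           n=60, **self._static_dynamics())
        study = simulate_study(cfg)
        table = compute_pdc_table(study.fills, cfg.windows)
        assert np.allclose(table["pdc"], 90 / 365)
        per_stream = study.fills.groupby(
            ["patient_id", "subclass", "drug_class"]
        ).size()
        assert (per_stream == 2).all()  # one fill per period

    def test_default_mean_pdc_in_published_band(self):
        cfg = SimulationConfig(seed=31, n_intervention=700, n_control=1300)
        study = simulate_study(cfg)
        table = compute_pdc_table(study.fills, cfg.windows)
        assert 0.83 <= table["pdc"].mean() <= 0.89

    def test_adherent_fraction_in_published_band(self):
        cfg = SimulationConfig(seed=32, n_intervention=1000, n_control=1000)
        study = simulate_study(cfg)
        table = compute_pdc_table(study.fills, cfg.windows)
        bl = table[table["period"] == "baseline"]
        assert 0.72 <= bl["adherent"].mean() <= 0.82

    def test_effect_shift_monotone(self):
        """More intervention shift can only raise intervention adherence."""
        rates = []
        for shift in (0.0, 0.06, 0.12):
            ensemble = []
            for seed in (101, 102, 103):
                cfg = small_config(
                    seed=seed, n=1500,
                    intervention_effect_shift={HTN: shift,
                                               "antihyperlipidemic": 0.0},
                )
                ensemble.append(_simulated_rates(cfg, HTN, 1500)[0])
            rates.append(np.mean(ensemble))
        assert rates[0] <= rates[1] <= rates[2]

    def test_fills_within_periods(self):
        cfg = small_config()
        study = simulate_study(cfg)
        w = cfg.windows
        day = study.fills["fill_day"]
        in_bl = (day >= w["baseline"].start_day) & (day < w["baseline"].end_day)
        in_fu = (day >= w["follow_up"].start_day) & (day < w["follow_up"].end_day)
        assert (in_bl | in_fu).all()


class TestRoundTrip:
    def test_csv_round_trip_validates(self, tmp_path):
        cfg = small_config(n=120)
        study = simulate_study(cfg)
        paths = study.write(tmp_path)
        assert read_patients(paths["patients"]) == study.roster
        fills_back = read_fills(paths["fills"])
        assert fills_back == study.fill_records()
        assert (tmp_path / "provenance.json").exists()


class TestCalibration:
    def test_equal_targets_give_null_shift(self):
        cfg = small_config(n=4000)
        out = calibrate_effect(cfg, (0.76, 0.76), HTN, n=4000, tol=0.02)
        assert abs(out.intervention_effect_shift[HTN]) < 0.05

    def test_unreachable_target_raises(self):
        cfg = small_config(n=500)
        with pytest.raises(CalibrationError):
            calibrate_effect(cfg, (0.999, 0.01), HTN, n=500, tol=0.001,
                             bounds=(-0.05, 0.05))

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError):
            calibrate_effect(small_config(), (1.2, 0.5), HTN, n=100)
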