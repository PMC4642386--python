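"""Effect estimation: Katz risk ratios, modified-Poisson adjustment against
the Mantel-Haenszel oracle, transitions, RD/NNT, baseline tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rxadhere.cohort import CohortMember
from rxadhere.effects import (
    REFERENCE_LEVEL, TransitionLevel, TransitionTable, TwoByTwo,
    VariableSpec, adherence_rate, adjusted_rr, adjusted_transition_rr,
    baseline_table, risk_difference_and_nnt, transition_classify,
    transition_rr, unadjusted_rr,
)
from rxadhere.records import DrugClass, Group

from conftest import mantel_haenszel_rr


def member(pid, group, bl, fu, **cov):
    return CohortMember(
        patient_id=pid, group=group, drug_class=DrugClass.ANTIHYPERTENSIVE,
        baseline_adherent=bl, followup_adherent=fu, covariates=cov,
    )


def cohort_from_2x2(a, n1, c, n2, **cov):
    """Synthetic cohort whose follow-up 2x2 equals the given counts."""
    out = []
    for i in range(n1):
        out.append(member(f"i{i}", Group.INTERVENTION, True, i < a, **cov))
    for i in range(n2):
        out.append(member(f"c{i}", Group.CONTROL, True, i < c, **cov))
    return out


class TestAdherenceRate:
    def test_reported_rate(self):
        k, n, p = adherence_rate([True] * 447 + [False] * 114)
        assert (k, n) == (447, 561)
        assert round(100 * p, 1) == 79.7

    def test_extremes(self):
        assert adherence_rate([False] * 5)[2] == 0.0
        assert adherence_rate([True] * 5)[2] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            adherence_rate([])


class TestUnadjustedRR:
    @pytest.mark.parametrize(
        "t,rr,ci,p",
        [
            (TwoByTwo(447, 561, 759, 1008), 1.06, (1.00, 1.12), ".04"),
            (TwoByTwo(368, 474, 706, 913), 1.00, (0.95, 1.07), ".90"),
            (TwoByTwo(439, 561, 799, 1008), 0.99, (0.94, 1.04), ".64"),
        ],
    )
    def test_published_rows(self, t, rr, ci, p):
        est = unadjusted_rr(t)
        assert round(est.estimate, 2) == rr
        assert (round(est.ci_low, 2), round(est.ci_high, 2)) == ci
        assert f"{est.p:.2f}".lstrip("0") == p
        assert est.method == "katz_log"

    def test_symmetry_identical_groups(self):
        est = unadjusted_rr(TwoByTwo(30, 100, 30, 100))
        assert est.estimate == 1.0

    def test_reciprocal_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n1, n2 = rng.integers(5, 500, size=2)
            a = rng.integers(1, n1 + 1)
            c = rng.integers(1, n2 + 1)
            t = TwoByTwo(int(a), int(n1), int(c), int(n2))
            assert unadjusted_rr(t).estimate * \
                unadjusted_rr(t.swapped()).estimate == pytest.approx(1.0)

    def test_zero_cell_flagged(self):
        est = unadjusted_rr(TwoByTwo(0, 10, 5, 10))
        assert est.estimate == 0.0
        assert math.isnan(est.ci_low) and est.p is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(11, 10, 0, 10)


class TestAdjustedRR:
    def test_group_only_equals_crude(self):
        cohort = cohort_from_2x2(63, 118, 93, 226)
        crude = unadjusted_rr(TwoByTwo(63, 118, 93, 226)).estimate
        adj = adjusted_rr(cohort).estimate
        assert abs(adj - crude) / crude < 1e-8

    def test_matches_mantel_haenszel_on_multiplicative_strata(self):
        # exactly multiplicative risks: stratum risks (0.6, 0.4) and
        # (0.3, 0.2) share RR 1.5, so GLM and MH both recover 1.5
        strata = [(60, 100, 40, 100), (60, 200, 40, 200)]
        rows = []
        for k, (a, n1, c, n2) in enumerate(strata):
            for i in range(n1):
                rows.append(member(f"s{k}i{i}", Group.INTERVENTION, True,
                                   i < a, z=float(k)))
            for i in range(n2):
                rows.append(member(f"s{k}c{i}", Group.CONTROL, True,
                                   i < c, z=float(k)))
        mh = mantel_haenszel_rr(strata)
        adj = adjusted_rr(rows, covariates=["z"]).estimate
        assert mh == pytest.approx(1.5)
        assert abs(adj - mh) < 1e-6

    def test_missing_covariates_excluded(self):
        cohort = cohort_from_2x2(30, 60, 25, 60)
        varied = [
            CohortMember(m.patient_id, m.group, m.drug_class,
                         m.baseline_adherent, m.followup_adherent,
                         {"bmi": None if i < 10 else 25.0 + (i % 13)})
            for i, m in enumerate(cohort)
        ]
        est = adjusted_rr(varied, covariates=["bmi"])
        assert math.isfinite(est.estimate)

    def test_collinear_covariates_rejected(self):
        cohort = cohort_from_2x2(30, 60, 25, 60, z=1.0, w=2.0)  # w = 2z
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            adjusted_rr(cohort, covariates=["z", "w"])


class TestTransitions:
    def test_level_assignment(self):
        assert TransitionLevel.of(True, False) is REFERENCE_LEVEL
        assert TransitionLevel.of(False, True) is \
            TransitionLevel.NONADHERENT_TO_ADHERENT

    def test_all_persistently_adherent(self):
        cohort = [member(f"p{i}", Group.INTERVENTION, True, True)
                  for i in range(7)]
        table = transition_classify(cohort)
        assert table.intervention[TransitionLevel.ADHERENT_TO_ADHERENT] == 7
        assert sum(table.intervention.values()) == 7

    def test_hand_enumerated_eight_members(self):
        flags = [(True, True), (True, False), (False, True), (False, False)]
        cohort = [member(f"i{i}", Group.INTERVENTION, *flags[i % 4])
                  for i in range(4)]
        cohort += [member(f"c{i}", Group.CONTROL, *flags[i % 2])
                   for i in range(4)]
        t = transition_classify(cohort)
        assert all(v == 1 for v in t.intervention.values())
        assert t.control[TransitionLevel.ADHERENT_TO_ADHERENT] == 2
        assert t.control[TransitionLevel.ADHERENT_TO_NONADHERENT] == 2
        assert t.group_total(Group.INTERVENTION) == 4
        assert t.group_total(Group.CONTROL) == 4

    def test_partition_property(self):
        rng = np.random.default_rng(9)
        cohort = [
            member(f"p{i}",
                   Group.INTERVENTION if rng.random() < 0.4 else Group.CONTROL,
                   bool(rng.random() < 0.7), bool(rng.random() < 0.7))
            for i in range(500)
        ]
        t = transition_classify(cohort)
        n_int = sum(1 for m in cohort if m.group is Group.INTERVENTION)
        assert sum(t.intervention.values()) == n_int
        assert sum(t.control.values()) == 500 - n_int


HTN_TABLE = TransitionTable(
    intervention={
        TransitionLevel.ADHERENT_TO_NONADHERENT: 55,
        TransitionLevel.NONADHERENT_TO_ADHERENT: 63,
        TransitionLevel.ADHERENT_TO_ADHERENT: 384,
        TransitionLevel.NONADHERENT_TO_NONADHERENT: 59,
    },
    control={
        TransitionLevel.ADHERENT_TO_NONADHERENT: 133,
        TransitionLevel.NONADHERENT_TO_ADHERENT: 93,
        TransitionLevel.ADHERENT_TO_ADHERENT: 666,
        TransitionLevel.NONADHERENT_TO_NONADHERENT: 116,
    },
)


class TestTransitionRR:
    @pytest.mark.parametrize(
        "level,expected",
        [
            (TransitionLevel.NONADHERENT_TO_ADHERENT, 1.30),
            (TransitionLevel.ADHERENT_TO_ADHERENT, 1.05),
        ],
    )
    def test_published_values(self, level, expected):
        est = transition_rr(HTN_TABLE, level)
        assert round(est.estimate, 2) == expected
        assert est.method == "conditional_pairwise"

    def test_identical_proportions_unity(self):
        t = TransitionTable(
            intervention={lvl: 10 for lvl in TransitionLevel},
            control={lvl: 30 for lvl in TransitionLevel},
        )
        est = transition_rr(t, TransitionLevel.NONADHERENT_TO_ADHERENT)
        assert est.estimate == pytest.approx(1.0)

    def test_reference_level_rejected(self):
        with pytest.raises(ValueError):
            transition_rr(HTN_TABLE, REFERENCE_LEVEL)

    def test_adjusted_no_covariates_equals_crude(self):
        rng = np.random.default_rng(17)
        cohort = [
            member(f"p{i}",
                   Group.INTERVENTION if i % 3 else Group.CONTROL,
                   bool(rng.random() < 0.7), bool(rng.random() < 0.7))
            for i in range(400)
        ]
        table = transition_classify(cohort)
        lvl = TransitionLevel.NONADHERENT_TO_ADHERENT
        crude = transition_rr(table, lvl).estimate
        adj = adjusted_transition_rr(cohort, lvl).estimate
        assert abs(adj - crude) / crude < 1e-8

    def test_adjusted_matches_mh_on_restricted_subset(self):
        # two strata of {level, reference} members with common RR 1.5
        rows = []
        strata = [(60, 100, 40, 100), (60, 200, 40, 200)]
        for k, (a, n1, c, n2) in enumerate(strata):
            for i in range(n1):
                rows.append(member(f"s{k}i{i}", Group.INTERVENTION,
                                   i >= a, i < a, z=float(k)))
            for i in range(n2):
                rows.append(member(f"s{k}c{i}", Group.CONTROL,
                                   i >= c, i < c, z=float(k)))
        lvl = TransitionLevel.NONADHERENT_TO_ADHERENT
        adj = adjusted_transition_rr(rows, lvl, covariates=["z"]).estimate
        mh = mantel_haenszel_rr(strata)
        assert mh == pytest.approx(1.5)
        assert abs(adj - mh) < 1e-6


class TestRdNnt:
    def test_published_transition_rd_nnt(self):
        rd, nnt = risk_difference_and_nnt(TwoByTwo(63, 561, 93, 1008))
        assert round(100 * rd.estimate, 1) == 2.0
        assert nnt.estimate == 50

    def test_followup_rd(self):
        rd, _ = risk_difference_and_nnt(TwoByTwo(447, 561, 759, 1008))
        assert round(100 * rd.estimate, 1) == 4.4

    def test_equal_rates_nnt_undefined(self):
        rd, nnt = risk_difference_and_nnt(TwoByTwo(30, 100, 30, 100))
        assert rd.estimate == 0.0
        assert math.isinf(nnt.estimate)

    def test_nnt_from_unrounded_rd(self):
        # RD = 0.021 -> NNT round(47.6) = 48, not 1/0.02 = 50
        rd, nnt = risk_difference_and_nnt(TwoByTwo(21, 1000, 0, 1000))
        assert nnt.estimate == round(1 / rd.estimate)


class TestBaselineTable:
    def _frame(self, rng, n=200, shift=0.0):
        return pd.DataFrame({
            "group": ["intervention"] * n + ["control"] * n,
            "age": np.r_[rng.normal(60, 10, n), rng.normal(60 + shift, 10, n)],
            "visits": np.r_[rng.lognormal(1, 0.5, n), rng.lognormal(1, 0.5, n)],
            "diabetes": rng.random(2 * n) < 0.25,
        })

    def test_identical_groups_p_one(self):
        frame = pd.DataFrame({
            "group": ["intervention"] * 10 + ["control"] * 10,
            "age": list(range(10)) * 2,
        })
        out = baseline_table(frame, [VariableSpec("age",
                                                  "continuous_symmetric")])
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_published_diabetes_chi_square(self):
        frame = pd.DataFrame({
            "group": ["intervention"] * 561 + ["control"] * 1008,
            "diabetes": [True] * 160 + [False] * 401
            + [True] * 231 + [False] * 777,
        })
        out = baseline_table(frame, [VariableSpec("diabetes", "categorical")])
        assert round(out.loc[0, "p"], 2) == 0.01

    def test_chi_square_closed_form(self):
        # 2x2 [[30,10],[20,20]]: X2 = 80*400^2/(40*40*50*30) = 16/3
        frame = pd.DataFrame({
            "group": ["intervention"] * 40 + ["control"] * 40,
            "flag": [True] * 30 + [False] * 10 + [True] * 20 + [False] * 20,
        })
        out = baseline_table(frame, [VariableSpec("flag", "categorical")])
        assert out.loc[0, "p"] == pytest.approx(stats.chi2.sf(16 / 3, 1))

    def test_all_zero_column_flagged(self):
        frame = pd.DataFrame({
            "group": ["intervention"] * 5 + ["control"] * 5,
            "flag": [True] * 10,
        })
        out = baseline_table(frame, [VariableSpec("flag", "categorical")])
        assert math.isnan(out.loc[0, "p"])

    def test_kruskal_used_for_asymmetric(self):
        rng = np.random.default_rng(5)
        frame = self._frame(rng)
        out = baseline_table(frame, [VariableSpec("visits",
                                                  "continuous_asymmetric")])
        xi = frame[frame.group == "intervention"]["visits"]
        xc = frame[frame.group == "control"]["visits"]
        assert out.loc[0, "p"] == pytest.approx(stats.kruskal(xi, xc).pvalue)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            VariableSpec("x", "nominal")
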