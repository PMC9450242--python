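"""The stratum estimator, gender adjustment, imputation, and tables."""

import pytest

import twophase as tp
from twophase.cohort import Cohort
from twophase.prevalence import EstimationError, table_value

from conftest import make_participant


class TestStratumEstimator:
    def test_zero_diagnosed_gives_zero(self):
        inp = tp.EstimationInput(d=0, i=10, L=40, N=100)
        assert tp.estimate_stratum_prevalence(inp) == 0.0

    def test_complete_followup_reduces_to_naive_rate(self):
        inp = tp.EstimationInput(d=10, i=10, L=0, N=100)
        assert tp.estimate_stratum_prevalence(inp) == pytest.approx(10.0)

    def test_lost_extrapolated_at_interviewed_rate(self):
        # (3 + 5 * 3/10) / 100 = 4.5%
        inp = tp.EstimationInput(d=3, i=10, L=5, N=100)
        assert tp.estimate_stratum_prevalence(inp) == pytest.approx(4.5)

    def test_linear_increasing_in_lost_count(self):
        vals = [tp.estimate_stratum_prevalence(
            tp.EstimationInput(d=4, i=10, L=L, N=200)) for L in range(0, 50, 5)]
        diffs = [b - a for a, b in zip(vals, vals[1:])]
        assert all(d > 0 for d in diffs)
        assert all(d == pytest.approx(diffs[0]) for d in diffs)

    def test_minimum_interview_base_enforced(self):
        inp = tp.EstimationInput(d=2, i=3, L=5, N=100)
        with pytest.raises(EstimationError, match="below the configured"):
            tp.estimate_stratum_prevalence(inp, min_interview_base=5)

    def test_invalid_counts_rejected(self):
        with pytest.raises(EstimationError):
            tp.EstimationInput(d=5, i=3, L=0, N=100)
        with pytest.raises(EstimationError):
            tp.EstimationInput(d=1, i=60, L=50, N=100)


class TestGenderAdjust:
    @pytest.mark.parametrize("f,m,want", [
        (5.1, 3.3, 4.2),        # alcohol harmful-use strata
        (0.0, 0.0, 0.0),
        (36.4, 17.0, 26.7),     # any-psychiatric strata
    ])
    def test_unweighted_mean(self, f, m, want):
        assert tp.gender_adjust(f, m) == pytest.approx(want)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            tp.gender_adjust(-1.0, 5.0)


class TestImputation:
    def test_zero_reference_fraction_gives_zero_pseudo_cases(self):
        out = tp.impute_cohort1_unscreened({"female": 0.0}, {"female": 80})
        assert out == {"female": 0.0}

    def test_proportionality(self):
        out = tp.impute_cohort1_unscreened({"male": 0.10}, {"male": 50})
        assert out["male"] == pytest.approx(5.0)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(EstimationError):
            tp.impute_cohort1_unscreened({"male": 1.2}, {"male": 10})


def _hand_cohort():
    """4 female + 2 male; two alcohol cases, one lost to interview."""
    people = []
    specs = [
        ("f1", "female", 10, True, 4),    # selected, interviewed, dependent
        ("f2", "female", 8, True, 0),     # selected, interviewed, negative
        ("f3", "female", 7, False, None),  # selected, lost
        ("f4", "female", 0, None, None),   # screen negative
        ("m1", "male", 9, True, 3),
        ("m2", "male", 0, None, None),
    ]
    for pid, gender, audit, interviewed, criteria in specs:
        p = make_participant(pid, gender=gender, audit_score=audit)
        if audit >= 6:
            p.selected_for = {"addis"}
        if interviewed:
            p.interviewed_with = {"addis"}
            from twophase.cohort import InterviewOutcome, SubstanceResult
            p.outcome = InterviewOutcome(substance_results={
                "alcohol": SubstanceResult(
                    dependence_criteria_lifetime=criteria,
                    dependence_criteria_past_year=criteria)})
        elif p.selected_for:
            p.loss_reason = "declined"
        people.append(p)
    return Cohort.from_participants(people)


class TestPrevalenceTable:
    def test_nobody_screen_positive_gives_all_zero(self):
        people = [make_participant(f"p{i}", gender=g)
                  for i, g in enumerate(["female"] * 3 + ["male"] * 3)]
        table = tp.build_prevalence_table(Cohort.from_participants(people))
        assert (table["prevalence"] == 0).all()

    def test_hand_cohort_estimates(self):
        table = tp.build_prevalence_table(_hand_cohort(),
                                          categories=["substance"])
        # girls: d=1 of i=2 interviewed, L=1, N=4 -> (1 + 1*0.5)/4 = 37.5%
        assert table_value(table, "alcohol:dependence", "female") \
            == pytest.approx(37.5)
        # boys: d=1, i=1, L=0, N=2 -> 50%
        assert table_value(table, "alcohol:dependence", "male") \
            == pytest.approx(50.0)
        assert table_value(table, "alcohol:dependence", "adjusted") \
            == pytest.approx(43.75)

    def test_complete_followup_equals_naive_rate(self, noiseless_config):
        cohort, truth = tp.generate_cohort(noiseless_config, seed=3)
        table = tp.build_prevalence_table(cohort)
        g = truth["gender"]
        for gender in ("female", "male"):
            mask = (truth["true_alcohol"] == "dependence") & (g == gender)
            naive = 100.0 * mask.sum() / (g == gender).sum()
            assert table_value(table, "alcohol:dependence", gender) \
                == pytest.approx(naive)

    def test_noiseless_limit_recovers_truth_exactly(self, noiseless_config):
        cohort, truth = tp.generate_cohort(noiseless_config, seed=8)
        table = tp.build_prevalence_table(cohort)
        g = truth["gender"]

        def true_rate(mask, gender):
            sel = g == gender
            return 100.0 * (mask & sel).sum() / sel.sum()

        checks = [
            ("any_substance:dependence",
             truth["true_any_substance"] == "dependence"),
            ("depression:lifetime", truth["true_depression"] == "case"),
            ("aspd:lifetime", truth["true_aspd"] == "case"),
            ("any_psychiatric:lifetime", truth["true_any_psychiatric"]),
            ("gambling:pathological",
             truth["true_gambling"] == "pathological"),
            ("gaming:at_risk", truth["true_gaming"] == "at_risk"),
        ]
        for cat, mask in checks:
            for gender in ("female", "male"):
                assert table_value(table, cat, gender) == pytest.approx(
                    true_rate(mask, gender)), cat

    def test_any_rows_dominate_component_rows(self, default_cohort):
        cohort, _ = default_cohort
        table = tp.build_prevalence_table(cohort, categories=["substance"])
        for stratum in ("female", "male", "adjusted"):
            for level in ("dependence", "harmful_use"):
                any_v = table_value(table, f"any_substance:{level}", stratum)
                for comp in ("alcohol", "cannabis", "other_substances"):
                    assert any_v >= table_value(
                        table, f"{comp}:{level}", stratum) - 1e-9

    def test_imputed_prevalence_tracks_truth(self, default_cohort):
        # single-cohort sanity check that the cohort-1 imputation keeps the
        # gambling estimate in the neighbourhood of the generating truth
        cohort, truth = default_cohort
        table = tp.build_prevalence_table(cohort,
                                          categories=["gambling_gaming"])
        g = truth["gender"]
        mask = truth["true_gambling"].isin(["problem", "pathological"])
        truth_adj = 50.0 * (mask[g == "female"].mean()
                            + mask[g == "male"].mean())
        got = (table_value(table, "gambling:problem", "adjusted")
               + table_value(table, "gambling:pathological", "adjusted"))
        assert abs(got - truth_adj) < 2.5
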