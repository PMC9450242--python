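"""Phi dyads, banding, conditional rates, type-level joint prevalence."""

import numpy as np
import pytest

import twophase as tp
from twophase.cohort import Cohort, InterviewOutcome, SubstanceResult, \
    ModuleResult
from twophase.comorbidity import ComorbidityError
from twophase.prevalence import table_value

from conftest import make_participant


def corrcoef_oracle(a, b, c, d):
    """Pearson correlation of the expanded binary indicators."""
    x = np.array([1] * a + [1] * b + [0] * c + [0] * d)
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
    return np.corrcoef(x, y)[0, 1]


class TestPhiDyad:
    def test_perfect_association(self):
        assert tp.phi_dyad(5, 0, 0, 5).phi == pytest.approx(1.0)

    def test_exact_independence(self):
        stat = tp.phi_dyad(5, 5, 5, 5)
        assert stat.phi == pytest.approx(0.0)
        assert stat.p_value == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # phi = (10*30 - 10*10) / sqrt(20*40*20*40) = 200/800 = 0.25;
        # chi-square 60 * 0.0625 = 3.75 on 1 df
        stat = tp.phi_dyad(10, 10, 10, 30)
        assert stat.phi == pytest.approx(0.25)
        assert stat.p_value == pytest.approx(0.052807511416113, abs=1e-9)
        assert stat.paired_n == 60

    def test_degenerate_margin_signalled(self):
        with pytest.raises(ComorbidityError, match="degenerate"):
            tp.phi_dyad(5, 5, 0, 0)

    @pytest.mark.parametrize("cells", [(3, 2, 4, 9), (1, 7, 2, 5),
                                       (6, 1, 1, 6), (2, 2, 9, 1)])
    def test_matches_indicator_correlation(self, cells):
        stat = tp.phi_dyad(*cells)
        assert stat.phi == pytest.approx(corrcoef_oracle(*cells), abs=1e-12)


class TestBanding:
    @pytest.mark.parametrize("phi,p,want", [
        (0.33, 0.001, "substantial"),
        (0.31, 0.2, "substantial"),      # band ignores significance above 0.30
        (0.25, 0.003, "considerable"),
        (0.30, 0.001, "considerable"),   # boundary: > 0.30 is strict
        (0.20, 0.001, "moderate"),       # boundary: > 0.20 is strict
        (0.15, 0.01, "moderate"),
        (0.05, 0.5, "none"),
        (0.15, 0.8, "none"),
    ])
    def test_band_rule(self, phi, p, want):
        assert tp.band_phi(phi, p) == want

    def test_alpha_configurable(self):
        assert tp.band_phi(0.1, 0.04, alpha=0.01) == "none"
        assert tp.band_phi(0.1, 0.004, alpha=0.01) == "moderate"


class TestConditionalComorbidity:
    def test_published_worked_example(self):
        # c = 2.6, p = 11.7 -> 22% (boys with a SUD having a psychiatric
        # disorder)
        assert tp.conditional_comorbidity(2.6, 11.7) \
            == pytest.approx(22.2222, abs=1e-3)

    def test_zero_joint_gives_zero(self):
        assert tp.conditional_comorbidity(0.0, 8.0) == 0.0

    def test_eleven_observed_pairs_not_computed(self):
        assert tp.conditional_comorbidity(2.6, 11.7, observed_pairs=11) is None
        assert tp.conditional_comorbidity(2.6, 11.7, observed_pairs=12) \
            is not None

    def test_zero_marginal_signalled(self):
        with pytest.raises(ComorbidityError):
            tp.conditional_comorbidity(1.0, 0.0)


def _two_type_cohort():
    """Complete-followup cohort with overlapping SUD and depression cases."""
    people = []
    # 6 with both, 4 SUD only, 4 depression only, 26 neither (half screened
    # positive and interviewed negative to give real interview bases)
    spec = (["both"] * 6 + ["sud"] * 4 + ["dep"] * 4 + ["neg_int"] * 10
            + ["neg"] * 16)
    for i, kind in enumerate(spec):
        gender = "female" if i % 2 == 0 else "male"
        p = make_participant(f"p{i}", gender=gender)
        if kind in ("both", "sud", "neg_int"):
            p.screening.audit_score = 10
            p.selected_for.add("addis")
            p.interviewed_with.add("addis")
        if kind in ("both", "dep", "neg_int"):
            p.screening.mini_screen_flags = {"depression": True}
            p.selected_for.add("mini")
            p.interviewed_with.add("mini")
        out = InterviewOutcome()
        if "addis" in p.interviewed_with:
            crit = 4 if kind in ("both", "sud") else 0
            out.substance_results["alcohol"] = SubstanceResult(
                dependence_criteria_lifetime=crit,
                dependence_criteria_past_year=crit)
        if "mini" in p.interviewed_with:
            pos = kind in ("both", "dep")
            out.mini_results["depression"] = ModuleResult(
                "depression", lifetime=pos, past_year=False)
        if p.interviewed_with:
            p.outcome = out
        people.append(p)
    return Cohort.from_participants(people)


class TestPairComorbidity:
    def test_complete_followup_equals_direct_count(self):
        cohort = _two_type_cohort()
        est = tp.estimate_pair_comorbidity(cohort, "sud", "psychiatric")
        # per gender: 3 of 20 have both -> 15%; gender mean 15%
        assert est.c_female == pytest.approx(15.0)
        assert est.c_male == pytest.approx(15.0)
        assert est.c_total == pytest.approx(15.0)
        assert est.observed_pairs == 6

    def test_disjoint_screen_positives_force_zero(self):
        people = []
        for i in range(10):
            gender = "female" if i % 2 == 0 else "male"
            p = make_participant(f"p{i}", gender=gender)
            if i < 5:
                p.screening.audit_score = 10
                p.selected_for, p.interviewed_with = {"addis"}, {"addis"}
                p.outcome = InterviewOutcome(substance_results={
                    "alcohol": SubstanceResult(
                        dependence_criteria_lifetime=5,
                        dependence_criteria_past_year=5)})
            else:
                p.screening.mini_screen_flags = {"depression": True}
                p.selected_for, p.interviewed_with = {"mini"}, {"mini"}
                p.outcome = InterviewOutcome(mini_results={
                    "depression": ModuleResult("depression", lifetime=True,
                                               past_year=True)})
            people.append(p)
        est = tp.estimate_pair_comorbidity(
            Cohort.from_participants(people), "sud", "psychiatric")
        assert est.c_total == 0.0

    def test_joint_never_exceeds_marginals(self, default_cohort):
        cohort, _ = default_cohort
        table = tp.build_prevalence_table(cohort)
        matrix = tp.comorbidity_matrix(cohort)
        marg = {}
        for g in ("female", "male"):
            marg[("sud", g)] = (
                table_value(table, "any_substance:dependence", g)
                + table_value(table, "any_substance:harmful_use", g))
            marg[("psychiatric", g)] = table_value(
                table, "any_psychiatric:lifetime", g)
        row = matrix[(matrix.type_a == "sud")
                     & (matrix.type_b == "psychiatric")].iloc[0]
        assert row["c_female"] <= marg[("sud", "female")] + 1e-9
        assert row["c_female"] <= marg[("psychiatric", "female")] + 1e-9
        assert row["c_male"] <= marg[("sud", "male")] + 1e-9
        assert row["c_male"] <= marg[("psychiatric", "male")] + 1e-9

    def test_estimated_joint_tracks_analytic_orthant(self):
        # perfect screening/participation, strong latent correlation:
        # the estimate should approach the bivariate-normal orthant mass
        cfg = tp.GeneratorConfig(
            n_female=6000, n_male=6000,
            substance_prevalence={"alcohol": {"female": (0.10, 0.05, 0.0),
                                              "male": (0.10, 0.05, 0.0)}},
            psychiatric_prevalence={"depression": {"female": 0.2,
                                                   "male": 0.2}},
            gambling_prevalence=None, gaming_prevalence=None,
            association={("alcohol", "depression"): 0.5},
            screen_sensitivity={"substance": 1.0, "psychiatric": 1.0,
                                "gambling": 1.0, "gaming": 1.0},
            screen_false_positive={"substance": 0.0, "psychiatric": 0.0,
                                   "gambling": 0.0, "gaming": 0.0},
            participation={"female": 1.0, "male": 1.0},
            cohort1_gambling_gap=False)
        cohort, _ = tp.generate_cohort(cfg, seed=21)
        est = tp.estimate_pair_comorbidity(cohort, "sud", "psychiatric")
        want = 100.0 * tp.joint_probability(cfg, "alcohol", "depression")
        se = 100.0 * np.sqrt(want / 100 * (1 - want / 100) / 12000)
        assert abs(est.c_total - want) < 4 * se


class TestDyadTable:
    def test_rare_disorders_excluded(self, default_cohort):
        cohort, _ = default_cohort
        from twophase.comorbidity import confirmed_indicators
        table = tp.dyad_table(cohort, min_pairs=12)
        ind = confirmed_indicators(cohort)
        counts = (ind == 1).sum()
        present = set(table["disorder_a"]) | set(table["disorder_b"])
        for disorder, count in counts.items():
            if count < 12:
                assert disorder not in present

    def test_min_pairs_threshold_is_effective(self, default_cohort):
        cohort, _ = default_cohort
        few = tp.dyad_table(cohort, min_pairs=10**6)
        assert len(few) == 0

    def test_nested_disorders_have_positive_phi(self):
        cfg = tp.GeneratorConfig(
            n_female=500, n_male=500,
            substance_prevalence={},
            psychiatric_prevalence={"depression": {"female": 0.2,
                                                   "male": 0.2},
                                    "ocd": {"female": 0.2, "male": 0.2}},
            gambling_prevalence=None, gaming_prevalence=None,
            association={("depression", "ocd"): 0.95},
            screen_sensitivity={"substance": 1.0, "psychiatric": 1.0,
                                "gambling": 1.0, "gaming": 1.0},
            screen_false_positive={"substance": 0.0, "psychiatric": 0.0,
                                   "gambling": 0.0, "gaming": 0.0},
            participation={"female": 1.0, "male": 1.0},
            cohort1_gambling_gap=False)
        cohort, _ = tp.generate_cohort(cfg, seed=4)
        table = tp.dyad_table(cohort)
        row = table[(table.disorder_a == "depression")
                    & (table.disorder_b == "ocd")]
        assert len(row) == 1
        assert row.iloc[0]["phi"] > 0.5
        assert row.iloc[0]["band"] == "substantial"
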