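"""Generator contracts: determinism, calibration, analytic oracles."""

import numpy as np
import pandas as pd
import pytest

import twophase as tp
from twophase.simulate import ConfigError, GeneratorConfig


def _minimal_cfg(**kw):
    base = dict(
        substance_prevalence={"alcohol": {"female": (0.08, 0.04, 0.06),
                                          "male": (0.08, 0.04, 0.06)}},
        psychiatric_prevalence={"depression": {"female": 0.15, "male": 0.15}},
        gambling_prevalence=None, gaming_prevalence=None,
        association=None)
    base.update(kw)
    return GeneratorConfig(**base)


class TestDeterminism:
    def test_identical_seeds_identical_cohorts(self, tmp_path):
        cfg = GeneratorConfig()
        c1, t1 = tp.generate_cohort(cfg, seed=13)
        c2, t2 = tp.generate_cohort(cfg, seed=13)
        pd.testing.assert_frame_equal(c1.df, c2.df)
        pd.testing.assert_frame_equal(t1, t2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        tp.write_cohort(c1, p1)
        tp.write_cohort(c2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        cfg = GeneratorConfig()
        c1, _ = tp.generate_cohort(cfg, seed=1)
        c2, _ = tp.generate_cohort(cfg, seed=2)
        assert not c1.df.equals(c2.df)

    def test_seed_required(self):
        with pytest.raises(ConfigError, match="seed"):
            tp.generate_cohort(GeneratorConfig())


class TestConfigValidation:
    def test_rejects_unknown_substance(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(substance_prevalence={
                "coffee": {"female": (0.1, 0, 0), "male": (0.1, 0, 0)}})

    def test_rejects_non_psd_association(self):
        cfg = _minimal_cfg(association=np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ConfigError, match="positive semi-definite"):
            cfg.association_matrix()

    def test_rejects_wrong_shape_association(self):
        cfg = _minimal_cfg(association=np.eye(3))
        with pytest.raises(ConfigError, match="association matrix"):
            cfg.association_matrix()


class TestCalibration:
    def test_zero_prevalence_means_no_cases_or_true_selections(self):
        cfg = _minimal_cfg(
            substance_prevalence={"alcohol": {"female": (0, 0, 0),
                                              "male": (0, 0, 0)}},
            psychiatric_prevalence={"depression": {"female": 0.0,
                                                   "male": 0.0}},
            screen_false_positive={"substance": 0.0, "psychiatric": 0.0,
                                   "gambling": 0.0, "gaming": 0.0})
        cohort, truth = tp.generate_cohort(cfg, seed=6)
        assert (truth["true_alcohol"] == "none").all()
        assert not cohort.df["sel_addis"].any()
        # remaining selections can only come from the percentile-based
        # supplementary scales (false positives by construction)
        sel_mini = cohort.df["sel_mini"].fillna(False)
        assert sel_mini.mean() < 0.35

    def test_screen_sensitivity_and_specificity_match_config(self):
        cfg = _minimal_cfg(n_female=10000, n_male=10000,
                           screen_sensitivity={"substance": 0.85,
                                               "psychiatric": 1.0,
                                               "gambling": 1.0,
                                               "gaming": 1.0},
                           screen_false_positive={"substance": 0.10,
                                                  "psychiatric": 0.0,
                                                  "gambling": 0.0,
                                                  "gaming": 0.0})
        cohort, truth = tp.generate_cohort(cfg, seed=9)
        pos = (truth["true_alcohol"] != "none").to_numpy()
        sel = cohort.df["sel_addis"].to_numpy(dtype=bool)
        sens = sel[pos].mean()
        fpr = sel[~pos].mean()
        assert abs(sens - 0.85) < 3 * np.sqrt(0.85 * 0.15 / pos.sum())
        assert abs(fpr - 0.10) < 3 * np.sqrt(0.1 * 0.9 / (~pos).sum())

    def test_attrition_matches_participation_config(self):
        cfg = GeneratorConfig(n_female=4000, n_male=4000)
        cohort, _ = tp.generate_cohort(cfg, seed=12)
        df = cohort.df
        sel_any = df[[f"sel_{k}" for k in ("addis", "mini", "nods", "igds")]] \
            .fillna(False).any(axis=1)
        int_any = df[[f"int_{k}" for k in ("addis", "mini", "nods", "igds")]] \
            .fillna(False).any(axis=1)
        for g, want in (("female", 0.549), ("male", 0.460)):
            m = (df["gender"] == g) & sel_any
            got = (int_any & m).sum() / m.sum()
            assert abs(got - want) < 3 * np.sqrt(want * (1 - want) / m.sum())

    def test_independent_disorders_have_near_zero_phi(self):
        cfg = _minimal_cfg(
            n_female=20000, n_male=20000,
            psychiatric_prevalence={"depression": {"female": 0.2,
                                                   "male": 0.2},
                                    "ocd": {"female": 0.2, "male": 0.2}},
            association=None)
        _, truth = tp.generate_cohort(cfg, seed=14)
        x = (truth["true_depression"] == "case").to_numpy()
        y = (truth["true_ocd"] == "case").to_numpy()
        assert abs(np.corrcoef(x, y)[0, 1]) < 3 / np.sqrt(x.size)

    def test_loss_reasons_only_for_lost(self, default_cohort):
        cohort, _ = default_cohort
        df = cohort.df
        sel = df[[f"sel_{k}" for k in ("addis", "mini", "nods", "igds")]] \
            .fillna(False).to_numpy(dtype=bool)
        itv = df[[f"int_{k}" for k in ("addis", "mini", "nods", "igds")]] \
            .fillna(False).to_numpy(dtype=bool)
        lost = (sel & ~itv).any(axis=1)
        assert (df.loc[lost, "loss_reason"] != "not_applicable").all()
        assert (df.loc[~lost, "loss_reason"] == "not_applicable").all()


class TestJointProbability:
    def test_independence_factorises(self):
        cfg = _minimal_cfg(
            psychiatric_prevalence={"depression": {"female": 0.2,
                                                   "male": 0.1}})
        got = tp.joint_probability(cfg, "alcohol", "depression")
        want = np.mean([0.12 * 0.2, 0.12 * 0.1])
        assert got == pytest.approx(want, abs=1e-9)

    def test_comonotone_limit_is_min_of_marginals(self):
        cfg = _minimal_cfg(
            psychiatric_prevalence={"depression": {"female": 0.12,
                                                   "male": 0.12}},
            association={("alcohol", "depression"): 1.0})
        got = tp.joint_probability(cfg, "alcohol", "depression")
        assert got == pytest.approx(0.12, abs=1e-9)

    def test_matches_monte_carlo(self):
        cfg = _minimal_cfg(
            substance_prevalence={"alcohol": {"female": (0.06, 0.04, 0.0),
                                              "male": (0.06, 0.04, 0.0)}},
            psychiatric_prevalence={"depression": {"female": 0.2,
                                                   "male": 0.2}},
            association={("alcohol", "depression"): 0.5})
        want = tp.joint_probability(cfg, "alcohol", "depression")
        rng = np.random.default_rng(123)
        n = 10**6
        z1 = rng.standard_normal(n)
        z2 = 0.5 * z1 + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        from scipy import stats
        mc = ((z1 > stats.norm.isf(0.10)) & (z2 > stats.norm.isf(0.20))).mean()
        assert abs(want - mc) < 3 * np.sqrt(mc * (1 - mc) / n)
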