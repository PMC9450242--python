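"""Synthetic two-phase cohorts with known ground truth.

The generator emulates the study design end to end: two gender strata,
two school-year cohorts (one lacking the gambling/gaming screening unless
a participant was contacted for a substance-use or psychiatric interview),
latent multivariate-normal disorder liabilities thresholded at quantiles
matching configured true prevalences, screening indicators with
configurable sensitivity and false-positive rate at the study cut-offs,
selection computed by the real screening rules, Bernoulli interview
participation, and interview outcomes consistent with the latent truth.

A ``TruthRecord`` table carries every latent state so estimator-recovery
tests can compare estimates against the generating truth.  A fixed seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    COLUMNS,
    Cohort,
    GAMING_BANDS,
    GENDERS,
    INSTRUMENTS,
    MODULE_TIMEFRAMES,
    MODULES,
    SUBSTANCES,
    SYNDROME_MODULES,
    SYNDROMES,
)
from .screening import CutoffPolicy, SampleThresholds, percentile_cutoff, \
    indicated_module_frame, selection_frame

#: False-positive rate of the stand-alone ADHD/ADD self-report question.
ADHD_SELF_REPORT_FP = 0.02
#: Mean of the Poisson psychosomatic-problems and delinquency scores
#: (supplementary indicator scales, drawn independent of latent truth).
PSP_MEAN = 3.0
DELINQUENCY_MEAN = 0.6

_SUBSTANCE_DEFAULTS = {
    "alcohol": {"female": (0.104, 0.051, 0.114),
                "male": (0.071, 0.033, 0.124)},
    "cannabis": {"female": (0.009, 0.001, 0.017),
                 "male": (0.014, 0.002, 0.024)},
    "other": {"female": (0.006, 0.000, 0.021),
              "male": (0.005, 0.007, 0.031)},
}

_PSYCHIATRIC_DEFAULTS = {
    "depression": {"female": 0.222, "male": 0.067},
    "suicidality": {"female": 0.044, "male": 0.049},
    "manic_episode": {"female": 0.017, "male": 0.021},
    "panic_disorder": {"female": 0.078, "male": 0.024},
    "agoraphobia": {"female": 0.023, "male": 0.002},
    "social_anxiety": {"female": 0.057, "male": 0.012},
    "ocd": {"female": 0.055, "male": 0.024},
    "ptsd": {"female": 0.006, "male": 0.0},
    "gad": {"female": 0.021, "male": 0.004},
    "psychotic_syndrome": {"female": 0.024, "male": 0.031},
    "affective_psychosis": {"female": 0.006, "male": 0.0},
    "anorexia": {"female": 0.006, "male": 0.0},
    "bulimia": {"female": 0.008, "male": 0.0},
    "aspd": {"female": 0.006, "male": 0.010},
    "adhd": {"female": 0.015, "male": 0.012},
    "add": {"female": 0.015, "male": 0.005},
}

_GAMBLING_DEFAULTS = {"female": (0.007, 0.0, 0.004),
                      "male": (0.097, 0.034, 0.024)}
_GAMING_DEFAULTS = {"female": (0.002, 0.0), "male": (0.057, 0.023)}


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the study's structure: 528 girls and 421 boys
    screened, cohort 1 (roughly 48.5% of the sample) lacking the
    gambling/gaming screening, per-gender true prevalences seeded from the
    study's estimated values, interview participation of 54.9% (girls) and
    46.0% (boys) among the selected, and a uniform latent correlation of
    0.2 between disorders.
    """

    n_female: int = 528
    n_male: int = 421
    cohort1_fraction: float = 460 / 949
    substance_prevalence: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in _SUBSTANCE_DEFAULTS.items()})
    psychiatric_prevalence: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in _PSYCHIATRIC_DEFAULTS.items()})
    gambling_prevalence: Optional[dict] = field(
        default_factory=lambda: dict(_GAMBLING_DEFAULTS))
    gaming_prevalence: Optional[dict] = field(
        default_factory=lambda: dict(_GAMING_DEFAULTS))
    association: object = 0.2
    screen_sensitivity: dict = field(default_factory=lambda: {
        "substance": 0.95, "psychiatric": 0.95,
        "gambling": 0.95, "gaming": 0.95})
    screen_false_positive: dict = field(default_factory=lambda: {
        "substance": 0.06, "psychiatric": 0.10,
        "gambling": 0.33, "gaming": 0.12})
    participation: dict = field(default_factory=lambda: {
        "female": 0.549, "male": 0.460})
    cohort1_gambling_gap: bool = True
    past_year_given_lifetime: float = 0.5
    harmful_remission: float = 0.3
    policy: CutoffPolicy = field(default_factory=CutoffPolicy)
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n_female <= 0 or self.n_male <= 0:
            raise ConfigError("stratum sizes must be positive")
        for s in self.substance_prevalence:
            if s not in SUBSTANCES:
                raise ConfigError(f"unknown substance group {s!r}")
        for m in self.psychiatric_prevalence:
            if m not in MODULES:
                raise ConfigError(f"unknown psychiatric module {m!r}")
        for d in (self.screen_sensitivity, self.screen_false_positive,
                  self.participation):
            for v in d.values():
                if not 0 <= v <= 1:
                    raise ConfigError(f"probability {v} outside [0, 1]")

    # -- latent structure ---------------------------------------------------

    @property
    def disorder_names(self) -> list[str]:
        names = list(self.substance_prevalence)
        names += list(self.psychiatric_prevalence)
        if self.gambling_prevalence is not None:
            names.append("gambling")
        if self.gaming_prevalence is not None:
            names.append("gaming")
        return names

    def association_matrix(self) -> np.ndarray:
        names = self.disorder_names
        k = len(names)
        a = self.association
        if a is None:
            mat = np.eye(k)
        elif np.isscalar(a):
            mat = np.full((k, k), float(a))
            np.fill_diagonal(mat, 1.0)
        elif isinstance(a, dict):
            mat = np.eye(k)
            idx = {n: i for i, n in enumerate(names)}
            for (x, y), r in a.items():
                mat[idx[x], idx[y]] = mat[idx[y], idx[x]] = float(r)
        else:
            mat = np.asarray(a, dtype=float)
            if mat.shape != (k, k):
                raise ConfigError(
                    f"association matrix must be {k}x{k} for disorders "
                    f"{names}")
        if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 1.0):
            raise ConfigError("association must be symmetric with unit "
                              "diagonal")
        if np.linalg.eigvalsh(mat).min() < -1e-8:
            raise ConfigError("association matrix is not positive "
                              "semi-definite")
        return mat

    def case_probability(self, disorder: str, gender: str) -> float:
        """Case-level marginal probability (the comorbidity definitions)."""
        if disorder in self.substance_prevalence:
            dep, harm, _ = self.substance_prevalence[disorder][gender]
            return dep + harm
        if disorder in self.psychiatric_prevalence:
            return self.psychiatric_prevalence[disorder][gender]
        if disorder == "gambling" and self.gambling_prevalence is not None:
            _, prob, path = self.gambling_prevalence[gender]
            return prob + path
        if disorder == "gaming" and self.gaming_prevalence is not None:
            return self.gaming_prevalence[gender][1]
        raise ConfigError(f"unknown disorder {disorder!r}")


# ---------------------------------------------------------------------------

def _tiered(z: np.ndarray, tiers: list[tuple[str, float]],
            base: str) -> np.ndarray:
    """Assign ordinal categories by thresholding a latent normal.

    ``tiers`` lists (category, probability) from most to least severe; the
    top ``p1`` of the latent distribution gets the first category, the next
    ``p2`` the second, and so on.
    """
    out = np.full(z.shape, base, dtype=object)
    cum = 0.0
    prev = np.full(z.shape, False)
    for cat, p in tiers:
        cum += p
        sel = (z > stats.norm.isf(min(cum, 1.0))) & ~prev
        out[sel] = cat
        prev |= sel
    return out


def _draw_truth(cfg: GeneratorConfig, rng: np.random.Generator,
                gender: np.ndarray) -> pd.DataFrame:
    names = cfg.disorder_names
    n = gender.size
    chol = np.linalg.cholesky(
        cfg.association_matrix() + 1e-10 * np.eye(len(names)))
    z = rng.standard_normal((n, len(names))) @ chol.T
    truth = pd.DataFrame(index=np.arange(n))
    for j, name in enumerate(names):
        col = np.full(n, "none", dtype=object)
        for g in GENDERS:
            m = gender == g
            if name in cfg.substance_prevalence:
                dep, harm, sub = cfg.substance_prevalence[name][g]
                col[m] = _tiered(z[m, j], [("dependence", dep),
                                           ("harmful_use", harm),
                                           ("sub_threshold", sub)], "none")
            elif name in cfg.psychiatric_prevalence:
                p = cfg.psychiatric_prevalence[name][g]
                col[m] = np.where(z[m, j] > stats.norm.isf(p), "case", "none")
            elif name == "gambling":
                ar, pr, pa = cfg.gambling_prevalence[g]
                col[m] = _tiered(z[m, j], [("pathological", pa),
                                           ("problem", pr),
                                           ("at_risk", ar)], "none")
            elif name == "gaming":
                ar, pa = cfg.gaming_prevalence[g]
                col[m] = _tiered(z[m, j], [("pathological", pa),
                                           ("at_risk", ar)], "none")
        truth[f"true_{name}"] = col
    return truth


def _bernoulli_by_truth(rng, positive: np.ndarray, p_pos: float,
                        p_neg: float) -> np.ndarray:
    u = rng.random(positive.size)
    return np.where(positive, u < p_pos, u < p_neg)


def generate_cohort(cfg: GeneratorConfig, seed: Optional[int] = None
                    ) -> tuple[Cohort, pd.DataFrame]:
    """Generate one cohort plus its truth record.

    ``seed`` overrides ``cfg.seed``; one of the two must be set.
    """
    if seed is None:
        seed = cfg.seed
    if seed is None:
        raise ConfigError("a seed is required (cfg.seed or the seed argument)")
    rng = np.random.default_rng(seed)
    n = cfg.n_female + cfg.n_male
    gender = np.array(["female"] * cfg.n_female + ["male"] * cfg.n_male)
    cohort_lab = np.where(rng.random(n) < cfg.cohort1_fraction,
                          "cohort1", "cohort2")
    truth = _draw_truth(cfg, rng, gender)
    truth.insert(0, "participant_id",
                 [f"P{i + 1:04d}" for i in range(n)])
    truth.insert(1, "gender", gender)
    truth.insert(2, "cohort", cohort_lab)

    sens = cfg.screen_sensitivity
    fp = cfg.screen_false_positive
    sub_groups = list(cfg.substance_prevalence)
    modules = list(cfg.psychiatric_prevalence)

    # -- phase-1 screening profiles ----------------------------------------
    sub_pos_true = np.full(n, False)
    for s in sub_groups:
        sub_pos_true |= (truth[f"true_{s}"] != "none").to_numpy()
    screen_sub = _bernoulli_by_truth(rng, sub_pos_true, sens["substance"],
                                     fp["substance"])
    audit = np.where(screen_sub,
                     6 + np.minimum(rng.poisson(3.0, n), 34),
                     np.minimum(rng.poisson(1.0, n), 5))
    dudit = np.where(screen_sub & (rng.random(n) < 0.35),
                     2 + np.minimum(rng.poisson(2.0, n), 42),
                     (rng.random(n) < 0.08).astype(int))
    surnc = np.where(screen_sub & (rng.random(n) < 0.30),
                     5 + rng.poisson(1.0, n),
                     np.minimum(rng.poisson(0.5, n), 4))

    scr_flags = {}
    for s in SYNDROMES:
        mapped = np.full(n, False)
        for m in SYNDROME_MODULES[s]:
            if m in modules:
                mapped |= (truth[f"true_{m}"] == "case").to_numpy()
        scr_flags[s] = _bernoulli_by_truth(rng, mapped, sens["psychiatric"],
                                           fp["psychiatric"])
    adhd_true = np.full(n, False)
    for m in ("adhd", "add"):
        if m in modules:
            adhd_true |= (truth[f"true_{m}"] == "case").to_numpy()
    adhd_self = _bernoulli_by_truth(rng, adhd_true, sens["psychiatric"],
                                    ADHD_SELF_REPORT_FP)
    psp = rng.poisson(PSP_MEAN, n)
    # delinquency is the sole screening route to the ASPD module: true ASPD
    # cases get a boost far above the 90th-percentile cut-off (when the
    # sensitivity draw hits); otherwise the scale is background noise
    aspd_true = ((truth["true_aspd"] == "case").to_numpy()
                 if "aspd" in modules else np.full(n, False))
    aspd_hit = _bernoulli_by_truth(rng, aspd_true, sens["psychiatric"], 0.0)
    delinq = rng.poisson(DELINQUENCY_MEAN, n) + 8 * aspd_hit

    if cfg.gambling_prevalence is not None:
        gam_true = (truth["true_gambling"] != "none").to_numpy()
        screen_gam = _bernoulli_by_truth(rng, gam_true, sens["gambling"],
                                         fp["gambling"])
    else:
        screen_gam = rng.random(n) < fp["gambling"]
    which = rng.random(n)
    ever_gambled = screen_gam & (which < 0.9)
    ever_paid = screen_gam & ((which >= 0.9) | (rng.random(n) < 0.4))

    if cfg.gaming_prevalence is not None:
        gaming_true = (truth["true_gaming"] != "none").to_numpy()
        screen_gaming = _bernoulli_by_truth(rng, gaming_true, sens["gaming"],
                                            fp["gaming"])
    else:
        screen_gaming = rng.random(n) < fp["gaming"]
    high_band = np.where(rng.random(n) < 0.6, "3_4h", "5h_plus")
    low_band = np.asarray(GAMING_BANDS)[:3][
        rng.choice(3, size=n, p=[0.3, 0.4, 0.3])]
    gaming_band = np.where(screen_gaming, high_band, low_band)

    df = pd.DataFrame({c: pd.NA for c in COLUMNS}, index=np.arange(n))
    df["participant_id"] = truth["participant_id"]
    df["gender"] = gender
    df["cohort"] = cohort_lab
    df["audit"] = audit
    df["dudit"] = dudit
    df["surnc"] = surnc
    df["psp"] = psp
    df["delinquency"] = delinq
    for s in SYNDROMES:
        df[f"scr_{s}"] = scr_flags[s]
    df["adhd_self_report"] = adhd_self
    df["ever_gambled_money"] = pd.array(ever_gambled, dtype="boolean")
    df["ever_paid_in_game"] = pd.array(ever_paid, dtype="boolean")
    df["gaming_hours_band"] = pd.array(gaming_band, dtype="object")

    # -- selection (real screening rules) and participation ----------------
    thresholds = SampleThresholds(
        psp=percentile_cutoff(psp, cfg.policy.psp_percentile),
        delinquency=percentile_cutoff(delinq,
                                      cfg.policy.delinquency_percentile))
    sel = selection_frame(df, cfg.policy, thresholds)
    part_p = pd.Series(gender).map(cfg.participation).to_numpy(float)
    participates = rng.random(n) < part_p
    for k in INSTRUMENTS:
        df[f"sel_{k}"] = sel[k].to_numpy()
        df[f"int_{k}"] = sel[k].to_numpy() & participates

    # cohort-1 gambling/gaming screening gap: only those contacted for an
    # ADDIS/M.I.N.I. interview were screened for gambling and gaming
    if cfg.cohort1_gambling_gap:
        contacted = (df["int_addis"] | df["int_mini"]).astype(bool)
        gap = (cohort_lab == "cohort1") & ~contacted.to_numpy()
        df.loc[gap, ["ever_gambled_money", "ever_paid_in_game",
                     "gaming_hours_band"]] = pd.NA
        df.loc[gap, ["sel_nods", "sel_igds", "int_nods", "int_igds"]] = False

    lost = np.full(n, False)
    for k in INSTRUMENTS:
        lost |= (df[f"sel_{k}"] & ~df[f"int_{k}"]).to_numpy(dtype=bool)
    reasons = np.asarray(["not_reached", "declined", "unknown"])[
        rng.choice(3, size=n, p=[0.55, 0.43, 0.02])]
    df["loss_reason"] = np.where(lost, reasons, "not_applicable")

    # -- phase-2 interview outcomes ----------------------------------------
    int_addis = df["int_addis"].to_numpy(dtype=bool)
    crit_dep = 3 + rng.binomial(3, 0.4, n)
    crit_sub = 1 + (rng.random(n) < 0.5)
    crit_harm = rng.binomial(2, 0.4, n)
    harm_with_dep = rng.random(n) < 0.5
    remits = rng.random(n) < cfg.harmful_remission
    for s in SUBSTANCES:
        cat = (truth[f"true_{s}"].to_numpy() if s in sub_groups
               else np.full(n, "none", dtype=object))
        dep_lt = np.select(
            [cat == "dependence", cat == "sub_threshold", cat == "harmful_use"],
            [crit_dep, crit_sub, crit_harm], 0)
        harm_lt = np.isin(cat, ["harmful_use"]) | \
            ((cat == "dependence") & harm_with_dep)
        harm_py = harm_lt & ~remits
        df.loc[int_addis, f"{s}_dep_lt"] = dep_lt[int_addis]
        df.loc[int_addis, f"{s}_harm_lt"] = harm_lt[int_addis]
        df.loc[int_addis, f"{s}_dep_py"] = dep_lt[int_addis]
        df.loc[int_addis, f"{s}_harm_py"] = harm_py[int_addis]

    int_mini = df["int_mini"].to_numpy(dtype=bool)
    indicated = indicated_module_frame(df, thresholds)
    py_keep = rng.random((n, len(MODULES))) < cfg.past_year_given_lifetime
    for j, m in enumerate(MODULES):
        true_m = ((truth[f"true_{m}"] == "case").to_numpy()
                  if m in modules else np.full(n, False))
        assessed = int_mini & indicated[m].to_numpy()
        tf = MODULE_TIMEFRAMES[m]
        if "lifetime" in tf:
            df.loc[assessed, f"{m}_lt"] = true_m[assessed]
        if "past_year" in tf:
            py = true_m & (py_keep[:, j] if "lifetime" in tf
                           else np.full(n, True))
            df.loc[assessed, f"{m}_py"] = py[assessed]

    int_nods = df["int_nods"].to_numpy(dtype=bool)
    if cfg.gambling_prevalence is not None:
        gcat = truth["true_gambling"].to_numpy()
    else:
        gcat = np.full(n, "none", dtype=object)
    nods = np.select(
        [gcat == "pathological", gcat == "problem", gcat == "at_risk"],
        [5 + rng.integers(0, 6, n), 3 + rng.integers(0, 2, n),
         1 + rng.integers(0, 2, n)], 0)
    df.loc[int_nods, "nods_score"] = nods[int_nods]

    int_igds = df["int_igds"].to_numpy(dtype=bool)
    if cfg.gaming_prevalence is not None:
        icat = truth["true_gaming"].to_numpy()
    else:
        icat = np.full(n, "none", dtype=object)
    igds = np.select(
        [icat == "pathological", icat == "at_risk"],
        [21 + rng.integers(0, 25, n), 17 + rng.integers(0, 4, n)],
        9 + rng.integers(0, 8, n))
    df.loc[int_igds, "igds_score"] = igds[int_igds]

    # derived truth summaries used by recovery tests
    order = {"none": 0, "sub_threshold": 1, "harmful_use": 2, "dependence": 3}
    best = np.zeros(n, dtype=int)
    for s in sub_groups:
        best = np.maximum(best,
                          truth[f"true_{s}"].map(order).to_numpy())
    inv = {v: k for k, v in order.items()}
    truth["true_any_substance"] = [inv[v] for v in best]
    any_psych = np.full(n, False)
    for m in modules:
        any_psych |= (truth[f"true_{m}"] == "case").to_numpy()
    truth["true_any_psychiatric"] = any_psych
    truth["true_sud"] = best >= 2
    truth["screen_positive_substance"] = screen_sub
    truth["participates"] = participates

    return Cohort(df), truth


# ---------------------------------------------------------------------------

def joint_probability(cfg: GeneratorConfig, type_a: str, type_b: str
                      ) -> float:
    """Analytic probability that one person has both disorders (case level).

    Bivariate-normal upper-orthant probability above the two case
    thresholds, computed per gender and averaged (the analytic expectation
    of the gender-adjusted estimated comorbidity, as a fraction).
    """
    names = cfg.disorder_names
    mat = cfg.association_matrix()
    ia, ib = names.index(type_a), names.index(type_b)
    rho = float(mat[ia, ib])
    out = []
    for g in GENDERS:
        pa = cfg.case_probability(type_a, g)
        pb = cfg.case_probability(type_b, g)
        if pa == 0 or pb == 0:
            out.append(0.0)
            continue
        ta, tb = stats.norm.isf(pa), stats.norm.isf(pb)
        if rho >= 1.0 - 1e-12:
            p = float(stats.norm.sf(max(ta, tb)))
        elif rho <= -1.0 + 1e-12:
            p = float(max(0.0, stats.norm.cdf(-tb) - stats.norm.cdf(ta)))
        else:
            p = float(stats.multivariate_normal(
                mean=[0.0, 0.0],
                cov=[[1.0, rho], [rho, 1.0]]).cdf([-ta, -tb]))
        out.append(p)
    return float(np.mean(out))
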