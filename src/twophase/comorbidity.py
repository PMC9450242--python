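"""Pairwise comorbidity: estimated joint prevalence, conditional rates,
and dyadic phi statistics on confirmed data.

Type-level comorbidity (substance use disorder, psychiatric disorder,
gambling problem, gaming disorder) is estimated under the same screening
assumptions as the marginal prevalences: screen-negative on either member
of a dyad means not comorbid, and those selected for both interviews but
not completing both are extrapolated at the both-interviewed joint rate.
Case definitions at this level combine dependence and harmful use (not
sub-threshold) for substances, problem and pathological gambling (not
at-risk), and only pathological gaming.

Dyads of specific disorders use confirmed data only (screening plus
interview, no lost-to-interview extrapolation) and are summarised with the
Pearson phi coefficient, tested via the chi-square statistic ``n * phi**2``
on one degree of freedom, and banded: phi > 0.30 substantial, > 0.20
considerable, otherwise moderate if significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt
from typing import Optional

import pandas as pd
from scipy import stats

from .cohort import Cohort, GENDERS, MODULES, SUBSTANCES
from . import scoring
from .screening import CutoffPolicy, derive_thresholds, indicated_module_frame

#: Problem types eligible for type-level comorbidity.
PROBLEM_TYPES = ("sud", "psychiatric", "gambling", "gaming")

PHI_SUBSTANTIAL = 0.30
PHI_CONSIDERABLE = 0.20

#: Minimum observed comorbid cases for conditional calculations (rule of thumb).
MIN_PAIRS = 12


class ComorbidityError(ValueError):
    pass


@dataclass
class ComorbidityEstimate:
    pair: tuple[str, str]
    c_female: float
    c_male: float
    c_total: float
    observed_pairs: int


@dataclass
class DyadStat:
    pair: tuple[str, str]
    phi: float
    p_value: float
    paired_n: int
    band: str


# ---------------------------------------------------------------------------
# Type-level case/screen/interview columns

def _type_columns(df: pd.DataFrame) -> dict[str, dict[str, pd.Series]]:
    sud = scoring.best_category_series(df, SUBSTANCES, "lifetime")
    gambling = scoring.gambling_category_series(df)
    gaming = scoring.gaming_category_series(df)
    return {
        "sud": {
            "case": sud.isin(["dependence", "harmful_use"]).astype("boolean")
                       .where(sud.notna()),
            "selected": df["sel_addis"].fillna(False).astype(bool),
            "interviewed": df["int_addis"].fillna(False).astype(bool),
        },
        "psychiatric": {
            "case": scoring.psychiatric_any_series(df),
            "selected": df["sel_mini"].fillna(False).astype(bool),
            "interviewed": df["int_mini"].fillna(False).astype(bool),
        },
        "gambling": {
            "case": gambling.isin(["problem", "pathological"])
                       .astype("boolean").where(gambling.notna()),
            "selected": df["sel_nods"].fillna(False).astype(bool),
            "interviewed": df["int_nods"].fillna(False).astype(bool),
        },
        "gaming": {
            "case": (gaming == "pathological").astype("boolean")
                       .where(gaming.notna()),
            "selected": df["sel_igds"].fillna(False).astype(bool),
            "interviewed": df["int_igds"].fillna(False).astype(bool),
        },
    }


def estimate_pair_comorbidity(cohort: Cohort, type_a: str, type_b: str
                              ) -> ComorbidityEstimate:
    """Estimated joint lifetime prevalence of two problem types (percent).

    Per gender: screen-negative on either type forces non-comorbid; the
    both-interviewed subgroup is counted directly; those selected for both
    but not interviewed with both are extrapolated at the both-interviewed
    joint rate.  The total is the gender mean.
    """
    for t in (type_a, type_b):
        if t not in PROBLEM_TYPES:
            raise ComorbidityError(f"unknown problem type {t!r}")
    df = cohort.df
    cols = _type_columns(df)
    a, b = cols[type_a], cols[type_b]
    both_sel = a["selected"] & b["selected"]
    both_int = a["interviewed"] & b["interviewed"]
    joint = (a["case"].fillna(False) & b["case"].fillna(False)).astype(bool)
    per_gender = {}
    observed = 0
    for g in GENDERS:
        mask = df["gender"] == g
        K = int((both_int & mask).sum())
        J = int((joint & both_int & mask).sum())
        M = int((both_sel & ~both_int & mask).sum())
        N = int(mask.sum())
        observed += J
        if J == 0:
            per_gender[g] = 0.0
            continue
        if K == 0:
            raise ComorbidityError(
                f"no both-interviewed base for {type_a}/{type_b} in {g}")
        per_gender[g] = 100.0 * (J + M * J / K) / N
    return ComorbidityEstimate(
        pair=(type_a, type_b),
        c_female=per_gender["female"], c_male=per_gender["male"],
        c_total=(per_gender["female"] + per_gender["male"]) / 2.0,
        observed_pairs=observed)


def comorbidity_matrix(cohort: Cohort) -> pd.DataFrame:
    """All type pairs, long format (the type-level comorbidity table)."""
    records = []
    for a, b in combinations(PROBLEM_TYPES, 2):
        est = estimate_pair_comorbidity(cohort, a, b)
        records.append({
            "type_a": a, "type_b": b,
            "c_female": est.c_female, "c_male": est.c_male,
            "c_total": est.c_total, "observed_pairs": est.observed_pairs})
    return pd.DataFrame.from_records(records)


def conditional_comorbidity(c: float, p: float,
                            observed_pairs: Optional[int] = None,
                            min_pairs: int = MIN_PAIRS) -> Optional[float]:
    """Share (percent) of those with one problem type who also have another.

    Computed as ``100 * c / p`` where ``c`` is the joint and ``p`` the
    marginal prevalence, both in percent.  Returns ``None`` (the explicit
    not-computed marker) when ``observed_pairs`` is given and falls below
    ``min_pairs``; passing ``observed_pairs=None`` asserts the rule holds.
    Raises when ``p`` is zero.
    """
    if p == 0:
        raise ComorbidityError("conditional comorbidity undefined at p = 0")
    if observed_pairs is not None and observed_pairs < min_pairs:
        return None
    return 100.0 * c / p


# ---------------------------------------------------------------------------
# Dyadic phi on confirmed data

def phi_dyad(a: int, b: int, c: int, d: int,
             alpha: float = 0.05) -> DyadStat:
    """Phi coefficient and significance for a 2x2 table.

    Cells are ``a`` both-positive, ``b`` first-only, ``c`` second-only,
    ``d`` both-negative.  phi = (ad - bc) / sqrt(row and column margin
    product); the p-value comes from ``n * phi**2`` on one chi-square
    degree of freedom (no continuity correction).
    """
    if min(a, b, c, d) < 0:
        raise ComorbidityError("cell counts must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise ComorbidityError("empty contingency table")
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise ComorbidityError("degenerate margin: phi undefined")
    phi = (a * d - b * c) / sqrt(denom)
    p = float(stats.chi2.sf(n * phi * phi, df=1))
    return DyadStat(pair=("", ""), phi=phi, p_value=p, paired_n=n,
                    band=band_phi(phi, p, alpha))


def band_phi(phi: float, p_value: float, alpha: float = 0.05) -> str:
    """Interpretation band for a phi coefficient."""
    if phi > PHI_SUBSTANTIAL:
        return "substantial"
    if phi > PHI_CONSIDERABLE:
        return "considerable"
    if p_value < alpha:
        return "moderate"
    return "none"


def confirmed_indicators(cohort: Cohort,
                         policy: Optional[CutoffPolicy] = None
                         ) -> pd.DataFrame:
    """Per-participant disorder indicators from confirmed data only.

    1 = case confirmed by interview; 0 = interview-negative or
    screen-negative (no screening indication is taken as no diagnosis);
    <NA> = selected for the relevant interview/module but not assessed, or
    never screened (the cohort-1 gambling/gaming gap).  Alcohol use disorder
    (AUD) is kept separate; all other substance groups collapse to drug use
    disorder (DUD); ADHD and ADD are combined.
    """
    df = cohort.df
    policy = policy or CutoffPolicy()
    thresholds = derive_thresholds(cohort, policy)
    indicated = indicated_module_frame(df, thresholds)
    sel_addis = df["sel_addis"].fillna(False).astype(bool)
    int_addis = df["int_addis"].fillna(False).astype(bool)
    sel_mini = df["sel_mini"].fillna(False).astype(bool)
    int_mini = df["int_mini"].fillna(False).astype(bool)

    out = pd.DataFrame(index=df.index)

    def _mask(values: pd.Series, pending: pd.Series) -> pd.Series:
        s = values.fillna(False).astype("boolean").astype("Int64")
        s[pending] = pd.NA
        return s

    aud = scoring.substance_category_series(df, "alcohol", "lifetime")
    dud = scoring.best_category_series(
        df, [s for s in SUBSTANCES if s != "alcohol"], "lifetime")
    addis_pending = sel_addis & ~int_addis
    out["aud"] = _mask(aud.isin(["dependence", "harmful_use"]), addis_pending)
    out["dud"] = _mask(dud.isin(["dependence", "harmful_use"]), addis_pending)

    gambling = scoring.gambling_category_series(df)
    unscreened_g = df["ever_gambled_money"].isna()
    pending_g = (df["sel_nods"].fillna(False) & ~df["int_nods"].fillna(False)
                 ).astype(bool) | unscreened_g
    out["gambling"] = _mask(gambling.isin(["problem", "pathological"]),
                            pending_g)
    gaming = scoring.gaming_category_series(df)
    unscreened_i = df["gaming_hours_band"].isna()
    pending_i = (df["sel_igds"].fillna(False) & ~df["int_igds"].fillna(False)
                 ).astype(bool) | unscreened_i
    out["gaming"] = _mask(gaming == "pathological", pending_i)

    module_cols: dict[str, pd.Series] = {}
    for m in MODULES:
        pending = sel_mini & indicated[m] & ~int_mini
        module_cols[m] = _mask(scoring.module_positive_series(df, m), pending)
    for m in MODULES:
        if m in ("adhd", "add"):
            continue
        out[m] = module_cols[m]
    # combined ADHD/ADD: positive if either confirmed positive; unknown if
    # neither positive but either still pending
    pos = ((module_cols["adhd"] == 1).fillna(False)
           | (module_cols["add"] == 1).fillna(False))
    any_na = module_cols["adhd"].isna() | module_cols["add"].isna()
    combined = pd.Series(0, index=df.index, dtype="Int64")
    combined[pos] = 1
    combined[~pos & any_na] = pd.NA
    out["adhd_add"] = combined
    return out


def dyad_table(cohort: Cohort, min_pairs: int = MIN_PAIRS,
               alpha: float = 0.05,
               policy: Optional[CutoffPolicy] = None) -> pd.DataFrame:
    """Phi statistics for all dyads among sufficiently frequent disorders.

    Disorders with fewer than ``min_pairs`` confirmed cases are excluded,
    genders are combined, and each dyad is evaluated on participants with
    confirmed information for both members.  Dyads with a degenerate margin
    are skipped.
    """
    ind = confirmed_indicators(cohort, policy)
    counts = {col: int((ind[col] == 1).sum()) for col in ind.columns}
    keep = [col for col in ind.columns if counts[col] >= min_pairs]
    records = []
    for x, y in combinations(keep, 2):
        both = ind[x].notna() & ind[y].notna()
        xi = ind[x][both].astype(int)
        yi = ind[y][both].astype(int)
        a = int(((xi == 1) & (yi == 1)).sum())
        b = int(((xi == 1) & (yi == 0)).sum())
        c = int(((xi == 0) & (yi == 1)).sum())
        d = int(((xi == 0) & (yi == 0)).sum())
        try:
            stat = phi_dyad(a, b, c, d, alpha)
        except ComorbidityError:
            continue
        records.append({
            "disorder_a": x, "disorder_b": y, "phi": stat.phi,
            "p_value": stat.p_value, "paired_n": stat.paired_n,
            "comorbid_n": a, "band": stat.band})
    return pd.DataFrame.from_records(
        records, columns=["disorder_a", "disorder_b", "phi", "p_value",
                          "paired_n", "comorbid_n", "band"])
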