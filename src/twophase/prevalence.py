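"""Phase-2 prevalence estimation under the study's missingness assumptions.

Two assumptions drive the estimator:

* screening below cut-off is interpreted as no diagnosis, and
* participants selected for an interview but lost to it (not reached or
  declining) carry the same diagnosis distribution as those interviewed,
  because both groups scored above the screening cut-off.

Within a gender stratum of size ``N`` with ``d`` diagnosed among ``i``
interviewed and ``L`` selected-but-lost, the estimated prevalence is::

    p = 100 * (d + L * d / i) / N

The combined estimate is the unweighted mean of the two gender strata,
adjusting for their unequal sizes.  For gambling/gaming, cohort-1
participants who were never screened are imputed from the comparable
cohort-2 subpopulation (see :func:`impute_cohort1_unscreened`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .cohort import (
    Cohort,
    GENDERS,
    MODULE_TIMEFRAMES,
    MODULES,
    OTHER_SUBSTANCE_GROUP,
    SUBSTANCES,
)
from . import scoring
from .screening import CutoffPolicy, SampleThresholds, derive_thresholds, \
    indicated_module_frame

logger = logging.getLogger(__name__)

#: Interview bases below this size trigger a logged small-base warning.
SMALL_BASE = 10


class EstimationError(ValueError):
    """The estimator's preconditions are not met."""


@dataclass
class EstimationInput:
    """Stratum counts: diagnosed / interviewed / lost / screened."""

    d: float
    i: float
    L: float
    N: float

    def __post_init__(self):
        if min(self.d, self.i, self.L, self.N) < 0:
            raise EstimationError("counts must be non-negative")
        if self.d > self.i:
            raise EstimationError("diagnosed cannot exceed interviewed")
        if self.i + self.L > self.N:
            raise EstimationError("interviewed + lost cannot exceed screened")


@dataclass
class PrevalenceEstimate:
    category: str
    timeframe: str
    p_female: float
    p_male: float
    p_adjusted: float
    provenance: dict


def estimate_stratum_prevalence(inp: EstimationInput,
                                min_interview_base: int = 1) -> float:
    """Percentage prevalence in one stratum under the two assumptions."""
    if inp.d == 0:
        return 0.0
    if inp.i == 0:
        raise EstimationError(
            "no interview base: selected cases but nobody interviewed")
    if inp.i < min_interview_base:
        raise EstimationError(
            f"interview base {inp.i} below the configured minimum "
            f"{min_interview_base}")
    if inp.i < SMALL_BASE:
        logger.warning("small interview base (i=%s) for estimation", inp.i)
    return 100.0 * (inp.d + inp.L * inp.d / inp.i) / inp.N


def gender_adjust(p_female: float, p_male: float) -> float:
    """Unweighted mean of the gender-stratum prevalences."""
    for p in (p_female, p_male):
        if not 0 <= p <= 100:
            raise ValueError(f"prevalence {p} outside [0, 100]")
    return (p_female + p_male) / 2.0


def impute_cohort1_unscreened(reference_fractions: dict[str, float],
                              unscreened_counts: dict[str, float]
                              ) -> dict[str, float]:
    """Pseudo-cases for cohort-1 participants never screened for a category.

    ``reference_fractions`` holds, per gender, the estimated category
    fraction in the cohort-2 reference subpopulation (those screened for
    gambling/gaming but not interviewed with ADDIS or M.I.N.I.);
    ``unscreened_counts`` the per-gender number of unscreened cohort-1
    participants.  Returns fractional pseudo-counts, never rounded.
    """
    out = {}
    for g, n in unscreened_counts.items():
        f = reference_fractions[g]
        if not 0 <= f <= 1:
            raise EstimationError(f"reference fraction {f} outside [0, 1]")
        out[g] = n * f
    return out


# ---------------------------------------------------------------------------
# Table construction

def _stratum_counts(case: pd.Series, interviewed: pd.Series,
                    selected: pd.Series, mask: pd.Series) -> EstimationInput:
    """Assemble (d, i, L, N) for one stratum.

    ``case`` is boolean among the interviewed (NA elsewhere).
    """
    i = int((interviewed & mask).sum())
    d = int((case.fillna(False) & interviewed & mask).sum())
    L = int((selected & ~interviewed & mask).sum())
    return EstimationInput(d=d, i=i, L=L, N=int(mask.sum()))


def _estimate_row(category: str, timeframe: str, case: pd.Series,
                  interviewed: pd.Series, selected: pd.Series,
                  df: pd.DataFrame, min_base: int) -> PrevalenceEstimate:
    per_gender = {}
    prov = {}
    for g in GENDERS:
        inp = _stratum_counts(case, interviewed, selected, df["gender"] == g)
        per_gender[g] = estimate_stratum_prevalence(inp, min_base)
        prov[g] = {"d": inp.d, "i": inp.i, "L": inp.L, "N": inp.N}
    return PrevalenceEstimate(
        category=category, timeframe=timeframe,
        p_female=per_gender["female"], p_male=per_gender["male"],
        p_adjusted=gender_adjust(per_gender["female"], per_gender["male"]),
        provenance=prov)


def _substance_rows(df: pd.DataFrame, timeframes, min_base: int
                    ) -> list[PrevalenceEstimate]:
    interviewed = df["int_addis"].fillna(False).astype(bool)
    selected = df["sel_addis"].fillna(False).astype(bool)
    groups: list[tuple[str, pd.Series]] = []
    rows = []
    for tf in timeframes:
        groups = [
            ("alcohol", scoring.substance_category_series(df, "alcohol", tf)),
            ("cannabis", scoring.substance_category_series(df, "cannabis", tf)),
            ("other_substances",
             scoring.best_category_series(df, OTHER_SUBSTANCE_GROUP, tf)),
            ("any_substance",
             scoring.best_category_series(df, SUBSTANCES, tf)),
        ]
        for name, cat in groups:
            for level in ("dependence", "harmful_use", "sub_threshold"):
                rows.append(_estimate_row(
                    f"{name}:{level}", tf, cat == level,
                    interviewed, selected, df, min_base))
    return rows


def _psychiatric_rows(df: pd.DataFrame, thresholds: SampleThresholds,
                      min_base: int) -> list[PrevalenceEstimate]:
    indicated = indicated_module_frame(df, thresholds)
    sel_mini = df["sel_mini"].fillna(False).astype(bool)
    int_mini = df["int_mini"].fillna(False).astype(bool)
    rows = []
    for m in MODULES:
        # assessed: interviewed and the module administered (indicated, or
        # any module via the full-interview rule already folded into
        # `indicated`); outcome columns are non-null exactly when assessed
        for tf in MODULE_TIMEFRAMES[m]:
            col = f"{m}_lt" if tf == "lifetime" else f"{m}_py"
            assessed = int_mini & df[col].notna()
            module_selected = sel_mini & indicated[m]
            rows.append(_estimate_row(
                f"{m}:{tf}", tf, df[col], assessed, module_selected,
                df, min_base))
    any_psych = scoring.psychiatric_any_series(df)
    rows.append(_estimate_row("any_psychiatric:lifetime", "lifetime",
                              any_psych, int_mini, sel_mini, df, min_base))
    return rows


def _reference_fraction(df: pd.DataFrame, case: pd.Series,
                        interviewed: pd.Series, selected: pd.Series,
                        ref_mask: pd.Series, min_base: int) -> float:
    """Estimated category fraction inside a reference subpopulation."""
    if ref_mask.sum() == 0:
        raise EstimationError("empty cohort-2 reference stratum")
    inp = _stratum_counts(case, interviewed, selected, ref_mask)
    return estimate_stratum_prevalence(inp, min_base) / 100.0


def _gambling_gaming_rows(df: pd.DataFrame, min_base: int
                          ) -> list[PrevalenceEstimate]:
    rows = []
    specs = [
        ("gambling", scoring.gambling_category_series(df),
         "nods", "ever_gambled_money", ("at_risk", "problem", "pathological")),
        ("gaming", scoring.gaming_category_series(df),
         "igds", "gaming_hours_band", ("at_risk", "pathological")),
    ]
    contacted = (df["int_addis"].fillna(False)
                 | df["int_mini"].fillna(False)).astype(bool)
    for name, cat, instrument, screen_col, levels in specs:
        interviewed = df[f"int_{instrument}"].fillna(False).astype(bool)
        selected = df[f"sel_{instrument}"].fillna(False).astype(bool)
        screened = df[screen_col].notna()
        ref = (df["cohort"] == "cohort2") & ~contacted & screened
        for level in levels:
            case = cat == level
            per_gender, prov = {}, {}
            for g in GENDERS:
                gmask = df["gender"] == g
                smask = gmask & screened
                inp = _stratum_counts(case, interviewed, selected, smask)
                # d <= i is enforced, so d > 0 implies a non-empty base
                cases_screened = (inp.d + inp.L * inp.d / inp.i
                                  if inp.d > 0 else 0.0)
                unscreened = int((gmask & ~screened).sum())
                pseudo = 0.0
                if unscreened:
                    f = _reference_fraction(df, case, interviewed, selected,
                                            ref & gmask, min_base)
                    pseudo = impute_cohort1_unscreened(
                        {g: f}, {g: unscreened})[g]
                N = int(gmask.sum())
                per_gender[g] = 100.0 * (cases_screened + pseudo) / N
                prov[g] = {"d": inp.d, "i": inp.i, "L": inp.L,
                           "N": N, "screened": int(smask.sum()),
                           "unscreened": unscreened,
                           "imputed_pseudo_cases": pseudo}
            rows.append(PrevalenceEstimate(
                category=f"{name}:{level}", timeframe="lifetime",
                p_female=per_gender["female"], p_male=per_gender["male"],
                p_adjusted=gender_adjust(per_gender["female"],
                                         per_gender["male"]),
                provenance=prov))
    return rows


def build_prevalence_table(cohort: Cohort,
                           categories: Iterable[str] = ("substance",
                                                        "psychiatric",
                                                        "gambling_gaming"),
                           timeframes: Iterable[str] = ("lifetime",),
                           policy: Optional[CutoffPolicy] = None,
                           min_interview_base: int = 1) -> pd.DataFrame:
    """Estimated prevalence per category, per gender and gender-adjusted.

    Returns a long-format table with columns ``category``, ``timeframe``,
    ``stratum`` (female / male / adjusted), the counts ``d, i, L, N`` used,
    and ``prevalence`` in percent (unrounded).
    """
    df = cohort.df
    policy = policy or CutoffPolicy()
    thresholds = derive_thresholds(cohort, policy)
    rows: list[PrevalenceEstimate] = []
    categories = set(categories)
    if "substance" in categories:
        rows += _substance_rows(df, tuple(timeframes), min_interview_base)
    if "psychiatric" in categories:
        rows += _psychiatric_rows(df, thresholds, min_interview_base)
    if "gambling_gaming" in categories:
        rows += _gambling_gaming_rows(df, min_interview_base)

    records = []
    for r in rows:
        for stratum, p in (("female", r.p_female), ("male", r.p_male),
                           ("adjusted", r.p_adjusted)):
            prov = r.provenance.get(stratum, {})
            records.append({
                "category": r.category, "timeframe": r.timeframe,
                "stratum": stratum,
                "d": prov.get("d"), "i": prov.get("i"),
                "L": prov.get("L"), "N": prov.get("N"),
                "prevalence": p,
            })
    return pd.DataFrame.from_records(records)


def table_value(table: pd.DataFrame, category: str,
                stratum: str = "adjusted", timeframe: str = "lifetime"
                ) -> float:
    """Convenience lookup of one prevalence cell."""
    m = ((table["category"] == category) & (table["stratum"] == stratum)
         & (table["timeframe"] == timeframe))
    if not m.any():
        raise KeyError(f"no row for {category}/{timeframe}/{stratum}")
    return float(table.loc[m, "prevalence"].iloc[0])
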