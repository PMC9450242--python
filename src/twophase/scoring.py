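"""Map interview outcomes onto the diagnostic categories used in reporting.

Substance outcomes follow ICD-10 logic: >= 3 of 6 dependence criteria give
a dependence diagnosis (which supersedes harmful use), a harmful-use flag
without dependence gives harmful use, and 1-2 criteria without either
diagnosis are sub-threshold ("diagnostic orphans").  Gambling severity
comes from NODS bands (1-2 at-risk, 3-4 problem, 5+ pathological) and
gaming severity from IGDS bands (17-20 at-risk, 21+ pathological).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .cohort import (
    CRITERIA_MAX,
    IGDS_MAX,
    IGDS_MIN,
    MODULE_TIMEFRAMES,
    MODULES,
    NODS_MAX,
    ModuleResult,
    SubstanceResult,
)

#: Substance categories, least to most severe.
SUBSTANCE_SEVERITY = ("none", "sub_threshold", "harmful_use", "dependence")
GAMBLING_CATEGORIES = ("none", "at_risk", "problem", "pathological")
GAMING_CATEGORIES = ("none", "at_risk", "pathological")

#: ICD-10 dependence requires at least this many of the six criteria.
DEPENDENCE_THRESHOLD = 3


def classify_substance(r: SubstanceResult,
                       timeframe: str = "lifetime") -> str:
    """Mutually exclusive substance category for one timeframe."""
    if timeframe == "lifetime":
        count, harmful = r.dependence_criteria_lifetime, r.harmful_use_lifetime
    elif timeframe == "past_year":
        count, harmful = (r.dependence_criteria_past_year,
                          r.harmful_use_past_year)
    else:
        raise ValueError(f"unknown timeframe {timeframe!r}")
    if not 0 <= count <= CRITERIA_MAX:
        raise ValueError(f"criterion count {count} outside 0-{CRITERIA_MAX}")
    if count >= DEPENDENCE_THRESHOLD:
        return "dependence"
    if harmful:
        return "harmful_use"
    if count >= 1:
        return "sub_threshold"
    return "none"


def any_substance(results: Mapping[str, SubstanceResult],
                  timeframe: str = "lifetime") -> str:
    """Person-level category: the most severe across assessed substances."""
    if not results:
        raise ValueError("any_substance: no substances assessed")
    cats = [classify_substance(r, timeframe) for r in results.values()]
    return max(cats, key=SUBSTANCE_SEVERITY.index)


def classify_gambling(nods_score: int) -> str:
    """NODS total -> gambling severity band."""
    if not 0 <= nods_score <= NODS_MAX:
        raise ValueError(f"NODS score {nods_score} outside 0-{NODS_MAX}")
    if nods_score >= 5:
        return "pathological"
    if nods_score >= 3:
        return "problem"
    if nods_score >= 1:
        return "at_risk"
    return "none"


def classify_gaming(igds_score: int) -> str:
    """IGDS total -> gaming severity band."""
    if not IGDS_MIN <= igds_score <= IGDS_MAX:
        raise ValueError(
            f"IGDS score {igds_score} outside {IGDS_MIN}-{IGDS_MAX}")
    if igds_score >= 21:
        return "pathological"
    if igds_score >= 17:
        return "at_risk"
    return "none"


def module_positive(r: ModuleResult) -> bool:
    """Positive on the module's primary timeframe (lifetime if reported)."""
    if "lifetime" in MODULE_TIMEFRAMES[r.module]:
        return bool(r.lifetime)
    return bool(r.past_year)


def psychiatric_any(mini: Mapping[str, ModuleResult]) -> bool:
    """Any of the 16 psychiatric modules positive.

    Modules absent from ``mini`` (not administered because the screening
    did not indicate them) count as negative.
    """
    return any(module_positive(r) for r in mini.values())


# ---------------------------------------------------------------------------
# Vectorised scoring over a cohort table

def substance_category_series(df: pd.DataFrame, substance: str,
                              timeframe: str = "lifetime") -> pd.Series:
    """Category per participant for one substance; <NA> when not assessed."""
    suffix = "lt" if timeframe == "lifetime" else "py"
    if timeframe not in ("lifetime", "past_year"):
        raise ValueError(f"unknown timeframe {timeframe!r}")
    count = df[f"{substance}_dep_{suffix}"]
    harm = df[f"{substance}_harm_{suffix}"].fillna(False)
    out = pd.Series("none", index=df.index, dtype="object")
    out[count >= 1] = "sub_threshold"
    out[harm.astype(bool) & (count < DEPENDENCE_THRESHOLD)] = "harmful_use"
    out[count >= DEPENDENCE_THRESHOLD] = "dependence"
    out[count.isna()] = pd.NA
    return out


def best_category_series(df: pd.DataFrame, substances, timeframe: str
                         ) -> pd.Series:
    """Most severe category across a set of substances, per participant."""
    order = {c: i for i, c in enumerate(SUBSTANCE_SEVERITY)}
    ranks = pd.concat(
        [substance_category_series(df, s, timeframe).map(order).astype("Int64")
         for s in substances], axis=1)
    best = ranks.max(axis=1)  # skips NA; all-NA rows stay NA
    return best.map(lambda i: SUBSTANCE_SEVERITY[int(i)] if pd.notna(i)
                    else pd.NA)


def module_positive_series(df: pd.DataFrame, module: str) -> pd.Series:
    """Boolean series for one module's primary timeframe; <NA> unassessed."""
    col = (f"{module}_lt" if "lifetime" in MODULE_TIMEFRAMES[module]
           else f"{module}_py")
    return df[col]


def psychiatric_any_series(df: pd.DataFrame) -> pd.Series:
    """Any-psychiatric-disorder flag among M.I.N.I.-interviewed participants.

    Unassessed modules count as negative; participants without a M.I.N.I.
    interview get <NA>.
    """
    out = pd.Series(False, index=df.index)
    for m in MODULES:
        out |= module_positive_series(df, m).fillna(False).astype(bool)
    out = out.astype("boolean")
    out[~df["int_mini"].fillna(False).astype(bool)] = pd.NA
    return out


def gambling_category_series(df: pd.DataFrame) -> pd.Series:
    return df["nods_score"].map(
        lambda v: classify_gambling(int(v)) if pd.notna(v) else pd.NA)


def gaming_category_series(df: pd.DataFrame) -> pd.Series:
    return df["igds_score"].map(
        lambda v: classify_gaming(int(v)) if pd.notna(v) else pd.NA)
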