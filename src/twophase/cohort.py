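"""Cohort data model and delimited-text I/O.

A cohort is one wide row per screened participant: gender, school-year
cohort, phase-1 screening profile, per-instrument selection and interview
flags, and phase-2 interview outcomes (per-substance ICD-10 criterion
counts and harmful-use flags, per-module diagnosis flags, NODS and IGDS
totals).  Absent-by-design values (e.g. the gambling/gaming screening gap
in cohort 1) are encoded as empty cells, never as 0, so that "not asked"
stays distinguishable from "answered no".

The full column dictionary ships in ``docs/columns.md``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Vocabulary

GENDERS = ("female", "male")
COHORTS = ("cohort1", "cohort2")
INSTRUMENTS = ("addis", "mini", "nods", "igds")
LOSS_REASONS = ("not_reached", "declined", "unknown", "not_applicable")

#: The 11 substance groups assessed by the substance-use interview.
SUBSTANCES = (
    "alcohol",
    "cannabis",
    "sedatives",
    "opioids",
    "cocaine",
    "stimulants",
    "ecstasy",
    "hallucinogens",
    "solvents",
    "other",
    "mixed",
)

#: Substance groups pooled into the "other substances" table row
#: (everything but alcohol, cannabis and mixed drugs).
OTHER_SUBSTANCE_GROUP = (
    "sedatives",
    "opioids",
    "cocaine",
    "stimulants",
    "ecstasy",
    "hallucinogens",
    "solvents",
    "other",
)

#: The 16 psychiatric interview modules.
MODULES = (
    "depression",
    "suicidality",
    "manic_episode",
    "panic_disorder",
    "agoraphobia",
    "social_anxiety",
    "ocd",
    "ptsd",
    "gad",
    "psychotic_syndrome",
    "affective_psychosis",
    "anorexia",
    "bulimia",
    "aspd",
    "adhd",
    "add",
)

#: Timeframes each module reports.  Some modules yield both a lifetime and a
#: past-year diagnosis, others only one of the two.
MODULE_TIMEFRAMES: dict[str, tuple[str, ...]] = {
    "depression": ("lifetime", "past_year"),
    "suicidality": ("lifetime", "past_year"),
    "manic_episode": ("lifetime", "past_year"),
    "panic_disorder": ("lifetime", "past_year"),
    "agoraphobia": ("past_year",),
    "social_anxiety": ("past_year",),
    "ocd": ("lifetime",),
    "ptsd": ("lifetime",),
    "gad": ("lifetime",),
    "psychotic_syndrome": ("lifetime", "past_year"),
    "affective_psychosis": ("lifetime", "past_year"),
    "anorexia": ("past_year",),
    "bulimia": ("past_year",),
    "aspd": ("lifetime",),
    "adhd": ("lifetime",),
    "add": ("lifetime",),
}

#: The 12 psychiatric screening syndromes (22 screen items summarised at
#: syndrome granularity; ASPD and ADHD/ADD are screened by separate scales).
SYNDROMES = (
    "depression",
    "suicidality",
    "mania",
    "panic",
    "agoraphobia",
    "social_anxiety",
    "ocd",
    "ptsd",
    "gad",
    "psychotic",
    "anorexia",
    "bulimia",
)

#: Which interview modules a positive screening syndrome indicates.
SYNDROME_MODULES: dict[str, tuple[str, ...]] = {
    "depression": ("depression",),
    "suicidality": ("suicidality",),
    "mania": ("manic_episode",),
    "panic": ("panic_disorder",),
    "agoraphobia": ("agoraphobia",),
    "social_anxiety": ("social_anxiety",),
    "ocd": ("ocd",),
    "ptsd": ("ptsd",),
    "gad": ("gad",),
    "psychotic": ("psychotic_syndrome", "affective_psychosis"),
    "anorexia": ("anorexia",),
    "bulimia": ("bulimia",),
}

#: Ordinal answer bands for "hours of gaming on a normal weekday".
GAMING_BANDS = ("none", "under_1h", "1_2h", "3_4h", "5h_plus")

AUDIT_MAX = 40
DUDIT_MAX = 44
NODS_MAX = 10
IGDS_MIN, IGDS_MAX = 9, 45
CRITERIA_MAX = 6


# ---------------------------------------------------------------------------
# Column dictionary

def _module_columns() -> list[str]:
    cols = []
    for m in MODULES:
        if "lifetime" in MODULE_TIMEFRAMES[m]:
            cols.append(f"{m}_lt")
        if "past_year" in MODULE_TIMEFRAMES[m]:
            cols.append(f"{m}_py")
    return cols


def _substance_columns() -> list[str]:
    cols = []
    for s in SUBSTANCES:
        cols += [f"{s}_dep_lt", f"{s}_harm_lt", f"{s}_dep_py", f"{s}_harm_py"]
    return cols


SCREEN_FLAG_COLUMNS = tuple(f"scr_{s}" for s in SYNDROMES)
SELECTION_COLUMNS = tuple(f"sel_{k}" for k in INSTRUMENTS)
INTERVIEW_COLUMNS = tuple(f"int_{k}" for k in INSTRUMENTS)
SUBSTANCE_COLUMNS = tuple(_substance_columns())
MODULE_COLUMNS = tuple(_module_columns())

COLUMNS: tuple[str, ...] = (
    ("participant_id", "gender", "cohort",
     "audit", "dudit", "surnc", "psp", "delinquency")
    + SCREEN_FLAG_COLUMNS
    + ("adhd_self_report", "ever_gambled_money", "ever_paid_in_game",
       "gaming_hours_band")
    + SELECTION_COLUMNS
    + INTERVIEW_COLUMNS
    + ("loss_reason",)
    + SUBSTANCE_COLUMNS
    + MODULE_COLUMNS
    + ("nods_score", "igds_score")
)

_BOOL_COLUMNS = (
    SCREEN_FLAG_COLUMNS
    + ("adhd_self_report", "ever_gambled_money", "ever_paid_in_game")
    + SELECTION_COLUMNS
    + INTERVIEW_COLUMNS
    + tuple(c for c in SUBSTANCE_COLUMNS if "_harm_" in c)
    + MODULE_COLUMNS
)
_INT_COLUMNS = (
    ("audit", "dudit", "surnc", "psp", "delinquency")
    + tuple(c for c in SUBSTANCE_COLUMNS if "_dep_" in c)
    + ("nods_score", "igds_score")
)


class CohortValidationError(ValueError):
    """A cohort table violates the documented schema."""


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class SubstanceResult:
    """Interview outcome for one substance group (ICD-10 logic)."""

    dependence_criteria_lifetime: int = 0
    harmful_use_lifetime: bool = False
    dependence_criteria_past_year: int = 0
    harmful_use_past_year: bool = False


@dataclass
class ModuleResult:
    """Interview outcome for one psychiatric module.

    Only the timeframes listed in :data:`MODULE_TIMEFRAMES` may carry a
    value; the other stays ``None``.
    """

    module: str
    lifetime: Optional[bool] = None
    past_year: Optional[bool] = None


@dataclass
class InterviewOutcome:
    substance_results: dict[str, SubstanceResult] = field(default_factory=dict)
    mini_results: dict[str, ModuleResult] = field(default_factory=dict)
    nods_score: Optional[int] = None
    igds_score: Optional[int] = None


@dataclass
class ScreeningProfile:
    audit_score: int = 0
    dudit_score: int = 0
    surnc_score: int = 0
    psp_score: int = 0
    delinquency_score: int = 0
    mini_screen_flags: dict[str, bool] = field(default_factory=dict)
    adhd_self_report: bool = False
    ever_gambled_money: Optional[bool] = None
    ever_paid_in_game: Optional[bool] = None
    gaming_hours_band: Optional[str] = None


@dataclass
class Participant:
    participant_id: str
    gender: str
    cohort: str
    screening: ScreeningProfile = field(default_factory=ScreeningProfile)
    selected_for: set[str] = field(default_factory=set)
    interviewed_with: set[str] = field(default_factory=set)
    outcome: Optional[InterviewOutcome] = None
    loss_reason: str = "not_applicable"


# ---------------------------------------------------------------------------
# Cohort container

class Cohort:
    """A validated two-phase cohort, backed by a typed wide DataFrame."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.reset_index(drop=True)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise CohortValidationError(f"missing columns: {missing}")
        extra = [c for c in df.columns if c not in COLUMNS]
        if extra:
            raise CohortValidationError(f"unknown columns: {extra}")
        self.df = df[list(COLUMNS)].copy()
        _coerce_dtypes(self.df)
        if validate:
            validate_cohort(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, Cohort) and self.df.equals(other.df)

    # -- conversion ---------------------------------------------------------

    @classmethod
    def from_participants(cls, participants: Iterable[Participant],
                          validate: bool = True) -> "Cohort":
        rows = [_participant_to_row(p) for p in participants]
        df = pd.DataFrame(rows, columns=list(COLUMNS))
        return cls(df, validate=validate)

    def participants(self) -> list[Participant]:
        return [_row_to_participant(row) for _, row in self.df.iterrows()]

    # -- convenience masks --------------------------------------------------

    def gender_mask(self, gender: str) -> pd.Series:
        return self.df["gender"] == gender

    def stratum_size(self, gender: str) -> int:
        return int(self.gender_mask(gender).sum())


def _coerce_dtypes(df: pd.DataFrame) -> None:
    for c in _INT_COLUMNS:
        df[c] = df[c].astype("Int64")
    for c in _BOOL_COLUMNS:
        df[c] = df[c].astype("boolean")
    for c in ("participant_id", "gender", "cohort", "loss_reason",
              "gaming_hours_band"):
        df[c] = df[c].astype("object")
    band = df["gaming_hours_band"]
    ok = (band.notna() & (band != "")).fillna(False).to_numpy(dtype=bool)
    df["gaming_hours_band"] = np.where(ok, band, None)


# ---------------------------------------------------------------------------
# Validation

def _err(row: int, column: str, message: str) -> CohortValidationError:
    return CohortValidationError(f"row {row}, column {column!r}: {message}")


def _check_range(df, col, lo, hi, allow_na):
    s = df[col]
    if not allow_na and s.isna().any():
        row = int(s.isna().idxmax())
        raise _err(row, col, "value required but missing")
    bad = s.notna() & ((s < lo) | (s > hi))
    if bad.any():
        row = int(bad.idxmax())
        raise _err(row, col, f"value {s[row]} outside [{lo}, {hi}]")


def validate_cohort(df: pd.DataFrame) -> None:
    """Enforce every schema invariant; raise naming row and column."""
    dup = df["participant_id"].duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise _err(row, "participant_id",
                   f"duplicate id {df['participant_id'][row]!r}")
    for col, allowed in (("gender", GENDERS), ("cohort", COHORTS),
                         ("loss_reason", LOSS_REASONS)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(bad.idxmax())
            raise _err(row, col, f"{df[col][row]!r} not in {allowed}")
    _check_range(df, "audit", 0, AUDIT_MAX, allow_na=False)
    _check_range(df, "dudit", 0, DUDIT_MAX, allow_na=False)
    for col in ("surnc", "psp", "delinquency"):
        _check_range(df, col, 0, 10**6, allow_na=False)
    _check_range(df, "nods_score", 0, NODS_MAX, allow_na=True)
    _check_range(df, "igds_score", IGDS_MIN, IGDS_MAX, allow_na=True)
    for c in [c for c in SUBSTANCE_COLUMNS if "_dep_" in c]:
        _check_range(df, c, 0, CRITERIA_MAX, allow_na=True)

    band = df["gaming_hours_band"]
    bad = band.notna() & ~band.isin(GAMING_BANDS)
    if bad.any():
        row = int(bad.idxmax())
        raise _err(row, "gaming_hours_band",
                   f"{band[row]!r} not in {GAMING_BANDS}")

    # interviewed_with subset of selected_for
    for k in INSTRUMENTS:
        bad = df[f"int_{k}"].fillna(False) & ~df[f"sel_{k}"].fillna(False)
        if bad.any():
            row = int(bad.idxmax())
            raise _err(row, f"int_{k}", "interviewed but not selected")

    # outcome data only for interviewed instruments
    addis = df["int_addis"].fillna(False)
    for c in SUBSTANCE_COLUMNS:
        bad = df[c].notna() & ~addis
        if bad.any():
            row = int(bad.idxmax())
            raise _err(row, c, "substance outcome without an ADDIS interview")
    mini = df["int_mini"].fillna(False)
    for c in MODULE_COLUMNS:
        bad = df[c].notna() & ~mini
        if bad.any():
            row = int(bad.idxmax())
            raise _err(row, c, "module outcome without a M.I.N.I. interview")
    for col, k in (("nods_score", "nods"), ("igds_score", "igds")):
        bad = df[col].notna() & ~df[f"int_{k}"].fillna(False)
        if bad.any():
            row = int(bad.idxmax())
            raise _err(row, col, f"score without a {k.upper()} interview")

    # past-year never exceeds lifetime
    for s in SUBSTANCES:
        lt, py = df[f"{s}_dep_lt"], df[f"{s}_dep_py"]
        bad = lt.notna() & py.notna() & (py > lt)
        if bad.any():
            row = int(bad.idxmax())
            raise _err(row, f"{s}_dep_py", "past-year criteria exceed lifetime")

    # loss_reason consistency with selection/interview state
    lost = pd.Series(False, index=df.index)
    for k in INSTRUMENTS:
        lost |= df[f"sel_{k}"].fillna(False) & ~df[f"int_{k}"].fillna(False)
    bad = lost & (df["loss_reason"] == "not_applicable")
    if bad.any():
        row = int(bad.idxmax())
        raise _err(row, "loss_reason", "lost to interview but marked not_applicable")
    bad = ~lost & (df["loss_reason"] != "not_applicable")
    if bad.any():
        row = int(bad.idxmax())
        raise _err(row, "loss_reason", "no interview loss but a loss reason given")

    # gambling/gaming screening gap: absent only in cohort1 without an
    # ADDIS/M.I.N.I. interview, and the three fields are absent together
    gam_cols = ["ever_gambled_money", "ever_paid_in_game", "gaming_hours_band"]
    present = df[gam_cols].notna()
    mixed = present.any(axis=1) & ~present.all(axis=1)
    if mixed.any():
        row = int(mixed.idxmax())
        raise _err(row, "ever_gambled_money",
                   "gambling/gaming screen fields must be absent or present together")
    absent = ~present.all(axis=1)
    contacted = addis | mini
    bad = absent & ((df["cohort"] == "cohort2") | contacted)
    if bad.any():
        row = int(bad.idxmax())
        raise _err(row, "ever_gambled_money",
                   "gambling/gaming screening may be absent only for cohort1 "
                   "participants without an ADDIS/M.I.N.I. interview")


# ---------------------------------------------------------------------------
# Participant <-> row conversion

def _na(x):
    return x is None or x is pd.NA or (isinstance(x, float) and np.isnan(x))


def _participant_to_row(p: Participant) -> dict:
    row: dict = {c: pd.NA for c in COLUMNS}
    row.update(participant_id=p.participant_id, gender=p.gender,
               cohort=p.cohort, loss_reason=p.loss_reason)
    sc = p.screening
    row.update(audit=sc.audit_score, dudit=sc.dudit_score,
               surnc=sc.surnc_score, psp=sc.psp_score,
               delinquency=sc.delinquency_score,
               adhd_self_report=sc.adhd_self_report)
    for s in SYNDROMES:
        row[f"scr_{s}"] = bool(sc.mini_screen_flags.get(s, False))
    row["ever_gambled_money"] = (
        pd.NA if _na(sc.ever_gambled_money) else bool(sc.ever_gambled_money))
    row["ever_paid_in_game"] = (
        pd.NA if _na(sc.ever_paid_in_game) else bool(sc.ever_paid_in_game))
    row["gaming_hours_band"] = (
        None if _na(sc.gaming_hours_band) else sc.gaming_hours_band)
    for k in INSTRUMENTS:
        row[f"sel_{k}"] = k in p.selected_for
        row[f"int_{k}"] = k in p.interviewed_with
    out = p.outcome
    if out is not None:
        for s, r in out.substance_results.items():
            row[f"{s}_dep_lt"] = r.dependence_criteria_lifetime
            row[f"{s}_harm_lt"] = r.harmful_use_lifetime
            row[f"{s}_dep_py"] = r.dependence_criteria_past_year
            row[f"{s}_harm_py"] = r.harmful_use_past_year
        for m, r in out.mini_results.items():
            if "lifetime" in MODULE_TIMEFRAMES[m] and r.lifetime is not None:
                row[f"{m}_lt"] = bool(r.lifetime)
            if "past_year" in MODULE_TIMEFRAMES[m] and r.past_year is not None:
                row[f"{m}_py"] = bool(r.past_year)
        if out.nods_score is not None:
            row["nods_score"] = out.nods_score
        if out.igds_score is not None:
            row["igds_score"] = out.igds_score
    return row


def _row_to_participant(row: pd.Series) -> Participant:
    sc = ScreeningProfile(
        audit_score=int(row["audit"]),
        dudit_score=int(row["dudit"]),
        surnc_score=int(row["surnc"]),
        psp_score=int(row["psp"]),
        delinquency_score=int(row["delinquency"]),
        mini_screen_flags={s: bool(row[f"scr_{s}"]) for s in SYNDROMES},
        adhd_self_report=bool(row["adhd_self_report"]),
        ever_gambled_money=(None if _na(row["ever_gambled_money"])
                            else bool(row["ever_gambled_money"])),
        ever_paid_in_game=(None if _na(row["ever_paid_in_game"])
                           else bool(row["ever_paid_in_game"])),
        gaming_hours_band=(None if _na(row["gaming_hours_band"])
                           else row["gaming_hours_band"]),
    )
    selected = {k for k in INSTRUMENTS if row[f"sel_{k}"]}
    interviewed = {k for k in INSTRUMENTS if row[f"int_{k}"]}
    outcome = None
    if interviewed:
        subs: dict[str, SubstanceResult] = {}
        if "addis" in interviewed:
            for s in SUBSTANCES:
                if not _na(row[f"{s}_dep_lt"]):
                    subs[s] = SubstanceResult(
                        dependence_criteria_lifetime=int(row[f"{s}_dep_lt"]),
                        harmful_use_lifetime=bool(row[f"{s}_harm_lt"]),
                        dependence_criteria_past_year=int(row[f"{s}_dep_py"]),
                        harmful_use_past_year=bool(row[f"{s}_harm_py"]),
                    )
        mods: dict[str, ModuleResult] = {}
        if "mini" in interviewed:
            for m in MODULES:
                lt = (row[f"{m}_lt"] if "lifetime" in MODULE_TIMEFRAMES[m]
                      else pd.NA)
                py = (row[f"{m}_py"] if "past_year" in MODULE_TIMEFRAMES[m]
                      else pd.NA)
                if not (_na(lt) and _na(py)):
                    mods[m] = ModuleResult(
                        module=m,
                        lifetime=None if _na(lt) else bool(lt),
                        past_year=None if _na(py) else bool(py),
                    )
        outcome = InterviewOutcome(
            substance_results=subs,
            mini_results=mods,
            nods_score=(None if _na(row["nods_score"])
                        else int(row["nods_score"])),
            igds_score=(None if _na(row["igds_score"])
                        else int(row["igds_score"])),
        )
    return Participant(
        participant_id=str(row["participant_id"]),
        gender=row["gender"],
        cohort=row["cohort"],
        screening=sc,
        selected_for=selected,
        interviewed_with=interviewed,
        outcome=outcome,
        loss_reason=row["loss_reason"],
    )


# ---------------------------------------------------------------------------
# I/O

def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV; empty cells encode absent-by-design."""
    out = cohort.df.copy()
    for c in _BOOL_COLUMNS:
        out[c] = out[c].map({True: "1", False: "0"}, na_action="ignore")
    out.to_csv(path, index=False, na_rep="")


def read_cohort(path, schema_config: Optional[Mapping] = None) -> Cohort:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    ``schema_config`` supports ``validate`` (default True).
    """
    cfg = dict(schema_config or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise CohortValidationError(f"header missing columns: {missing}")
    df = pd.DataFrame(index=raw.index)
    for c in COLUMNS:
        col = raw[c].replace("", None)
        if c in _INT_COLUMNS:
            try:
                df[c] = pd.array([None if v is None else int(v) for v in col],
                                 dtype="Int64")
            except ValueError as exc:
                raise CohortValidationError(
                    f"column {c!r}: non-integer value ({exc})") from exc
        elif c in _BOOL_COLUMNS:
            bad = col.dropna()[~col.dropna().isin(["0", "1"])]
            if len(bad):
                row = int(bad.index[0])
                raise _err(row, c, f"boolean cell must be 0/1, got {bad.iloc[0]!r}")
            df[c] = pd.array([None if v is None else v == "1" for v in col],
                             dtype="boolean")
        else:
            df[c] = col
    return Cohort(df, validate=cfg.get("validate", True))


# ---------------------------------------------------------------------------
# Internal consistency

def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha, covariance form, complete cases only.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total score)),
    with sample (ddof=1) variances.  Rows containing missing values are
    dropped with a logged count.  Raises ``ValueError`` when fewer than two
    items/participants remain or the total score has zero variance.
    """
    x = np.asarray(pd.DataFrame(item_matrix), dtype=float)
    complete = ~np.isnan(x).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("cronbach_alpha: dropped %d incomplete rows", dropped)
    x = x[complete]
    n, k = x.shape
    if k < 2:
        raise ValueError("cronbach_alpha needs at least 2 items")
    if n < 2:
        raise ValueError("cronbach_alpha needs at least 2 complete cases")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("cronbach_alpha undefined: zero total-score variance")
    item_var = x.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)
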