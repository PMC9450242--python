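"""Phase-1 screening rules: cut-offs, selection, and module indication.

Selection for the four diagnostic interviews follows the study design:

* substance-use interview (ADDIS): AUDIT >= 6, DUDIT >= 2 or SURNC >= 5;
* psychiatric interview (M.I.N.I.): any screen syndrome flag, self-reported
  ADHD/ADD, or psychosomatic-problems (PSP) / delinquency score in the most
  severe decile (nearest-rank 90th percentile, computed from the sample);
* gambling interview (NODS): ever gambled for money, or ever paid money
  inside a game;
* gaming interview (IGDS): gaming "3-4 hours a day or more".

Named cut-off scores are themselves selecting (>=), consistent with the
SURNC 90th percentile of five points being a selecting score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    GAMING_BANDS,
    INSTRUMENTS,
    MODULES,
    SYNDROMES,
    SYNDROME_MODULES,
    Participant,
)

logger = logging.getLogger(__name__)

#: Modules indicated by a severe PSP score: PSP is a general emotional
#: problems scale, mapped to the mood / generalised-anxiety modules.
PSP_MODULES = ("depression", "gad")
#: The delinquency scale screens for antisocial personality disorder.
DELINQUENCY_MODULES = ("aspd",)
#: Self-reported ADHD/ADD indicates both attention-deficit modules.
ADHD_MODULES = ("adhd", "add")

#: More than this many indicated modules triggers the full 16-module interview.
FULL_INTERVIEW_THRESHOLD = 3


@dataclass
class CutoffPolicy:
    """Screening cut-offs; defaults are the study's values."""

    audit_cutoff: int = 6
    dudit_cutoff: int = 2
    surnc_cutoff: int = 5
    psp_percentile: float = 90.0
    delinquency_percentile: float = 90.0
    gaming_hours_cutoff: str = "3_4h"

    def __post_init__(self):
        for name in ("audit_cutoff", "dudit_cutoff", "surnc_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("psp_percentile", "delinquency_percentile"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must be in (0, 100)")
        if self.gaming_hours_cutoff not in GAMING_BANDS:
            raise ValueError(
                f"gaming_hours_cutoff must be one of {GAMING_BANDS}")


@dataclass
class SampleThresholds:
    """Percentile cut-offs derived from the screened sample."""

    psp: int
    delinquency: int


def percentile_cutoff(scores, percentile: float) -> int:
    """Nearest-rank upper-percentile threshold.

    Returns the smallest *observed* score ``s`` such that at least
    ``percentile`` percent of the sample scores strictly below ``s``;
    scoring >= the threshold therefore places a participant in the most
    severe <= (100 - percentile)% tail.  On a degenerate distribution where
    no observed score qualifies (e.g. all scores equal) the maximum score is
    returned and the whole sample is flagged, with a logged warning.
    """
    arr = np.asarray(list(scores))
    if arr.size == 0:
        raise ValueError("percentile_cutoff: empty score collection")
    n = arr.size
    need = percentile / 100.0 * n
    for s in np.unique(arr):          # ascending
        if (arr < s).sum() >= need:
            return int(s)
    top = int(arr.max())
    logger.warning(
        "percentile_cutoff: degenerate distribution, threshold %d flags the "
        "entire sample", top)
    return top


def derive_thresholds(cohort: Cohort, policy: CutoffPolicy) -> SampleThresholds:
    """Compute the PSP / delinquency thresholds from the full screened sample."""
    return SampleThresholds(
        psp=percentile_cutoff(cohort.df["psp"].astype(int),
                              policy.psp_percentile),
        delinquency=percentile_cutoff(cohort.df["delinquency"].astype(int),
                                      policy.delinquency_percentile),
    )


def select_for_interviews(p: Participant, policy: CutoffPolicy,
                          thresholds: SampleThresholds) -> set[str]:
    """Phase-1 selection decision for a single participant.

    Absent gambling/gaming screening (the cohort-1 gap) yields no NODS/IGDS
    decision — those instruments are simply not in the returned set.
    """
    sc = p.screening
    out: set[str] = set()
    if (sc.audit_score >= policy.audit_cutoff
            or sc.dudit_score >= policy.dudit_cutoff
            or sc.surnc_score >= policy.surnc_cutoff):
        out.add("addis")
    if (any(sc.mini_screen_flags.get(s, False) for s in SYNDROMES)
            or sc.adhd_self_report
            or sc.psp_score >= thresholds.psp
            or sc.delinquency_score >= thresholds.delinquency):
        out.add("mini")
    if sc.ever_gambled_money or sc.ever_paid_in_game:
        out.add("nods")
    if sc.gaming_hours_band is not None:
        cut = GAMING_BANDS.index(policy.gaming_hours_cutoff)
        if GAMING_BANDS.index(sc.gaming_hours_band) >= cut:
            out.add("igds")
    return out


def mini_module_indication(p: Participant, policy: CutoffPolicy,
                           thresholds: SampleThresholds
                           ) -> tuple[set[str], bool]:
    """Indicated psychiatric modules and the full-interview flag.

    Returns ``(assessed_modules, full_interview)``: the specific modules the
    screening indicated, or all 16 when more than three were indicated.
    Raises on a participant not selected for the psychiatric interview.
    """
    if "mini" not in select_for_interviews(p, policy, thresholds):
        raise ValueError(
            "mini_module_indication called on a participant not selected "
            "for a M.I.N.I. interview")
    sc = p.screening
    indicated: set[str] = set()
    for s in SYNDROMES:
        if sc.mini_screen_flags.get(s, False):
            indicated.update(SYNDROME_MODULES[s])
    if sc.adhd_self_report:
        indicated.update(ADHD_MODULES)
    if sc.psp_score >= thresholds.psp:
        indicated.update(PSP_MODULES)
    if sc.delinquency_score >= thresholds.delinquency:
        indicated.update(DELINQUENCY_MODULES)
    full = len(indicated) > FULL_INTERVIEW_THRESHOLD
    return (set(MODULES) if full else indicated), full


# ---------------------------------------------------------------------------
# Vectorised counterparts used by the estimators

def selection_frame(df: pd.DataFrame, policy: CutoffPolicy,
                    thresholds: SampleThresholds) -> pd.DataFrame:
    """Per-instrument selection decisions for a whole cohort table."""
    out = pd.DataFrame(index=df.index)
    out["addis"] = ((df["audit"] >= policy.audit_cutoff)
                    | (df["dudit"] >= policy.dudit_cutoff)
                    | (df["surnc"] >= policy.surnc_cutoff)).fillna(False)
    mini = (df["adhd_self_report"].fillna(False)
            | (df["psp"] >= thresholds.psp)
            | (df["delinquency"] >= thresholds.delinquency))
    for s in SYNDROMES:
        mini |= df[f"scr_{s}"].fillna(False)
    out["mini"] = mini.fillna(False)
    out["nods"] = (df["ever_gambled_money"].fillna(False)
                   | df["ever_paid_in_game"].fillna(False)).astype(bool)
    cut = GAMING_BANDS.index(policy.gaming_hours_cutoff)
    band_rank = df["gaming_hours_band"].map(
        {b: i for i, b in enumerate(GAMING_BANDS)})
    out["igds"] = (band_rank >= cut).fillna(False).astype(bool)
    return out


def indicated_module_frame(df: pd.DataFrame, thresholds: SampleThresholds
                           ) -> pd.DataFrame:
    """Boolean frame (participants x 16 modules) of screening indication.

    Applies the full-interview rule: participants with more than three
    indicated modules are marked indicated for all 16.
    """
    out = pd.DataFrame(False, index=df.index, columns=list(MODULES))
    for s in SYNDROMES:
        flag = df[f"scr_{s}"].fillna(False).astype(bool)
        for m in SYNDROME_MODULES[s]:
            out[m] |= flag
    adhd = df["adhd_self_report"].fillna(False).astype(bool)
    for m in ADHD_MODULES:
        out[m] |= adhd
    psp = (df["psp"] >= thresholds.psp).fillna(False).astype(bool)
    for m in PSP_MODULES:
        out[m] |= psp
    delinq = (df["delinquency"] >= thresholds.delinquency).fillna(False)
    for m in DELINQUENCY_MODULES:
        out[m] |= delinq.astype(bool)
    full = out.sum(axis=1) > FULL_INTERVIEW_THRESHOLD
    out.loc[full, :] = True
    return out


def apply_selection(cohort: Cohort, policy: CutoffPolicy | None = None
                    ) -> tuple[Cohort, dict[str, int]]:
    """Recompute the ``sel_*`` columns from the screening profile.

    Returns the updated cohort and per-instrument selection counts.  The
    PSP / delinquency thresholds are derived from this sample.
    """
    policy = policy or CutoffPolicy()
    thresholds = derive_thresholds(cohort, policy)
    sel = selection_frame(cohort.df, policy, thresholds)
    df = cohort.df.copy()
    for k in INSTRUMENTS:
        df[f"sel_{k}"] = pd.array(sel[k], dtype="boolean")
    counts = {k: int(sel[k].sum()) for k in INSTRUMENTS}
    logger.info("selection counts: %s (psp>=%d, delinquency>=%d)",
                counts, thresholds.psp, thresholds.delinquency)
    return Cohort(df, validate=False), counts
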