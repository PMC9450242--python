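"""Reproduction of the source study's headline composite figures.

The study's individual-level data are not public, but its per-gender
stratum prevalences and type-level comorbidity rates are.  Those printed
stratum values are the *inputs* here; the package's own operations
(gender adjustment, within-stratum summation, conditional c/p rates)
recompute every headline composite from them, so the composite arithmetic
of the reporting pipeline is verifiable exactly.

All values are percentages.  Composites are returned unrounded; display
rounding is half-up to one decimal.
"""

from __future__ import annotations

from .prevalence import gender_adjust
from .comorbidity import conditional_comorbidity

#: Published per-gender stratum prevalences (percent): (female, male).
STRATUM_ESTIMATES: dict[str, tuple[float, float]] = {
    # substance table
    "alcohol_dependence": (10.4, 7.1),
    "alcohol_harmful_use": (5.1, 3.3),
    "any_substance_dependence": (13.1, 8.8),
    "any_substance_harmful_use": (4.5, 2.9),
    # psychiatric table
    "any_psychiatric": (36.4, 17.0),
    # gambling/gaming table
    "gambling_at_risk": (0.7, 9.7),
    "gambling_problem": (0.0, 3.4),
    "gambling_pathological": (0.4, 2.4),
    "gaming_at_risk": (0.2, 5.7),
    "gaming_pathological": (0.0, 2.3),
    # type-level comorbidity table
    "comorbid_sud_psychiatric": (7.0, 2.6),
}


def headline_composites() -> dict[str, float]:
    """Recompute every headline composite from the stratum inputs."""
    s = STRATUM_ESTIMATES

    def adj(key: str) -> float:
        return gender_adjust(*s[key])

    sud_f = s["any_substance_dependence"][0] + s["any_substance_harmful_use"][0]
    sud_m = s["any_substance_dependence"][1] + s["any_substance_harmful_use"][1]
    alc_f = s["alcohol_dependence"][0] + s["alcohol_harmful_use"][0]
    alc_m = s["alcohol_dependence"][1] + s["alcohol_harmful_use"][1]
    # the >= 12 observed-pair rule held in the study for the SUD/psychiatric
    # conditionals, so observed_pairs is not re-checked here
    cond = conditional_comorbidity
    return {
        # diagnosable SUD (dependence or harmful use), gender-adjusted
        "total_sud_prevalence_pct": gender_adjust(sud_f, sud_m),
        # alcohol-specific SUD, gender-adjusted
        "alcohol_sud_prevalence_pct": gender_adjust(alc_f, alc_m),
        # any of the 16 psychiatric disorders, gender-adjusted
        "any_psychiatric_prevalence_pct": adj("any_psychiatric"),
        # joint SUD and psychiatric disorder, gender-adjusted
        "sud_psychiatric_comorbidity_pct": adj("comorbid_sud_psychiatric"),
        # conditional comorbidity c/p: share of those with one type who
        # also have the other
        "boys_sud_with_psychiatric_pct":
            cond(s["comorbid_sud_psychiatric"][1], sud_m),
        "boys_psychiatric_with_sud_pct":
            cond(s["comorbid_sud_psychiatric"][1], s["any_psychiatric"][1]),
        "girls_sud_with_psychiatric_pct":
            cond(s["comorbid_sud_psychiatric"][0], sud_f),
        # gambling / gaming severity bands, gender-adjusted
        "gambling_at_risk_prevalence_pct": adj("gambling_at_risk"),
        "gambling_problem_prevalence_pct": adj("gambling_problem"),
        "gambling_pathological_prevalence_pct": adj("gambling_pathological"),
        "gaming_at_risk_prevalence_pct": adj("gaming_at_risk"),
        # boys meeting gambling-disorder criteria (problem + pathological)
        "boys_gambling_disorder_pct":
            s["gambling_problem"][1] + s["gambling_pathological"][1],
    }


#: Published values of the same composites, for verification listings.
PUBLISHED_COMPOSITES: dict[str, tuple[float, float]] = {
    # key -> (published value, comparison tolerance in percentage points)
    "total_sud_prevalence_pct": (14.6, 0.1),
    "alcohol_sud_prevalence_pct": (13.0, 0.5),
    "any_psychiatric_prevalence_pct": (26.7, 0.1),
    "sud_psychiatric_comorbidity_pct": (4.8, 0.1),
    "boys_sud_with_psychiatric_pct": (22.0, 0.5),
    "boys_psychiatric_with_sud_pct": (15.0, 0.5),
    "girls_sud_with_psychiatric_pct": (40.0, 0.5),
    "gambling_at_risk_prevalence_pct": (5.2, 0.1),
    "gambling_problem_prevalence_pct": (1.7, 0.1),
    "gambling_pathological_prevalence_pct": (1.4, 0.1),
    "gaming_at_risk_prevalence_pct": (3.0, 0.1),
    "boys_gambling_disorder_pct": (5.8, 0.1),
}
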