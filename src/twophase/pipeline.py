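"""End-to-end orchestration: simulate -> select -> score -> estimate ->
comorbidity -> report bundle, plus verification against expected values.

The report bundle is plain delimited text plus one structured key-value
summary; every numeric cell is emitted unrounded alongside its
display-rounded form, because rounding ambiguity is the main reproduction
hazard in two-phase composite arithmetic.  A provenance log records every
estimation assumption invoked together with the affected counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .cohort import Cohort, read_cohort
from .comorbidity import comorbidity_matrix, conditional_comorbidity, \
    dyad_table, MIN_PAIRS
from .prevalence import build_prevalence_table, table_value
from .published import PUBLISHED_COMPOSITES, headline_composites
from .screening import CutoffPolicy
from .simulate import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)


def round_half_up(x: float, digits: int = 1) -> float:
    """Display rounding: half-up, as tables conventionally print."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    input_path: Optional[str] = None
    simulate: Optional[GeneratorConfig] = None
    seed: Optional[int] = None
    policy: CutoffPolicy = field(default_factory=CutoffPolicy)
    min_interview_base: int = 1
    alpha: float = 0.05
    min_pairs: int = MIN_PAIRS
    out_dir: str = "twophase_report"

    def __post_init__(self):
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError(
                "exactly one of input_path / simulate must be given")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


BUNDLE_FILES = (
    "table_substance.csv",
    "table_psychiatric.csv",
    "table_gambling_gaming.csv",
    "table_comorbidity_types.csv",
    "table_dyads.csv",
    "summary.yaml",
    "provenance.log",
)


def _summary_from_tables(prev: pd.DataFrame, com: pd.DataFrame,
                         min_pairs: int) -> dict[str, float]:
    """Headline composites of one pipeline run (unrounded percentages)."""
    def val(cat, stratum="adjusted"):
        return table_value(prev, cat, stratum)

    out = {
        "total_sud_prevalence_pct":
            val("any_substance:dependence") + val("any_substance:harmful_use"),
        "alcohol_sud_prevalence_pct":
            val("alcohol:dependence") + val("alcohol:harmful_use"),
        "any_psychiatric_prevalence_pct": val("any_psychiatric:lifetime"),
    }
    for cat in ("gambling:at_risk", "gambling:problem",
                "gambling:pathological", "gaming:at_risk",
                "gaming:pathological"):
        try:
            out[cat.replace(":", "_") + "_prevalence_pct"] = val(cat)
        except KeyError:
            pass
    row = com[(com["type_a"] == "sud") & (com["type_b"] == "psychiatric")]
    if len(row):
        r = row.iloc[0]
        out["sud_psychiatric_comorbidity_pct"] = float(r["c_total"])
        pairs = int(r["observed_pairs"])
        specs = [
            ("boys_sud_with_psychiatric_pct", r["c_male"],
             val("any_substance:dependence", "male")
             + val("any_substance:harmful_use", "male")),
            ("boys_psychiatric_with_sud_pct", r["c_male"],
             val("any_psychiatric:lifetime", "male")),
            ("girls_sud_with_psychiatric_pct", r["c_female"],
             val("any_substance:dependence", "female")
             + val("any_substance:harmful_use", "female")),
            ("girls_psychiatric_with_sud_pct", r["c_female"],
             val("any_psychiatric:lifetime", "female")),
        ]
        for key, c, p in specs:
            if p > 0:
                cond = conditional_comorbidity(float(c), p, pairs, min_pairs)
                if cond is not None:
                    out[key] = cond
    return out


def _provenance_lines(cohort: Cohort) -> list[str]:
    df = cohort.df
    lines = ["assumptions applied (with affected counts):"]
    for k in ("addis", "mini", "nods", "igds"):
        sel = df[f"sel_{k}"].fillna(False).astype(bool)
        itv = df[f"int_{k}"].fillna(False).astype(bool)
        lines.append(
            f"  {k}: selected={int(sel.sum())} interviewed={int(itv.sum())} "
            f"lost={int((sel & ~itv).sum())} "
            "(lost assumed distributed as interviewed)")
    neg = (~df["sel_addis"].fillna(False).astype(bool)).sum()
    lines.append(f"  screen-negative => no diagnosis: {int(neg)} "
                 "participants below every substance cut-off")
    unscreened = df["ever_gambled_money"].isna()
    lines.append(f"  cohort-1 gambling/gaming imputation: "
                 f"{int(unscreened.sum())} never-screened participants "
                 "imputed from the cohort-2 non-contacted reference")
    return lines


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; return file paths.

    Any stage error aborts with a stage-named diagnostic and removes
    partial outputs.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        stage = "load"
        if cfg.input_path is not None:
            cohort = read_cohort(cfg.input_path)
        else:
            cohort, truth = generate_cohort(cfg.simulate, seed=cfg.seed)
            truth_path = out_dir / "truth.csv"
            truth.to_csv(truth_path, index=False)
            written.append(truth_path)

        stage = "estimate"
        gambling_screened = cohort.df["ever_gambled_money"].notna().any()
        categories = ["substance", "psychiatric"]
        if gambling_screened:
            categories.append("gambling_gaming")
        prev = build_prevalence_table(
            cohort, categories=categories,
            policy=cfg.policy, min_interview_base=cfg.min_interview_base)
        prev = prev.assign(
            prevalence_rounded=prev["prevalence"].map(
                lambda v: round_half_up(v, 1)))

        def _write(name: str, frame: pd.DataFrame) -> Path:
            p = out_dir / name
            frame.to_csv(p, index=False)
            written.append(p)
            return p

        is_sub = prev["category"].str.split(":").str[0].isin(
            ["alcohol", "cannabis", "other_substances", "any_substance"])
        is_gam = prev["category"].str.startswith(("gambling", "gaming"))
        _write("table_substance.csv", prev[is_sub])
        _write("table_psychiatric.csv", prev[~is_sub & ~is_gam])
        if gambling_screened:
            _write("table_gambling_gaming.csv", prev[is_gam])
        else:
            p = out_dir / "table_gambling_gaming.csv"
            p.write_text("category,timeframe,stratum,d,i,L,N,prevalence,"
                         "prevalence_rounded\n"
                         "# no participant screened for gambling/gaming: "
                         "unscreened cohort, nothing to estimate\n")
            written.append(p)

        stage = "comorbidity"
        com = comorbidity_matrix(cohort)
        com = com.assign(
            c_total_rounded=com["c_total"].map(lambda v: round_half_up(v, 1)))
        _write("table_comorbidity_types.csv", com)
        dyads = dyad_table(cohort, min_pairs=cfg.min_pairs, alpha=cfg.alpha,
                           policy=cfg.policy)
        _write("table_dyads.csv", dyads)

        stage = "summary"
        summary = _summary_from_tables(prev, com, cfg.min_pairs)
        payload = {k: {"value": float(v), "rounded": round_half_up(v, 1)}
                   for k, v in summary.items()}
        spath = out_dir / "summary.yaml"
        spath.write_text(yaml.safe_dump(payload, sort_keys=True))
        written.append(spath)

        ppath = out_dir / "provenance.log"
        ppath.write_text("\n".join(_provenance_lines(cohort)) + "\n")
        written.append(ppath)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return {p.name: p for p in written}


# ---------------------------------------------------------------------------
# Verification

def default_expectations() -> pd.DataFrame:
    """Expected composite values shipped with the package."""
    with resources.files("twophase.data").joinpath(
            "expectations.csv").open() as fh:
        return pd.read_csv(fh)


def verify_values(values: dict[str, float],
                  expectations: Optional[pd.DataFrame] = None
                  ) -> pd.DataFrame:
    """Compare computed values with expectations (id, expected, tolerance).

    Returns one row per expectation with the computed value, the absolute
    deviation and a pass flag; a missing computed value is a failing row,
    not a crash.
    """
    exp = expectations if expectations is not None else default_expectations()
    records = []
    for _, row in exp.iterrows():
        key = row["id"]
        got = values.get(key)
        ok = got is not None and abs(got - row["expected"]) <= row["tolerance"]
        records.append({
            "id": key, "expected": row["expected"],
            "tolerance": row["tolerance"], "value": got,
            "deviation": None if got is None
            else abs(got - row["expected"]),
            "passed": bool(ok)})
    return pd.DataFrame.from_records(records)


def verify_report(summary_path,
                  expectations: Optional[pd.DataFrame] = None
                  ) -> pd.DataFrame:
    """Verify a written ``summary.yaml`` report against expectations."""
    with open(summary_path) as fh:
        payload = yaml.safe_load(fh) or {}
    values = {k: v["value"] for k, v in payload.items()}
    return verify_values(values, expectations)


def verify_published(expectations: Optional[pd.DataFrame] = None
                     ) -> pd.DataFrame:
    """Recompute the headline composites from the published stratum values
    and verify them (the worked-example reproduction)."""
    return verify_values(headline_composites(), expectations)


def _expectations_frame_from_published() -> pd.DataFrame:
    return pd.DataFrame(
        [{"id": k, "expected": v, "tolerance": tol}
         for k, (v, tol) in PUBLISHED_COMPOSITES.items()])
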