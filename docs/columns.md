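# Cohort column dictionary (schema version 1)

One wide CSV row per screened participant, UTF-8, header row required.
Booleans are written `1`/`0`; an **empty cell encodes absent-by-design**
(never conflated with `0`): the cohort-1 gambling/gaming screening gap and
outcomes of interviews that did not take place.

## Identity and stratification

| column | type | values |
|---|---|---|
| `participant_id` | string | unique, opaque |
| `gender` | enum | `female`, `male` |
| `cohort` | enum | `cohort1` (no baseline gambling/gaming screening), `cohort2` |

## Phase-1 screening

| column | type | notes |
|---|---|---|
| `audit` | int 0–40 | alcohol screen; cut-off 6 selects |
| `dudit` | int 0–44 | drug screen; cut-off 2 selects |
| `surnc` | int ≥ 0 | substance-related negative consequences; cut-off 5 selects |
| `psp` | int ≥ 0 | psychosomatic problems; sample 90th percentile selects |
| `delinquency` | int ≥ 0 | delinquent behaviours; sample 90th percentile selects |
| `scr_<syndrome>` | bool | 12 psychiatric screen syndromes: `depression`, `suicidality`, `mania`, `panic`, `agoraphobia`, `social_anxiety`, `ocd`, `ptsd`, `gad`, `psychotic`, `anorexia`, `bulimia` |
| `adhd_self_report` | bool | self-reported ADHD/ADD |
| `ever_gambled_money` | bool or absent | gambling screen question |
| `ever_paid_in_game` | bool or absent | gambling screen question |
| `gaming_hours_band` | enum or absent | `none`, `under_1h`, `1_2h`, `3_4h`, `5h_plus`; band `3_4h`+ selects |

The three gambling/gaming fields are absent together, and only for
cohort-1 participants who never had a substance-use or psychiatric
interview (where the late screening would have happened).

## Selection and participation

| column | type | notes |
|---|---|---|
| `sel_addis`, `sel_mini`, `sel_nods`, `sel_igds` | bool | phase-1 selection per instrument |
| `int_addis`, `int_mini`, `int_nods`, `int_igds` | bool | interview completed; `int_*` implies `sel_*` |
| `loss_reason` | enum | `not_reached`, `declined`, `unknown`; `not_applicable` iff nothing was lost |

## Phase-2 interview outcomes (absent unless interviewed)

Per substance group `s` in `alcohol, cannabis, sedatives, opioids,
cocaine, stimulants, ecstasy, hallucinogens, solvents, other, mixed`:

| column | type |
|---|---|
| `<s>_dep_lt`, `<s>_dep_py` | int 0–6 dependence criteria (past-year ≤ lifetime) |
| `<s>_harm_lt`, `<s>_harm_py` | bool harmful-use flag |

Per psychiatric module: `<m>_lt` and/or `<m>_py` (bool) for exactly the
timeframes the module reports — lifetime and past-year for `depression`,
`suicidality`, `manic_episode`, `panic_disorder`, `psychotic_syndrome`,
`affective_psychosis`; past-year only for `agoraphobia`, `social_anxiety`,
`anorexia`, `bulimia`; lifetime only for `ocd`, `ptsd`, `gad`, `aspd`,
`adhd`, `add`.

| column | type |
|---|---|
| `nods_score` | int 0–10 (gambling severity) |
| `igds_score` | int 9–45 (gaming severity) |
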