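"""Generate a synthetic two-phase cohort and inspect its structure.

The generator draws latent disorder liabilities, screening scores with
configurable sensitivity/specificity, interview selection via the real
cut-off rules, and Bernoulli participation — returning both the cohort
table and a truth record with every latent state.
"""

import twophase as tp

cohort, truth = tp.generate_cohort(tp.GeneratorConfig(), seed=42)
df = cohort.df

print(f"participants: {len(cohort)} "
      f"({cohort.stratum_size('female')} girls, "
      f"{cohort.stratum_size('male')} boys)")
for k in ("addis", "mini", "nods", "igds"):
    sel, itv = int(df[f'sel_{k}'].sum()), int(df[f'int_{k}'].sum())
    print(f"  {k:5s}: selected {sel:3d}, interviewed {itv:3d} "
          f"(lost {sel - itv})")
unscreened = int(df["ever_gambled_money"].isna().sum())
print(f"cohort-1 members never screened for gambling/gaming: {unscreened}")
print(f"true alcohol-dependent adolescents: "
      f"{int((truth['true_alcohol'] == 'dependence').sum())}")

# Selected/interviewed counts fall out of the screening cut-offs and the
# per-gender participation rates; the truth column is the latent state the
# estimators will be asked to recover.
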