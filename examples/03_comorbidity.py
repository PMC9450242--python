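"""Type-level comorbidity and confirmed-data phi dyads.

Type-level joint prevalence uses the same screening assumptions as the
marginal estimator; dyads of specific disorders use confirmed data only
and are banded: phi > 0.30 substantial, > 0.20 considerable, otherwise
moderate when significant at alpha = 0.05.
"""

import twophase as tp

cohort, _ = tp.generate_cohort(tp.GeneratorConfig(), seed=42)

matrix = tp.comorbidity_matrix(cohort)
print("type-level comorbidity (% of all screened, gender mean):")
print(matrix[["type_a", "type_b", "c_female", "c_male", "c_total"]]
      .round(2).to_string(index=False))

row = matrix[(matrix.type_a == "sud") & (matrix.type_b == "psychiatric")]
c, pairs = float(row.c_male.iloc[0]), int(row.observed_pairs.iloc[0])
table = tp.build_prevalence_table(cohort, categories=["substance"])
p = (tp.table_value(table, "any_substance:dependence", "male")
     + tp.table_value(table, "any_substance:harmful_use", "male"))
share = tp.conditional_comorbidity(c, p, observed_pairs=pairs)
print(f"\nboys with a SUD who also have a psychiatric disorder: "
      f"{share:.0f}% (c/p = {c:.1f}/{p:.1f}, {pairs} observed pairs)")

dyads = tp.dyad_table(cohort)
print(f"\n{len(dyads)} dyads among disorders with >= 12 confirmed cases; "
      "strongest five by phi:")
print(dyads.sort_values('phi', ascending=False).head(5)
      .round(3).to_string(index=False))
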