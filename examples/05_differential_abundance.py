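"""Per-taxon differential abundance with ethnic x geography interactions.

Builds a synthetic 12-taxon cohort in which 3 taxa carry a true age
effect of +0.8 on the log-mean scale, runs the per-taxon ZINB pipeline,
and prints the age effects: a taxon is "discriminatory" when its 95%
credible interval excludes zero, and effects above 0.35 are highlighted.
The interaction report then lists each (ethnic, geography) combination's
effect relative to the reference group, flagging taxa whose combinations
have non-overlapping intervals.
"""

from microzinb import DAConfig, interaction_effect_report, run_da_pipeline, synthetic_cohort

data = synthetic_cohort(n_samples=150, n_taxa=12, n_affected=3, effect=0.8, seed=13)
res = run_da_pipeline(data["counts"], data["metadata"], config=DAConfig(seed=13))
print(f"taxa in: {res.taxa_in}, filtered: {res.taxa_filtered}, analysed: {res.taxa_out}")

age = res.effects[res.effects["parameter"] == "age"]
cols = ["taxon", "effect", "q2.5", "q97.5", "discriminatory", "highlight"]
print(age[cols].round(3).to_string(index=False))
print(f"true age-affected taxa: {data['affected']}\n")

rep = interaction_effect_report(res)
flagged = rep[rep["nonoverlap_flag"]]["taxon"].unique()
print(f"taxa with at least one pair of non-overlapping ethnogeographic intervals: {len(flagged)}")
print(rep.head(8).round(3).to_string(index=False))
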