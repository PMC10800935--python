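"""Classify depression-like mice and analyze SIT/TST treatment effects.

A mouse is depression-like iff its interaction time dropped in both
post-defeat tests: dSIT2 < dSIT1 and dSIT3 < dSIT1.  Depressed mice are
assigned to vehicle/diazepam/allopregnanolone arms; the simulated
allopregnanolone effect is +40 s interaction time from day 1.
"""

from sdsephys import behavior, synth

cfg = synth.BehaviorSimConfig(n_mice=78, p_depressed=1.0, seed=6)
table = synth.simulate_behavior_cohort(cfg)

frac = behavior.depressed_fraction(table)
print(f"cohort: {len(table)} mice, {frac:.1%} classified depression-like")

sit = behavior.sit_time_course(table)
print("\nSIT time course (mean interaction time, s):")
print(sit.summary.to_string(index=False))
print("\narm contrasts (Tukey per day):")
for t in sit.tests:
    flag = "*" if t.significant else " "
    print(f" {flag} {t.comparison:45s} p_adj = {t.p_adjusted:.4f}")

tst = behavior.treatment_effect_table(table, "tst")
print("\nTST immobility (Dunnett vs vehicle):")
for t in tst.tests:
    flag = "*" if t.significant else " "
    print(f" {flag} {t.comparison:45s} p_adj = {t.p_adjusted:.4f}")
# Expect the allopregnanolone-vs-vehicle SIT contrasts to be significant at
# every post-drug day, and the diazepam arm to track vehicle.
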