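"""Clean a LipidSearch-style results table with the inclusion criteria
RT > 2 min, area > 1000, score < 0.5 (strict inequalities), and restrict
adducts to negative-mode deprotonations.

The demonstration table is constructed with known labels: every false row
violates exactly one criterion, some sitting exactly on a threshold.
"""

from gangliotk import apply_filters, restrict_adducts
from gangliotk.simulate import simulate_results_table

table, labels = simulate_results_table(n_true=40, n_false=60, seed=7)
print(f"input: {len(table)} rows ({labels.sum()} built to survive)")

kept, flagged = restrict_adducts(table, allowed=("-H", "-2H"))
filtered, report = apply_filters(kept)

print(f"kept {report.n_kept} rows; removed per criterion: "
      f"rt {report.removed_by_rt}, area {report.removed_by_area}, "
      f"score {report.removed_by_score}")
survivors_match_truth = set(filtered.index) == set(table.index[labels])
print("survivors are exactly the true rows:", survivors_match_truth)
print("Rows at exactly RT=2 min, area=1000 or score=0.5 are removed: the "
      "criteria read 'more than / greater than / less than'.")
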