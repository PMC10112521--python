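"""Score assay calls against the packaged reference-chemical truth tables.

Prints the confusion counts and performance metrics of each assay column
for both modes — the numbers a screener uses to compare assay variants.
"""

from arscreen.reference_classification import (
    load_reference_table,
    score_reference_table,
)

for mode in ("agonist", "antagonist"):
    table = load_reference_table(mode)
    print(f"\n{mode} references (n={len(table)}):")
    for column in table.columns[2:]:
        m = score_reference_table(table, column, mode=mode).printed()
        print(f"  {column:>17}: TP={m['tp']:>2} FP={m['fp']} FN={m['fn']} "
              f"TN={m['tn']:>2} | sens {m['sensitivity_pct']:>3}% "
              f"spec {m['specificity_pct']:>3}% "
              f"BA {m['balanced_accuracy_pct']:>3}%")
# balanced accuracy = (sensitivity + specificity) / 2, computed from
# unrounded fractions and reported to whole percent
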