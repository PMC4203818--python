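"""Worked arithmetic over published-style summary counts.

Builds a diplotype-call set realizing a published allele-count table
(2040 chromosome slots from 1020 individuals), then re-derives allele
frequencies by gene counting, the activity-class percentages over the
evaluable denominator, and the region-by-activity chi-square.
"""

import numpy as np

from cyp2d6pop import (
    DiplotypeCall,
    activity_class_table,
    allele_frequencies,
    chi2_independence,
    load_definition_table,
)
from cyp2d6pop.diplotyping import slot_multiplier

SLOT_COUNTS = {
    "*1": 814, "*2": 438, "*3": 14, "*4": 191, "*5": 94, "*9": 23,
    "*10": 42, "*17": 114, "*29": 69, "*34": 1, "*35": 53, "*39": 17,
    "*41": 112, "*1x2": 12, "*1x3": 1, "*2x2": 11, "*2x5": 1, "*4x2": 4,
    "*17x2": 1, "*35x2": 1, "Others": 27,
}

defs = load_definition_table()
slots = [lab for lab, n in SLOT_COUNTS.items() for _ in range(n)]
slots.sort(key=lambda lab: -slot_multiplier(lab))
half = len(slots) // 2
calls = [
    DiplotypeCall(f"r{i}", a, b, slot_multiplier(a) + slot_multiplier(b))
    for i, (a, b) in enumerate(zip(slots[:half], slots[half:][::-1]))
]

ft = allele_frequencies(calls)
print(f"chromosomes: {ft.chromosomes['Total']}")
for star in ("*1", "*2", "*4", "*17", "*41"):
    print(f"  {star:5s} {ft.pct.loc[star, 'Total']:5.1f}%")

act = activity_class_table(calls, defs)
print(f"\nevaluable chromosomes (ND excluded): {act.chromosomes['Total']}")
print(act.pct["Total"].round(1).to_string())

# region x activity-class percentages and chromosome totals, as printed
PCTS = {
    "North": [14.7, 14.2, 68.2, 2.9], "Northeast": [15.9, 17.8, 63.2, 3.1],
    "Southeast": [14.3, 21.4, 61.9, 2.4], "South": [15.4, 18.4, 64.2, 2.0],
}
CHROM = {"North": 484, "Northeast": 517, "Southeast": 509, "South": 501}
table = np.array(
    [[round(p * CHROM[r] / 100) for p in PCTS[r]] for r in PCTS]
)
res = chi2_independence(table)
print(f"\nregion x activity chi2 = {res.statistic:.1f}, df = {res.df:.0f}, "
      f"p = {res.p_value:.2f}")
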