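"""Positional importance ranking from an alanine-scan blot experiment.

Each analog group replaces one EntF* residue with alanine; lanes are
normalized to total protein with the placebo mean at 100 %.  A pooled
one-way ANOVA gives Fisher's-LSD p-values, combined per position as
(1 - p_placebo_vs_analog) * p_EntF*_vs_analog: low scores mean the
substitution abolished activity, i.e. the position matters.  Positions
are classified into 5 importance classes (class 1 = most important).
"""

from entfkit.alascan import scan_pipeline
from entfkit.synthetic import gen_blots

blots = gen_blots(seed=0)  # placebo / EntF* / 15 alanine analogs, 15 lanes each
ranking = scan_pipeline(blots)

print("position  combined score  class  alignment weight")
for pos in sorted(ranking.scores):
    print(f"{pos:>8}  {ranking.scores[pos]:14.3e}  {ranking.classes[pos]:>5}"
          f"  {ranking.multipliers[pos]:>16}")

print(f"\nclass 1 (most important): {sorted(ranking.positions_in_class(1))}")
print(f"class 2:                  {sorted(ranking.positions_in_class(2))}")
if ranking.jenks_disagreement:
    print(f"Jenks natural-breaks disagrees at: {ranking.jenks_disagreement}")
else:
    print("Jenks natural-breaks confirms the clustering.")
print("\nThe generator planted placebo-like effects at positions 1, 2, 10 "
      "and intermediate ones at 3, 9; the ranking recovers them.")
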