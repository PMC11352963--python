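"""Agreement between two dichotomous screening instruments.

A 2x2 cross-table of dyslexia/typical classifications is summarised by a
Pearson chi-square (no continuity correction, 1 df): a large statistic
means the two instruments pick out overlapping sets of children far beyond
chance.
"""

from lettura import agreement_from_counts

print("battery vs word/nonword list screening (both+, A-only, B-only, both-):")
t = agreement_from_counts(51, 71, 59, 426)
print(f"  counts {t.counts}: chi-square = {t.chi_square:.2f}, p = {t.p:.2g}")

print("battery vs text-reading screening:")
t = agreement_from_counts(8, 7, 102, 501)
print(f"  counts {t.counts}: chi-square = {t.chi_square:.2f}, p = {t.p:.2g}")
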