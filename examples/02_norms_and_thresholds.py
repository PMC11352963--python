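"""Single-case thresholds from normative statistics.

The abnormality cutoff for an error cluster is the smallest integer count
exceeding the Crawford-Howell critical value at one-sided alpha = 0.005:
round(M + t_crit(0.995, n-1) * SD * sqrt((n+1)/n)), floored at 2 errors.
The packaged reference table carries the published per-grade cells.
"""

from lettura import cluster_threshold, crawford_howell, load_embedded_norms

norms = load_embedded_norms()

print("grade-2 word-list cells (M, SD, n -> printed threshold / recomputed):")
for label in ("Attentional", "LetterPosition", "Surface", "Vowel", "Total"):
    cell = norms.get(2, label, "words")
    recomputed = cluster_threshold(cell.M, cell.SD, cell.n)
    print(
        f"  {label:16s} M={cell.M:5.1f} SD={cell.SD:5.1f} n={cell.n}"
        f"  printed={cell.threshold:3d}  recomputed={recomputed:3d}"
    )

print()
print("single case: a grade-2 child with 15 between-word migrations")
t, df, p1, p2 = crawford_howell(15, M=5.4, SD=3.6, n=74)
print(f"  t({df}) = {t:.3f}, one-sided p = {p1:.4f}")
print("  -> at or above the cutoff of "
      f"{cluster_threshold(5.4, 3.6, 74)}: flagged at alpha = 0.005")
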