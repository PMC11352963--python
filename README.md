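# lettura

Dyslexia-type screening for Italian reading-aloud batteries: classify a
child's reading errors under a dual-route reading model, aggregate them into
dyslexia-type cluster scores, compare them with per-grade norms through a
single-case test, and emit a diagnostic profile — plus the
stimulus-construction algorithms and a simulated-reader generator that make
every stage testable without real child data.

## Who it is for

Clinical researchers and psycholinguists working with list-reading batteries
whose items are *sensitive* by construction: migratable words whose letter
transposition yields another word (*lardo → ladro*), word pairs supporting
position-preserving between-word exchanges (*viso vano → vino vaso*), words
embedding other words after a left prefix (*convento → vento*), trisyllabic
words with lexically determined stress, and nonwords one vowel away from
real words (*\*bredo → brodo*). Different dyslexia types leave different
signatures on these items:

| cluster | signature error | mechanism |
|---|---|---|
| Attentional | between-word migration | letter-to-word binding |
| Letter Position | within-word migration (anagram) | letter-order encoding |
| Surface | stress-position error | lexical route |
| Multi-letter | digraph / context-rule failure | sublexical conversion |
| Vowel / Consonant / Voicing | unit-selective substitutions | sublexical conversion |
| Doubling | gemination errors | phonological output buffer |
| Deep | semantic / morphological errors | lexical-semantic route |
| Neglect | left-prefix omissions | visual-spatial attention |

## The statistical core

Observed errors are coded with weights: one discrepancy admitting *k* ≤ 3
alternative readings becomes an "or" group with weight 1/*k* per
alternative; independent discrepancies in the same word are separate "and"
groups of weight 1. Cluster scores are the weight sums per list group
(words, word pairs, nonwords).

A child's count *x* is compared with their grade's normative sample
(*M*, *SD*, *n*) by the Crawford–Howell single-case statistic

```
t = (x − M) / (SD · √((n+1)/n)),   df = n − 1
```

and the integer abnormality cutoff of a cell is

```
threshold = max(2, round(M + t_crit(0.995, n−1) · SD · √((n+1)/n)))
```

i.e. one-sided α = 0.005 with a floor of two errors. The published per-grade
reference tables for the word and nonword lists ship with the package;
`build_norms` recomputes the same structure (with percentile-based outlier
trimming) from any scored cohort.

## Worked example

`python examples/03_synthetic_screening.py` builds a seeded synthetic
lexicon, assembles the default 255-item battery, simulates a grade-5 reader
who migrates letters on half of the migratable items, and diagnoses the
scored profile:

```
lexicon: 1200 words; battery: 255 items
simulated reader made errors on 11 of 255 items
child demo-lpd (grade 5): pure
  ...
  LetterPosition|words          11.00 / threshold 6 *FLAG*
  ...
  labels: Letter Position Dyslexia
```

The reader's 11 within-word migrations exceed the grade-5 cutoff of 6 for
the letter-position cluster and no other cluster is flagged, so the profile
is a *pure* Letter Position Dyslexia. The other examples cover single-error
classification (`01`), norms and thresholds (`02`) and instrument agreement
chi-squares (`04`).

A thin CLI mirrors the pipeline for shell use:

```
lettura simulate --seed 7 --battery-out battery.csv --transcript-out resp.csv \
        --reader "migration=0.5,grade=5"
lettura code --stimuli battery.csv --transcripts resp.csv --out coded.csv
lettura score --stimuli battery.csv --coded coded.csv --transcripts resp.csv --out scores.csv
lettura diagnose --stimuli battery.csv --coded coded.csv --transcripts resp.csv --out diag.json
lettura norms --embedded --out norms.json
lettura agreement diagA.json diagB.json
```

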