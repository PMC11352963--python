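# Methods

This note documents the models, conventions and design choices behind
`lettura`, in the order the pipeline runs them.

## Grapheme model

All error analysis operates on graphemes — the 1–3 letter conversion units
of Italian orthography — rather than raw letters, so that a failure of a
multi-letter rule (e.g. reading *chiesa* with /tʃ/ instead of /k/) is
distinguishable from a plain consonant substitution. The inventory is a
versioned CSV rule table (`data/grapheme_rules.csv`): vowels, consonants,
the digraphs *ch, gh, gn, qu*, and the context-sensitive units *gl* (+ *i*),
*sc* (+ *e/i*), *ci/gi* (+ vowel, diacritic *i*). Parsing is longest-match,
left-to-right, with no backtracking — deterministic and adequate for
Italian; the table format allows other languages, none are shipped.
Feature relations live in the same table: voicing pairs *p/b, t/d, c/g,
f/v, s/z* (plus *ch/gh* and *ci/gi*; *k* maps one-way into the *c/g* pair)
and homorganic nasality pairs *b/m, d/n*. Accented vowels (*à è é ì ò ù*)
keep their surface but share the identity of the plain vowel: the accent
marks stress, not letter identity. Case folding and trimming happen at I/O,
giving a single normalization point. Sibilance is representable in the
table but no detector consumes it: no error code is defined over it.

## Alignment and error coding

The classifier aligns target and response with a minimal edit script under
unit costs over four operations — substitute, insert, delete, and
single-grapheme move (adjacent or not) — found by uniform-cost search that
always repairs the leftmost mismatch; ties resolve toward moves and
leftmost edits. The move operation is what lets a transposition cost 1
rather than 2, so *lardo → ladro* is one migration, not two substitutions.
The search is verified against a brute-force minimal-edit oracle
(operations at any position) on exhaustive small alphabets and sampled
pairs up to length 6.

Classification is layered:

1. a missing response is one whole-word *no-response* code of weight 1,
   outside every cluster (it counts only toward raw error totals, since the
   taxonomy assigns it no mechanism);
2. a segmentally correct response can only carry a *stress-shift* (stress
   list only; stress errors on segmentally wrong readings are not counted,
   and nonwords never yield stress codes because either stress is a
   legitimate reading of a string with no lexical entry);
3. an anagram response is coded as within-word migration(s), pre-empting
   every other reading (so *corpo → copro* is never analysed as affix
   material);
4. otherwise whole-word detectors that explain the entire discrepancy —
   neglect (left-prefix omission, or a fully substituted left prefix of
   ≥ 2 graphemes), semantic (table membership), morphological (shared stem,
   affix from a configurable inventory) — compete; when several fire they
   form one "or" group with equal weights (capped at 3 alternatives in
   precedence order);
5. failing those, each edit operation becomes its own "and" group, with
   three refinements: an insert/delete duplicating or degeminating an
   adjacent grapheme is a doubling code; a substitution between feature
   counterparts is labelled voicing- or nasality-feature; any grapheme with
   a rule id on either side is a multi-letter-rule unit.

Between-word migration uses the printed neighborhood: the horizontal pair
partner and the items on the lines immediately above and below in the same
list. A **substitution** whose response grapheme matches the *horizontal*
partner at the same within-word position is coded as a between-word
migration outright — the pairs list is constructed precisely so that the
exchange is the signature (*viso vano → vino vaso* yields two migration
codes). A **vertical** match, or any **addition** matching a neighbor
position, is genuinely ambiguous and joins the letter-level reading as an
"or" alternative (*prati → pirati* under *circo*: vowel addition or
vertical migration, 0.5 each). Treating vertical substitution matches as
outright migrations was tried and rejected: on dense synthetic lexicons it
suppressed legitimate vowel and voicing readings whenever a neighbor
happened to share the discrepant grapheme's position.

A single-letter initial substitution is *not* treated as neglect: it
carries no side signature, and claiming it would contaminate the pairs-list
exchange coding. Semantic coding requires table membership and yields to a
visual reading only when the response is both letter-close (edit distance
≤ 2) and letter-overlapping (≥ half of its letters occur in the target).

Weights are exact `Fraction`s (1, 1/2, 1/3), so cluster scores are exact
multiples of 1/6 and "or" groups sum to exactly 1 by construction.
Self-corrected responses are coded identically, with the flag carried
through — screening counts the initial reading.

## Cluster scores

Each code feeds the cluster named for the dyslexia whose signature it is
(see README table); nasality errors count as consonant errors. By default a
migration or doubling of a vowel *also* feeds the Vowel cluster
(`vowel_migrations_feed_vowel=True`), since that cluster collects every
error in which a vowel is involved; the choice is exposed because the
alternative reading (migrations stay exclusively positional) is defensible.
Scores aggregate per list group — words (word + stress lists), pairs,
nonwords — plus the overall index, and two normative views are
materialised: Surface errors restricted to the stress list, and
between-word migrations within the pairs list.

## Norming

Per grade, the worst-performing 5% tail (the 95th percentile of the error
distribution, linear interpolation by default) in any of the four indexes
is removed before computing descriptives: norms describe unimpaired
reading. A zero cutoff is ignored — error-free readers are never outliers.
Strata under 20 children trigger a warning.

The abnormality cutoff is `max(2, round(M + t_crit(1−α, n−1) · SD ·
sqrt((n+1)/n)))` with α = 0.005 **one-sided** and round-half-away-from-zero.
One-sided is deliberate: only high error counts are abnormal, and this
convention reproduces the published reference cells that are robust to the
rounding of their printed inputs; both α and sidedness are configuration
knobs. The floor of 2 errors prevents flagging a child for a single slip
when the normative sample made almost none. The packaged reference table
embeds the published cells verbatim (thresholds as printed, not
recomputed — some cells cannot be reproduced from their rounded M/SD and
were presumably computed from unrounded statistics) and is
checksum-verified at load. One embedded cell (grade-5 words, Consonant)
lost its printed SD in transcription of the source tables; its SD is
reconstructed as 2.0, the mid-range value consistent with the printed
threshold of 7 under the package's convention. No Voicing column exists in
the reference tables, so Voicing is computed and normable from cohorts but
never flagged against the embedded norms. Continuous (model-based) norming
is out of scope.

## Diagnosis

A cell is flagged when the (possibly fractional, unrounded) score is **at
or above** the integer threshold — the threshold is defined as the first
abnormal count, and the floor rule only makes sense inclusively; strict
comparison is available. A profile flagging exactly one cluster across list
groups is *pure*, several are *mixed*. The Surface Dyslexia label
additionally requires the stress-list view to be flagged when that view is
normed, since the stress list is the designed Surface instrument. Selective
sublexical patterns are labelled on top of the flags: consonant (or vowel)
deficits confined to nonwords with the other unit intact indicate a
conversion-route deficit; consonant errors in both words and nonwords are
the letter-identity candidate. Agreement between two dichotomous
screenings is a Pearson chi-square on the 2×2 table without continuity
correction (matching the published statistics), undefined when a margin is
zero.

## Synthetic data

The generator exists so the pipeline's statistical behavior can be measured
without child data; its defaults are the study conditions, not tuning
knobs.

**Lexicon.** CV-phonotactic words (4–9 letters, disyllabic/trisyllabic
bias, final vowels) with Zipf-like frequencies, from a consonant inventory
that avoids the letters opening multi-letter conversion sites, so
letter-level and grapheme-level operations coincide in simulation. Quotas
are guaranteed by construction: anagram pairs via adjacent middle-consonant
transposition (the *lardo/ladro* pattern), four-word exchange families
sharing exactly their two vowels (the *cena/pera/pena/cera* pattern:
"two shared letters" is read as two shared letter *types* at any position,
with a strictness option for same-position sharing), neglect carriers
(CV(C) prefix + embedded word), and one-middle-vowel-apart pairs. Default
size 1200 fills the default battery composition comfortably.

**Battery.** The default composition mirrors the published instrument:
125 words (20 migratable + 40 neglect + 20 vowel-neighbor + 30
function/abstract + 15 synonym-prone), 40 stress items, 25 word pairs and
40 nonwords — 255 items. Function/abstract and synonym-prone quotas are
filled from the remaining lexicon without frequency balancing (the
construction sources do not state one); synonym pairs are registered in the
semantic table the coder consults. Within-list order is randomised once per
seed; pairs share a printed line.

**Readers.** A profile holds one per-opportunity probability per error
type; at most one operator applies per item, and every operator draws
whether or not it fires, keeping the random stream — and hence all other
items' outcomes — invariant to upstream operators. Stress items are always
read segmentally correctly.

**Cohorts.** Per-cluster counts are drawn from a negative binomial
moment-matched to the cell's (M, SD) — the reference cells are
overdispersed (SD ≈ M) — with a Poisson fallback when SD² ≤ M, and the
summary totals recomputed as sums of the cluster draws. Because cells are
drawn independently while real error counts correlate across clusters, the
simulated *totals* are underdispersed relative to the reference Total
cells; calibration claims therefore attach to cluster cells, not totals.

## What the synthetic tests do and do not show

Passing calibration on synthetic cohorts shows the flagging machinery is
consistent with its own threshold convention (simulated false-flag rates
match the analytic tails of the count model, ≈ 1–2.5% for non-floor cells —
wider than the nominal 0.5% because integer thresholds and skewed counts
are coarser than the normal-theory derivation), and that signature errors
are recovered end-to-end (simulated letter-position readers at a 0.5
migration rate are flagged as pure letter-position profiles in ≥ 90% of
runs at grade 5, where the cluster threshold of 6 sits well inside the
Binomial(20, 0.5) mass; at grade 2 the same θ would sit near the threshold
of 10 and recovery is not claimed). It does **not** show field validity:
the synthetic lexicon has no frequency–familiarity structure, no semantic
space, no multi-letter-rule items, and real children's errors correlate
across clusters in ways independent draws do not capture.

## Problem sizes and numerical choices

Test simulations use 1,000 injection trials, 200 reader recovery runs and
5,000–6,000-child cohorts per check — sizes at which binomial Monte-Carlo
error is several times smaller than every asserted margin. The edit-script
oracle is exhaustive over a binary alphabet to length 4 and sampled over a
five-letter alphabet to length 6. Thresholds round half away from zero;
percentile method, α, sidedness, floor, flag comparison and the
vowel-migration routing are all `RunConfig` knobs with the defaults stated
above. Degenerate inputs: SD = 0 yields a floored threshold with a warning
in norm building and an error in the single-case test; empty responses are
no-response codes; one-grapheme words map to the exterior-left zone.
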