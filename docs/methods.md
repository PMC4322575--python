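# Methods

## Model and procedure

`cofreq` computes co-occurrence statistics over a longitudinal corpus of
timestamped clinical notes. The unit of co-occurrence is the **temporal
bin**: for a patient *p* and bin width *w* (days), let *t₀* be the time of
the patient's first note, *t* a note's offset from *t₀* in fractional
days, and *r* ~ U[0, *w*] a per-patient random offset. The note's bin is

    bin(w, r, t) = ⌊(t + r)/w⌋.

Bin *k* therefore covers *t + r* ∈ [*k·w*, (*k*+1)·*w*): half-open
semantics follow directly from the floor, and two notes more than *w* days
apart can never share a bin. The random offset removes any systematic
alignment between bin edges and calendar structure (e.g. weekends). The
distinguished width ∞ puts a patient's entire record in one bin.

The content of a bin is the **set** of term (or concept) IDs recognised in
its notes — within-bin multiplicity is deliberately ignored, because the
occurrence matrix the counts represent is binary. Counts are aggregated
two ways:

* **per-bin** — every bin containing an entity (or both members of a
  pair) contributes one count; a patient can contribute many;
* **per-patient** — a patient contributes at most one count per entity or
  pair, regardless of how many bins qualify.

At *w* = ∞ the two modes coincide. Per-patient singleton counts are
independent of *w* (the bin partition never changes which patients carry a
term), so a full export stores them once per level. Self-pairs are
excluded from the pair matrix: under set semantics f(X,X) = f(X), which is
already in the singleton file.

Patient eligibility follows the usual longitudinal-record criterion: at
least 10 notes spanning at least 365 days (both inclusive; both
configurable). "One year" is implemented as 365 days to match the
bin-width convention.

## Annotation

Term recognition is dictionary-based: the note is lowercased and tokenised
on non-word boundaries, and matching is longest-match, leftmost,
non-overlapping (maximal munch) over token n-grams. This policy is a
design choice — it is the standard concept-recogniser convention and is
deterministic and insertion-order independent. Lexicon construction drops
entries that are stop words, first/surname homonyms, or shorter than four
characters (short strings are overwhelmingly ambiguous abbreviations);
dropped entries are reported with their reason.

Negation is a trigger-window approximation of NegEx rather than the full
regular-expression engine: a mention is negated when a pre-trigger ends
within a 6-token window before it or a post-trigger starts within the
window after it, and the scope never crosses sentence-ending punctuation
(`. ; : ? !`). Trigger lists are plain-text data files shipped with the
package and fully overridable. History and family-history flags are set
when a mention falls after a matching section marker and before the next
section marker of any kind; family-history markers subsume the plain
"history" token they contain.

Whether negated, history and family-history mentions belong in the counts
is not a settled convention; the default policy **excludes negated and
family-history mentions and includes history mentions**, and all three are
independent booleans on the pipeline configuration.

Term→concept mapping is many-to-many, with three data-driven refinements
applied in order: explicitly suppressed (term, concept) interpretations
are removed (the "clip"-as-peptide case); optionally, a term is kept only
when its remaining concepts all fall in a requested set of semantic groups
and the mapping is unambiguous (exactly one concept); drug concepts are
replaced by their ingredient concepts through a supplied normalisation
map. Terms with no surviving concept are dropped from concept-level
output. Concept→CUI is enforced one-to-one. The ambiguity suppression is
driven by an explicit pairs file rather than a likelihood model, because
any "least likely interpretation" ranking is corpus-derived and not
portable.

## Counting and its validation

Pair counting is O(n·m²) for n bins of mean size m, which is the
pipeline's bottleneck at production scale (n = 5.5 M, m = 200 gives
2.2·10¹¹ candidate pairs for weekly bins); `pair_enumeration_cost` exposes
that estimate for planning. The production counter shards bins across
worker processes **by whole patients**, so each shard can apply the
per-patient union locally and partial sparse maps merge by plain
summation in both modes; results are invariant to worker count and bin
order. A second, deliberately naive single-threaded counter
(`reference_count`) implements the same semantics as an order-obvious
double loop and exists purely as an independent oracle.

Validation is simulation-based: the synthetic generator records exactly
which terms it planted in each note, and `ground_truth_counts` recomputes
bins and counts from that record by direct exhaustive enumeration,
independent of the annotation and counting code paths. The acceptance
suite requires the three computations to agree **exactly** — every
singleton and pair count, all seven widths, both modes — on a seeded
100-patient, 1,000-note corpus whose notes pass through the real
annotator.

The published-file filter (drop rows with counts ≤ 100) is applied at
serialization time only, so in-memory statistics always use exact counts;
the threshold is configurable and the boundary is strict (101 survives,
100 does not).

## Synthetic corpus: what it emulates and what it does not

Per patient, the note count is uniform on a configured range and
timestamps are uniform on [0, `time_span_days`], then sorted — the
minimal assumption that still exercises every bin width. Note text is the
planted terms' dictionary strings (every fifth vocabulary entry is a
two-word phrase to exercise multi-token matching) shuffled with
out-of-lexicon filler tokens, making annotation exactly invertible.

Planted associations co-inject both pair members into a note with the
configured joint probability *p*, and background terms are drawn from the
vocabulary **excluding** planted-pair members. Consequently a planted
term's marginal equals the pair's joint probability, and at one note per
bin the analytic lift is exactly 1/*p* — giving the parameter-recovery
test a closed-form target (checked within 3 binomial standard errors at
10,000 bins). The defaults (100 patients, 10 notes each, 200-term
vocabulary, 5–15 terms per note, 730-day span) are the scale of the
counting validation design.

The generator does **not** emulate realistic clinical language: no
sections, no negation-rich prose, no visit-pattern clustering, no term
frequency skew. Negation and section flagging are therefore tested on
small hand-written fixtures, and a green suite says the *counting
machinery* is exact on known placements — not that annotation accuracy on
real notes is high.

## Statistics

For margins f(X), f(Y), joint f(X,Y) and universe N, the 2×2 table is
A = f(X,Y), B = f(X)−f(X,Y), C = f(Y)−f(X,Y), D = N−[f(X)+f(Y)]+f(X,Y);
preconditions (f(X,Y) ≤ min margins, union ≤ N) guarantee D ≥ 0.
Per-patient counts must use the patient-count universe (the ∞-width N).
χ² = Σ(O−E)²/E and G = 2·Σ O·ln(O/E) use margin-derived expectations with
0·ln 0 = 0 and **no Yates correction**; their p-values are upper-tail
χ²₁. Ratio statistics with a zero denominator are reported as `None` with
a machine-readable reason code; Haldane's +0.5 correction is opt-in only,
so raw counts are never silently distorted.

Correlated-feature groups (for group-penalty regression designs) are the
connected components of the graph with an edge wherever the pair count
meets `min_count` and lift meets `lift_threshold` — parameter-free and
deterministic, in preference to clique-finding.

Enrichment of entities in a selected cohort uses the upper-tail
hypergeometric p-value against the background (two-sided tests are kept
for χ²/G; enrichment is inherently one-sided). The dependency adjustment
models a cohort selected on entity *x*: entity *y*'s expectation becomes
`selected_size · f(x,y)/f(x)` — the conditional rate among *x*-carriers —
realised as a hypergeometric draw from the f(x) eligible items of which
f(x,y) carry *y*. This is one concrete, configurable reading of
co-occurrence-based expectation adjustment; others (e.g. regression-based
calibration) are out of scope. Multiple testing is handled by
Benjamini–Hochberg across the tested entities.

## Numerical and formatting choices

* Offsets *r* come from a keyed counter-based generator (BLAKE2 digest of
  seed, width and patient ID seeding a PCG64 stream), so runs are
  reproducible, patients are independent, and *r* is redrawn per width.
* Timestamps are fractional days, so sub-day note spacing behaves
  correctly under 1-day bins.
* Count files are header-less UTF-8 TSV, LF-terminated, rows sorted by ID
  with the pair key canonicalised as (min, max) — sorted canonical output
  makes re-runs byte-identical and diffs meaningful. Readers reject wrong
  arity, non-integer fields, non-canonical or duplicate keys, with line
  numbers.
* All output files are written to a temporary name and atomically
  renamed; a failed run leaves no truncated files.

## Problem sizes

The test suite and the acceptance script run on simulated corpora of 20 to
10,000 patients (at one note per patient for the lift-recovery check) and
property-based sweeps of ~240 randomized small fixtures; these sizes give
tight Monte-Carlo bounds for every stochastic check while keeping a full
run under a minute on one CPU. Larger corpora only change runtime: the
counting path is exact, not approximate.

## Known limitations

* The annotator is a clean-room dictionary matcher; its accuracy on real
  clinical text is not evaluated here and the NegEx approximation is
  intentionally simpler than the full regex engine.
* Binning is strictly arithmetic on day offsets — no calendar months, no
  time zones.
* The enrichment adjustment covers conditioning on a single entity; joint
  conditioning on several would require higher-order co-occurrence data
  the count files do not carry.
* Distributed (cluster-scale) counting is out of scope; the
  multiprocessing counter targets desk-scale corpora.
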