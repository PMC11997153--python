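# Methods

This note documents the models, conventions and numerical choices behind
`szfreq`, and what its tests do and do not establish.

## Annotation model

A segment is a short UTF-8 string (typically one to a few dozen words) from
the seizure-frequency subsection of an epilepsy-monitoring-unit report. Two
span layers annotate it:

* **Frequency phrases** — contiguous spans, each describing one seizure
  frequency. A segment may hold zero phrases (frequency not explicitly
  defined: "Uncertain", "Happened only once", remission statements), one, or
  several.
* **Attributes** — typed spans from a closed set of 17 types. Event,
  Quantity, Temporal unit and Duration carry most rate information;
  Minimum/Maximum quantity and duration encode ranges; Interval start/end,
  Time, Relative time, Relative time period, Age, Age start/end and
  Periodic encode the remaining temporal idioms.

**Offsets** are 0-based Unicode code points with an *inclusive* end:
`(0, 15)` on "Right arm clonic 1 every 2 weeks" addresses the 16-character
event mention. Annotation tools that export half-open ends are accepted via
a per-file flag and converted on load. Hyphen and en-dash are distinct
characters and preserved; files are written with `ensure_ascii=False` so a
round trip is byte-stable.

Both span layers are strictly ordered and non-overlapping (the end of one
span precedes the start of the next). Attribute surfaces are stored
redundantly and re-checked against the addressed substring on every load,
which catches stale offsets immediately.

**Corpus median.** The per-segment frequency-count distribution of a
realistic corpus is dominated by zeros and ones, so the two central order
statistics of an even-sized corpus can straddle the 0/1 boundary.
`corpus_summary` reports the *upper* median (`statistics.median_high`),
which is the convention consistent with reporting a typical segment as
carrying one frequency; the interpolated median of the default distribution
would be 0.5.

## Composition by span containment

Given phrase set `P` and attribute set `A`, the structured frequency for
phrase `p` is the set of all attributes `a` with `p.start ≤ a.start` and
`p.end ≥ a.end`. Because both sets are non-overlapping, each attribute has
at most one owning phrase and each phrase's subset is maximal — the
implementation is a linear scan, and the test suite checks it against a
brute-force subset-enumeration oracle on instances with ≤ 8 attributes.
Phrases containing no attribute yield no structured frequency but are
surfaced in the leftover report, as are orphan attributes, so nothing is
silently dropped. Duplicate attribute types within one phrase are retained;
the normalizer refuses them (below).

`compose_within_phrases` implements the alternative strategy of running
attribute extraction per phrase substring and mapping offsets back; it
exists for head-to-head comparisons with whole-text attribute extraction,
which can avoid absorbing in-phrase distractors such as event durations
("lasting 1–2 minutes").

## Codecs

*Tokenizer.* Whitespace split, then peeling of leading/trailing punctuation
into single-character tokens, then interior splitting at dash (`-`, `–`,
`—`) and slash characters. The interior split exists so that range
annotations ("1–2" with Minimum and Maximum quantity on either side of an
en-dash) are token-aligned; decimals like "0.5" stay whole. The tokenizer
is deterministic and every token addresses its exact source offsets.

*IOB2.* Spans must start and end on token boundaries (misalignment raises).
Decoding repairs orphan `I-` tags by treating them as `B-` (a strict mode
raises instead), the standard lenient convention for model output.

*Inline tags.* The emitter writes the backslash closing form (`<\FREQ>`)
used in generative fine-tuning data; the parser accepts both `<\X>` and
`</X>`. Decoding first strips tags and compares with the original text:
equality gives exact offsets; otherwise stripped-to-original positions are
mapped through `difflib` longest-common-subsequence matching blocks and the
segment is flagged approximately aligned. Unknown, unclosed, unopened,
empty or overlapping decoded tags are dropped with report entries — decoding
generated output never raises.

## Normalization to seizures/day

The rate is `quantity / period_in_days`.

* Quantity: the Quantity surface parsed as a numeral, a number word
  (once→1 … twelve→12) or a vague term from an explicit lexicon (few→3,
  couple→2, several→4; flagged `vague`); otherwise the midpoint of
  Minimum/Maximum quantity; otherwise an implied 1 when a Periodic marker
  is present.
* Period, in resolution order: Duration × unit; Minimum/Maximum duration
  midpoint × unit; Temporal unit alone; Interval start/end parsed as years,
  `(end − start) × 365.25`; Periodic word (daily/weekly/…); Relative time
  period ("last 10 months").
* Unit lengths: day 1, week 7, month 30.44, year 365.25, hour 1/24,
  night/morning/evening 1 — documented constants in `UnitTable`,
  overridable.
* Ranges collapse to the midpoint by default (`range_mode` selects min or
  max); the midpoint is the unbiased single-value reading of "1–2 per week"
  absent any other information.

Time, Relative time and the age types are non-rate context: alone they make
a frequency non-normalizable. Non-normalizable frequencies (including any
with a duplicated rate-relevant attribute type, an ambiguity the normalizer
refuses to guess about) receive a placeholder rate and an `imputed` flag.
The conventional placeholder is `corpus_mean_rate`: the mean per-day rate
over all normalizable gold frequencies of the corpus, excluding imputed
ones to avoid circularity. It is computed over the gold layer by default
(configurable), since the placeholder represents the expected frequency of
an average patient rather than a property of any particular model.

## SUDEP-7 scoring

Only the four frequency-related inventory factors are computable from
extracted frequencies. Three are fixed by their inventory wording; the
fourth defaults to the high-frequency item (>50 seizures of any type per
month) and, like the rest, is configurable rather than hard-coded — factor
definitions carry event class (GTC or any), threshold, window (year or
month), comparison and weight. Weights default to 1, consistent with a
single satisfied factor producing a score of 1.

Per segment, every structured frequency is normalized (with imputation),
rates are summed per event class, annualized (×365.25) and monthlyized
(×30.44), and each factor's predicate is evaluated on the summed applicable
rate. Event surfaces are classified by a case-insensitive substring lexicon
(gtc, tonic-clonic, generalized tonic, grand mal, convuls → GTC). Imputed
rates have unknown event class and feed the any-type factors only — they
can never inflate the GTC factors. This yields the expected nesting (factor
1 ⟹ 2 ⟹ 3) and monotonicity (adding a frequency never lowers the score),
both under property test.

## Evaluation protocol

Extractions are scored by exact character-offset match (plus type for
attributes); a structured frequency is correct only if its entire attribute
bundle (spans and types) equals a gold bundle. The bundle comparison
deliberately ignores the phrase span: a phrase extended by a trailing
period can still group exactly the right attributes, and the structured
output is then correct even though the phrase-level extraction is not. A
strict mode that also requires phrase equality is available.

Zero-denominator convention: with nothing predicted *and* nothing gold in a
resample, precision/recall/F1 are 100 (vacuously perfect); a zero
denominator against a non-empty other side scores 0.

MAEs compare per-segment aggregates — the sum of a segment's normalized
rates (or its SUDEP-7 score) — between predicted and gold layers, pairing
by segment. Aggregation by summation avoids an arbitrary within-segment
matching step for multi-frequency segments; a greedy per-frequency pairing
is intentionally not the default.

The paired bootstrap draws 10,000 trials of 200 segment indices with
replacement from one seeded `numpy` generator; the identical index matrix
is used for every system being compared, and is stored on the result for
audit. Metrics decompose into per-segment statistics (TP/predicted/gold
counts, or absolute errors) that are resummed per trial, so the full
10,000×200 protocol runs in well under a second. Significance follows the
strict-dominance rule: A is better than B iff A's per-trial score strictly
exceeds B's in more than 95% of trials; exactly 95% is not significant.

## Synthetic corpus

The generator exists because real annotated corpora of this kind are
private. It assembles segments from ~14 phrase templates with slot-filled
numerals, events, units, years and ages, emitting gold spans by
construction. Defaults encode the study conditions: 800 segments whose
frequency-count distribution is 381:377:39:2:1 for 0–4 frequencies per
segment (mean 0.58), all 17 attribute types covered, GTC and non-GTC events
both present so factor routing is exercised, and no-frequency segments
drawn from exemplars of the three narrative categories (missing temporal
context, indeterminable frequency, remission). Multi-frequency segments
join templates with ", ". Word counts arise from the template length
mixture (mean ≈ 5–6 words) and are not enforced to match any particular
corpus exactly. The typo injector perturbs characters outside gold spans,
with insertions and deletions shifting all downstream offsets consistently,
so perturbed corpora still validate.

What passing tests on synthetic data establish: the machinery —
composition, normalization, scoring, codecs, bootstrap — is exact and
lossless on well-formed annotations, and robust to the injected noise
patterns. What they do not establish: extraction quality on real clinical
language, whose variability (institution-specific jargon, free-form
temporal idioms, misspellings inside entity mentions) the templates do not
model.

## Rule-based baseline

The rule extractor is a priority-ordered lexicon + regex grammar over the
surface language of frequency narratives: year intervals, month-name
times, relative times/periods, ages, periodic words, events, "every N
unit" durations (with ranges), per/every temporal units, then quantity
ranges and quantities — each hit claims its character range and later
patterns skip claimed text. Bare numbers are only read as quantities in a
licensing context (followed by per/every/times/seizures or preceding an
event mention), and a negated mention ("no seizures …") suppresses the
segment, which keeps remission statements out of the false positives. The
grammar is frozen under test, with a repository bar of ≥95% attribute F1 on
the clean template corpus; it is a floor and pipeline exerciser, not a
reproduction of any published extraction system. Phrase prediction clusters
attribute hits, breaking at separators (comma/semicolon/"and") or gaps over
30 characters; gold phrases that include literal lead-ins ("Last known …")
are therefore not always recovered exactly, which the evaluation reflects.

## Problem sizes

Default test and acceptance runs use corpora of 120–1,000 segments, the
full 10,000×200 bootstrap, and a 300-segment sample for the brute-force
composition oracle — sizes chosen so the complete suite runs in seconds
while every protocol runs at its full configuration.
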