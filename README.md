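# szfreq

A toolkit for extracting **structured seizure frequencies** from short
clinical free-text segments, and for scoring their impact on SUDEP risk.

Seizure frequency ("GTC one every 2 months", "Aura- 1–2 per week") is
central to epilepsy care: it drives treatment evaluation and the
frequency-related items of the SUDEP-7 risk inventory (Sudden Unexpected
Death in Epilepsy). In epilepsy-monitoring-unit reports this information is
narrative text, so extraction systems first detect *frequency phrases*
(contiguous spans) and *typed attributes* (17 types: Event, Quantity,
Temporal unit, minimum/maximum quantities and durations, interval
start/end, times, relative times, ages, Periodic), then combine them.

`szfreq` implements everything around such extractors, with no model
training involved:

* **Schema + corpus I/O** — character spans (0-based, inclusive ends, in
  Unicode code points) over annotated segments; line-delimited JSON corpora
  in the common annotation-export shape (`szfreq.schema`, `szfreq.corpus`).
* **Codecs** — lossless conversion between spans and the two model-facing
  encodings: IOB2 token tags for encoder-style classifiers and HTML-like
  inline tags (`<FREQ>…<\FREQ>`) for generative models, including offset
  recovery from noisy generated output via LCS alignment (`szfreq.codecs`).
* **Composition** — the span-containment rule that turns a phrase set *P*
  and an attribute set *A* into structured frequencies: each structured
  frequency *S ⊆ A* collects exactly the attributes whose spans fall inside
  one phrase, i.e. *p_s ≤ a_s* and *p_e ≥ a_e* (`szfreq.compose`).
* **Normalization** — structured frequency → seizures/day (quantity over a
  resolved period; week = 7 d, month = 30.44 d, year = 365.25 d), with
  corpus-mean placeholder imputation when normalization is impossible
  (`szfreq.normalize`).
* **SUDEP-7 scoring** — the four frequency-related inventory factors
  (>3 GTC/year, ≥1 GTC/year, ≥1 any-type/year, >50 any-type/month), unit
  weights by default, fully configurable (`szfreq.sudep7`).
* **Evaluation** — exact span match precision/recall/F1, structured-bundle
  matching, no-frequency detection, rate and SUDEP-7 MAEs, and the paired
  bootstrap (10,000 trials of 200 resampled segments; A beats B
  significantly when it wins >95% of paired trials) (`szfreq.evaluation`).
* **Baseline + synthetic data** — a deterministic rule-based extractor and
  a template generator that emulates the shape of real annotated corpora
  (frequency-count distribution 381:377:39:2:1 per 800 segments, all 17
  attribute types), so the whole pipeline runs and is tested without any
  private clinical data (`szfreq.baseline`, `szfreq.synthetic`).

## Worked example

```python
from szfreq import *

text = "Right arm clonic 1 every 2 weeks, GTC one every 2 months"
phrases = PhraseSet((Span(0, 31), Span(34, 55)))
attributes = rule_extract_attributes(text)

structured, report = compose(phrases, attributes)
for freq in structured:
    print([(a.attr_type.value, a.surface) for a in freq.attributes])

rate = to_per_day(structured[1], placeholder=0.05)
print(round(rate.rate, 5))

score = sudep7_score(structured, placeholder=0.05)
print(score.score, score.fired)
```

prints

```
[('Event', 'Right arm clonic'), ('Quantity', '1'), ('Duration', '2'), ('Temporal unit', 'weeks')]
[('Event', 'GTC'), ('Quantity', 'one'), ('Duration', '2'), ('Temporal unit', 'months')]
0.01643
3.0 [1, 2, 3]
```

Two structured frequencies are composed from the segment; "one every 2
months" normalizes to 1/60.88 ≈ 0.01643 seizures/day; summed over both
frequencies the GTC-class rate exceeds three per year, so SUDEP-7 factors
1–3 fire for a score of 3.

The same pipeline is available from the shell:

```bash
szfreq generate --n 800 --seed 1 --out corpus.jsonl
szfreq extract --extractor rules corpus.jsonl --out pred.jsonl
szfreq evaluate --task attribute --gold corpus.jsonl --pred pred.jsonl --bootstrap 10000
```

## Limitations

The rule-based extractor is a reproducible floor for pipeline testing, not
a clinical NLP system; the synthetic generator emulates corpus statistics,
not real clinical language (see `docs/methods.md` for what that does and
does not establish).
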