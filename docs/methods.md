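# Methods

This note documents the models, rules, parameters and design choices
behind `eippcs`, and what the synthetic corpus does and does not show
about real safety data.

## Problem setting

An individual case safety report (ICSR) carries structured fields — a
set of MedDRA preferred-term (PT) codes, a product list, a source tag —
and a free-text narrative, often split into named sections. The target
signal is a specific medication error: a patient **extracts insulin from
a prefilled pen or cartridge with a syringe** (EIPPCS). No single MedDRA
term codes this error, so detection must combine coded terms with
narrative text. The package implements three detectors over a shared
corpus model and measures them against gold labels.

## Text model

All text is NFKC-normalized with trademark glyphs (®, ™) removed on
ingest, because narratives carry branded product names while rules match
plain words. Tokenization keeps **word tokens only**: runs of word
characters, with internal hyphens and apostrophes retained
("re-used", "patient's"); punctuation is discarded. This makes the
"within *k* words" proximity rule unambiguous — punctuation never counts
toward a gap — at the cost that token concatenation reconstructs only
the word content of a sentence, not its punctuation.

Sentence segmentation is rule-based: a sentence ends at `.`, `!` or `?`
followed by whitespace and an uppercase letter or digit, guarded by a
short abbreviation allowlist (e.g., i.e., Dr., vs., …). Safety
narratives are template-like translated prose; deterministic,
dependency-free splitting is adequate and keeps every downstream result
reproducible bit-for-bit. A lowercase continuation after a period is
treated as the same sentence by design.

Dictionary tagging is case-insensitive longest-match: at each token
position the longest matching lexicon phrase wins and matching resumes
after it, so spans from one lexicon never overlap. Proximity between two
same-sentence spans is the count of word tokens strictly between their
nearest edges; adjacent (and overlapping) spans have gap 0, and the
bound is inclusive ("equal or less than"). Both primitives are verified
against naive brute-force references in the test suite.

## The three detectors

**SSA** (traditional surveillance cascade): a record passes if (1) any
narrative token has folded prefix `syringe` — prefix matching covers the
plural; an exact-token switch exists — and (2) it carries at least one
of 12 curated PT names (device failures/malfunctions, wrong-device and
wrong-technique errors, intentional misuse, …). PT matching is by name,
case-insensitively with whitespace collapsed, because curated lists are
maintained as names; codes are bookkeeping.

**CPR-style pipeline** (NER tagging + proximity), rules in execution
order with their trace ids:

| rule | behaviour |
|------|-----------|
| `cpr_rule_2` | drop sections whose name contains "analysis" (product-return lab analyses are not consumer mishandling); a record with no retained text stops here |
| `cpr_rule_1` | require an anchor span (`syringe`/`syringes`) in retained text |
| `cpr_rule_3` | disqualify if a negation cue ("did not", "denied", "never", …) shares a sentence with an anchor or cue span — sentence-scoped cues, not full scope resolution, matching the granularity at which such filters are described |
| `cpr_rule_4` | disqualify on inhaled-insulin vocabulary anywhere in retained text, or when the token immediately preceding an anchor is "prefilled" (prefilled *syringes* are a marketed product, not an extraction error) |
| `cpr_rule_5` | retrieve iff an anchor and an EIPPCS-dictionary span co-occur in one sentence within `max_gap` words (default 8, configurable) |

The EIPPCS dictionary deliberately contains multiword variants such as
"withdrew insulin": longest-match tagging then measures the gap from the
end of the two-word span, which is what lets the canonical narrative
"…withdrew insulin out of the ⟨pen⟩ with a regular syringe" fall exactly
at gap 8. No stemming anywhere; inflected forms are listed explicitly.

**I2E-style rule cascade**: a configurable ordered `RuleSet`; a record is
retrieved iff all include-rules pass and no exclude-rule fires, at
sentence scope, over the raw narrative (all sections) by default. The
shipped default — a documented reconstruction, since the original
commercial query is not recoverable verbatim — is:

1. `i2e_rule_1` anchor present;
2. `i2e_rule_2` product mention, satisfied by a product-dictionary span
   in text *or* by the record's structured product list (narratives often
   say only "a pen", so the dictionary includes generic device words);
3. `i2e_rule_3` exclude inhaled-insulin vocabulary;
4. `i2e_rule_4` an action verb (inject, administer, use, withdraw, mix, …)
   in the same sentence as the anchor.

The default I2E product dictionary deliberately omits one brand
(`dosetouch` in the synthetic world) to reproduce the documented failure
mode of a query that does not cover a newer product. Note the published
account is internally inconsistent about whether the verb-vocabulary
rule is "rule 1" or "rule 4"; the ids here follow the miss-attribution
table convention.

## Evaluation

Recall is tp/(tp+fn) over gold positives. Two precision conventions are
computed side by side and never merged:

* `precision_testset` = tp/(tp+fp) within the annotated universe
  (textbook PPV);
* `precision_paper` = annotated-test-set TPs ÷ the method's **total**
  retrieval from the full corpus. Surveillance-comparison studies quote
  this ratio (37/1104 ≈ 3.4%, 38/2042 ≈ 1.9%, 33/2019 ≈ 1.6%); it
  understates PPV because the numerator is restricted to the annotated
  sample while the denominator is not.

Percentages are reported at full precision plus two one-decimal
renderings, half-up (`percent_round`) and truncated (`percent_trunc`),
because published one-decimal figures demonstrably mix both conventions
(88.1 = round(37/42); 90.4 = trunc(38/42)).

Cohen's κ is computed from the closed form (observed vs marginal-chance
agreement), with the degenerate both-constant-same-label case defined as
1.0; it is cross-checked against scikit-learn's implementation in tests.
The published inter-annotator κ of 0.96 cannot be recomputed because the
underlying 2×2 cell counts were never printed; κ is therefore validated
against hand-computed tables instead.

Supporting analyses: `overlap_analysis` counts gold positives captured
by exactly each subset of methods (all 2^k − 1 regions plus a
captured-by-none bucket; counts sum to the positive total);
`pt_frequency` profiles which curated PTs captured a record set, with
records matching several PTs counted once under "Composite PTs" and
rare PTs merged into a "PTs < N" bucket; `fp_only_terms` mines word
n-grams (1–5, within sentences, stop-words retained — real FP-only term
lists contain function-word phrases) occurring in a method's
false-positive pool and never in its true-positive pool.

Sampling uses half-up rounding of fraction × N (the convention under
which a 10% sample of 25,328 is 2533) and an owned PCG64 stream, never
ambient global randomness.

## Synthetic corpus

`synthetic_corpus.generate` produces a labelled corpus from weighted
narrative templates. Defaults are the study conditions: prevalence
0.017, coding-noise 0.05, extra analysis-section probability 0.10.
Positive templates paraphrase real root-cause styles (intentional mixing
of two insulins in one syringe; switching to a syringe after a pen
fault; mistaken withdrawal from a pen) plus two designed CPR-miss
families totalling 0.20 of positive mass: a cue→anchor gap beyond 8
words, and error wording confined to an "analysis results" section
(labelled positive — the error did occur — but invisible to a
section-isolating pipeline). One positive family mentions only the
I2E-uncovered brand. Distractors supply the documented false-positive
drivers: device-malfunction complaints (with and without incidental
syringe mentions), prefilled-syringe dispensing, negated errors,
inhaled-insulin trial reports, vial-and-syringe narratives describing
normal clinical practice, and glucose-complaint filler carrying the
characteristic FP-only vocabulary ("woman", "elevated blood glucose",
"was introduced to", …).

Template counts are allocated by largest remainder over weights, not
multinomial sampling, so the designed-miss fraction *m* is exact and CPR
recall on a generated corpus equals 1 − m in exact arithmetic — the
parameter-recovery check in the acceptance tests. Gold labels come from
template semantics, never from detector behaviour. PT coding is drawn
per template family and perturbed by coding noise that substitutes
off-signal PTs; a noised positive still contains the word "syringe", so
it specifically reproduces the "coded outside the curated PT list" SSA
miss mechanism.

What the generator does **not** model: realistic narrative length and
section-structure distributions (the real ones are proprietary),
translation artifacts, misspellings, and open-vocabulary paraphrase.
Passing tests show the detectors implement their rules exactly and that
the evaluation arithmetic is right; they do not show that the shipped
dictionaries would achieve any particular recall/precision on real
safety data.

One protocol subtlety reproduced faithfully: when evaluation is
restricted to the post-HLGT-filter universe (as in the full pipeline
command), positives whose coding noise moved them to an off-filter HLGT
leave the universe entirely, so SSA recall measured there can exceed SSA
recall on the full corpus.

## Numerical and degenerate-input choices

* Metrics with zero denominators raise `UndefinedMetricError` rather
  than returning a sentinel.
* `sample_fraction` requires fraction ∈ (0, 1]; size half-up.
* Unknown PT codes: lenient by default (skip + debug log) because
  synthetic coding noise includes uncodable terms; strict mode raises.
* Duplicate corpus ids, conflicting hierarchy rows, empty lexicons and
  rulesets without an include rule are validation errors at load time.
* Tie-breaks: FP-only terms rank by descending count then
  lexicographically; largest-remainder allocation breaks ties by
  template order.

## Problem sizes

The acceptance script generates 5,000 records (85 positives at 1.7%)
for its end-to-end measurements, and the oracle-equivalence check runs
1,000 randomized corpora of at most ~100 sentences against the
brute-force references; both complete in seconds on one CPU.
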