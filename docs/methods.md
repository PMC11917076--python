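# Methods

## The assessment model

The engine rates one *study* — a published longitudinal investigation of
mental-health problems in children with a neurodevelopmental disorder — on
four measurement-bias domains and aggregates them into an overall
judgement. Every judgement is a pure function of the curated extraction
(`StudyRecord`) and the numeric cut-offs (`RubricThresholds`); there is no
randomness, no state, and re-running an assessment always reproduces it.

Assumptions worth making explicit:

- **Group means, not individuals.** Ages and IQs are diagnosis-group means,
  as study characteristics tables report them. A group whose *mean* age
  crosses a threshold is treated as crossing it; within-group spread is not
  modelled.
- **Equal wave spacing as fallback.** When a study reports only first-wave
  age, follow-up length and wave count, wave ages are imputed as an
  arithmetic progression over the follow-up interval. Explicit wave ages
  always take precedence.
- **Unknowns propagate, never impute.** Missing informants, ages or IQ
  become `can't tell` answers and `unclear` ratings; nothing is filled in
  silently.

## Sub-question semantics and edge cases

- **1a / 1b (overlap).** Finding-level addressed statuses roll up
  worst-case: any unaddressed finding ⇒ 1b = no; all addressed ⇒ yes; mixed
  or partly addressed ⇒ can't tell. With zero findings, 1b inherits yes only
  when items *and* criteria were available for comparison; otherwise it is
  can't tell, so a study whose overlap could not be assessed rates
  `unclear`, not `low`.
- **2 (informants).** Two or more distinct informant *types* on the same
  outcome is sufficient for `low` regardless of age availability. A single
  known wave at or past school age forces 2c = no even when other waves are
  unknown.
- **3a (self-report feasibility).** The functioning category is the
  n-weighted majority across groups (ties break toward the more severe
  category); the age condition is the n-weighted mean, over groups, of the
  fraction of waves at or above the applicable threshold, compared with the
  wave fraction ½ using ≥ ("at half or more of the waves"). Moderate/severe
  intellectual disability is infeasible at any age; so is *unknown*
  functioning whenever all but a minority of waves are under the lowest
  threshold (9 y) — the age alone then forces the answer. Unknown
  functioning with older children is genuinely undecidable ⇒ can't tell.
- **IQ bands** are half-open: [70, ∞) no ID, [55, 70) mild, (−∞, 55)
  moderate/severe. Exactly 70 is *not* an intellectual disability (the
  "IQ < 70" definition wins over the inclusive "55–70" phrasing of the mild
  band).
- **4 (instruments).** Rated per instrument actually used by a
  mental-health outcome: an instrument passes iff designed-for or
  adapted-to is yes. All pass ⇒ low; none passes and none is wholly
  unextractable ⇒ high; anything else ⇒ unclear.
- **Overall.** Strict plurality of the four ratings; all ties ⇒ unclear.
  Over four items this is equivalent to the three published principles
  (plurality; high/low 2–2 ⇒ unclear; two-definite/two-unclear ⇒ unclear),
  which the test suite verifies by exhaustive enumeration of all 81
  vectors against a literal transcription of those rules, including the
  non-monotonicity witness (high, high, low, unclear) → high vs
  (high, high, unclear, unclear) → unclear.

## Tunable parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `school_age` | 6 | years | single informant insufficient from this age |
| `self_report_age_no_id` | 9 | years | self-report feasible, no ID |
| `self_report_age_mild_id` | 11 | years | self-report feasible, mild ID |
| `iq_no_id_min` / `iq_mild_id_min` | 70 / 55 | IQ points | band edges |
| `min_informants_school_age` | 2 | informant types | domain-2 low bar |
| `wave_fraction_for_feasible` | 0.5 | fraction | "half or more of the waves" |

Defaults are the published values; changing them changes the instrument
being studied, so the regression tests pin the defaults.

## Counting conventions (cohort summaries)

A *counted scale score* is an outcome counted at the most general level its
instrument reports within a study: totals, else broad-bands, else
subscales. Instruments are deduplicated cohort-wide by case-insensitive
name; form variants count separately only if named distinctly in the
extraction. Percentages are computed on raw counts and rounded half-up to
one decimal at presentation only. Study-level denominators: all studies for
informant/child percentages; studies with ≥ 1 overlap for the unaddressed
share; studies with no child-rated outcome for the feasible-among-missing
share; counted scale scores for the outcome-level overlap share. Because
the characteristics table reports integer-rounded follow-up lengths, the
mean follow-up is reported both over group rows and over studies, and
neither value is privileged.

## Synthetic cohorts

The generator emulates the *categorical* structure the rubric consumes.
Default marginals are the rates reported for the 49-study review the rubric
was developed on: 44.9% of studies with ≥ 1 overlap, 77.3% of those with an
unaddressed one, 12.2% multi-informant, 8.2% justifiably single-informant
(all waves under 6 y), 12.2% with a child-rated outcome, 8.8% of
instruments designed for NDD, and no adaptations. Where the review states
no rate (IQ mixture, group sizes, wave counts), values were chosen once to
be realistic for this literature: wave counts 3 + Poisson(2) clipped to
3–17 (mean ≈ 5), follow-up 2–16.74 y, first-wave ages 0.51–12.30 y, group
sizes 10–722, functioning mixture 35/15/15/35% (no ID / mild / mod-severe /
unknown).

Structural couplings are enforced, not sampled: a child-rated study always
has the child among its informants (one shared uniform nests child-rating
within multi-informant so both marginals are exact); the under-six flag is
drawn with the conditional probability that makes the configured
*joint* "single-informant and under six" come out exactly; the addressed
status is drawn once per overlapping study so the configured map is the
study-level marginal (mixed-status studies are representable in curated
data but not generated). Each study has its own counter-derived substream
(`default_rng([seed, index])`), so cohorts are reproducible byte-for-byte
and insertion-stable.

What passing synthetic tests do **not** show: real extractions have
correlated domains (e.g. symptom-based diagnoses attract both overlap and
parent-only designs), multi-group studies with heterogeneous functioning,
and mixed addressed statuses within a study. The generator makes domains
independent by construction, so calibration tests validate the engine's
marginal behaviour, not joint structure.

## Fixtures and their provenance

`worked_examples` encodes the four fully printed example extractions
(alsem2013, anderson2011, auerbach2008, baribeau2021) and reproduces every
printed domain rating exactly; it is the primary regression suite.
`table3_characteristics` transcribes all 63 diagnosis-group rows of the
review's characteristics table. Digit grouping in the typeset source was
verified by checking that n × %female/100 is an integer for nearly every
row. Two cells (the 17-year follow-up lengths of the Rosema 2015
moderate/severe groups, which exceed the review's stated 16.74-y maximum)
are flagged `low_confidence` so descriptive checks can exclude them. The
table's n-column sums to 9,681 (9,431 counting the three repeated-sample
Lahey 2016 age-cohort rows once), while the review prints a participant
total of 9,446; the discrepancy is in the source and is surfaced, not
patched. The full 49-study extraction is deposited externally and not
bundled; the loader raises with instructions until a transcription is
installed.

## Numerical and design choices

- Percent rounding uses decimal half-up (`ROUND_HALF_UP`), matching the
  printed style; binary-float "round-half-even" artefacts are avoided by
  computing in `Decimal`.
- Serialization is canonical (stable field order, sorted informant sets,
  2-space indent, trailing newline) so identical cohorts are byte-identical
  on disk — a property the determinism tests rely on.
- Overlap screening: Jaccard ≥ 0.5 on content tokens ⇒ verbatim candidate
  (the threshold is an artifact choice, surfaced in configuration — the
  original comparison was human); a curated synonym pair ⇒ synonym
  candidate; no transitive closure over the lexicon; stemming strips only
  s/es/ed/ing/ies and only when ≥ 4 characters remain. Screening is
  advisory; the engine never consumes raw candidates.
- SVG rendering pins `svg.hashsalt` and omits date metadata, making figures
  pure functions of their inputs.
- Acceptance-scale runs use 2000 synthetic studies: large enough that every
  configured marginal is estimated to within ~±2 percentage points (3 SE),
  small enough to assess in well under a second.

## Known limitations

- Domain-3 severity is binary below mild ID: moderate and severe/profound
  are not distinguished (both infeasible).
- The engine takes `addressed` statuses as curated input; it does not infer
  from article text whether an overlap was "addressed".
- Multi-group combination (n-weighted majority/mean) is one defensible
  choice among several; the source is silent on it, and the rationale
  strings record the combination used.
- No inter-rater machinery: the rubric's reliability across human curators
  is outside scope.
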