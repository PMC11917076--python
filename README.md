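# ndd-rob

A rating engine for assessing **measurement-related risk of bias in
longitudinal studies of mental health problems in children with
neurodevelopmental disorders (NDD)**, with cohort-level summaries,
traffic-light figures and a synthetic-cohort simulator.

Standard critical-appraisal checklists (CASP, Cochrane's tools) say little
about four measurement problems that are acute in this literature:

1. **Conceptual overlap** — items in a mental-health scale that restate the
   diagnostic criteria defining the study group (e.g. a hyperactivity item
   in an ADHD cohort), inflating apparent psychopathology;
2. **Single-informant reliance** — school-age children rated by one
   informant (almost always a parent);
3. **Omission of the child's perspective** where self-report would have
   been feasible given age and intellectual functioning;
4. **Instruments neither designed for nor adapted to** children with NDD.

This package implements a four-domain supplementary appraisal rubric for
those problems as a deterministic, testable engine: curated study
extractions go in, reproducible `low` / `unclear` / `high` judgements come
out. It is aimed at systematic-review teams appraising this literature and
at methodologists studying the appraisal process itself.

## The rubric

Each domain *d* is rated from three-valued sub-question answers
(yes / no / can't tell):

- **D1**: `low` ⇔ no item–criterion overlaps (1a = yes) or all addressed
  (1b = yes); `high` ⇔ 1a = no ∧ 1b = no; else `unclear`.
- **D2**: `low` ⇔ ≥ 2 informant types on some outcome, or mean age < 6 y at
  every wave; `high` ⇔ one informant with any wave at ≥ 6 y; `unclear` when
  informants or ages cannot be established.
- **D3**: self-report is *feasible* (3a = yes) when mean age ≥ 9 y (no
  intellectual disability) or ≥ 11 y (mild ID, IQ 55–70) at ≥ half the
  waves, and never with moderate/severe ID (IQ < 55). `high` ⇔ feasible but
  no child-rated outcome; `low` ⇔ infeasible or child-rated.
- **D4**: `low` ⇔ every instrument designed for or adapted to the
  population; `high` ⇔ none is; else `unclear`.

The **overall** rating is the strict plurality of the four domain ratings;
every tie (including high/low 2–2 and two-definite/two-unclear splits)
resolves to `unclear`. Note the aggregation is deliberately not monotone:
(high, high, low, unclear) → high, yet (high, high, unclear, unclear) →
unclear.

Wave ages are group means; when only the first-wave age, follow-up length
and wave count are reported, waves are assumed equally spaced. All
thresholds live in `RubricThresholds` and are configurable; the defaults
are the published values (ages 6/9/11, IQ 55/70, wave fraction ½).

## Worked example

Four fully extracted example studies ship with the package:

```python
from ndd_rob import load_fixture, assess_study

for record in load_fixture("worked_examples").studies:
    a = assess_study(record)
    print(record.study_id, [r.value for r in a.ratings], "->", a.overall.value)
```

```
alsem2013 ['low', 'low', 'low', 'high'] -> low
anderson2011 ['high', 'high', 'low', 'low'] -> unclear
auerbach2008 ['high', 'high', 'high', 'high'] -> high
baribeau2021 ['low', 'high', 'low', 'high'] -> unclear
```

Reading the first line: Alsem 2013 followed 92 preschoolers with cerebral
palsy (mean age 2.5–4.5 y), so parent-only reporting is justified (D2 low)
and self-report infeasible (D3 low), but the quality-of-life scale used was
developed for typically developing children (D4 high); the overall plurality
is `low`. Auerbach 2008, by contrast, used the CBCL (not designed/adapted,
with a "Poor school work" item overlapping the dyscalculia criteria, left
unaddressed) on parent-rated, typically-intelligent 11-year-olds: every
domain and the overall rating are `high`.

The same works from the shell:

```bash
ndd-rob simulate --seed 42 --n-studies 49 --out cohort.json
ndd-rob assess cohort.json --out assessments.csv --rationale report.md
ndd-rob summarize cohort.json --out summary.json
ndd-rob figure cohort.json --kind traffic --out traffic.svg
ndd-rob screen-overlap --items items.csv --criteria criteria.csv --out candidates.csv
```

`screen-overlap` is a lexical aid that proposes *verbatim* and *synonym*
item–criterion overlap candidates for human curation; *concretisation*
overlaps are a semantic judgement left to the reviewer.

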