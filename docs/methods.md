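# Methods

## The problem and the pipeline

ISO/IEC 11179 common data elements (CDEs) in the caDSR registry carry
their temporal semantics in free-text fields (`LONGNAME`,
`PREFERREDDEFINITION`).  The package implements a four-stage pipeline to
make that semantics explicit and machine-readable:

1. **Extraction** (`teocde.lexicon`): a keyword lexicon of five regex
   groups flags a CDE as time-relevant when any alternative fires in
   LongName or PreferredDefinition.  Each keyword carries an *ambiguous*
   group of TEO class tags (building blocks) — e.g. *date* maps to
   TimeInstant/TimeInterval/Date — which guide, but do not replace, a
   human annotator.
2. **Modelling** (`teocde.patterns`, `teocde.teo`): annotators assign
   each time-relevant CDE a pattern template over the TEO classes; the
   ten most frequently needed templates ship as the built-in registry
   (ids `P1`..`P10` in observed frequency order).  Instantiating a
   template against a CDE and a slot-binding map produces a typed node
   graph.
3. **Serialization** (`teocde.rdf`): node graphs become RDF triples and
   Turtle/N-Triples text, and can be read back.
4. **Evaluation** (`teocde.stats`): closed-form statistics quantify
   extraction quality, annotation agreement and pattern coverage.

## The temporal model

TEO (Time Event Ontology, the successor of the clinical-narrative
ontology CNTRO) models occurrences (`Event`) linked to time via
`hasValidTime` and to each other via temporal relations extended from
Allen's interval algebra.  Time is a `TimeInstant` (surface form,
normalized timestamp, granularity), a `TimeInterval` (start/end instants
and/or a duration), or a `TimePhase` (a periodically recurring
interval).  `Duration` carries a compact pattern string — grammar
`(integer unit)+` with units `Y`, `M` (month), `W`, `D`, `H`, `Min`
(minute), `S` — or a verbose form (`"7 days"`), or an explicit
value/unit pair.  `TemporalRelationStatement` qualifies a relation with
`hasApproximation` (uncertainty) and `hasTemporalOffset` (a displacing
duration).

Two inference contracts are implemented directly rather than through an
OWL reasoner (general OWL classification is out of scope):

* **Interval completion.**  With exactly two concrete components of
  {start, end, duration}, the third follows by calendar arithmetic.
  Durations must be in calendar-exact units (week and finer); months and
  years have no fixed length and are rejected with a commensurability
  error rather than silently approximated (no 30-day months).  Inferred
  durations are reported in whole days when the endpoints are
  day-granularity, otherwise greedily decomposed into D/H/Min/S.
* **Phase completion.**  A recurring phase satisfies
  `period = repeat_unit + repeat_unit_interval` (the period of a
  recurrence is the duration of one instance plus the gap to the next);
  any one term follows from the other two, and a fully specified
  inconsistent triple is an error.  `hasRepeatTime` (the recurrence
  count) is stored but takes part in no inference: its interaction with
  the period is deliberately left unspecified.

Placeholders are first-class: `VARIABLE` (printed `*`) marks a slot
filled per data instance, and `Symbolic("date_of_CDE")` defers to the
date the data instance is recorded.  Both are distinct from an absent
slot, and both survive RDF round trips (`"*"^^teo:Variable` as a
reserved typed literal; symbols as reserved IRIs).

Time-literal normalization tries an ordered, configurable format list
(`"DD MON YYYY"`, `"MON DD, YYYY"`, ISO 8601 date-time/date and its
coarser prefixes); the first match wins and the granularity is the
finest field the matched format carries.

## Pattern grammar and instantiation

The grammar is a small recursive bracket language:
`[Class* (prop, prop*=[Class ...])]`, with whitespace-separated
top-level groups forming node sequences and `[TemporalRelation]`
relating its flanking nodes.  Canonical rendering normalizes whitespace
(one space after the class name, `", "` between slots); the source
strings of the built-in templates are typographically inconsistent in
exactly this respect, so the round-trip contract is tree equality plus
idempotent rendering, not byte identity.

Bindings address slots by dotted paths over template node order
(`node1.hasValidTime.hasOrigTime`; `node1.label`, `node1.event_type`,
`node2.relation`, with bare `relation` accepted when unambiguous).
Unasterisked slots are static information fixed by the CDE definition
and must be bound — explicitly to `"*"` when genuinely unfilled, a case
the worked examples themselves exhibit — while asterisked slots default
to `VARIABLE`.  Instantiation never mutates the template; node ids are
assigned per class (`event1`, `tInstant1`, `tInterval1`, `tPhase1`,
`durat1`).

Candidate-template filtering from building blocks is exactly that — a
filter (templates whose classes can host every block group); automatic
pattern assignment is out of scope.

## Evaluation statistics

* Sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`; undefined
  denominators raise rather than return NaN.
* Margin of error `d = z·sqrt(p̂(1−p̂)/TP)` with the **true-positive
  count** as denominator.  The alternative denominator `TP+FN` fails to
  reproduce the published pilot margins, while `TP` reproduces all nine
  at three decimals; the two formulas below are then mutual inverses,
  which the tests verify row by row.
* Required sample size `n = z²·p̂(1−p̂)/d²`, rounded to nearest (410.33
  → 410, matching the published derivation); `ceil=True` gives the
  conservative variant.
* Coverage rate `(existing+new)/(existing+new+cannot_represent)`:
  not-time-related CDEs are a parser fault, not a representability
  fault, and are excluded from both sides.  Because a summary figure
  elsewhere divides by all categorized CDEs, `denominator="all"` exposes
  that convention too.
* Agreement: with three annotators per CDE, all-equivalent / exactly one
  deviant (majority-vote consensus) / all-different (unresolved).  The
  equivalence relation is injectable; the default is literal pattern-id
  equality, which is stricter than a human "same or equivalent pattern"
  judgement.
* Percentages are rounded half-up to one decimal.  Published tables show
  occasional digits no single rounding rule reproduces (31.2 where
  half-up gives 31.3); those digits are not chased.

## Synthetic corpora

`teocde.synthetic` emulates caDSR naming style (templated
LongName/PreferredDefinition text) with controlled structure: a
prevalence fraction of records carries a planted keyword surface;
`fp_noise` plants near-miss tokens (*Candidate*, *Update*, *Postal*, …)
in negatives that word-boundary matching must reject; `fn_noise`
obfuscates the keyword in positives whose gold label stays positive.
All fractions are allocated exactly (`floor(rate·n)`), never sampled, so
recovery tests assert identities: noise-free extraction has sensitivity
and specificity exactly 1, and planted `fn_noise` of rate *r* yields
sensitivity exactly `1−floor(r·n_pos)/n_pos`.  Annotator planting
likewise allocates one-difference/all-different CDEs and optional
new-pattern / cannot-represent strata exactly.  The default prevalence
(0.4) is of the order seen when keyword extraction is run against a full
registry export with roughly even test-set splits; the default pattern
mix is the observed relative frequency of the ten built-in templates.

What the generator does **not** emulate: the true caDSR keyword
distribution, NCIt concept codes, and real annotator error processes
(disagreement is planted structurally, not behaviourally).  Passing
recovery tests therefore demonstrate correctness of the pipeline's
bookkeeping and statistics, not field performance on real registry text.

## Numerical and design choices

* Keyword matching is case-insensitive inside word-boundary lookarounds
  (`(?<!\w)…(?!\w)`), so *date* cannot fire inside *candidate*;
  `word_boundary=False` reproduces a looser matcher (whose over-firing
  is visible as specificity < 1 on noisy corpora).  At equal offsets the
  longest match wins; remaining ties break by lexicon order.
* The compact duration unit `M` means *month*; minutes are `Min`.  This
  follows the worked duration examples, and is stated prominently
  because it is the grammar's one surprising token.
* XML element names match case-sensitively in the upper-case caDSR
  dialect (`PUBLICID`); `case_insensitive=True` relaxes this.
* Serialization is deterministic (subjects in first-appearance order,
  `rdf:type` and `rdfs:label` first within a subject), giving
  byte-identical Turtle for identical instances; `rdflib` is the
  independent parse/isomorphism oracle in the tests, never the emitter.
* Event subclassing (`event_type`, e.g. Treatment) serializes as a
  second `rdf:type` triple alongside `teo:Event`.
* In the emitted examples, quoted strings are literals and bare tokens
  (`durat1`) are node references; that convention is applied uniformly.
* Problem sizes in tests and the acceptance script (corpora of 100–1000
  records, 500 for the self-check) are chosen so every recovery identity
  is exercised at non-trivial scale while the full suite runs in
  seconds.

## Known limitations

* Ordinal series ("second occurrence"), bare relational qualifiers with
  only one event ("most recent"), and irregularly recurring events are
  not representable by the pattern registry — a limitation of the
  ontology itself, not of this implementation; such content survives
  only in labels.
* No SPARQL/SWRL querying, no OWL emission of the ontology, no NCIt
  concept-code mapping, no automatic pattern-to-CDE matching.
* No time zones; normalization treats all literals as naive timestamps.
* The `PREFERREDNAME` field is not scanned for keywords — only LongName
  and PreferredDefinition are used, matching the extraction procedure
  the statistics describe.
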