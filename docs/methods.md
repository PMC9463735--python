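# Methods

## The problem

Prescribing errors are the most frequent class of medication error in
hospitals. `ontorx` implements a knowledge-driven prescription checker
of the kind embedded in a computerised physician order entry (CPOE)
system: drug-safety knowledge is compiled into a semantic knowledge
base, and each prescribing event triggers an evaluation of the
patient's active medication list against four rule families —
maximum daily dose, drug–drug interaction, renal dose adjustment and
drug allergy. The design premise is that representing this knowledge
as ontology individuals (rather than relational rows) makes it more
compact and more maintainable: clinically equivalent product-level
rows collapse onto one (ingredient, route) individual, and
interactions are stated once at the appropriate level of the ATC
hierarchy rather than once per product pair.

## Knowledge representation

Three interlinked ontologies live in three IRI namespaces:

* **drugs** (`urn:ontorx:drugs:`) — identification and technical data of
  medicinal products: the abstraction ladder VTM (ingredient devoid of
  strength and form) → VMP (VTM + strength + route) → AMP (supplier's
  actual product), product packs (VMPP/AMPP with pack size and price),
  ingredients, two-level chemical groups (group → member ingredients,
  used for allergen expansion), routes, dose units and frequencies.
* **dss** (`urn:ontorx:dss:`) — appropriateness knowledge: the three
  criterion classes (maximum dose adult, drug interaction, renal
  adjustment) and the alert texts they reference, each alert carrying a
  description, recommendation, source, date and one of three severity
  levels.
* **local** (`urn:ontorx:local:`) — the hospital-side mapping layer:
  every local EHR/CPOE code (drug, route, unit, frequency, lab test,
  allergen) maps onto exactly one canonical concept.

The dependency direction is strict: drugs references nothing outside
itself, dss may reference drugs, local may reference both. The
terminological half (T-Box) is a static schema shipped with the package
(`src/ontorx/data/tbox.ttl`); only the assertional half (A-Box) is
compiled from data — this split means routine knowledge updates cannot
corrupt the schema. No OWL reasoning runs at evaluation time: class
membership is materialised at compile time and all queries (SPARQL 1.1
SELECT/ASK via rdflib) read asserted triples only. Serialisation is
Turtle (default) or RDF/XML, and serialise → parse → serialise is a
fixed point on the canonicalised triple set.

## Compilation rules

The compiler turns three tabular sources (maximum-daily-dose table,
interaction pair table, renal dosing table) into criterion individuals.

**Maximum dose.** Rows are resolved through a product index
(code → ingredient(s), route, ATC) and grouped by
(ingredient, route, age range); clinically equivalent rows merge into
one criterion, keeping the most severe alert. A route token of
`any` produces a route-independent criterion under which the engine
sums doses across all routes. Not represented (each row lands in an
exclusion report with a reason): indication-dependent doses
(`indication_dependent`), combination products
(`combination_product`), doses that differ by pharmaceutical form at
the same route (`form_dependent`), codes the index cannot resolve
(`unmapped_code`), and rows at the sources' lowest gravity
(`low_severity` — dropped deliberately to limit alert fatigue).
Disagreeing maxima for one (ingredient, route, age range) without a
form distinction are treated as a curation failure and abort
compilation rather than being silently averaged: this knowledge is
safety-critical and conflicts belong in front of a human reviewer.
Overlapping (but unequal) age ranges are refused for the same reason;
disjoint age-specific maxima are allowed.

**Interactions.** Each pair is normalised to ATC (directly, or via the
product index), deduplicated as an unordered pair, and merged keeping
the most severe alert. A finer pair subsumed by a coarser pair with an
identical alert (both prefixes extend the coarser pair's prefixes) is
dropped. A pair whose two sides coincide after normalisation is a
compile error.

**Renal adjustment.** Each clearance bracket of an entry becomes one
criterion. A recommendation spanning a dose range and an interval
range is simplified to a single daily range on a 24 h base:

    daily_min = dose_low × 24 / interval_high
    daily_max = dose_high × 24 / interval_low

so 500–2000 mg every 8–12 h is represented as 1000–6000 mg/24 h. The
daily minimum pairs the lowest dose with the longest interval and vice
versa, which makes the function monotone in each dose argument and
antitone in the matching interval argument. Dialysis-only entries are
excluded (dialysis modality is not a structured field in the
evaluation request), as are unresolvable free-text descriptions. GFR
brackets for one (ingredient, route) must not overlap, and adjacent
brackets must not share an endpoint, since brackets are inclusive at
both ends.

**Conservation and compression.** For every dataset,
compiled + excluded = total input rows, and the compiler reports an
input/output compression ratio per dataset. Max-dose and interaction
compilation only ever collapse rows (ratio ≤ 1); renal compilation can
expand, because one entry with several clearance brackets yields one
individual per bracket.

## The rule engine

Criteria are pulled from the knowledge base with SPARQL once, at engine
construction; per-patient evaluation is then plain arithmetic. All
local codes in a request are resolved through the mapping layer first;
an unmapped concept skips the affected check for that item and appends
a typed note to the response — it never leaks into dose maths.

* **Daily-dose normalisation.** total = dose × unit conversion ×
  administrations per 24 h. Units carry a dimension (mass, volume,
  biological activity) with fixed factors to base units mg / mL / IU;
  cross-dimension conversion is a `unit_mismatch` skip, never a
  coercion. Frequencies accept "every N h", "N times daily", "qNh" or
  an explicit number.
* **Maximum dose.** For each criterion whose age range contains the
  patient's age, doses of non-PRN prescriptions of that ingredient are
  summed — per route, or across all routes when the criterion is
  route-independent. An alert fires when the total *strictly* exceeds
  the maximum; a total exactly at the maximum passes (boundary-
  inclusive pass, chosen against alert fatigue). One alert per
  criterion, naming all contributing prescriptions.
* **Interactions.** Every unordered pair of distinct non-PRN
  prescriptions whose half-open intervals [start, end) overlap and
  whose full ATC codes extend the two sides of a criterion fires
  exactly one alert per (criterion, pair). The check is symmetric by
  construction.
* **Renal.** The patient's GFR is the most recent value in the
  criterion's unit (ml/min/1.73 m²); ties on the timestamp break
  toward the larger value (conservative: fewer false renal alerts).
  If the GFR falls in a bracket (inclusive ends), the same daily-dose
  total as the maximum-dose rule is compared against the adjusted
  maximum. Underdosing does not alert (open for extension); the
  loading dose is informational and surfaced in the recommendation
  text only, since requests carry no loading/maintenance distinction.
* **Allergy.** The patient's allergen history is expanded —
  a chemical-group allergy covers every member ingredient; an
  ingredient-level allergy covers only itself (no upward expansion in
  the two-level tree) — and every prescription (PRN included; dose and
  route are irrelevant here) containing an implicated ingredient fires
  a hard-stop alert. Excipients are not checked.

**Alert lifecycle.** Severity maps onto display colour as
not_allowed → red, contraindicated → orange, not_recommended → yellow.
Overdose, interaction and renal alerts are soft stops; allergy alerts
are the only hard stops. A soft alert carries a suppression key —
a hash of (rule, criterion IRI, ingredient set, patient id),
deliberately excluding dose and dates so an ignored alert stays
suppressed even if the dose changes within the episode. The override
ledger is per patient and per care episode, append-only, and cleared
on discharge. Accepting an interaction alert requires naming which of
the two medications will be modified; ignoring a hard stop is refused.
Fired alerts are ordered hard stops first, then decreasing severity,
with a stable (rule, drugs, criterion) tie-break.

## Service layer and audit

`AlertService` is a synchronous JSON-in/JSON-out endpoint pair
(evaluate, decision) plus a health probe, exposed through the `ontorx`
CLI; the service adds no alert logic — its response alerts are the
engine's output, serialised. Requests are validated against a
published pydantic schema (doses are {value, unit} objects, timestamps
ISO 8601); schema violations, duplicate request ids, unknown
suppression keys and forbidden decisions map onto HTTP-style status
codes 422/409/404/403. Every request/response pair and every decision
is appended to a JSON Lines audit log before the response is returned.
`audit_report` aggregates the log: requests, alerts by rule and
severity, and an acceptance rate defined as accepted / decided over
soft alerts, with hard-stop alerts counted as accepted (they cannot be
ignored). The knowledge base is versioned by a content hash of its
canonicalised triples; the mapping table by the hash of its file.

## Synthetic data

The fixture knowledge base contains exactly four criteria — oral
atorvastatin 80 mg/24 h (age 18–99), route-independent acetaminophen
4000 mg/24 h, the (N06AF, R05FB02) interaction, and the parenteral
dalbavancin bracket (GFR 31–130, loading 1000 mg, maintenance
500–500 mg/24 h) — plus the proton-pump-inhibitor group (omeprazole,
pantoprazole), the backing products at all abstraction levels, and
local mappings for every code the cohort generator uses.

The cohort generator emulates an internal-medicine ward: ages drawn
around a median near 69, a Poisson number of benign prescriptions per
patient (default mean 3, drawn from an eight-product formulary), 20 %
of fillers flagged PRN, and one GFR result per patient (sometimes with
an older superseded value). Violations are injected per rule at
configured rates (defaults 0.20 / 0.15 / 0.15 / 0.05 for max dose /
interaction / renal / allergy), each constructed to trip exactly one
fixture criterion; the filler pool is pruned per patient so no
accidental combination can fire (e.g. never both interaction partners
as fillers, at most one acetaminophen product). The generator returns
a ground-truth label — expected alert count per rule — for every
patient, and the test suite asserts the engine reproduces the labels
exactly on seeded cohorts of up to 200 patients, cross-checked against
a brute-force in-memory reference evaluator that shares no code with
the engine.

What the synthetic cohort does **not** emulate: real prescribing
frequency distributions, co-morbidity structure, free-text allergy
histories, mapping gaps at hospital scale, or the alert acceptance
behaviour of real clinicians. Passing these tests demonstrates the
engine's rule semantics and the pipeline's bookkeeping, not clinical
performance on real wards.

## Numerical and design notes

* Problem sizes in the test suite (cohorts of 30–200 patients, source
  tables of 12–30 base rows) were chosen so the whole suite exercises
  every rule and every exclusion path while staying comfortably
  desk-scale; all worked-example arithmetic is closed-form and exact.
* Supported units at launch: mg, g, µg (aliases mcg/ug), mL, IU.
  Volume↔mass conversion is out of scope by design; such prescriptions
  are skipped with a `unit_mismatch` note rather than guessed at.
* PRN is a boolean prescription flag, not a frequency.
* The compiler, not the engine, drops the lowest source gravity; the
  engine therefore only ever sees the three retained severities.
* Randomness: one `numpy.random.default_rng(seed)` per generator call,
  no global state; identical configs give identical cohorts and tables
  across platforms.
* Known limitations: no indication-aware dosing, no interactions among
  more than two drugs, no pediatric dosing, no excipient-level allergy
  checking, no care-setting gating, SNOMED identifiers carried as
  opaque codes without validation against a release.
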