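# ontorx

Ontology-backed medication-safety checking for prescribing systems.

`ontorx` compiles drug-safety knowledge — maximum daily doses,
drug–drug interactions, renal dose adjustments and allergen groups —
into an RDF knowledge base (three interlinked ontologies queried with
SPARQL) and evaluates patient prescriptions against it, emitting
graded, suppressible alerts over a JSON interface. It is aimed at
clinical-informatics teams who maintain a computerised physician order
entry (CPOE) system and want a decision-support knowledge base that is
compact (product-level source rows collapse onto ingredient-level
individuals), inspectable and versioned.

## The model

Knowledge lives in three namespaces: **drugs** (medicinal products on
the VTM → VMP → AMP abstraction ladder, ingredients, two-level chemical
groups, routes, units, frequencies), **dss** (appropriateness criteria
and alert texts) and **local** (hospital EHR/CPOE codes mapped onto
canonical concepts). Four rules fire alerts:

* **max dose** — the total daily dose of an ingredient, `dose × unit
  factor × administrations/24 h` summed over non-PRN prescriptions
  (across routes when the criterion is route-independent), strictly
  exceeds the criterion maximum for the patient's age;
* **interaction** — two temporally overlapping prescriptions whose ATC
  codes extend the two sides of an interaction criterion (criteria sit
  at any ATC level, e.g. N06AF × R05FB02);
* **renal** — for the most recent GFR value inside a criterion bracket
  (e.g. 31–130 ml/min/1.73 m²), the daily dose exceeds the adjusted
  maximum;
* **allergy** — a prescribed ingredient appears in the expansion of the
  allergy history (group allergy ⇒ all member ingredients).

Severity maps to colour (not_allowed → red, contraindicated → orange,
not_recommended → yellow). Allergy alerts are hard stops and can never
be dismissed; the other three are soft stops — once a clinician ignores
one, it is suppressed for the rest of the care episode.

See `docs/methods.md` for the full account of the compilation rules,
dose arithmetic and synthetic-data design.

## Worked example

Build the fixture knowledge base, evaluate a patient, act on an alert:

```python
from ontorx import RuleEngine, OverrideLedger, build_fixture_kb, record_decision
from ontorx.engine import PatientRecord, Prescription, LabResult
from datetime import datetime, timedelta, timezone

t0 = datetime(2026, 1, 1, tzinfo=timezone.utc)
engine = RuleEngine(build_fixture_kb())
patient = PatientRecord(
    patient_id="P-DEMO", age_years=71,
    prescriptions=[
        Prescription(id="rx1", drug_code="ATORVA40", dose=80, dose_unit="MG",
                     frequency="Q12H", route="PO", start=t0, end=t0 + timedelta(days=7)),
        Prescription(id="rx2", drug_code="DALBA500", dose=1000, dose_unit="MG",
                     frequency="Q24H", route="IV", start=t0, end=t0 + timedelta(days=7)),
    ],
    labs=[LabResult("GFR-LOCAL", 45, "ml/min/1.73 m2", t0)],
)
ledger = OverrideLedger()
for a in engine.evaluate(patient, ledger).alerts:
    print(a.rule, a.colour, "|", a.description)
```

prints

```
max_dose yellow | atorvastatin: total 160 mg/24 h exceeds maximum 80 mg/24 h. maximum daily dose of atorvastatin is 80 mg
renal yellow | dalbavancin: total 1000 mg/24 h exceeds adjusted maximum 500 mg/24 h at GFR 45. dalbavancin requires dose adjustment in renal failure
```

80 mg every 12 h is 160 mg/24 h against an 80 mg maximum, and
1000 mg/24 h of dalbavancin exceeds the 500 mg adjusted maintenance
dose for a GFR of 45 (bracket 31–130). Ignoring the first alert
(`record_decision(ledger, "P-DEMO", key, "ignored")`) suppresses it on
re-evaluation; an allergy alert would refuse the ignore.

The same flows are available from the shell:

```bash
ontorx synth kb --out kbdir                  # fixture knowledge base (Turtle)
ontorx synth tables --size 20 --out tabledir # synthetic source CSVs + manifest
ontorx compile --max-dose tabledir/max_dose.csv \
    --interactions tabledir/interactions.csv --renal tabledir/renal.csv \
    --products tabledir/products.csv --out compiled   # Turtle + report.json
ontorx evaluate --patient request.json --kb kbdir --audit audit.jsonl
ontorx report --audit audit.jsonl            # alerts by rule, acceptance rate
```

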