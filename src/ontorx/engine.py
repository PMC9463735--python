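"""Prescription checking: the four safety rules and the alert lifecycle.

The engine evaluates a patient record against the compiled knowledge
base and fires graded alerts for four error classes:

* **max_dose** — the summed daily dose of an ingredient exceeds the
  criterion maximum (summed across routes when the criterion is
  route-independent);
* **interaction** — two temporally overlapping prescriptions whose ATC
  codes extend the two sides of an interaction criterion;
* **renal** — daily dose above the adjusted maximum for the patient's
  most recent glomerular filtration rate bracket;
* **allergy** — a prescribed ingredient appears in the expansion of the
  patient's allergy history (a chemical-group allergy covers every
  member ingredient).

Prescriptions flagged "as needed" (PRN) are ignored by the first three
rules but still checked for allergy.  Overdose, interaction and renal
alerts are *soft stops*: once ignored by the clinician they are
suppressed for the rest of the care episode.  Allergy alerts are the
only *hard stops* and can never be suppressed.

Criteria are pulled from the knowledge base with SPARQL at engine
construction (the knowledge is asserted, no reasoning is involved);
per-patient evaluation is then plain arithmetic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Optional, Sequence, Union

from rdflib import Graph

from .kb import CompiledKnowledgeBase, DRUGS_NS, DSS_NS, LOCAL_NS
from .mapping import MappingSet, Unmapped
from .model import (
    ANY_ROUTE,
    ConceptRef,
    GFR_CONCEPT,
    SEVERITY_COLOUR,
    SEVERITY_RANK,
    Severity,
    route_ref,
)
from .units import Frequency, UNITS, UnitMismatchError, convert, parse_frequency

RULES = ("max_dose", "interaction", "renal", "allergy")

SKIP_REASONS = (
    "unmapped_drug",
    "unmapped_route",
    "unmapped_unit",
    "unmapped_frequency",
    "unmapped_allergen",
    "unit_mismatch",
    "no_gfr_result",
)


# --- patient-side records ---------------------------------------------------


@dataclass
class Prescription:
    """One active prescription line, in local (hospital) codes."""

    id: str
    drug_code: str
    dose: float
    dose_unit: str
    frequency: Union[str, float, Frequency]
    route: str
    start: datetime
    end: datetime
    prn: bool = False

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if self.start >= self.end:
            raise ValueError("prescription start must precede end")

    def overlaps(self, other: "Prescription") -> bool:
        # half-open intervals [start, end)
        return self.start < other.end and other.start < self.end


@dataclass
class LabResult:
    test_code: str
    value: float
    unit: str
    taken_at: datetime


@dataclass
class PatientRecord:
    patient_id: str
    age_years: int
    prescriptions: list[Prescription] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    allergies: list[str] = field(default_factory=list)
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.age_years < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class FiredAlert:
    rule: str
    severity: Severity
    hard_stop: bool
    drugs: tuple[str, ...]  # involved prescription ids
    criterion: ConceptRef
    description: str
    recommendation: str
    suppression_key: str

    @property
    def colour(self) -> str:
        return SEVERITY_COLOUR[self.severity]


@dataclass
class EvaluationResult:
    alerts: list[FiredAlert]
    skipped: list[dict]


# --- override ledger ---------------------------------------------------------


class DecisionError(ValueError):
    """Invalid clinician decision (e.g. ignoring a hard stop)."""


class UnknownAlertError(KeyError):
    """Decision references a suppression key never emitted."""


class OverrideLedger:
    """Per-patient record of ignored alerts driving suppression.

    Append-only within a care episode; a soft alert ignored once stays
    suppressed until the episode is cleared (discharge).  Hard-stop
    alerts never enter the suppression set.
    """

    def __init__(self) -> None:
        self._ignored: dict[str, dict[str, str]] = {}
        self._emitted: dict[tuple[str, str], FiredAlert] = {}
        self.decisions: list[dict] = []

    def is_suppressed(self, patient_id: str, key: str) -> bool:
        return key in self._ignored.get(patient_id, {})

    def ignored_keys(self, patient_id: str) -> set[str]:
        return set(self._ignored.get(patient_id, {}))

    def note_emitted(self, patient_id: str, alerts: Sequence[FiredAlert]) -> None:
        for alert in alerts:
            self._emitted[(patient_id, alert.suppression_key)] = alert

    def emitted(self, patient_id: str, key: str) -> Optional[FiredAlert]:
        return self._emitted.get((patient_id, key))

    def clear_episode(self, patient_id: str) -> None:
        self._ignored.pop(patient_id, None)
        self._emitted = {
            k: v for k, v in self._emitted.items() if k[0] != patient_id
        }

    def _add_ignored(self, patient_id: str, key: str) -> None:
        self._ignored.setdefault(patient_id, {})[key] = datetime.now(
            timezone.utc
        ).isoformat()


def record_decision(
    ledger: OverrideLedger,
    patient_id: str,
    suppression_key: str,
    decision: str,
    chosen_prescription: Optional[str] = None,
) -> OverrideLedger:
    """Record a clinician decision on a previously emitted alert.

    ``ignored`` adds the key to the suppression set (soft stops only);
    accepting an interaction alert involving two or more medications
    requires naming the prescription the clinician will modify.
    """
    if decision not in ("accepted", "ignored"):
        raise DecisionError(f"decision must be accepted or ignored: {decision!r}")
    alert = ledger.emitted(patient_id, suppression_key)
    if alert is None:
        raise UnknownAlertError(
            f"no alert with key {suppression_key!r} was emitted for {patient_id!r}"
        )
    if decision == "ignored":
        if alert.hard_stop:
            raise DecisionError("hard-stop (allergy) alerts cannot be ignored")
        ledger._add_ignored(patient_id, suppression_key)
    else:
        if alert.rule == "interaction" and len(alert.drugs) >= 2:
            if not chosen_prescription:
                raise DecisionError(
                    "accepting an interaction alert requires choosing which "
                    "medication to modify"
                )
            if chosen_prescription not in alert.drugs:
                raise DecisionError(
                    f"chosen prescription {chosen_prescription!r} is not part "
                    f"of the alert"
                )
    ledger.decisions.append(
        {
            "patient_id": patient_id,
            "suppression_key": suppression_key,
            "decision": decision,
            "rule": alert.rule,
            "hard_stop": alert.hard_stop,
            "chosen_prescription": chosen_prescription,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
    )
    return ledger


# --- dose arithmetic ----------------------------------------------------------


def normalize_daily_dose(
    dose: float,
    unit: str,
    frequency: Union[str, float, Frequency],
    target_unit: str,
) -> float:
    """Total daily dose: dose × unit conversion × administrations/24 h.

    Raises :class:`UnitMismatchError` when the prescribed and target
    units live in different dimensions (the check is then skipped and
    noted, never silently computed).
    """
    freq = parse_frequency(frequency)
    return convert(dose, unit, target_unit) * freq.administrations_per_24h


# --- knowledge view (SPARQL extraction) ----------------------------------------

_PREFIXES = f"""
PREFIX drugs: <{DRUGS_NS}>
PREFIX dss: <{DSS_NS}>
PREFIX local: <{LOCAL_NS}>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
"""

_Q_ALERTS = _PREFIXES + """
SELECT ?a ?desc ?rec ?level WHERE {
  ?a a dss:Alert ; dss:alertDescription ?desc ;
     dss:alertRecommendation ?rec ; dss:alertLevel ?level .
}"""

_Q_MAX_DOSE = _PREFIXES + """
SELECT ?c ?ing ?ingLabel ?route ?max ?unit ?ageMin ?ageMax ?alert WHERE {
  ?c a dss:MaximumDoseAdult ;
     dss:ingredient ?ing ; dss:route ?route ;
     dss:maxDailyDose ?max ; dss:doseUnit ?unit ;
     dss:ageMin ?ageMin ; dss:ageMax ?ageMax .
  ?ing rdfs:label ?ingLabel .
  OPTIONAL { ?c dss:alert ?alert }
}"""

_Q_INTERACTION = _PREFIXES + """
SELECT ?c ?a ?b ?alert WHERE {
  ?c a dss:DrugInteraction ; dss:atcA ?a ; dss:atcB ?b .
  OPTIONAL { ?c dss:alert ?alert }
}"""

_Q_RENAL = _PREFIXES + """
SELECT ?c ?ing ?ingLabel ?route ?test ?labUnit ?lo ?hi ?minD ?maxD ?unit
       ?loading ?loadingUnit ?alert WHERE {
  ?c a dss:RenalAdjustment ;
     dss:ingredient ?ing ; dss:route ?route ; dss:labTest ?test ;
     dss:labUnit ?labUnit ; dss:gfrLow ?lo ; dss:gfrHigh ?hi ;
     dss:adjustedMinDaily ?minD ; dss:adjustedMaxDaily ?maxD ;
     dss:doseUnit ?unit .
  ?ing rdfs:label ?ingLabel .
  OPTIONAL { ?c dss:loadingDose ?loading . ?c dss:loadingUnit ?loadingUnit }
  OPTIONAL { ?c dss:alert ?alert }
}"""

_Q_PRODUCTS = _PREFIXES + """
SELECT ?p ?label ?atc ?route WHERE {
  { ?p a drugs:VTM } UNION { ?p a drugs:VMP } UNION { ?p a drugs:AMP }
  ?p rdfs:label ?label .
  OPTIONAL { ?p drugs:hasATC ?atc }
  OPTIONAL { ?p drugs:hasRoute ?route }
}"""

_Q_PRODUCT_INGREDIENTS = _PREFIXES + """
SELECT ?p ?i WHERE { ?p drugs:hasIngredient ?i }"""

_Q_GROUPS = _PREFIXES + """
SELECT ?g ?m WHERE { ?g a drugs:ChemicalGroup ; drugs:hasMember ?m }"""

_Q_UNITS = _PREFIXES + """
SELECT ?u ?label WHERE { ?u a drugs:Unit ; rdfs:label ?label }"""

_Q_FREQUENCIES = _PREFIXES + """
SELECT ?f ?per24 WHERE { ?f a drugs:Frequency ; drugs:administrationsPer24h ?per24 }"""

_Q_ROUTES = _PREFIXES + """
SELECT ?r ?label WHERE { ?r a drugs:Route ; rdfs:label ?label }"""

_Q_MAPPINGS = _PREFIXES + """
SELECT ?code ?domain ?target WHERE {
  ?m local:localCode ?code ; local:domain ?domain ; local:mapsTo ?target .
}"""


@dataclass(frozen=True)
class _AlertView:
    description: str
    recommendation: str
    level: Severity


@dataclass(frozen=True)
class _MaxDoseView:
    criterion: ConceptRef
    ingredient_iri: str
    ingredient_label: str
    route_iri: str
    max_daily_dose: float
    dose_unit: str
    age_min: int
    age_max: int
    alert: Optional[_AlertView]


@dataclass(frozen=True)
class _InteractionView:
    criterion: ConceptRef
    atc_a: str
    atc_b: str
    alert: Optional[_AlertView]


@dataclass(frozen=True)
class _RenalView:
    criterion: ConceptRef
    ingredient_iri: str
    ingredient_label: str
    route_iri: str
    lab_test_iri: str
    lab_unit: str
    gfr_low: float
    gfr_high: float
    adjusted_min_daily: float
    adjusted_max_daily: float
    dose_unit: str
    loading_dose: Optional[float]
    loading_unit: Optional[str]
    alert: Optional[_AlertView]


@dataclass(frozen=True)
class _ProductView:
    iri: str
    label: str
    ingredients: tuple[str, ...]
    atc: Optional[str]
    route_iri: Optional[str]


class KnowledgeView:
    """All engine-relevant knowledge, extracted from the graph via SPARQL."""

    def __init__(self, graph: Graph):
        alerts: dict[str, _AlertView] = {}
        for a, desc, rec, level in graph.query(_Q_ALERTS):
            alerts[str(a)] = _AlertView(str(desc), str(rec), Severity(str(level)))

        def _alert(node) -> Optional[_AlertView]:
            return alerts.get(str(node)) if node is not None else None

        self.max_dose: list[_MaxDoseView] = []
        for row in graph.query(_Q_MAX_DOSE):
            c, ing, ing_label, route, mx, unit, amin, amax, alert = row
            self.max_dose.append(
                _MaxDoseView(
                    ConceptRef(str(c), str(c).rsplit(":", 1)[-1]),
                    str(ing),
                    str(ing_label),
                    str(route),
                    float(mx),
                    str(unit),
                    int(amin),
                    int(amax),
                    _alert(alert),
                )
            )
        self.max_dose.sort(key=lambda v: v.criterion.iri)

        self.interactions: list[_InteractionView] = []
        for c, a, b, alert in graph.query(_Q_INTERACTION):
            self.interactions.append(
                _InteractionView(
                    ConceptRef(str(c), str(c).rsplit(":", 1)[-1]),
                    str(a),
                    str(b),
                    _alert(alert),
                )
            )
        self.interactions.sort(key=lambda v: v.criterion.iri)

        self.renal: list[_RenalView] = []
        for row in graph.query(_Q_RENAL):
            (c, ing, ing_label, route, test, lab_unit, lo, hi, mind, maxd,
             unit, loading, loading_unit, alert) = row
            self.renal.append(
                _RenalView(
                    ConceptRef(str(c), str(c).rsplit(":", 1)[-1]),
                    str(ing),
                    str(ing_label),
                    str(route),
                    str(test),
                    str(lab_unit),
                    float(lo),
                    float(hi),
                    float(mind),
                    float(maxd),
                    str(unit),
                    float(loading) if loading is not None else None,
                    str(loading_unit) if loading_unit is not None else None,
                    _alert(alert),
                )
            )
        self.renal.sort(key=lambda v: v.criterion.iri)

        ing_by_product: dict[str, list[str]] = {}
        for p, i in graph.query(_Q_PRODUCT_INGREDIENTS):
            ing_by_product.setdefault(str(p), []).append(str(i))
        self.products: dict[str, _ProductView] = {}
        for p, label, atc, route in graph.query(_Q_PRODUCTS):
            iri = str(p)
            self.products[iri] = _ProductView(
                iri=iri,
                label=str(label),
                ingredients=tuple(sorted(ing_by_product.get(iri, ()))),
                atc=str(atc) if atc is not None else None,
                route_iri=str(route) if route is not None else None,
            )

        self.group_members: dict[str, set[str]] = {}
        for g, m in graph.query(_Q_GROUPS):
            self.group_members.setdefault(str(g), set()).add(str(m))

        self.unit_symbols: dict[str, str] = {
            str(u): str(label) for u, label in graph.query(_Q_UNITS)
        }
        self.frequencies: dict[str, float] = {
            str(f): float(per24) for f, per24 in graph.query(_Q_FREQUENCIES)
        }
        self.routes: dict[str, str] = {
            str(r): str(label) for r, label in graph.query(_Q_ROUTES)
        }
        self.ingredient_labels: dict[str, str] = {
            v.ingredient_iri: v.ingredient_label for v in self.max_dose
        }
        for v in self.renal:
            self.ingredient_labels[v.ingredient_iri] = v.ingredient_label

    def mappings_from_graph(self, graph: Graph) -> MappingSet:
        from .model import LocalConceptMapping

        rows = []
        for code, domain, target in graph.query(_Q_MAPPINGS):
            rows.append(
                LocalConceptMapping(
                    local_code=str(code),
                    local_label=str(code),
                    domain=str(domain),
                    target=ConceptRef(str(target), str(target).rsplit(":", 1)[-1]),
                )
            )
        return MappingSet(rows)


# --- the engine ------------------------------------------------------------------


def suppression_key(
    rule: str, criterion_iri: str, ingredient_iris: Sequence[str], patient_id: str
) -> str:
    """Stable key identifying an alert for suppression purposes.

    Deliberately excludes dose and dates: once ignored, the alert stays
    suppressed even if the dose changes within the episode.
    """
    payload = "|".join([rule, criterion_iri, ",".join(sorted(ingredient_iris)),
                        patient_id])
    return hashlib.sha256(payload.encode()).hexdigest()[:20]


@dataclass
class _ResolvedRx:
    rx: Prescription
    product: _ProductView
    route_iri: str
    unit_symbol: Optional[str]
    frequency: Optional[Frequency]


class RuleEngine:
    """Evaluates patient records against a compiled knowledge base."""

    def __init__(self, kb: Union[CompiledKnowledgeBase, Graph],
                 mappings: Optional[MappingSet] = None):
        graph = kb.to_graph() if isinstance(kb, CompiledKnowledgeBase) else kb
        self.view = KnowledgeView(graph)
        if mappings is None:
            mappings = self.view.mappings_from_graph(graph)
        self.mappings = mappings

    # --- resolution helpers ------------------------------------------------

    def _resolve_unit(self, code: str) -> Optional[str]:
        target = self.mappings.resolve(code, "unit")
        if isinstance(target, ConceptRef):
            return self.view.unit_symbols.get(target.iri, target.label)
        return code if code in UNITS else None

    def _resolve_frequency(self, spec) -> Optional[Frequency]:
        if isinstance(spec, (Frequency, int, float)):
            return parse_frequency(spec)
        target = self.mappings.resolve(str(spec), "frequency")
        if isinstance(target, ConceptRef):
            per24 = self.view.frequencies.get(target.iri)
            if per24 is not None:
                return Frequency(label=str(spec), administrations_per_24h=per24)
        try:
            return parse_frequency(str(spec))
        except ValueError:
            return None

    def _resolve_route(self, code: str) -> Optional[str]:
        target = self.mappings.resolve(code, "route")
        if isinstance(target, ConceptRef):
            return target.iri
        cand = route_ref(code)
        if cand.iri in self.view.routes or cand.iri == ANY_ROUTE.iri:
            return cand.iri
        return None

    def _resolve_prescriptions(
        self, patient: PatientRecord
    ) -> tuple[list[_ResolvedRx], list[dict]]:
        resolved, skipped = [], []

        def skip(rx_id: str, reason: str) -> None:
            note = {"prescription_id": rx_id, "reason": reason}
            if note not in skipped:
                skipped.append(note)

        for rx in patient.prescriptions:
            target = self.mappings.resolve(rx.drug_code, "drug")
            if isinstance(target, Unmapped) or target.iri not in self.view.products:
                skip(rx.id, "unmapped_drug")
                continue
            product = self.view.products[target.iri]
            route_iri = self._resolve_route(rx.route)
            if route_iri is None:
                skip(rx.id, "unmapped_route")
                route_iri = ""
            unit = self._resolve_unit(rx.dose_unit)
            if unit is None:
                skip(rx.id, "unmapped_unit")
            freq = self._resolve_frequency(rx.frequency)
            if freq is None:
                skip(rx.id, "unmapped_frequency")
            resolved.append(_ResolvedRx(rx, product, route_iri, unit, freq))
        return resolved, skipped

    def _daily_dose(
        self, r: _ResolvedRx, target_unit: str, skipped: list[dict]
    ) -> Optional[float]:
        if r.unit_symbol is None or r.frequency is None:
            return None
        try:
            return normalize_daily_dose(
                r.rx.dose, r.unit_symbol, r.frequency, target_unit
            )
        except UnitMismatchError:
            note = {"prescription_id": r.rx.id, "reason": "unit_mismatch"}
            if note not in skipped:
                skipped.append(note)
            return None

    # --- the four checks -----------------------------------------------------

    def check_max_dose(
        self, patient: PatientRecord,
        resolved: Optional[list[_ResolvedRx]] = None,
        skipped: Optional[list[dict]] = None,
    ) -> list[FiredAlert]:
        if resolved is None:
            resolved, skipped = self._resolve_prescriptions(patient)
        skipped = skipped if skipped is not None else []
        alerts = []
        for crit in self.view.max_dose:
            if not (crit.age_min <= patient.age_years <= crit.age_max):
                continue
            contributors: list[tuple[_ResolvedRx, float]] = []
            for r in resolved:
                if r.rx.prn:
                    continue
                if crit.ingredient_iri not in r.product.ingredients:
                    continue
                if crit.route_iri != ANY_ROUTE.iri and r.route_iri != crit.route_iri:
                    continue
                dose = self._daily_dose(r, crit.dose_unit, skipped)
                if dose is not None:
                    contributors.append((r, dose))
            if not contributors:
                continue
            total = sum(d for _, d in contributors)
            if total > crit.max_daily_dose:  # equality passes
                alert = crit.alert
                severity = alert.level if alert else Severity.NOT_RECOMMENDED
                drug_ids = tuple(sorted(r.rx.id for r, _ in contributors))
                desc = (
                    alert.description
                    if alert
                    else f"maximum daily dose exceeded for {crit.ingredient_label}"
                )
                desc = (
                    f"{crit.ingredient_label}: total {total:g} {crit.dose_unit}/24 h "
                    f"exceeds maximum {crit.max_daily_dose:g} {crit.dose_unit}/24 h. "
                    + desc
                )
                alerts.append(
                    FiredAlert(
                        rule="max_dose",
                        severity=severity,
                        hard_stop=False,
                        drugs=drug_ids,
                        criterion=crit.criterion,
                        description=desc,
                        recommendation=alert.recommendation if alert else "",
                        suppression_key=suppression_key(
                            "max_dose",
                            crit.criterion.iri,
                            [crit.ingredient_iri],
                            patient.patient_id,
                        ),
                    )
                )
        return alerts

    def check_interactions(
        self, patient: PatientRecord,
        resolved: Optional[list[_ResolvedRx]] = None,
        skipped: Optional[list[dict]] = None,
    ) -> list[FiredAlert]:
        if resolved is None:
            resolved, skipped = self._resolve_prescriptions(patient)
        active = [r for r in resolved if not r.rx.prn and r.product.atc]
        alerts = []
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                r1, r2 = active[i], active[j]
                if not r1.rx.overlaps(r2.rx):
                    continue
                for crit in self.view.interactions:
                    a1, a2 = r1.product.atc, r2.product.atc
                    hit = (
                        a1.startswith(crit.atc_a) and a2.startswith(crit.atc_b)
                    ) or (a1.startswith(crit.atc_b) and a2.startswith(crit.atc_a))
                    if not hit:
                        continue
                    alert = crit.alert
                    severity = alert.level if alert else Severity.NOT_RECOMMENDED
                    ingredients = sorted(
                        set(r1.product.ingredients) | set(r2.product.ingredients)
                    )
                    desc = (
                        f"interaction between {r1.product.label} and "
                        f"{r2.product.label} (ATC {crit.atc_a} x {crit.atc_b}). "
                        + (alert.description if alert else "")
                    )
                    alerts.append(
                        FiredAlert(
                            rule="interaction",
                            severity=severity,
                            hard_stop=False,
                            drugs=tuple(sorted((r1.rx.id, r2.rx.id))),
                            criterion=crit.criterion,
                            description=desc,
                            recommendation=alert.recommendation if alert else "",
                            suppression_key=suppression_key(
                                "interaction",
                                crit.criterion.iri,
                                ingredients,
                                patient.patient_id,
                            ),
                        )
                    )
        return alerts

    def _most_recent_gfr(
        self, patient: PatientRecord, lab_unit: str
    ) -> Optional[float]:
        results = []
        for lab in patient.labs:
            target = self.mappings.resolve(lab.test_code, "lab_test")
            test_iri = target.iri if isinstance(target, ConceptRef) else lab.test_code
            if test_iri != GFR_CONCEPT.iri:
                continue
            if lab.unit.replace(" ", "") != lab_unit.replace(" ", ""):
                continue
            results.append(lab)
        if not results:
            return None
        # most recent value; ties broken toward the larger (fewer false alerts)
        best = max(results, key=lambda lab: (lab.taken_at, lab.value))
        return best.value

    def check_renal(
        self, patient: PatientRecord,
        resolved: Optional[list[_ResolvedRx]] = None,
        skipped: Optional[list[dict]] = None,
    ) -> list[FiredAlert]:
        if resolved is None:
            resolved, skipped = self._resolve_prescriptions(patient)
        skipped = skipped if skipped is not None else []
        alerts = []
        for crit in self.view.renal:
            gfr = self._most_recent_gfr(patient, crit.lab_unit)
            if gfr is None:
                continue
            if not (crit.gfr_low <= gfr <= crit.gfr_high):
                continue
            contributors = []
            for r in resolved:
                if r.rx.prn:
                    continue
                if crit.ingredient_iri not in r.product.ingredients:
                    continue
                if crit.route_iri != ANY_ROUTE.iri and r.route_iri != crit.route_iri:
                    continue
                dose = self._daily_dose(r, crit.dose_unit, skipped)
                if dose is not None:
                    contributors.append((r, dose))
            if not contributors:
                continue
            total = sum(d for _, d in contributors)
            if total > crit.adjusted_max_daily:
                alert = crit.alert
                severity = alert.level if alert else Severity.NOT_RECOMMENDED
                rec = (
                    f"adjusted dose {crit.adjusted_min_daily:g}-"
                    f"{crit.adjusted_max_daily:g} {crit.dose_unit}/24 h for "
                    f"GFR {crit.gfr_low:g}-{crit.gfr_high:g} {crit.lab_unit}"
                )
                if crit.loading_dose is not None:
                    rec += (
                        f"; loading dose {crit.loading_dose:g} "
                        f"{crit.loading_unit or crit.dose_unit}/24 h"
                    )
                if alert and alert.recommendation:
                    rec += ". " + alert.recommendation
                desc = (
                    f"{crit.ingredient_label}: total {total:g} "
                    f"{crit.dose_unit}/24 h exceeds adjusted maximum "
                    f"{crit.adjusted_max_daily:g} {crit.dose_unit}/24 h at "
                    f"GFR {gfr:g}. " + (alert.description if alert else "")
                )
                alerts.append(
                    FiredAlert(
                        rule="renal",
                        severity=severity,
                        hard_stop=False,
                        drugs=tuple(sorted(r.rx.id for r, _ in contributors)),
                        criterion=crit.criterion,
                        description=desc,
                        recommendation=rec,
                        suppression_key=suppression_key(
                            "renal",
                            crit.criterion.iri,
                            [crit.ingredient_iri],
                            patient.patient_id,
                        ),
                    )
                )
        return alerts

    def check_allergy(
        self, patient: PatientRecord,
        resolved: Optional[list[_ResolvedRx]] = None,
        skipped: Optional[list[dict]] = None,
    ) -> list[FiredAlert]:
        """Hard-stop check: dose, route and PRN status are not considered."""
        if resolved is None:
            resolved, skipped = self._resolve_prescriptions(patient)
        skipped = skipped if skipped is not None else []
        allergen_ingredients: set[str] = set()
        allergen_source: dict[str, ConceptRef] = {}
        for code in patient.allergies:
            target = self.mappings.resolve(code, "allergen")
            if isinstance(target, Unmapped):
                note = {"prescription_id": "", "reason": "unmapped_allergen"}
                if note not in skipped:
                    skipped.append(note)
                continue
            members = self.view.group_members.get(target.iri)
            expansion = members if members else {target.iri}
            for iri in expansion:
                allergen_ingredients.add(iri)
                allergen_source.setdefault(iri, target)
        if not allergen_ingredients:
            return []
        alerts = []
        for r in resolved:  # PRN included: allergy ignores dosing semantics
            hits = sorted(set(r.product.ingredients) & allergen_ingredients)
            if not hits:
                continue
            source = allergen_source[hits[0]]
            label = self.view.ingredient_labels.get(hits[0], hits[0].rsplit(":", 1)[-1])
            alerts.append(
                FiredAlert(
                    rule="allergy",
                    severity=Severity.NOT_ALLOWED,
                    hard_stop=True,
                    drugs=(r.rx.id,),
                    criterion=source,
                    description=(
                        f"allergy: {r.product.label} contains {label}, listed "
                        f"in the patient's allergy history ({source.label})"
                    ),
                    recommendation="do not administer; choose an alternative",
                    suppression_key=suppression_key(
                        "allergy", source.iri, hits, patient.patient_id
                    ),
                )
            )
        return alerts

    # --- orchestration ---------------------------------------------------------

    def evaluate(
        self, patient: PatientRecord, ledger: Optional[OverrideLedger] = None
    ) -> EvaluationResult:
        """Run all four checks; apply suppression; order by severity.

        Soft-stop alerts whose suppression key was previously ignored
        for this patient are removed; hard stops always surface.
        Ordering: hard stops first, then decreasing severity, then a
        stable (rule, drugs) tie-break.
        """
        resolved, skipped = self._resolve_prescriptions(patient)
        alerts = (
            self.check_max_dose(patient, resolved, skipped)
            + self.check_interactions(patient, resolved, skipped)
            + self.check_renal(patient, resolved, skipped)
            + self.check_allergy(patient, resolved, skipped)
        )
        if ledger is not None:
            alerts = [
                a
                for a in alerts
                if a.hard_stop
                or not ledger.is_suppressed(patient.patient_id, a.suppression_key)
            ]
        alerts.sort(
            key=lambda a: (
                not a.hard_stop,
                -SEVERITY_RANK[a.severity],
                a.rule,
                a.drugs,
                a.criterion.iri,
            )
        )
        if ledger is not None:
            ledger.note_emitted(patient.patient_id, alerts)
        return EvaluationResult(alerts=alerts, skipped=skipped)
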