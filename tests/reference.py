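"""Brute-force reference evaluator.

Independent oracle for the rule engine: enumerates every
(prescription, criterion) combination with plain loops over the
knowledge base's in-memory collections — no triple store, no SPARQL,
no shared code path with :mod:`ontorx.engine`.  Returns alerts as
(rule, criterion_iri, drug_id_tuple) triples.
"""

from __future__ import annotations

from ontorx.kb import CompiledKnowledgeBase
from ontorx.mapping import MappingSet, Unmapped
from ontorx.model import (
    ANY_ROUTE,
    ConceptRef,
    GFR_CONCEPT,
    frequency_concept_ref,
    route_ref,
    unit_concept_ref,
)
from ontorx.units import UNITS


def _resolve_unit(mappings: MappingSet, kb: CompiledKnowledgeBase, code: str):
    target = mappings.resolve(code, "unit")
    if not isinstance(target, Unmapped):
        for symbol, unit in kb.units.items():
            if unit_concept_ref(symbol).iri == target.iri:
                return unit
        return None
    return UNITS.get(code)


def _resolve_freq(mappings: MappingSet, kb: CompiledKnowledgeBase, spec):
    if isinstance(spec, (int, float)):
        return float(spec)
    target = mappings.resolve(str(spec), "frequency")
    if not isinstance(target, Unmapped):
        for label, freq in kb.frequencies.items():
            if frequency_concept_ref(label).iri == target.iri:
                return freq.administrations_per_24h
    return None


def _resolve_route(mappings: MappingSet, kb: CompiledKnowledgeBase, code: str):
    target = mappings.resolve(code, "route")
    if not isinstance(target, Unmapped):
        return target.iri
    cand = route_ref(code)
    if cand.iri in kb.routes or cand.iri == ANY_ROUTE.iri:
        return cand.iri
    return None


def _daily(kb, mappings, rx, target_unit_symbol):
    unit = _resolve_unit(mappings, kb, rx.dose_unit)
    per24 = _resolve_freq(mappings, kb, rx.frequency)
    target = UNITS.get(target_unit_symbol) or kb.units.get(target_unit_symbol)
    if unit is None or per24 is None or target is None:
        return None
    if unit.dimension != target.dimension:
        return None
    return rx.dose * unit.factor_to_base / target.factor_to_base * per24


def _resolved(kb, mappings, patient):
    out = []
    for rx in patient.prescriptions:
        target = mappings.resolve(rx.drug_code, "drug")
        if isinstance(target, Unmapped) or target.iri not in kb.products:
            continue
        product = kb.products[target.iri]
        route_iri = _resolve_route(mappings, kb, rx.route) or ""
        out.append((rx, product, route_iri))
    return out


def brute_force_alerts(
    kb: CompiledKnowledgeBase, mappings: MappingSet, patient
) -> set[tuple[str, str, tuple[str, ...]]]:
    resolved = _resolved(kb, mappings, patient)
    alerts: set[tuple[str, str, tuple[str, ...]]] = set()

    # --- max dose
    for crit in kb.max_dose_criteria:
        if not (crit.age_min <= patient.age_years <= crit.age_max):
            continue
        total, ids = 0.0, []
        for rx, product, route_iri in resolved:
            if rx.prn:
                continue
            if crit.ingredient.iri not in {i.iri for i in product.ingredients}:
                continue
            if crit.route.iri != ANY_ROUTE.iri and route_iri != crit.route.iri:
                continue
            dose = _daily(kb, mappings, rx, crit.dose_unit)
            if dose is not None:
                total += dose
                ids.append(rx.id)
        if ids and total > crit.max_daily_dose:
            alerts.add(("max_dose", crit.ref.iri, tuple(sorted(ids))))

    # --- interactions
    active = [
        (rx, product)
        for rx, product, _ in resolved
        if not rx.prn and product.atc
    ]
    for i in range(len(active)):
        for j in range(i + 1, len(active)):
            (rx1, p1), (rx2, p2) = active[i], active[j]
            if not (rx1.start < rx2.end and rx2.start < rx1.end):
                continue
            for crit in kb.interaction_criteria:
                a, b = crit.atc_a, crit.atc_b
                if (p1.atc.startswith(a) and p2.atc.startswith(b)) or (
                    p1.atc.startswith(b) and p2.atc.startswith(a)
                ):
                    alerts.add(
                        ("interaction", crit.ref.iri,
                         tuple(sorted((rx1.id, rx2.id))))
                    )

    # --- renal
    for crit in kb.renal_criteria:
        gfr_labs = []
        for lab in patient.labs:
            target = mappings.resolve(lab.test_code, "lab_test")
            iri = lab.test_code if isinstance(target, Unmapped) else target.iri
            if iri == GFR_CONCEPT.iri and (
                lab.unit.replace(" ", "") == crit.lab_unit.replace(" ", "")
            ):
                gfr_labs.append(lab)
        if not gfr_labs:
            continue
        gfr = max(gfr_labs, key=lambda lab: (lab.taken_at, lab.value)).value
        if not (crit.gfr_low <= gfr <= crit.gfr_high):
            continue
        total, ids = 0.0, []
        for rx, product, route_iri in resolved:
            if rx.prn:
                continue
            if crit.ingredient.iri not in {i.iri for i in product.ingredients}:
                continue
            if crit.route.iri != ANY_ROUTE.iri and route_iri != crit.route.iri:
                continue
            dose = _daily(kb, mappings, rx, crit.dose_unit)
            if dose is not None:
                total += dose
                ids.append(rx.id)
        if ids and total > crit.adjusted_max_daily:
            alerts.add(("renal", crit.ref.iri, tuple(sorted(ids))))

    # --- allergy (PRN included; dose and route irrelevant)
    expansion: dict[str, ConceptRef] = {}
    for code in patient.allergies:
        target = mappings.resolve(code, "allergen")
        if isinstance(target, Unmapped):
            continue
        group = kb.groups.get(target.iri)
        members = [m.iri for m in group.members] if group else [target.iri]
        for iri in members:
            expansion.setdefault(iri, target)
    for rx, product, _ in resolved:
        hits = sorted(
            i.iri for i in product.ingredients if i.iri in expansion
        )
        if hits:
            source = expansion[hits[0]]
            alerts.add(("allergy", source.iri, (rx.id,)))
    return alerts


def engine_alert_set(result) -> set[tuple[str, str, tuple[str, ...]]]:
    return {(a.rule, a.criterion.iri, a.drugs) for a in result.alerts}
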