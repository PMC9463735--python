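"""Compiled knowledge base: triple materialisation, validation, SPARQL.

The terminological half (T-Box) is a static schema shipped with the
package (``data/tbox.ttl``); only the assertional half (A-Box) is
compiled from source data.  No OWL reasoning happens at runtime: class
membership is materialised at compile time and all queries run over
asserted triples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import XSD

from .model import (
    ANY_ROUTE,
    AlertKnowledge,
    ChemicalGroup,
    ConceptRef,
    DRUGS_NS,
    DSS_NS,
    GFR_CONCEPT,
    Ingredient,
    InteractionCriterion,
    LOCAL_NS,
    LocalConceptMapping,
    MaxDoseCriterion,
    MedicinalProduct,
    PackagedProduct,
    ProductLevel,
    RenalAdjustmentCriterion,
)
from .units import Frequency, Unit

DRUGS = Namespace(DRUGS_NS)
DSS = Namespace(DSS_NS)
LOCAL = Namespace(LOCAL_NS)

_LOCAL_CLASS = {
    "drug": LOCAL.LocalDrug,
    "route": LOCAL.LocalRoute,
    "unit": LOCAL.LocalUnit,
    "frequency": LOCAL.LocalFrequency,
    "lab_test": LOCAL.LocalLabTest,
    "allergen": LOCAL.LocalAllergen,
}

_RDFLIB_FORMAT = {"turtle": "turtle", "rdfxml": "xml"}


class KBValidationError(ValueError):
    """The knowledge base violates a structural invariant."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid knowledge base:\n" + "\n".join(errors))


def load_tbox() -> Graph:
    """Parse the packaged T-Box schema into a fresh graph."""
    g = Graph()
    text = resources.files("ontorx").joinpath("data/tbox.ttl").read_text()
    g.parse(data=text, format="turtle")
    return g


@dataclass
class CompiledKnowledgeBase:
    """In-memory individuals plus their RDF materialisation.

    The three sub-ontologies are distinguishable by IRI namespace; the
    dependency direction is drugs ← dss ← local (drugs references
    neither of the others).
    """

    ingredients: dict[str, Ingredient] = field(default_factory=dict)
    groups: dict[str, ChemicalGroup] = field(default_factory=dict)
    products: dict[str, MedicinalProduct] = field(default_factory=dict)
    packs: dict[str, PackagedProduct] = field(default_factory=dict)
    routes: dict[str, ConceptRef] = field(default_factory=dict)
    units: dict[str, Unit] = field(default_factory=dict)  # by symbol
    frequencies: dict[str, Frequency] = field(default_factory=dict)  # by label
    alerts: dict[str, AlertKnowledge] = field(default_factory=dict)
    max_dose_criteria: list[MaxDoseCriterion] = field(default_factory=list)
    interaction_criteria: list[InteractionCriterion] = field(default_factory=list)
    renal_criteria: list[RenalAdjustmentCriterion] = field(default_factory=list)
    mappings: list[LocalConceptMapping] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    # --- registration helpers ---------------------------------------------

    def add_ingredient(self, ing: Ingredient) -> Ingredient:
        self.ingredients.setdefault(ing.ref.iri, ing)
        return self.ingredients[ing.ref.iri]

    def add_route(self, route: ConceptRef) -> ConceptRef:
        self.routes.setdefault(route.iri, route)
        return self.routes[route.iri]

    def add_alert(self, alert: AlertKnowledge) -> AlertKnowledge:
        self.alerts.setdefault(alert.ref.iri, alert)
        return self.alerts[alert.ref.iri]

    # --- lookup -------------------------------------------------------------

    def all_individual_iris(self) -> dict[str, str]:
        """Every individual IRI mapped to the collection it lives in."""
        out: dict[str, str] = {}
        buckets: list[tuple[str, Iterable[str]]] = [
            ("ingredient", self.ingredients),
            ("group", self.groups),
            ("product", self.products),
            ("pack", self.packs),
            ("route", self.routes),
            ("alert", self.alerts),
            ("max_dose", (c.ref.iri for c in self.max_dose_criteria)),
            ("interaction", (c.ref.iri for c in self.interaction_criteria)),
            ("renal", (c.ref.iri for c in self.renal_criteria)),
            ("mapping", (m.iri for m in self.mappings)),
        ]
        for kind, iris in buckets:
            for iri in iris:
                if iri in out:
                    raise KBValidationError(
                        [f"duplicate individual IRI {iri} ({out[iri]} vs {kind})"]
                    )
                out[iri] = kind
        return out

    def has_iri(self, iri: str) -> bool:
        from .model import frequency_concept_ref, unit_concept_ref

        if iri in (ANY_ROUTE.iri, GFR_CONCEPT.iri):
            return True
        if any(unit_concept_ref(sym).iri == iri for sym in self.units):
            return True
        if any(frequency_concept_ref(lbl).iri == iri for lbl in self.frequencies):
            return True
        return any(
            iri in coll
            for coll in (
                self.ingredients,
                self.groups,
                self.products,
                self.packs,
                self.routes,
                self.alerts,
            )
        ) or any(
            iri == c.ref.iri
            for c in (
                *self.max_dose_criteria,
                *self.interaction_criteria,
                *self.renal_criteria,
            )
        )

    # --- validation ---------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errors: list[str] = []
        try:
            iris = self.all_individual_iris()
        except KBValidationError as exc:
            return exc.errors

        def _ns_check(iri: str, expect: str, what: str) -> None:
            ns = {"drugs": DRUGS_NS, "dss": DSS_NS, "local": LOCAL_NS}[expect]
            if not iri.startswith(ns):
                errors.append(f"{what} {iri} not in {expect} namespace")

        for iri, ing in self.ingredients.items():
            _ns_check(iri, "drugs", "ingredient")
            if ing.chemical_group is not None:
                grp = self.groups.get(ing.chemical_group.iri)
                if grp is None:
                    errors.append(f"ingredient {iri} references missing group")
                elif all(m.iri != iri for m in grp.members):
                    errors.append(
                        f"group {grp.ref.iri} does not list member {iri}"
                    )
        member_of: dict[str, str] = {}
        for iri, grp in self.groups.items():
            _ns_check(iri, "drugs", "group")
            if not grp.members:
                errors.append(f"chemical group {iri} has no members")
            for m in grp.members:
                if m.iri not in self.ingredients:
                    errors.append(f"group {iri} lists missing ingredient {m.iri}")
                if m.iri in member_of and member_of[m.iri] != iri:
                    errors.append(
                        f"ingredient {m.iri} belongs to two groups (two-level tree)"
                    )
                member_of[m.iri] = iri

        for iri, prod in self.products.items():
            _ns_check(iri, "drugs", "product")
            if not prod.ingredients:
                errors.append(f"product {iri} resolves to no ingredient")
            for ing in prod.ingredients:
                if ing.iri not in self.ingredients:
                    errors.append(f"product {iri} references missing ingredient")
            if prod.level == ProductLevel.VTM:
                if prod.strength_value is not None or prod.dose_form is not None:
                    errors.append(f"VTM {iri} must not carry strength or form")
            elif prod.level == ProductLevel.VMP:
                if prod.vtm is None or prod.vtm.iri not in self.products:
                    errors.append(f"VMP {iri} lacks an existing VTM parent")
                if prod.strength_value is None or prod.route is None:
                    errors.append(f"VMP {iri} must carry strength and route")
            elif prod.level == ProductLevel.AMP:
                if prod.vmp is None or prod.vmp.iri not in self.products:
                    errors.append(f"AMP {iri} lacks an existing VMP parent")
            if prod.route is not None and prod.route.iri not in self.routes:
                errors.append(f"product {iri} references missing route")

        for iri, pack in self.packs.items():
            _ns_check(iri, "drugs", "pack")
            target = self.products.get(pack.product.iri)
            if target is None:
                errors.append(f"pack {iri} references missing product")
            elif pack.level == "AMPP" and target.level != ProductLevel.AMP:
                errors.append(f"AMPP {iri} must reference an AMP")
            elif pack.level == "VMPP" and target.level != ProductLevel.VMP:
                errors.append(f"VMPP {iri} must reference a VMP")

        for iri in self.alerts:
            _ns_check(iri, "dss", "alert")

        def _criterion_common(crit, kind: str) -> None:
            _ns_check(crit.ref.iri, "dss", kind)
            if crit.alert is not None and crit.alert.ref.iri not in self.alerts:
                errors.append(f"{kind} {crit.ref.iri} references missing alert")

        seen_md: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for crit in self.max_dose_criteria:
            _criterion_common(crit, "max-dose criterion")
            if (
                crit.ingredient.iri not in self.ingredients
            ):
                errors.append(
                    f"max-dose criterion {crit.ref.iri} references missing ingredient"
                )
            if crit.route.iri != ANY_ROUTE.iri and crit.route.iri not in self.routes:
                errors.append(
                    f"max-dose criterion {crit.ref.iri} references missing route"
                )
            key = (crit.ingredient.iri, crit.route.iri)
            for lo, hi in seen_md.get(key, []):
                if crit.age_min <= hi and lo <= crit.age_max:
                    errors.append(
                        f"overlapping age ranges for max-dose criteria on {key}"
                    )
            seen_md.setdefault(key, []).append((crit.age_min, crit.age_max))

        for crit in self.interaction_criteria:
            _criterion_common(crit, "interaction criterion")

        seen_renal: dict[tuple[str, str], list[tuple[float, float]]] = {}
        for crit in self.renal_criteria:
            _criterion_common(crit, "renal criterion")
            if crit.ingredient.iri not in self.ingredients:
                errors.append(
                    f"renal criterion {crit.ref.iri} references missing ingredient"
                )
            key = (crit.ingredient.iri, crit.route.iri)
            for lo, hi in seen_renal.get(key, []):
                if crit.gfr_low <= hi and lo <= crit.gfr_high:
                    errors.append(f"overlapping GFR brackets for {key}")
            seen_renal.setdefault(key, []).append((crit.gfr_low, crit.gfr_high))

        for m in self.mappings:
            if not (
                m.target.iri.startswith(DRUGS_NS) or m.target.iri.startswith(DSS_NS)
            ):
                errors.append(
                    f"mapping {m.local_code}/{m.domain} targets non-canonical IRI"
                )
            elif not self.has_iri(m.target.iri):
                errors.append(
                    f"mapping {m.local_code}/{m.domain} targets missing {m.target.iri}"
                )
        seen_map = set()
        for m in self.mappings:
            key = (m.local_code, m.domain)
            if key in seen_map:
                errors.append(f"duplicate mapping for {key}")
            seen_map.add(key)

        # namespace partition over everything
        for iri in iris:
            if not (
                iri.startswith(DRUGS_NS)
                or iri.startswith(DSS_NS)
                or iri.startswith(LOCAL_NS)
            ):
                errors.append(f"individual {iri} outside the three namespaces")
        return errors

    # --- RDF materialisation -------------------------------------------------

    def to_graph(self, include_tbox: bool = True) -> Graph:
        g = load_tbox() if include_tbox else Graph()
        g.bind("drugs", DRUGS)
        g.bind("dss", DSS)
        g.bind("local", LOCAL)

        def node(ref: ConceptRef) -> URIRef:
            return URIRef(ref.iri)

        def add_labelled(ref: ConceptRef, cls: URIRef) -> URIRef:
            n = node(ref)
            g.add((n, RDF.type, cls))
            g.add((n, RDFS.label, Literal(ref.label)))
            return n

        for route in self.routes.values():
            add_labelled(route, DRUGS.Route)
        if any(c.route.iri == ANY_ROUTE.iri for c in self.max_dose_criteria):
            add_labelled(ANY_ROUTE, DRUGS.Route)

        for symbol, unit in self.units.items():
            from .model import unit_concept_ref

            n = add_labelled(unit_concept_ref(symbol), DRUGS.Unit)
            g.add((n, DRUGS.unitDimension, Literal(unit.dimension)))
            g.add((n, DRUGS.factorToBase, Literal(unit.factor_to_base)))

        for label, freq in self.frequencies.items():
            from .model import frequency_concept_ref

            n = add_labelled(frequency_concept_ref(label), DRUGS.Frequency)
            g.add(
                (n, DRUGS.administrationsPer24h, Literal(freq.administrations_per_24h))
            )

        for ing in self.ingredients.values():
            n = add_labelled(ing.ref, DRUGS.Ingredient)
            if ing.chemical_group is not None:
                g.add((n, DRUGS.memberOf, node(ing.chemical_group)))
        for grp in self.groups.values():
            n = add_labelled(grp.ref, DRUGS.ChemicalGroup)
            for m in grp.members:
                g.add((n, DRUGS.hasMember, node(m)))

        level_cls = {
            ProductLevel.VTM: DRUGS.VTM,
            ProductLevel.VMP: DRUGS.VMP,
            ProductLevel.AMP: DRUGS.AMP,
        }
        for prod in self.products.values():
            n = add_labelled(prod.ref, level_cls[prod.level])
            for ing in prod.ingredients:
                g.add((n, DRUGS.hasIngredient, node(ing)))
            if prod.vtm is not None:
                g.add((n, DRUGS.hasVTM, node(prod.vtm)))
            if prod.vmp is not None:
                g.add((n, DRUGS.hasVMP, node(prod.vmp)))
            if prod.route is not None:
                g.add((n, DRUGS.hasRoute, node(prod.route)))
            if prod.dose_form is not None:
                g.add((n, DRUGS.hasDoseForm, node(prod.dose_form)))
                g.add((node(prod.dose_form), RDF.type, DRUGS.DoseForm))
                g.add(
                    (node(prod.dose_form), RDFS.label, Literal(prod.dose_form.label))
                )
            if prod.strength_value is not None:
                g.add((n, DRUGS.strengthValue, Literal(prod.strength_value)))
                g.add((n, DRUGS.strengthUnit, Literal(prod.strength_unit)))
            if prod.atc is not None:
                g.add((n, DRUGS.hasATC, Literal(prod.atc)))
            if prod.state is not None:
                g.add((n, DRUGS.state, Literal(prod.state.value)))

        for pack in self.packs.values():
            cls = DRUGS.AMPP if pack.level == "AMPP" else DRUGS.VMPP
            n = add_labelled(pack.ref, cls)
            g.add((n, DRUGS.packOf, node(pack.product)))
            g.add((n, DRUGS.packSize, Literal(pack.pack_size)))
            if pack.price is not None:
                g.add((n, DRUGS.price, Literal(pack.price)))

        for alert in self.alerts.values():
            n = add_labelled(alert.ref, DSS.Alert)
            g.add((n, DSS.alertDescription, Literal(alert.description)))
            g.add((n, DSS.alertRecommendation, Literal(alert.recommendation)))
            g.add((n, DSS.alertSource, Literal(alert.source)))
            if alert.last_updated is not None:
                g.add(
                    (
                        n,
                        DSS.alertLastUpdated,
                        Literal(alert.last_updated, datatype=XSD.date),
                    )
                )
            g.add((n, DSS.alertLevel, Literal(alert.level.value)))

        for crit in self.max_dose_criteria:
            n = add_labelled(crit.ref, DSS.MaximumDoseAdult)
            g.add((n, DSS.ingredient, node(crit.ingredient)))
            g.add((n, DSS.route, node(crit.route)))
            g.add((n, DSS.maxDailyDose, Literal(crit.max_daily_dose)))
            g.add((n, DSS.doseUnit, Literal(crit.dose_unit)))
            g.add((n, DSS.ageMin, Literal(crit.age_min)))
            g.add((n, DSS.ageMax, Literal(crit.age_max)))
            if crit.alert is not None:
                g.add((n, DSS.alert, node(crit.alert.ref)))

        for crit in self.interaction_criteria:
            n = add_labelled(crit.ref, DSS.DrugInteraction)
            g.add((n, DSS.atcA, Literal(crit.atc_a)))
            g.add((n, DSS.atcB, Literal(crit.atc_b)))
            if crit.alert is not None:
                g.add((n, DSS.alert, node(crit.alert.ref)))

        for crit in self.renal_criteria:
            n = add_labelled(crit.ref, DSS.RenalAdjustment)
            g.add((n, DSS.ingredient, node(crit.ingredient)))
            g.add((n, DSS.route, node(crit.route)))
            g.add((n, DSS.labTest, node(crit.lab_test)))
            g.add((node(crit.lab_test), RDF.type, DSS.LabTest))
            g.add((node(crit.lab_test), RDFS.label, Literal(crit.lab_test.label)))
            g.add((n, DSS.labUnit, Literal(crit.lab_unit)))
            g.add((n, DSS.gfrLow, Literal(crit.gfr_low)))
            g.add((n, DSS.gfrHigh, Literal(crit.gfr_high)))
            if crit.loading_dose is not None:
                g.add((n, DSS.loadingDose, Literal(crit.loading_dose)))
                g.add((n, DSS.loadingUnit, Literal(crit.loading_unit or "")))
            g.add((n, DSS.adjustedMinDaily, Literal(crit.adjusted_min_daily)))
            g.add((n, DSS.adjustedMaxDaily, Literal(crit.adjusted_max_daily)))
            g.add((n, DSS.doseUnit, Literal(crit.dose_unit)))
            if crit.alert is not None:
                g.add((n, DSS.alert, node(crit.alert.ref)))

        for m in self.mappings:
            n = URIRef(m.iri)
            g.add((n, RDF.type, _LOCAL_CLASS[m.domain]))
            g.add((n, RDFS.label, Literal(m.local_label or m.local_code)))
            g.add((n, LOCAL.localCode, Literal(m.local_code)))
            g.add((n, LOCAL.domain, Literal(m.domain)))
            g.add((n, LOCAL.mapsTo, URIRef(m.target.iri)))
        return g

    def version(self) -> str:
        """Content hash of the materialised graph (order-independent)."""
        nt = self.to_graph().serialize(format="nt")
        lines = sorted(line for line in nt.splitlines() if line.strip())
        return hashlib.sha256("\n".join(lines).encode()).hexdigest()[:16]


def serialize_kb(kb: CompiledKnowledgeBase, format: str = "turtle") -> bytes:
    """Serialise the knowledge base (T-Box + A-Box) to Turtle or RDF/XML.

    Raises :class:`KBValidationError` listing the offending individuals
    when the knowledge base violates its invariants.
    """
    if format not in _RDFLIB_FORMAT:
        raise ValueError(f"unsupported format: {format!r} (turtle or rdfxml)")
    errors = kb.validate()
    if errors:
        raise KBValidationError(errors)
    data = kb.to_graph().serialize(format=_RDFLIB_FORMAT[format])
    return data.encode() if isinstance(data, str) else data


def serialize_kb_split(kb: CompiledKnowledgeBase) -> dict[str, bytes]:
    """Serialise one Turtle document per sub-ontology plus the T-Box.

    A-Box triples are partitioned by the namespace of their subject;
    the schema goes to ``tbox``.
    """
    errors = kb.validate()
    if errors:
        raise KBValidationError(errors)
    abox = kb.to_graph(include_tbox=False)
    parts: dict[str, Graph] = {}
    for name, ns in (("drugs", DRUGS_NS), ("dss", DSS_NS), ("local", LOCAL_NS)):
        sub = Graph()
        sub.bind("drugs", DRUGS)
        sub.bind("dss", DSS)
        sub.bind("local", LOCAL)
        for s, p, o in abox:
            if str(s).startswith(ns):
                sub.add((s, p, o))
        parts[name] = sub
    out = {name: g.serialize(format="turtle").encode() for name, g in parts.items()}
    out["tbox"] = load_tbox().serialize(format="turtle").encode()
    return out


def parse_graph(data: bytes | str, format: str = "turtle") -> Graph:
    """Parse a serialised knowledge-base document back into a graph."""
    g = Graph()
    g.parse(data=data, format=_RDFLIB_FORMAT.get(format, format))
    return g


def load_kb_graph(paths: Iterable) -> Graph:
    """Union the Turtle files of a knowledge-base directory into one graph."""
    g = Graph()
    for path in paths:
        g.parse(str(path), format="turtle")
    return g


def run_query(kb: CompiledKnowledgeBase | Graph, query: str):
    """Run a SPARQL 1.1 SELECT/ASK over the knowledge base.

    SELECT returns a list of binding tuples (deterministic modulo row
    order); ASK returns a bool.  Malformed queries raise rdflib's parse
    error.
    """
    g = kb if isinstance(kb, Graph) else kb.to_graph()
    result = g.query(query)
    if result.type == "ASK":
        return bool(result.askAnswer)
    return [tuple(row) for row in result]
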