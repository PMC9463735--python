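"""Domain model for the three interlinked drug-safety ontologies.

The knowledge base is split across three namespaces mirroring its three
sub-ontologies:

* **drugs** — identification and technical data of medicinal products:
  the VTM/VMP/AMP abstraction ladder (bare ingredient → strength+route
  → marketed product), packs (VMPP/AMPP), ingredients, chemical groups,
  routes, units and frequencies.
* **dss** — appropriateness knowledge: maximum-dose, drug–drug
  interaction and renal-adjustment criteria plus the alert texts they
  point at.
* **local** — the hospital-side mapping layer from EHR/CPOE codes onto
  canonical concepts.

Everything here is a plain frozen-ish dataclass; RDF materialisation
and SPARQL live in :mod:`ontorx.kb`.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Optional

DRUGS_NS = "urn:ontorx:drugs:"
DSS_NS = "urn:ontorx:dss:"
LOCAL_NS = "urn:ontorx:local:"

NAMESPACES = {"drugs": DRUGS_NS, "dss": DSS_NS, "local": LOCAL_NS}


def slugify(text: str) -> str:
    """Stable lowercase ASCII slug for IRIs, derived from source codes."""
    norm = unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode()
    slug = re.sub(r"[^a-z0-9]+", "-", norm.lower()).strip("-")
    if not slug:
        raise ValueError(f"cannot derive a slug from {text!r}")
    return slug


def make_iri(ontology: str, cls: str, slug: str) -> str:
    """IRI scheme: ``urn:ontorx:{drugs|dss|local}:{class}:{slug}``."""
    ns = NAMESPACES[ontology]
    return f"{ns}{cls}:{slugify(slug)}"


@dataclass(frozen=True)
class ConceptRef:
    """Node identity shared by every individual in the knowledge base."""

    iri: str
    label: str

    def __post_init__(self) -> None:
        if not self.iri:
            raise ValueError("ConceptRef.iri must be non-empty")
        if not self.label:
            raise ValueError(f"ConceptRef.label must be non-empty ({self.iri})")

    @property
    def namespace(self) -> Optional[str]:
        for name, ns in NAMESPACES.items():
            if self.iri.startswith(ns):
                return name
        return None


#: Sentinel route meaning "the maximum applies regardless of route";
#: under it daily doses are aggregated across all routes.
ANY_ROUTE = ConceptRef(iri=DRUGS_NS + "route:any", label="any route")


# --- ATC codes ------------------------------------------------------------

_ATC_PATTERNS = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d{2}$"),
    4: re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    5: re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
    7: re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$"),
}


def validate_atc(code: str) -> str:
    """Validate an ATC code at any of the five hierarchy levels.

    Valid lengths are 1, 3, 4, 5 and 7 characters; every prefix of a
    valid code at one of those lengths is itself a valid coarser code.
    """
    pattern = _ATC_PATTERNS.get(len(code))
    if pattern is None or not pattern.match(code):
        raise ValueError(f"invalid ATC code: {code!r}")
    return code


def atc_matches(code: str, prefix: str) -> bool:
    """True if ``code`` falls under ``prefix`` in the ATC hierarchy."""
    return code.startswith(prefix)


# --- Matter: ingredients and chemical groups ------------------------------


@dataclass
class Ingredient:
    """An active substance; optionally a member of one chemical group.

    The allergen model is a strict two-level tree: a patient allergic to
    a chemical group (e.g. proton pump inhibitors) is treated as
    allergic to every member ingredient (e.g. omeprazole); an
    ingredient-level allergy does not expand upward.
    """

    ref: ConceptRef
    chemical_group: Optional[ConceptRef] = None


@dataclass
class ChemicalGroup:
    ref: ConceptRef
    members: tuple[ConceptRef, ...] = ()


# --- Medicinal products ----------------------------------------------------


class ProductLevel(str, Enum):
    VTM = "VTM"  # ingredient devoid of strength and form
    VMP = "VMP"  # VTM + strength + route
    AMP = "AMP"  # supplier's actual product


class ProductState(str, Enum):
    AUTHORIZED = "authorized"
    MARKETED = "marketed"
    WITHDRAWN = "withdrawn"


@dataclass
class MedicinalProduct:
    ref: ConceptRef
    level: ProductLevel
    ingredients: tuple[ConceptRef, ...] = ()
    vtm: Optional[ConceptRef] = None
    vmp: Optional[ConceptRef] = None  # AMP parent
    strength_value: Optional[float] = None
    strength_unit: Optional[str] = None
    dose_form: Optional[ConceptRef] = None
    route: Optional[ConceptRef] = None
    atc: Optional[str] = None
    state: Optional[ProductState] = None

    def __post_init__(self) -> None:
        if self.atc is not None:
            validate_atc(self.atc)


@dataclass
class PackagedProduct:
    """VMPP/AMPP: a pack of a (virtual or actual) medicinal product."""

    ref: ConceptRef
    product: ConceptRef
    level: str  # 'VMPP' | 'AMPP'
    pack_size: int = 1
    price: Optional[float] = None

    def __post_init__(self) -> None:
        if self.level not in ("VMPP", "AMPP"):
            raise ValueError(f"pack level must be VMPP or AMPP: {self.level}")
        if self.pack_size < 1:
            raise ValueError("pack_size must be >= 1")
        if self.price is not None and self.price < 0:
            raise ValueError("price must be non-negative")


# --- Alerts and severity ---------------------------------------------------


class Severity(str, Enum):
    """Alert level, from mildest retained to most severe.

    The sources' lowest level ("to take into account") is dropped at
    compile time to limit alert fatigue and never reaches the engine.
    """

    NOT_RECOMMENDED = "not_recommended"
    CONTRAINDICATED = "contraindicated"
    NOT_ALLOWED = "not_allowed"


SEVERITY_RANK = {
    Severity.NOT_RECOMMENDED: 1,
    Severity.CONTRAINDICATED: 2,
    Severity.NOT_ALLOWED: 3,
}

#: Display colour is a pure function of severity.
SEVERITY_COLOUR = {
    Severity.NOT_RECOMMENDED: "yellow",
    Severity.CONTRAINDICATED: "orange",
    Severity.NOT_ALLOWED: "red",
}


@dataclass
class AlertKnowledge:
    """The displayed knowledge attached to a criterion."""

    ref: ConceptRef
    description: str
    recommendation: str = ""
    source: str = ""
    last_updated: Optional[date] = None
    level: Severity = Severity.NOT_RECOMMENDED

    def __post_init__(self) -> None:
        if not self.description:
            raise ValueError(f"alert description must be non-empty ({self.ref.iri})")
        self.level = Severity(self.level)


# --- Appropriateness criteria ----------------------------------------------


@dataclass
class MaxDoseCriterion:
    """Maximum total daily dose for an (ingredient, route) pair.

    ``route == ANY_ROUTE`` means the maximum is route-independent and
    all prescribed doses of the ingredient are summed across routes.
    Dose is per 24 h; the age range is inclusive in whole years.
    """

    ref: ConceptRef
    ingredient: ConceptRef
    route: ConceptRef
    max_daily_dose: float
    dose_unit: str
    age_min: int = 18
    age_max: int = 99
    alert: Optional[AlertKnowledge] = None

    def __post_init__(self) -> None:
        if self.max_daily_dose <= 0:
            raise ValueError("max_daily_dose must be positive")
        if self.age_min > self.age_max:
            raise ValueError("age_min must be <= age_max")


@dataclass
class InteractionCriterion:
    """A symmetric drug–drug interaction keyed by two ATC prefixes.

    Prefixes may sit at any ATC level; a prescription matches a side if
    its full ATC code extends that prefix.  The pair is unordered.
    """

    ref: ConceptRef
    atc_a: str
    atc_b: str
    alert: Optional[AlertKnowledge] = None

    def __post_init__(self) -> None:
        validate_atc(self.atc_a)
        validate_atc(self.atc_b)
        # canonical unordered representation
        if self.atc_b < self.atc_a:
            self.atc_a, self.atc_b = self.atc_b, self.atc_a

    @property
    def pair(self) -> tuple[str, str]:
        return (self.atc_a, self.atc_b)


@dataclass
class RenalAdjustmentCriterion:
    """Adjusted daily dosing for one GFR bracket of an (ingredient, route).

    GFR is in ml/min/1.73 m²; the bracket is inclusive at both ends.
    Adjusted doses are normalised to a 24 h base; the optional loading
    dose is informational and surfaced in the alert text only.
    """

    ref: ConceptRef
    ingredient: ConceptRef
    route: ConceptRef
    lab_test: ConceptRef
    gfr_low: float
    gfr_high: float
    adjusted_min_daily: float
    adjusted_max_daily: float
    dose_unit: str
    lab_unit: str = "ml/min/1.73 m2"
    loading_dose: Optional[float] = None
    loading_unit: Optional[str] = None
    alert: Optional[AlertKnowledge] = None

    def __post_init__(self) -> None:
        if self.gfr_low > self.gfr_high:
            raise ValueError("gfr_low must be <= gfr_high")
        if self.adjusted_min_daily > self.adjusted_max_daily:
            raise ValueError("adjusted_min_daily must be <= adjusted_max_daily")

    def contains_gfr(self, gfr: float) -> bool:
        return self.gfr_low <= gfr <= self.gfr_high


# --- Local terminology mapping ---------------------------------------------

MAPPING_DOMAINS = ("drug", "route", "unit", "frequency", "lab_test", "allergen")


@dataclass(frozen=True)
class LocalConceptMapping:
    """One row of the local→canonical terminology map."""

    local_code: str
    local_label: str
    domain: str
    target: ConceptRef

    def __post_init__(self) -> None:
        if self.domain not in MAPPING_DOMAINS:
            raise ValueError(f"unknown mapping domain: {self.domain!r}")
        if not self.local_code:
            raise ValueError("local_code must be non-empty")

    @property
    def iri(self) -> str:
        return make_iri("local", self.domain, self.local_code)


# --- Canonical concept helpers --------------------------------------------


def ingredient_ref(name: str) -> ConceptRef:
    return ConceptRef(make_iri("drugs", "ingredient", name), name)


def group_ref(name: str) -> ConceptRef:
    return ConceptRef(make_iri("drugs", "group", name), name)


def route_ref(name: str) -> ConceptRef:
    if name.lower() in ("any", "all", "*"):
        return ANY_ROUTE
    return ConceptRef(make_iri("drugs", "route", name), name)


def unit_concept_ref(symbol: str) -> ConceptRef:
    return ConceptRef(make_iri("drugs", "unit", symbol), symbol)


def frequency_concept_ref(label: str) -> ConceptRef:
    return ConceptRef(make_iri("drugs", "frequency", label), label)


#: Canonical glomerular-filtration-rate lab concept (DSS ontology).
GFR_CONCEPT = ConceptRef(
    iri=DSS_NS + "labtest:gfr", label="glomerular filtration rate"
)
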