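"""Fixture knowledge base and synthetic data generation.

Every stage of the pipeline is testable without external downloads:

* :func:`build_fixture_kb` assembles a small but complete knowledge
  base covering all four rules — a statin maximum-dose criterion, a
  route-independent analgesic maximum, one drug–drug interaction at the
  ATC subgroup level, one renal-adjustment bracket for a long-acting
  antibiotic, and a proton-pump-inhibitor allergen group — plus the
  products, units, frequencies and local mappings they need.
* :func:`generate_cohort` draws synthetic inpatients and injects rule
  violations at configured rates, emitting a ground-truth label (the
  expected alert count per rule) for every patient.  Injections are
  constructed to trip exactly one known criterion; filler prescriptions
  are chosen so they can never trip anything.
* :func:`generate_source_tables` fabricates the three tabular source
  datasets with planted duplicates, exclusions and multi-bracket rows,
  plus a manifest of what was planted, so compiler dedup/exclusion
  behaviour can be checked against known counts.

All randomness flows through one seeded generator; the same config
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np
import pandas as pd

from .engine import LabResult, PatientRecord, Prescription, RULES
from .kb import CompiledKnowledgeBase
from .mapping import MappingSet, load_mappings
from .model import (
    ANY_ROUTE,
    AlertKnowledge,
    ChemicalGroup,
    ConceptRef,
    GFR_CONCEPT,
    Ingredient,
    InteractionCriterion,
    MaxDoseCriterion,
    MedicinalProduct,
    PackagedProduct,
    ProductLevel,
    ProductState,
    RenalAdjustmentCriterion,
    Severity,
    frequency_concept_ref,
    group_ref,
    ingredient_ref,
    make_iri,
    route_ref,
    unit_concept_ref,
)
from .units import UNITS, parse_frequency

GFR_UNIT = "ml/min/1.73 m2"

_EPOCH = datetime(2026, 1, 1, tzinfo=timezone.utc)


# --- fixture knowledge base ---------------------------------------------------


def build_fixture_kb() -> CompiledKnowledgeBase:
    """The worked-example knowledge base: four criteria, eight products.

    Contents: an oral atorvastatin maximum of 80 mg/24 h for adults
    (18–99); a route-independent acetaminophen maximum of 4000 mg/24 h
    (doses summed across routes); an interaction between ATC subgroups
    N06AF and R05FB02; a parenteral dalbavancin renal bracket (GFR
    31–130, loading 1000 mg, adjusted maintenance 500–500 mg/24 h); and
    the proton-pump-inhibitor chemical group containing omeprazole and
    pantoprazole for allergy expansion.
    """
    kb = CompiledKnowledgeBase()
    oral = route_ref("oral")
    parenteral = route_ref("parenteral")
    kb.add_route(oral)
    kb.add_route(parenteral)

    for sym in ("mg", "g"):
        kb.units[sym] = UNITS[sym]
    for label in ("every 24 h", "every 12 h", "every 8 h"):
        kb.frequencies[label] = parse_frequency(label)

    ppi = group_ref("proton pump inhibitors")
    names = [
        "atorvastatin",
        "acetaminophen",
        "dalbavancin",
        "phenelzine",
        "cloperastine",
        "omeprazole",
        "pantoprazole",
    ]
    ings = {n: ingredient_ref(n) for n in names}
    for n, ref in ings.items():
        grp = ppi if n in ("omeprazole", "pantoprazole") else None
        kb.add_ingredient(Ingredient(ref=ref, chemical_group=grp))
    kb.groups[ppi.iri] = ChemicalGroup(
        ref=ppi, members=(ings["omeprazole"], ings["pantoprazole"])
    )

    def vtm(name: str) -> MedicinalProduct:
        ref = ConceptRef(make_iri("drugs", "vtm", name), name)
        p = MedicinalProduct(
            ref=ref, level=ProductLevel.VTM, ingredients=(ings[name],)
        )
        kb.products[ref.iri] = p
        return p

    def vmp(
        name: str, strength: float, unit: str, route: ConceptRef, atc: str,
        suffix: str = "",
    ) -> MedicinalProduct:
        parent = kb.products.get(make_iri("drugs", "vtm", name)) or vtm(name)
        label = f"{name} {strength:g} {unit} {route.label}{suffix}"
        ref = ConceptRef(make_iri("drugs", "vmp", label), label)
        p = MedicinalProduct(
            ref=ref,
            level=ProductLevel.VMP,
            ingredients=(ings[name],),
            vtm=parent.ref,
            strength_value=strength,
            strength_unit=unit,
            route=route,
            atc=atc,
            state=ProductState.MARKETED,
        )
        kb.products[ref.iri] = p
        return p

    for n in names:
        vtm(n)
    atorva = vmp("atorvastatin", 40, "mg", oral, "C10AA05")
    paracet_po = vmp("acetaminophen", 500, "mg", oral, "N02BE01")
    paracet_iv = vmp("acetaminophen", 1000, "mg", parenteral, "N02BE01")
    dalba = vmp("dalbavancin", 500, "mg", parenteral, "J01XA04")
    phenelzine = vmp("phenelzine", 15, "mg", oral, "N06AF03")
    cloperastine = vmp("cloperastine", 10, "mg", oral, "R05FB02")
    omeprazole = vmp("omeprazole", 20, "mg", oral, "A02BC01")
    pantoprazole = vmp("pantoprazole", 40, "mg", oral, "A02BC02")

    # one actual product + packs to exercise the lower abstraction levels
    amp_ref = ConceptRef(
        make_iri("drugs", "amp", "omeprazole acme 20 mg capsule"),
        "omeprazole Acme 20 mg capsule",
    )
    kb.products[amp_ref.iri] = MedicinalProduct(
        ref=amp_ref,
        level=ProductLevel.AMP,
        ingredients=(ings["omeprazole"],),
        vmp=omeprazole.ref,
        strength_value=20,
        strength_unit="mg",
        route=oral,
        atc="A02BC01",
        state=ProductState.MARKETED,
    )
    vmpp_ref = ConceptRef(
        make_iri("drugs", "vmpp", "omeprazole 20 mg 28 capsules"),
        "omeprazole 20 mg 28 capsules",
    )
    kb.packs[vmpp_ref.iri] = PackagedProduct(
        ref=vmpp_ref, product=omeprazole.ref, level="VMPP", pack_size=28
    )
    ampp_ref = ConceptRef(
        make_iri("drugs", "ampp", "omeprazole acme 20 mg 28 capsules"),
        "omeprazole Acme 20 mg 28 capsules",
    )
    kb.packs[ampp_ref.iri] = PackagedProduct(
        ref=ampp_ref, product=amp_ref, level="AMPP", pack_size=28, price=3.5
    )

    def alert(key: str, desc: str, rec: str, level: Severity) -> AlertKnowledge:
        a = AlertKnowledge(
            ref=ConceptRef(make_iri("dss", "alert", key), f"alert {key}"),
            description=desc,
            recommendation=rec,
            source="fixture formulary",
            level=level,
        )
        kb.add_alert(a)
        return a

    kb.max_dose_criteria.append(
        MaxDoseCriterion(
            ref=ConceptRef(
                make_iri("dss", "maxdose", "atorvastatin-oral-18-99"),
                "max dose atorvastatin oral",
            ),
            ingredient=ings["atorvastatin"],
            route=oral,
            max_daily_dose=80,
            dose_unit="mg",
            age_min=18,
            age_max=99,
            alert=alert(
                "maxdose-atorvastatin",
                "maximum daily dose of atorvastatin is 80 mg",
                "reduce the total daily dose to at most 80 mg",
                Severity.NOT_RECOMMENDED,
            ),
        )
    )
    kb.max_dose_criteria.append(
        MaxDoseCriterion(
            ref=ConceptRef(
                make_iri("dss", "maxdose", "acetaminophen-any-18-99"),
                "max dose acetaminophen any route",
            ),
            ingredient=ings["acetaminophen"],
            route=ANY_ROUTE,
            max_daily_dose=4000,
            dose_unit="mg",
            age_min=18,
            age_max=99,
            alert=alert(
                "maxdose-acetaminophen",
                "maximum daily dose of acetaminophen is 4000 mg across all routes",
                "keep the combined daily dose at or below 4000 mg",
                Severity.CONTRAINDICATED,
            ),
        )
    )
    kb.interaction_criteria.append(
        InteractionCriterion(
            ref=ConceptRef(
                make_iri("dss", "interaction", "N06AF-R05FB02"),
                "interaction N06AF x R05FB02",
            ),
            atc_a="N06AF",
            atc_b="R05FB02",
            alert=alert(
                "interaction-n06af-r05fb02",
                "MAO inhibitors must not be combined with this antitussive",
                "withdraw one of the two drugs",
                Severity.CONTRAINDICATED,
            ),
        )
    )
    kb.renal_criteria.append(
        RenalAdjustmentCriterion(
            ref=ConceptRef(
                make_iri("dss", "renal", "dalbavancin-parenteral-gfr-31-130"),
                "renal adjustment dalbavancin parenteral",
            ),
            ingredient=ings["dalbavancin"],
            route=parenteral,
            lab_test=GFR_CONCEPT,
            lab_unit=GFR_UNIT,
            gfr_low=31,
            gfr_high=130,
            adjusted_min_daily=500,
            adjusted_max_daily=500,
            dose_unit="mg",
            loading_dose=1000,
            loading_unit="mg",
            alert=alert(
                "renal-dalbavancin",
                "dalbavancin requires dose adjustment in renal failure",
                "loading dose 1000 mg, then 500 mg every 24 h",
                Severity.NOT_RECOMMENDED,
            ),
        )
    )

    mapping_rows = [
        ("ATORVA40", "atorvastatin 40 mg tablet", "drug", atorva.ref.iri),
        ("PARA500PO", "paracetamol 500 mg tablet", "drug", paracet_po.ref.iri),
        ("PARA1000IV", "paracetamol 1 g vial", "drug", paracet_iv.ref.iri),
        ("DALBA500", "dalbavancin 500 mg vial", "drug", dalba.ref.iri),
        ("PHENEL15", "phenelzine 15 mg tablet", "drug", phenelzine.ref.iri),
        ("CLOPER10", "cloperastine 10 mg tablet", "drug", cloperastine.ref.iri),
        ("OMEP20", "omeprazole 20 mg capsule", "drug", omeprazole.ref.iri),
        ("PANTO40", "pantoprazole 40 mg tablet", "drug", pantoprazole.ref.iri),
        ("PO", "oral", "route", oral.iri),
        ("IV", "intravenous", "route", parenteral.iri),
        ("MG", "milligram", "unit", unit_concept_ref("mg").iri),
        ("G", "gram", "unit", unit_concept_ref("g").iri),
        ("Q24H", "every 24 h", "frequency", frequency_concept_ref("every 24 h").iri),
        ("Q12H", "every 12 h", "frequency", frequency_concept_ref("every 12 h").iri),
        ("Q8H", "every 8 h", "frequency", frequency_concept_ref("every 8 h").iri),
        ("GFR-LOCAL", "glomerular filtration rate", "lab_test", GFR_CONCEPT.iri),
        ("PPI-ALRG", "proton pump inhibitor allergy", "allergen", ppi.iri),
        ("OMEP-ALRG", "omeprazole allergy", "allergen", ings["omeprazole"].iri),
    ]
    table = pd.DataFrame(
        mapping_rows, columns=["local_code", "local_label", "domain", "target_iri"]
    )
    ms = load_mappings(table, iri_exists=kb.has_iri)
    kb.mappings = ms.mappings
    kb.provenance = {"source": "fixture", "criteria": 4}
    errors = kb.validate()
    if errors:  # pragma: no cover - construction bug guard
        raise AssertionError("fixture kb invalid: " + "; ".join(errors))
    return kb


def fixture_mapping_set() -> MappingSet:
    return MappingSet(build_fixture_kb().mappings)


# --- synthetic cohorts ----------------------------------------------------------


@dataclass
class SynthesisConfig:
    """Study conditions for the synthetic cohort.

    Demographics loosely mirror an internal-medicine inpatient ward
    (median age about 69, a handful of concurrent medications); the
    violation rates control how many patients get one deliberate
    rule-tripping prescription per rule.
    """

    seed: int = 0
    n_patients: int = 50
    violation_rates: dict[str, float] = field(
        default_factory=lambda: {
            "max_dose": 0.2,
            "interaction": 0.15,
            "renal": 0.15,
            "allergy": 0.05,
        }
    )
    fillers_per_patient: float = 3.0  # Poisson mean of benign prescriptions
    fraction_prn: float = 0.2
    gfr_mean: float = 75.0
    gfr_sd: float = 25.0

    def __post_init__(self) -> None:
        for rule, rate in self.violation_rates.items():
            if rule not in RULES:
                raise ValueError(f"unknown rule in violation_rates: {rule!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"violation rate out of [0,1] for {rule}")


#: Benign prescription templates: each is safe alone and in any
#: combination the generator allows (guards below remove combinations
#: that could trip a criterion).
_FILLERS = [
    # (drug_code, dose, unit, frequency, route)
    ("ATORVA40", 40, "MG", "Q24H", "PO"),
    ("PARA500PO", 500, "MG", "Q8H", "PO"),  # 1500 mg/24 h, max 4000
    ("PARA1000IV", 1000, "MG", "Q12H", "IV"),  # 2000 mg/24 h
    ("OMEP20", 20, "MG", "Q24H", "PO"),
    ("PANTO40", 40, "MG", "Q24H", "PO"),
    ("PHENEL15", 15, "MG", "Q12H", "PO"),
    ("CLOPER10", 10, "MG", "Q8H", "PO"),
    ("DALBA500", 500, "MG", "Q24H", "IV"),  # equals adjusted max: passes
]


def _rx(
    rx_id: str, code: str, dose: float, unit: str, freq: str, route: str,
    day: int = 0, days: int = 7, prn: bool = False,
) -> Prescription:
    start = _EPOCH + timedelta(days=day)
    return Prescription(
        id=rx_id,
        drug_code=code,
        dose=dose,
        dose_unit=unit,
        frequency=freq,
        route=route,
        start=start,
        end=start + timedelta(days=days),
        prn=prn,
    )


def generate_cohort(
    config: SynthesisConfig, kb: Optional[CompiledKnowledgeBase] = None
) -> tuple[list[PatientRecord], dict[str, dict[str, int]]]:
    """Draw a synthetic cohort with controlled violation injection.

    Returns the patients plus ground-truth labels: for every patient, a
    mapping rule → expected alert count.  Each injected violation trips
    exactly one fixture criterion; filler prescriptions and labs are
    constructed so they can never fire an alert.
    """
    if kb is not None:
        have = {
            "max_dose": bool(kb.max_dose_criteria),
            "interaction": bool(kb.interaction_criteria),
            "renal": bool(kb.renal_criteria),
            "allergy": bool(kb.groups),
        }
        for rule, rate in config.violation_rates.items():
            if rate > 0 and not have.get(rule, False):
                raise ValueError(
                    f"violation rate for {rule!r} requested but the knowledge "
                    f"base has no criterion for it"
                )
    rng = np.random.default_rng(config.seed)
    patients: list[PatientRecord] = []
    labels: dict[str, dict[str, int]] = {}
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        age = int(np.clip(round(rng.normal(69, 14)), 18, 99))
        inject = {
            rule: bool(rng.random() < rate)
            for rule, rate in config.violation_rates.items()
        }
        benign_allergy = rng.random() < 0.1  # ingredient-level allergy, no rx

        rx_list: list[Prescription] = []
        allergies: list[str] = []
        counter = 0

        def next_id() -> str:
            nonlocal counter
            counter += 1
            return f"{pid}-R{counter}"

        # renal: dalbavancin 1000 mg/24 h with most recent GFR inside 31-130
        if inject.get("renal"):
            rx_list.append(_rx(next_id(), "DALBA500", 1000, "MG", "Q24H", "IV"))
            gfr = float(rng.uniform(35, 120))
        else:
            gfr = float(np.clip(rng.normal(config.gfr_mean, config.gfr_sd), 20, 180))
        if inject.get("max_dose"):
            rx_list.append(_rx(next_id(), "ATORVA40", 80, "MG", "Q12H", "PO"))
        if inject.get("interaction"):
            rx_list.append(_rx(next_id(), "PHENEL15", 15, "MG", "Q12H", "PO"))
            rx_list.append(_rx(next_id(), "CLOPER10", 10, "MG", "Q8H", "PO"))
        if inject.get("allergy"):
            allergies.append("PPI-ALRG")
            rx_list.append(_rx(next_id(), "OMEP20", 20, "MG", "Q24H", "PO"))

        banned = set()
        if inject.get("max_dose"):
            banned.add("ATORVA40")
        if inject.get("interaction"):
            banned.update({"PHENEL15", "CLOPER10"})
        else:
            # never both MAOI and antitussive as fillers
            banned.add("CLOPER10" if rng.random() < 0.5 else "PHENEL15")
        if inject.get("renal"):
            banned.add("DALBA500")
        elif gfr <= 130:
            # 500 mg/24 h equals the adjusted max: safe, but keep one only
            pass
        if inject.get("allergy") or benign_allergy:
            banned.update({"OMEP20", "PANTO40"})
        if benign_allergy and not inject.get("allergy"):
            allergies.append("OMEP-ALRG")
        # at most one acetaminophen product: the route-independent maximum
        # sums across routes and the two fillers together stay below it,
        # but keep the margin wide
        if rng.random() < 0.5:
            banned.add("PARA1000IV")
        else:
            banned.add("PARA500PO")

        pool = [f for f in _FILLERS if f[0] not in banned]
        n_fill = min(int(rng.poisson(config.fillers_per_patient)), len(pool))
        chosen = rng.choice(len(pool), size=n_fill, replace=False)
        for k in sorted(chosen):
            code, dose, unit, freq, route = pool[k]
            prn = bool(rng.random() < config.fraction_prn)
            rx_list.append(
                _rx(next_id(), code, dose, unit, freq, route, prn=prn)
            )

        labs = [
            LabResult(
                test_code="GFR-LOCAL",
                value=round(gfr, 1),
                unit=GFR_UNIT,
                taken_at=_EPOCH + timedelta(days=1),
            )
        ]
        if rng.random() < 0.3:  # an older, superseded GFR value
            labs.insert(
                0,
                LabResult(
                    test_code="GFR-LOCAL",
                    value=round(float(np.clip(gfr + rng.normal(0, 15), 15, 180)), 1),
                    unit=GFR_UNIT,
                    taken_at=_EPOCH - timedelta(days=3),
                ),
            )

        patients.append(
            PatientRecord(
                patient_id=pid,
                age_years=age,
                prescriptions=rx_list,
                labs=labs,
                allergies=allergies,
            )
        )
        labels[pid] = {rule: int(inject.get(rule, False)) for rule in RULES}
    return patients, labels


def synthetic_name_resolver(description: str) -> Optional[str]:
    """Resolve the synthetic tables' free-text drug descriptions.

    The generated renal descriptions look like ``"name (non-standardised
    text)"``; anything that does not parse resolves to None (unmapped).
    """
    name = description.split(" (")[0].strip()
    return name or None


# --- synthetic source tables ------------------------------------------------------


def generate_source_tables(
    config: SynthesisConfig, size: int = 20
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Fabricate the three source datasets plus the product index.

    ``size`` is the number of base (clean) max-dose rows; the other
    tables scale with it.  Planted features and their counts go into
    the manifest: duplicate national-drug-code rows that must collapse,
    combination-product and indication-dependent rows that must be
    excluded, reversed interaction pairs that must deduplicate, and
    dialysis-only plus multi-bracket renal entries.
    """
    if size <= 0:
        empty = {
            "max_dose": pd.DataFrame(
                columns=["code_type", "code", "description", "route",
                         "max_daily_dose", "dose_unit", "indication", "age_min",
                         "age_max", "gravity", "alert_description",
                         "recommendation", "bibliography", "dose_form"]
            ),
            "interactions": pd.DataFrame(
                columns=["code_type_a", "code_a", "description_a", "code_type_b",
                         "code_b", "description_b", "gravity",
                         "alert_description", "recommendation", "bibliography"]
            ),
            "renal": pd.DataFrame(
                columns=["drug_description", "route", "gfr_low", "gfr_high",
                         "dose_low", "dose_high", "interval_low_h",
                         "interval_high_h", "unit", "loading_dose",
                         "loading_unit", "dialysis_dosing", "gravity",
                         "alert_description", "recommendation", "bibliography"]
            ),
            "products": pd.DataFrame(
                columns=["code_type", "code", "ingredient", "route", "atc",
                         "dose_form"]
            ),
        }
        manifest = {
            "max_dose": {"total_rows": 0, "base_rows": 0, "planted_duplicates": 0,
                         "combination_rows": 0, "indication_rows": 0},
            "interactions": {"total_rows": 0, "unique_pairs": 0,
                             "planted_reversed_duplicates": 0, "unmapped_rows": 0},
            "renal": {"total_entries": 0, "dialysis_only_entries": 0,
                      "multi_bracket_entries": 0, "total_brackets": 0},
        }
        return empty, manifest
    rng = np.random.default_rng(config.seed + 1)
    ingredients = [f"ingr{k:03d}" for k in range(max(size, 4))]
    routes = ["oral", "parenteral"]
    gravities = ["not_recommended", "contraindicated", "not_allowed"]

    index_rows: list[dict] = []
    code_counter = 0

    def new_code(ingredient_names: list[str], route: str, atc: Optional[str]) -> str:
        nonlocal code_counter
        code_counter += 1
        code = f"NDC{code_counter:05d}"
        index_rows.append(
            {
                "code_type": "national_drug_code",
                "code": code,
                "ingredient": "+".join(ingredient_names),
                "route": route,
                "atc": atc or "",
                "dose_form": "",
            }
        )
        return code

    max_rows: list[dict] = []

    def md_row(code: str, ingredient: str, route: str, dose: float, **kw) -> None:
        max_rows.append(
            {
                "code_type": "national_drug_code",
                "code": code,
                "description": ingredient,
                "route": route,
                "max_daily_dose": dose,
                "dose_unit": "mg",
                "indication": kw.get("indication", ""),
                "age_min": 18,
                "age_max": 99,
                "gravity": kw.get("gravity", "not_recommended"),
                "alert_description": f"maximum daily dose of {ingredient}",
                "recommendation": "reduce the dose",
                "bibliography": "synthetic",
                "dose_form": kw.get("dose_form", ""),
            }
        )

    n_dup = max(size // 5, 1)  # extra clinically-equivalent rows
    n_comb = max(size // 10, 1)
    n_ind = max(size // 10, 1)
    used = list(range(size))
    for k in used:
        ingredient = ingredients[k]
        route = routes[int(rng.integers(2))]
        dose = float(rng.choice([100, 200, 500, 1000, 2000]))
        gravity = gravities[int(rng.integers(3))]
        code = new_code([ingredient], route, None)
        md_row(code, ingredient, route, dose, gravity=gravity)
        max_rows[-1]["_base"] = True
    base_rows = [dict(r) for r in max_rows]
    for j in range(n_dup):  # same ingredient/route/dose, new product code
        src = base_rows[int(rng.integers(len(base_rows)))]
        code = new_code([src["description"]], src["route"], None)
        md_row(
            code, src["description"], src["route"], src["max_daily_dose"],
            gravity=src["gravity"],
        )
    for j in range(n_comb):
        a, b = rng.choice(len(ingredients), size=2, replace=False)
        code = new_code([ingredients[a], ingredients[b]], "oral", None)
        md_row(code, f"{ingredients[a]}/{ingredients[b]}", "oral", 2625)
    for j in range(n_ind):
        ingredient = f"ind-only-{j}"
        code = new_code([ingredient], "oral", None)
        md_row(code, ingredient, "oral", 300, indication="analgesic")
    for row in max_rows:
        row.pop("_base", None)
    max_df = pd.DataFrame(max_rows)

    # interactions: clean pairs + reversed duplicates + one unmapped code
    letters = "ABCDGJLMNPRSV"
    atc_pool = []
    while len(atc_pool) < max(size, 6):
        code = (
            letters[int(rng.integers(len(letters)))]
            + f"{int(rng.integers(1, 17)):02d}"
            + "ABCDEX"[int(rng.integers(6))]
            + "ABCDEX"[int(rng.integers(6))]
            + f"{int(rng.integers(1, 100)):02d}"
        )
        if code not in atc_pool:
            atc_pool.append(code)
    int_rows: list[dict] = []

    def ix_row(ta, a, tb, b, gravity="contraindicated") -> None:
        int_rows.append(
            {
                "code_type_a": ta,
                "code_a": a,
                "description_a": a,
                "code_type_b": tb,
                "code_b": b,
                "description_b": b,
                "gravity": gravity,
                "alert_description": f"interaction {a} x {b}",
                "recommendation": "review the combination",
                "bibliography": "synthetic",
            }
        )

    n_pairs = max(size // 2, 3)
    pairs = []
    while len(pairs) < n_pairs:
        a, b = rng.choice(len(atc_pool), size=2, replace=False)
        pair = tuple(sorted((atc_pool[a], atc_pool[b])))
        if pair not in pairs:
            pairs.append(pair)
    for a, b in pairs:
        ix_row("ATC", a, "ATC", b)
    n_rev = max(n_pairs // 3, 1)  # reversed duplicates of existing pairs
    for a, b in pairs[:n_rev]:
        ix_row("ATC", b, "ATC", a)
    n_unmapped = 1
    ix_row("national_drug_code", "NO-SUCH-CODE", "ATC", atc_pool[0])

    int_df = pd.DataFrame(int_rows)

    # renal: entries with 1-2 brackets + dialysis-only rows
    renal_rows: list[dict] = []
    n_renal = max(size // 3, 2)
    n_dialysis = max(size // 10, 1)
    n_multi = max(n_renal // 3, 1)
    renal_names = [f"renal-drug-{k}" for k in range(n_renal)]
    for k, name in enumerate(renal_names):
        brackets = (
            [(10.0, 30.0), (31.0, 130.0)] if k < n_multi else [(31.0, 130.0)]
        )
        for lo, hi in brackets:
            dose_low = float(rng.choice([250, 500, 1000]))
            dose_high = dose_low * float(rng.choice([1, 2, 4]))
            renal_rows.append(
                {
                    "drug_description": f"{name} (non-standardised text)",
                    "route": "parenteral",
                    "gfr_low": lo,
                    "gfr_high": hi,
                    "dose_low": dose_low,
                    "dose_high": dose_high,
                    "interval_low_h": 8.0,
                    "interval_high_h": 12.0,
                    "unit": "mg",
                    "loading_dose": "",
                    "loading_unit": "",
                    "dialysis_dosing": "",
                    "gravity": "not_recommended",
                    "alert_description": f"adjust {name} in renal failure",
                    "recommendation": "",
                    "bibliography": "synthetic",
                }
            )
    for k in range(n_dialysis):
        renal_rows.append(
            {
                "drug_description": f"dialysis-only-drug-{k}",
                "route": "parenteral",
                "gfr_low": "",
                "gfr_high": "",
                "dose_low": "",
                "dose_high": "",
                "interval_low_h": "",
                "interval_high_h": "",
                "unit": "mg",
                "loading_dose": "",
                "loading_unit": "",
                "dialysis_dosing": "500 mg after each session",
                "gravity": "not_recommended",
                "alert_description": "",
                "recommendation": "",
                "bibliography": "synthetic",
            }
        )
    renal_df = pd.DataFrame(renal_rows)
    index_df = pd.DataFrame(
        index_rows, columns=["code_type", "code", "ingredient", "route", "atc",
                             "dose_form"]
    )

    manifest = {
        "max_dose": {
            "total_rows": len(max_df),
            "base_rows": size,
            "planted_duplicates": n_dup,
            "combination_rows": n_comb,
            "indication_rows": n_ind,
        },
        "interactions": {
            "total_rows": len(int_df),
            "unique_pairs": n_pairs,
            "planted_reversed_duplicates": n_rev,
            "unmapped_rows": n_unmapped,
        },
        "renal": {
            "total_entries": n_renal + n_dialysis,
            "dialysis_only_entries": n_dialysis,
            "multi_bracket_entries": n_multi,
            "total_brackets": n_renal + n_multi,
        },
    }
    tables = {
        "max_dose": max_df,
        "interactions": int_df,
        "renal": renal_df,
        "products": index_df,
    }
    return tables, manifest
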