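"""Compile tabular drug-safety sources into knowledge-base criteria.

Three source datasets feed the assertional knowledge:

* a **maximum daily dose** table (one row per product code);
* a **drug–drug interaction** pair table;
* a **renal dosing** table for antimicrobials, with dosing per
  creatinine-clearance bracket.

Compilation abstracts product-level rows up to the (ingredient, route)
level, deduplicating clinically equivalent rows, and applies the
curated exclusion rules: indication-dependent doses, combination
products, form-dependent doses, dialysis-only rows and unmappable codes
are not represented, and rows at the lowest source gravity are dropped
to limit alert fatigue.  Every input row is accounted for: compiled +
excluded = total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import pandas as pd

from .model import (
    AlertKnowledge,
    ConceptRef,
    InteractionCriterion,
    MaxDoseCriterion,
    GFR_CONCEPT,
    RenalAdjustmentCriterion,
    SEVERITY_RANK,
    Severity,
    ingredient_ref,
    make_iri,
    route_ref,
    slugify,
    validate_atc,
)

#: Exclusion reason vocabulary.  ``low_severity`` holds rows at the
#: sources' lowest gravity ("to take into account"), dropped at compile
#: time so they never generate alerts.
EXCLUSION_REASONS = (
    "indication_dependent",
    "combination_product",
    "form_dependent",
    "dialysis_only",
    "unmapped_code",
    "low_severity",
)

#: Source gravity labels mapped to retained alert levels; the lowest
#: level is absent on purpose (see ``low_severity``).
GRAVITY_LEVELS = {
    "not_recommended": Severity.NOT_RECOMMENDED,
    "contraindicated": Severity.CONTRAINDICATED,
    "not_allowed": Severity.NOT_ALLOWED,
}
LOW_GRAVITY = "to_take_into_account"


class CompileError(ValueError):
    """Curation failure in the source data (conflicts, invalid rows)."""


# --- source entry types -----------------------------------------------------


@dataclass
class MaxDoseSourceEntry:
    code_type: str  # 'ATC' | 'national_drug_code' | 'snomed'
    code: str
    description: str
    route: str
    max_daily_dose: float
    dose_unit: str
    gravity: str
    indication: Optional[str] = None
    age_min: int = 18
    age_max: int = 99
    alert_description: str = ""
    recommendation: str = ""
    bibliography: str = ""
    dose_form: Optional[str] = None

    def __post_init__(self) -> None:
        if self.max_daily_dose <= 0:
            raise ValueError("max_daily_dose must be positive")
        if self.age_min > self.age_max:
            raise ValueError("age range min must be <= max")


@dataclass
class InteractionSourceEntry:
    code_type_a: str
    code_a: str
    code_type_b: str
    code_b: str
    gravity: str
    description_a: str = ""
    description_b: str = ""
    route_a: str = ""
    route_b: str = ""
    alert_description: str = ""
    recommendation: str = ""
    bibliography: str = ""


@dataclass
class ClearanceBracket:
    gfr_low: float
    gfr_high: float
    dose_low: float
    dose_high: float
    interval_low_h: float
    interval_high_h: float
    unit: str = "mg"
    loading_dose: Optional[float] = None
    loading_unit: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.gfr_low < self.gfr_high:
            raise ValueError("gfr_low must be < gfr_high")
        if self.dose_low > self.dose_high:
            raise ValueError("dose_low must be <= dose_high")
        if self.interval_low_h > self.interval_high_h:
            raise ValueError("interval_low_h must be <= interval_high_h")


@dataclass
class RenalSourceEntry:
    drug_description: str  # free text, non-standardised
    route: str
    dosing_by_clearance: list[ClearanceBracket] = field(default_factory=list)
    dialysis_dosing: Optional[str] = None
    gravity: str = "not_recommended"
    alert_description: str = ""
    recommendation: str = ""
    bibliography: str = ""


@dataclass
class ProductInfo:
    ingredients: tuple[str, ...]  # ingredient names
    route: Optional[str] = None
    atc: Optional[str] = None
    dose_form: Optional[str] = None


class ProductIndex:
    """Resolves source codes to ingredient(s), route and ATC."""

    def __init__(self) -> None:
        self._by_code: dict[tuple[str, str], ProductInfo] = {}

    def add(self, code_type: str, code: str, info: ProductInfo) -> None:
        self._by_code[(code_type, code)] = info

    def lookup(self, code_type: str, code: str) -> Optional[ProductInfo]:
        return self._by_code.get((code_type, code))

    def atc_for(self, code_type: str, code: str) -> Optional[str]:
        if code_type == "ATC":
            try:
                return validate_atc(code)
            except ValueError:
                return None
        info = self.lookup(code_type, code)
        return info.atc if info else None

    @classmethod
    def from_csv(cls, path) -> "ProductIndex":
        df = pd.read_csv(path, dtype=str).fillna("")
        idx = cls()
        for row in df.itertuples(index=False):
            ingredients = tuple(
                s.strip() for s in str(row.ingredient).split("+") if s.strip()
            )
            idx.add(
                row.code_type,
                row.code,
                ProductInfo(
                    ingredients=ingredients,
                    route=row.route or None,
                    atc=row.atc or None,
                    dose_form=getattr(row, "dose_form", "") or None,
                ),
            )
        return idx


@dataclass
class ExclusionReport:
    """Rows not represented in the knowledge base, with the reason why."""

    total: int = 0
    compiled: int = 0
    excluded: list[tuple[object, str]] = field(default_factory=list)

    def exclude(self, entry, reason: str) -> None:
        if reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason: {reason!r}")
        self.excluded.append((entry, reason))

    @property
    def counts(self) -> dict[str, int]:
        out = {r: 0 for r in EXCLUSION_REASONS}
        for _, reason in self.excluded:
            out[reason] += 1
        return {r: n for r, n in out.items() if n}

    def check_conservation(self) -> None:
        if self.compiled + len(self.excluded) != self.total:
            raise CompileError(
                f"conservation violated: {self.compiled} compiled + "
                f"{len(self.excluded)} excluded != {self.total} total"
            )


# --- alert construction -----------------------------------------------------

_alert_counter = 0


def _make_alert(
    description: str,
    recommendation: str,
    gravity: str,
    source: str,
    key: str,
) -> AlertKnowledge:
    level = GRAVITY_LEVELS[gravity]
    ref = ConceptRef(make_iri("dss", "alert", key), f"alert {slugify(key)}")
    return AlertKnowledge(
        ref=ref,
        description=description or key,
        recommendation=recommendation,
        source=source,
        level=level,
    )


# --- maximum daily dose ------------------------------------------------------


def collapse_max_dose(
    entries: Sequence[MaxDoseSourceEntry],
    product_index: ProductIndex,
) -> tuple[list[MaxDoseCriterion], ExclusionReport]:
    """Collapse product-level max-dose rows into (ingredient, route) criteria.

    Rows of clinically equivalent products (same ingredient, route, age
    range and dose) merge into one criterion.  Exclusions: indication-
    dependent doses, combination products, form-dependent doses,
    unmappable codes and lowest-gravity rows.  Disagreeing doses for the
    same (ingredient, route, age range) without a form distinction are a
    curation conflict and raise :class:`CompileError`.
    """
    report = ExclusionReport(total=len(entries))
    resolved: list[tuple[MaxDoseSourceEntry, str, str]] = []
    for e in entries:
        if e.gravity == LOW_GRAVITY:
            report.exclude(e, "low_severity")
            continue
        if e.gravity not in GRAVITY_LEVELS:
            raise CompileError(f"unknown gravity {e.gravity!r} for code {e.code}")
        if e.indication:
            report.exclude(e, "indication_dependent")
            continue
        if e.code_type == "ATC":
            info = product_index.lookup("ATC", e.code)
        else:
            info = product_index.lookup(e.code_type, e.code)
        if info is None or not info.ingredients:
            report.exclude(e, "unmapped_code")
            continue
        if len(info.ingredients) > 1:
            report.exclude(e, "combination_product")
            continue
        route = e.route or info.route or "any"
        resolved.append((e, info.ingredients[0], route))

    groups: dict[tuple[str, str, int, int], list[tuple[MaxDoseSourceEntry, str]]] = {}
    for e, ingredient, route in resolved:
        key = (ingredient, route.lower(), e.age_min, e.age_max)
        groups.setdefault(key, []).append((e, ingredient))

    criteria: list[MaxDoseCriterion] = []
    for (ingredient, route, age_min, age_max), members in sorted(groups.items()):
        doses = {(e.max_daily_dose, e.dose_unit) for e, _ in members}
        if len(doses) > 1:
            forms = {e.dose_form for e, _ in members}
            if len(forms) > 1 and None not in forms:
                # dose depends on the pharmaceutical form: not represented
                for e, _ in members:
                    report.exclude(e, "form_dependent")
                continue
            raise CompileError(
                f"conflicting maximum doses for ({ingredient}, {route}, "
                f"{age_min}-{age_max}): {sorted(doses)}"
            )
        first = max(members, key=lambda m: SEVERITY_RANK[GRAVITY_LEVELS[m[0].gravity]])[0]
        slug = f"{ingredient}-{route}-{age_min}-{age_max}"
        alert = _make_alert(
            first.alert_description,
            first.recommendation,
            first.gravity,
            first.bibliography,
            f"maxdose-{slug}",
        )
        criteria.append(
            MaxDoseCriterion(
                ref=ConceptRef(
                    make_iri("dss", "maxdose", slug), f"max dose {ingredient} {route}"
                ),
                ingredient=ingredient_ref(ingredient),
                route=route_ref(route),
                max_daily_dose=first.max_daily_dose,
                dose_unit=first.dose_unit,
                age_min=age_min,
                age_max=age_max,
                alert=alert,
            )
        )
        report.compiled += len(members)
    # overlapping (but unequal) age ranges for one (ingredient, route) are
    # ambiguous knowledge and refused
    by_pair: dict[tuple[str, str], list[MaxDoseCriterion]] = {}
    for c in criteria:
        by_pair.setdefault((c.ingredient.iri, c.route.iri), []).append(c)
    for pair, crits in by_pair.items():
        spans = sorted((c.age_min, c.age_max) for c in crits)
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise CompileError(
                    f"overlapping age ranges for max-dose criteria on {pair}"
                )
    report.check_conservation()
    return criteria, report


# --- drug-drug interactions ---------------------------------------------------


def compile_interactions(
    entries: Sequence[InteractionSourceEntry],
    product_index: Optional[ProductIndex] = None,
) -> tuple[list[InteractionCriterion], ExclusionReport]:
    """Normalise interaction pairs to ATC and deduplicate them.

    Pairs are unordered; pairs identical after ATC normalisation merge
    into one criterion keeping the most severe alert.  A finer pair
    subsumed by a coarser pair carrying an identical alert is dropped.
    Codes that cannot be normalised to ATC are excluded
    (``unmapped_code``); a pair whose two sides coincide after
    normalisation is a curation error.
    """
    index = product_index or ProductIndex()
    report = ExclusionReport(total=len(entries))
    by_pair: dict[tuple[str, str], list[InteractionSourceEntry]] = {}
    for e in entries:
        if e.gravity == LOW_GRAVITY:
            report.exclude(e, "low_severity")
            continue
        if e.gravity not in GRAVITY_LEVELS:
            raise CompileError(f"unknown gravity {e.gravity!r}")
        atc_a = index.atc_for(e.code_type_a, e.code_a)
        atc_b = index.atc_for(e.code_type_b, e.code_b)
        if atc_a is None or atc_b is None:
            report.exclude(e, "unmapped_code")
            continue
        if atc_a == atc_b:
            raise CompileError(
                f"self-interaction after ATC normalisation: {atc_a}"
            )
        pair = tuple(sorted((atc_a, atc_b)))
        by_pair.setdefault(pair, []).append(e)
        report.compiled += 1

    criteria: list[InteractionCriterion] = []
    for pair, members in sorted(by_pair.items()):
        best = max(members, key=lambda m: SEVERITY_RANK[GRAVITY_LEVELS[m.gravity]])
        slug = f"{pair[0]}-{pair[1]}"
        alert = _make_alert(
            best.alert_description,
            best.recommendation,
            best.gravity,
            best.bibliography,
            f"interaction-{slug}",
        )
        criteria.append(
            InteractionCriterion(
                ref=ConceptRef(
                    make_iri("dss", "interaction", slug),
                    f"interaction {pair[0]} x {pair[1]}",
                ),
                atc_a=pair[0],
                atc_b=pair[1],
                alert=alert,
            )
        )

    # drop pairs subsumed by a coarser pair with an identical alert
    def _subsumed(fine: InteractionCriterion, coarse: InteractionCriterion) -> bool:
        if fine is coarse or fine.alert is None or coarse.alert is None:
            return False
        if (fine.alert.level, fine.alert.description) != (
            coarse.alert.level,
            coarse.alert.description,
        ):
            return False
        a, b = fine.pair
        ca, cb = coarse.pair
        direct = a.startswith(ca) and b.startswith(cb)
        crossed = a.startswith(cb) and b.startswith(ca)
        return (direct or crossed) and fine.pair != coarse.pair

    kept = [
        c for c in criteria if not any(_subsumed(c, other) for other in criteria)
    ]
    report.check_conservation()
    return kept, report


# --- renal adjustment ----------------------------------------------------------


def simplify_renal_range(
    dose_low: float,
    dose_high: float,
    interval_low_h: float,
    interval_high_h: float,
) -> tuple[float, float]:
    """Collapse a dose/interval recommendation to one daily-dose range.

    A recommendation "dose_low–dose_high every interval_low–interval_high
    hours" is normalised to a 24 h base: the daily minimum pairs the
    lowest dose with the *longest* interval, the daily maximum the
    highest dose with the *shortest* interval.  E.g. 500–2000 mg every
    8–12 h becomes 1000–6000 mg per 24 h.
    """
    if dose_low <= 0 or dose_high <= 0:
        raise ValueError("doses must be positive")
    if not 0 < interval_low_h <= interval_high_h <= 24 * 7:
        raise ValueError("intervals must satisfy 0 < low <= high <= 168 h")
    if dose_low > dose_high:
        raise ValueError("dose_low must be <= dose_high")
    daily_min = dose_low * 24.0 / interval_high_h
    daily_max = dose_high * 24.0 / interval_low_h
    return daily_min, daily_max


def compile_renal(
    entries: Sequence[RenalSourceEntry],
    name_resolver: Callable[[str], Optional[str]],
) -> tuple[list[RenalAdjustmentCriterion], ExclusionReport]:
    """Compile renal-dosing entries into per-bracket criteria.

    ``name_resolver`` maps the free-text drug description to a canonical
    ingredient name (the descriptions are not standardised).  Each
    clearance bracket becomes one criterion with a simplified daily
    range; dialysis-only entries are excluded (dialysis modality is not
    a structured field in the evaluation request), unresolvable
    descriptions are excluded as ``unmapped_code``.  Overlapping GFR
    brackets for one (ingredient, route) are refused.
    """
    report = ExclusionReport(total=len(entries))
    criteria: list[RenalAdjustmentCriterion] = []
    brackets_seen: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for e in entries:
        if not e.dosing_by_clearance:
            if e.dialysis_dosing:
                report.exclude(e, "dialysis_only")
                continue
            report.exclude(e, "unmapped_code")
            continue
        ingredient = name_resolver(e.drug_description)
        if ingredient is None:
            report.exclude(e, "unmapped_code")
            continue
        gravity = e.gravity
        if gravity == LOW_GRAVITY:
            report.exclude(e, "low_severity")
            continue
        key = (ingredient, e.route.lower())
        for i, br in enumerate(e.dosing_by_clearance):
            for lo, hi in brackets_seen.get(key, []):
                if br.gfr_low <= hi and lo <= br.gfr_high:
                    raise CompileError(
                        f"overlapping GFR brackets for {key}: "
                        f"[{br.gfr_low}, {br.gfr_high}] vs [{lo}, {hi}]"
                    )
            brackets_seen.setdefault(key, []).append((br.gfr_low, br.gfr_high))
            daily_min, daily_max = simplify_renal_range(
                br.dose_low, br.dose_high, br.interval_low_h, br.interval_high_h
            )
            loading_daily = None
            if br.loading_dose is not None:
                loading_daily = br.loading_dose
            slug = f"{ingredient}-{e.route}-gfr-{br.gfr_low:g}-{br.gfr_high:g}"
            alert = _make_alert(
                e.alert_description
                or f"dose adjustment required for {ingredient} in renal failure",
                e.recommendation
                or (
                    f"adjusted dose {daily_min:g}-{daily_max:g} {br.unit}/24 h "
                    f"for GFR {br.gfr_low:g}-{br.gfr_high:g}"
                ),
                gravity,
                e.bibliography,
                f"renal-{slug}",
            )
            criteria.append(
                RenalAdjustmentCriterion(
                    ref=ConceptRef(
                        make_iri("dss", "renal", slug),
                        f"renal adjustment {ingredient} {e.route}",
                    ),
                    ingredient=ingredient_ref(ingredient),
                    route=route_ref(e.route),
                    lab_test=GFR_CONCEPT,
                    gfr_low=br.gfr_low,
                    gfr_high=br.gfr_high,
                    adjusted_min_daily=daily_min,
                    adjusted_max_daily=daily_max,
                    dose_unit=br.unit,
                    loading_dose=loading_daily,
                    loading_unit=br.loading_unit or br.unit,
                    alert=alert,
                )
            )
        report.compiled += 1
    report.check_conservation()
    return criteria, report


# --- statistics ----------------------------------------------------------------


def compression_stats(
    datasets: dict[str, tuple[int, int]]
) -> dict[str, dict[str, object]]:
    """Per-dataset compression: input rows vs compiled individuals.

    ``datasets`` maps a dataset name to (input_entries,
    output_individuals).  The ratio is output/input, or None for an
    empty dataset.  Max-dose and interaction compilation only ever
    collapses rows (ratio <= 1); renal compilation can expand, since
    each clearance bracket of an entry becomes its own individual.
    """
    out: dict[str, dict[str, object]] = {}
    for name, (n_in, n_out) in datasets.items():
        out[name] = {
            "input_entries": n_in,
            "output_individuals": n_out,
            "ratio": (n_out / n_in) if n_in else None,
        }
    return out


# --- CSV readers -----------------------------------------------------------------


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def read_max_dose_csv(path) -> list[MaxDoseSourceEntry]:
    df = pd.read_csv(path)
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            MaxDoseSourceEntry(
                code_type=row.code_type,
                code=str(row.code),
                description=_opt(row.description) or "",
                route=_opt(row.route) or "",
                max_daily_dose=float(row.max_daily_dose),
                dose_unit=row.dose_unit,
                indication=_opt(row.indication),
                age_min=int(row.age_min),
                age_max=int(row.age_max),
                gravity=row.gravity,
                alert_description=_opt(row.alert_description) or "",
                recommendation=_opt(row.recommendation) or "",
                bibliography=_opt(row.bibliography) or "",
                dose_form=_opt(getattr(row, "dose_form", None)),
            )
        )
    return entries


def read_interactions_csv(path) -> list[InteractionSourceEntry]:
    df = pd.read_csv(path)
    return [
        InteractionSourceEntry(
            code_type_a=row.code_type_a,
            code_a=str(row.code_a),
            code_type_b=row.code_type_b,
            code_b=str(row.code_b),
            gravity=row.gravity,
            description_a=_opt(row.description_a) or "",
            description_b=_opt(row.description_b) or "",
            alert_description=_opt(row.alert_description) or "",
            recommendation=_opt(row.recommendation) or "",
            bibliography=_opt(row.bibliography) or "",
        )
        for row in df.itertuples(index=False)
    ]


def read_renal_csv(path) -> list[RenalSourceEntry]:
    """Read the renal CSV (one row per clearance bracket).

    Consecutive rows sharing (drug_description, route) are grouped into
    one entry with a bracket list; a row with empty bracket fields but a
    dialysis_dosing value is a dialysis-only entry.
    """
    df = pd.read_csv(path)
    entries: list[RenalSourceEntry] = []
    current: Optional[RenalSourceEntry] = None
    for row in df.itertuples(index=False):
        key = (row.drug_description, row.route)
        if current is None or (current.drug_description, current.route) != key:
            current = RenalSourceEntry(
                drug_description=row.drug_description,
                route=row.route,
                dialysis_dosing=_opt(row.dialysis_dosing),
                gravity=getattr(row, "gravity", "not_recommended"),
                alert_description=_opt(getattr(row, "alert_description", None)) or "",
                recommendation=_opt(getattr(row, "recommendation", None)) or "",
                bibliography=_opt(getattr(row, "bibliography", None)) or "",
            )
            entries.append(current)
        if _opt(row.gfr_low) is not None:
            loading = _opt(getattr(row, "loading_dose", None))
            current.dosing_by_clearance.append(
                ClearanceBracket(
                    gfr_low=float(row.gfr_low),
                    gfr_high=float(row.gfr_high),
                    dose_low=float(row.dose_low),
                    dose_high=float(row.dose_high),
                    interval_low_h=float(row.interval_low_h),
                    interval_high_h=float(row.interval_high_h),
                    unit=row.unit,
                    loading_dose=float(loading) if loading else None,
                    loading_unit=_opt(getattr(row, "loading_unit", None)),
                )
            )
    return entries
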