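import pytest
from hypothesis import given, strategies as st

from ontorx.compiler import (
    CompileError,
    ClearanceBracket,
    InteractionSourceEntry,
    MaxDoseSourceEntry,
    ProductIndex,
    ProductInfo,
    RenalSourceEntry,
    collapse_max_dose,
    compile_interactions,
    compile_renal,
    compression_stats,
    simplify_renal_range,
)
from ontorx.model import ANY_ROUTE, Severity


def make_index(**codes) -> ProductIndex:
    idx = ProductIndex()
    for code, spec in codes.items():
        idx.add("national_drug_code", code, ProductInfo(**spec))
    return idx


def md_entry(code, route="oral", dose=500.0, **kw) -> MaxDoseSourceEntry:
    return MaxDoseSourceEntry(
        code_type=kw.pop("code_type", "national_drug_code"),
        code=code,
        description=code,
        route=route,
        max_daily_dose=dose,
        dose_unit=kw.pop("dose_unit", "mg"),
        gravity=kw.pop("gravity", "not_recommended"),
        **kw,
    )


# --- max dose -----------------------------------------------------------------


def test_equivalent_products_collapse_to_one_criterion():
    """Three clinically equivalent product codes yield one criterion."""
    idx = make_index(
        A={"ingredients": ("amoxicillin",), "route": "oral"},
        B={"ingredients": ("amoxicillin",), "route": "oral"},
        C={"ingredients": ("amoxicillin",), "route": "oral"},
    )
    entries = [md_entry(c, dose=6000) for c in "ABC"]
    criteria, report = collapse_max_dose(entries, idx)
    assert len(criteria) == 1
    assert criteria[0].max_daily_dose == 6000
    assert report.compiled == 3 and not report.excluded


def test_combination_product_is_excluded():
    idx = make_index(
        AMOX={"ingredients": ("amoxicillin",), "route": "oral"},
        AMOXCLAV={"ingredients": ("amoxicillin", "clavulanic acid"), "route": "oral"},
    )
    entries = [md_entry("AMOX", dose=6000), md_entry("AMOXCLAV", dose=2625)]
    criteria, report = collapse_max_dose(entries, idx)
    assert len(criteria) == 1
    assert report.counts == {"combination_product": 1}


def test_indication_dependent_and_unmapped_and_low_severity_exclusions():
    idx = make_index(ASA={"ingredients": ("acetylsalicylic acid",), "route": "oral"})
    entries = [
        md_entry("ASA", dose=4000, indication="analgesic"),
        md_entry("NOPE", dose=100),
        md_entry("ASA", dose=4000, gravity="to_take_into_account"),
    ]
    criteria, report = collapse_max_dose(entries, idx)
    assert criteria == []
    assert report.counts == {
        "indication_dependent": 1,
        "unmapped_code": 1,
        "low_severity": 1,
    }
    assert report.compiled + len(report.excluded) == report.total == 3


def test_form_dependent_doses_are_excluded():
    """Same route, different forms with different maxima -> not represented."""
    idx = make_index(
        TAB={"ingredients": ("hydroxycarbamide",), "route": "oral"},
        CAP={"ingredients": ("hydroxycarbamide",), "route": "oral"},
    )
    entries = [
        md_entry("TAB", dose=4200, dose_form="tablet"),
        md_entry("CAP", dose=9600, dose_form="capsule"),
    ]
    criteria, report = collapse_max_dose(entries, idx)
    assert criteria == []
    assert report.counts == {"form_dependent": 2}


def test_conflicting_doses_without_form_distinction_raise():
    idx = make_index(
        A={"ingredients": ("drugx",), "route": "oral"},
        B={"ingredients": ("drugx",), "route": "oral"},
    )
    with pytest.raises(CompileError, match="conflicting"):
        collapse_max_dose([md_entry("A", dose=100), md_entry("B", dose=200)], idx)


def test_overlapping_age_ranges_raise():
    idx = make_index(A={"ingredients": ("drugx",), "route": "oral"})
    entries = [
        md_entry("A", dose=100, age_min=18, age_max=65),
        md_entry("A", dose=200, age_min=60, age_max=99),
    ]
    with pytest.raises(CompileError, match="age ranges"):
        collapse_max_dose(entries, idx)


def test_disjoint_age_ranges_allowed():
    idx = make_index(A={"ingredients": ("drugx",), "route": "oral"})
    entries = [
        md_entry("A", dose=100, age_min=18, age_max=64),
        md_entry("A", dose=50, age_min=65, age_max=99),
    ]
    criteria, _ = collapse_max_dose(entries, idx)
    assert len(criteria) == 2


def test_any_route_token_becomes_any_route_criterion():
    idx = make_index(A={"ingredients": ("acetaminophen",), "route": "any"})
    criteria, _ = collapse_max_dose([md_entry("A", route="any", dose=4000)], idx)
    assert criteria[0].route.iri == ANY_ROUTE.iri


def test_empty_input_yields_empty_output():
    criteria, report = collapse_max_dose([], ProductIndex())
    assert criteria == [] and report.total == 0 and report.excluded == []


def test_merged_duplicates_keep_most_severe_alert():
    idx = make_index(
        A={"ingredients": ("drugx",), "route": "oral"},
        B={"ingredients": ("drugx",), "route": "oral"},
    )
    entries = [
        md_entry("A", dose=100, gravity="not_recommended"),
        md_entry("B", dose=100, gravity="not_allowed"),
    ]
    criteria, _ = collapse_max_dose(entries, idx)
    assert criteria[0].alert.level == Severity.NOT_ALLOWED


# --- interactions ----------------------------------------------------------------


def ix_entry(a, b, gravity="contraindicated", ta="ATC", tb="ATC", desc=""):
    return InteractionSourceEntry(
        code_type_a=ta, code_a=a, code_type_b=tb, code_b=b,
        gravity=gravity, alert_description=desc,
    )


def test_reversed_pairs_deduplicate():
    criteria, report = compile_interactions(
        [ix_entry("A01AA01", "B01AA02"), ix_entry("B01AA02", "A01AA01")]
    )
    assert len(criteria) == 1
    assert criteria[0].pair == ("A01AA01", "B01AA02")
    assert report.compiled == 2


def test_product_level_pairs_merge_via_atc_normalisation():
    idx = ProductIndex()
    idx.add("national_drug_code", "P1", ProductInfo(("moclobemide",), atc="N06AF"))
    idx.add("national_drug_code", "P2", ProductInfo(("cough",), atc="R05FB02"))
    entries = [
        ix_entry("P1", "P2", ta="national_drug_code", tb="national_drug_code"),
        ix_entry("N06AF", "R05FB02"),
    ]
    criteria, _ = compile_interactions(entries, idx)
    assert len(criteria) == 1
    assert criteria[0].pair == ("N06AF", "R05FB02")


def test_distinct_pairs_stay_distinct():
    entries = [
        ix_entry("A01AA01", "B01AA02"),
        ix_entry("A01AA01", "C01AA05"),
        ix_entry("B01AA02", "C01AA05"),
        ix_entry("D01AA01", "J01XA04"),
    ]
    criteria, _ = compile_interactions(entries)
    assert len(criteria) == 4


def test_duplicate_pairs_keep_most_severe_alert():
    criteria, _ = compile_interactions(
        [
            ix_entry("A01AA01", "B01AA02", gravity="not_recommended"),
            ix_entry("B01AA02", "A01AA01", gravity="not_allowed"),
        ]
    )
    assert criteria[0].alert.level == Severity.NOT_ALLOWED


def test_subsumed_finer_pair_with_identical_alert_is_dropped():
    entries = [
        ix_entry("N06AF", "R05FB02", desc="same warning"),
        ix_entry("N06AF03", "R05FB02", desc="same warning"),
    ]
    criteria, _ = compile_interactions(entries)
    assert [c.pair for c in criteria] == [("N06AF", "R05FB02")]


def test_subsumed_pair_with_different_alert_is_kept():
    entries = [
        ix_entry("N06AF", "R05FB02", desc="class warning"),
        ix_entry("N06AF03", "R05FB02", desc="specific warning",
                 gravity="not_allowed"),
    ]
    criteria, _ = compile_interactions(entries)
    assert len(criteria) == 2


def test_unmapped_interaction_code_is_excluded():
    criteria, report = compile_interactions(
        [ix_entry("NOCODE", "B01AA02", ta="national_drug_code")]
    )
    assert criteria == []
    assert report.counts == {"unmapped_code": 1}


def test_self_pair_after_normalisation_raises():
    with pytest.raises(CompileError, match="self-interaction"):
        compile_interactions([ix_entry("A01AA01", "A01AA01")])


# --- renal ------------------------------------------------------------------------


def test_simplify_renal_range_printed_example():
    assert simplify_renal_range(500, 2000, 8, 12) == (1000.0, 6000.0)


@pytest.mark.parametrize(
    "args,expected",
    [
        ((750, 750, 24, 24), (750, 750)),  # identity interval
        ((100, 300, 6, 8), (300, 1200)),
    ],
)
def test_simplify_renal_range_cases(args, expected):
    assert simplify_renal_range(*args) == pytest.approx(expected)


def test_simplify_renal_range_rejects_bad_input():
    for args in [(0, 1, 8, 12), (1, 2, 0, 12), (1, 2, 12, 8), (2, 1, 8, 12),
                 (1, 2, 8, 200)]:
        with pytest.raises(ValueError):
            simplify_renal_range(*args)


@given(
    dose_low=st.floats(min_value=1, max_value=1e3),
    dose_delta=st.floats(min_value=0, max_value=1e3),
    ilow=st.floats(min_value=1, max_value=24),
    idelta=st.floats(min_value=0, max_value=24),
)
def test_simplify_renal_range_monotonicity(dose_low, dose_delta, ilow, idelta):
    """Monotone in doses, antitone in the matching interval bound."""
    lo, hi = simplify_renal_range(dose_low, dose_low + dose_delta, ilow, ilow + idelta)
    assert lo <= hi
    lo2, hi2 = simplify_renal_range(
        dose_low * 2, (dose_low + dose_delta) * 2, ilow, ilow + idelta
    )
    assert lo2 >= lo and hi2 >= hi
    lo3, hi3 = simplify_renal_range(
        dose_low, dose_low + dose_delta, ilow / 2, ilow + idelta
    )
    assert hi3 >= hi  # shorter minimum interval -> larger daily max


def renal_entry(name="dalbavancin", brackets=(), dialysis=None):
    return RenalSourceEntry(
        drug_description=name,
        route="parenteral",
        dosing_by_clearance=list(brackets),
        dialysis_dosing=dialysis,
    )


def test_compile_renal_fixture_bracket():
    """GFR 31-130 bracket: loading 1000 mg/24 h, adjusted 500-500 mg/24 h."""
    entry = renal_entry(
        brackets=[
            ClearanceBracket(
                gfr_low=31, gfr_high=130, dose_low=500, dose_high=500,
                interval_low_h=24, interval_high_h=24, unit="mg",
                loading_dose=1000, loading_unit="mg",
            )
        ]
    )
    criteria, report = compile_renal([entry], lambda s: s)
    assert len(criteria) == 1
    c = criteria[0]
    assert (c.gfr_low, c.gfr_high) == (31, 130)
    assert c.loading_dose == 1000
    assert (c.adjusted_min_daily, c.adjusted_max_daily) == (500, 500)
    assert report.compiled == 1


def test_dialysis_only_entry_is_excluded():
    criteria, report = compile_renal(
        [renal_entry(dialysis="500 mg after each session")], lambda s: s
    )
    assert criteria == []
    assert report.counts == {"dialysis_only": 1}


def test_unresolvable_drug_description_is_excluded():
    entry = renal_entry(
        name="mystery elixir",
        brackets=[
            ClearanceBracket(10, 30, 100, 200, 8, 12),
        ],
    )
    criteria, report = compile_renal([entry], lambda s: None)
    assert criteria == []
    assert report.counts == {"unmapped_code": 1}


def test_two_disjoint_brackets_give_two_criteria():
    entry = renal_entry(
        brackets=[
            ClearanceBracket(10, 30, 100, 200, 8, 12),
            ClearanceBracket(31, 130, 200, 400, 8, 12),
        ]
    )
    criteria, _ = compile_renal([entry], lambda s: s)
    assert len(criteria) == 2


def test_overlapping_brackets_raise():
    entry = renal_entry(
        brackets=[
            ClearanceBracket(10, 40, 100, 200, 8, 12),
            ClearanceBracket(31, 130, 200, 400, 8, 12),
        ]
    )
    with pytest.raises(CompileError, match="overlapping GFR"):
        compile_renal([entry], lambda s: s)


# --- stats & idempotence ------------------------------------------------------------


def test_compression_stats():
    stats = compression_stats({"max_dose": (10, 6), "empty": (0, 0)})
    assert stats["max_dose"]["ratio"] == pytest.approx(0.6)
    assert stats["empty"]["ratio"] is None


def test_recompiling_expanded_criteria_is_idempotent():
    """Re-expanding compiled criteria to entries and recompiling is a no-op."""
    idx = make_index(
        A={"ingredients": ("drugx",), "route": "oral"},
        B={"ingredients": ("drugx",), "route": "oral"},
        C={"ingredients": ("drugy",), "route": "parenteral"},
    )
    entries = [
        md_entry("A", dose=100),
        md_entry("B", dose=100),
        md_entry("C", route="parenteral", dose=50),
    ]
    criteria, _ = collapse_max_dose(entries, idx)

    idx2 = ProductIndex()
    re_entries = []
    for k, c in enumerate(criteria):
        code = f"RE{k}"
        idx2.add(
            "national_drug_code", code,
            ProductInfo((c.ingredient.label,), route=c.route.label),
        )
        re_entries.append(
            md_entry(code, route=c.route.label, dose=c.max_daily_dose,
                     age_min=c.age_min, age_max=c.age_max)
        )
    criteria2, _ = collapse_max_dose(re_entries, idx2)
    key = lambda c: (c.ingredient.iri, c.route.iri, c.age_min, c.age_max,
                     c.max_daily_dose, c.dose_unit)
    assert sorted(map(key, criteria)) == sorted(map(key, criteria2))
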