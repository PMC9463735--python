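import pytest
from hypothesis import given, settings, strategies as st

from ontorx.engine import (
    DecisionError,
    OverrideLedger,
    UnknownAlertError,
    record_decision,
)
from ontorx.model import SEVERITY_COLOUR, SEVERITY_RANK, Severity

from conftest import gfr, patient, rx
from reference import brute_force_alerts, engine_alert_set


def alert_rules(result):
    return [a.rule for a in result.alerts]


# --- max dose ---------------------------------------------------------------


def test_total_equal_to_maximum_passes(engine):
    """40 mg every 12 h totals exactly the 80 mg maximum: no alert."""
    p = patient(prescriptions=[rx("r1", "ATORVA40", 40, freq="Q12H")])
    assert engine.check_max_dose(p) == []


def test_total_above_maximum_fires(engine):
    p = patient(prescriptions=[rx("r1", "ATORVA40", 80, freq="Q12H")])
    alerts = engine.check_max_dose(p)
    assert len(alerts) == 1
    a = alerts[0]
    assert a.rule == "max_dose" and not a.hard_stop
    assert a.drugs == ("r1",)
    assert "160" in a.description and "80" in a.description


def test_route_independent_criterion_sums_across_routes(engine):
    """Parenteral 1000 mg/8 h + oral 500 mg/8 h aggregate to 4500 mg/24 h."""
    p = patient(
        prescriptions=[
            rx("iv", "PARA1000IV", 1000, freq="Q8H", route="IV"),
            rx("po", "PARA500PO", 500, freq="Q8H", route="PO"),
        ]
    )
    alerts = engine.check_max_dose(p)
    assert len(alerts) == 1
    assert alerts[0].drugs == ("iv", "po")
    assert "4500" in alerts[0].description


def test_route_specific_criterion_ignores_other_routes(engine):
    # oral atorvastatin criterion: an (hypothetical) IV line is not summed
    p = patient(
        prescriptions=[
            rx("r1", "ATORVA40", 40, freq="Q12H", route="PO"),
            rx("r2", "ATORVA40", 40, freq="Q12H", route="IV"),
        ]
    )
    assert engine.check_max_dose(p) == []


def test_prn_prescriptions_do_not_count_toward_daily_dose(engine):
    p = patient(prescriptions=[rx("r1", "ATORVA40", 80, freq="Q12H", prn=True)])
    assert engine.check_max_dose(p) == []


def test_age_outside_criterion_range_skips(engine):
    p = patient(age=10, prescriptions=[rx("r1", "ATORVA40", 80, freq="Q12H")])
    assert engine.check_max_dose(p) == []


def test_gram_doses_convert_before_summation(engine):
    # 2.5 g every 12 h = 5000 mg/24 h > 4000 mg acetaminophen maximum
    p = patient(prescriptions=[rx("r1", "PARA500PO", 2.5, unit="G", freq="Q12H")])
    alerts = engine.check_max_dose(p)
    assert len(alerts) == 1 and "5000" in alerts[0].description


def test_volume_dose_is_skipped_with_unit_mismatch_note(engine):
    p = patient(prescriptions=[rx("r1", "ATORVA40", 5, unit="ml", freq="Q12H")])
    result = engine.evaluate(p)
    assert result.alerts == []
    assert {"prescription_id": "r1", "reason": "unit_mismatch"} in result.skipped


def test_unmapped_drug_is_skipped_with_note(engine):
    p = patient(prescriptions=[rx("r1", "MYSTERY-99", 100)])
    result = engine.evaluate(p)
    assert result.alerts == []
    assert {"prescription_id": "r1", "reason": "unmapped_drug"} in result.skipped


# --- interactions ------------------------------------------------------------


def test_interaction_fires_on_overlap(engine):
    p = patient(
        prescriptions=[
            rx("r1", "PHENEL15", 15, freq="Q12H"),
            rx("r2", "CLOPER10", 10, freq="Q8H"),
        ]
    )
    alerts = engine.check_interactions(p)
    assert len(alerts) == 1
    assert alerts[0].drugs == ("r1", "r2")
    assert alerts[0].severity == Severity.CONTRAINDICATED


def test_interaction_requires_temporal_overlap(engine):
    p = patient(
        prescriptions=[
            rx("r1", "PHENEL15", 15, day=0, days=5),
            rx("r2", "CLOPER10", 10, day=5, days=5),  # half-open: no overlap
        ]
    )
    assert engine.check_interactions(p) == []


def test_single_prescription_never_interacts(engine):
    p = patient(prescriptions=[rx("r1", "PHENEL15", 15)])
    assert engine.check_interactions(p) == []


def test_prn_prescription_does_not_interact(engine):
    p = patient(
        prescriptions=[
            rx("r1", "PHENEL15", 15),
            rx("r2", "CLOPER10", 10, prn=True),
        ]
    )
    assert engine.check_interactions(p) == []


def test_interaction_symmetry_under_order_swap(engine):
    a = [rx("r1", "PHENEL15", 15), rx("r2", "CLOPER10", 10)]
    p1 = patient(prescriptions=a)
    p2 = patient(prescriptions=list(reversed(a)))
    k1 = {(x.criterion.iri, x.drugs) for x in engine.check_interactions(p1)}
    k2 = {(x.criterion.iri, x.drugs) for x in engine.check_interactions(p2)}
    assert k1 == k2 and k1


# --- renal ---------------------------------------------------------------------


def test_renal_alert_inside_bracket(engine):
    p = patient(
        prescriptions=[rx("r1", "DALBA500", 1000, route="IV")],
        labs=[gfr(45)],
    )
    alerts = engine.check_renal(p)
    assert len(alerts) == 1
    a = alerts[0]
    assert "500" in a.recommendation and "loading dose 1000" in a.recommendation
    assert a.rule == "renal" and not a.hard_stop


def test_no_renal_alert_outside_bracket(engine):
    p = patient(
        prescriptions=[rx("r1", "DALBA500", 1000, route="IV")],
        labs=[gfr(140)],
    )
    assert engine.check_renal(p) == []


def test_dose_at_adjusted_maximum_passes(engine):
    p = patient(
        prescriptions=[rx("r1", "DALBA500", 500, route="IV")],
        labs=[gfr(45)],
    )
    assert engine.check_renal(p) == []


def test_most_recent_gfr_value_wins(engine):
    p = patient(
        prescriptions=[rx("r1", "DALBA500", 1000, route="IV")],
        labs=[gfr(140, day=-3), gfr(45, day=1)],
    )
    assert len(engine.check_renal(p)) == 1
    p2 = patient(
        prescriptions=[rx("r1", "DALBA500", 1000, route="IV")],
        labs=[gfr(45, day=-3), gfr(140, day=1)],
    )
    assert engine.check_renal(p2) == []


def test_equally_recent_gfr_tie_breaks_to_larger(engine):
    p = patient(
        prescriptions=[rx("r1", "DALBA500", 1000, route="IV")],
        labs=[gfr(45, day=1), gfr(140, day=1)],
    )
    assert engine.check_renal(p) == []


def test_no_gfr_result_skips_renal_check(engine):
    p = patient(prescriptions=[rx("r1", "DALBA500", 1000, route="IV")])
    assert engine.check_renal(p) == []


# --- allergy ---------------------------------------------------------------------


def test_group_allergy_covers_member_ingredient(engine):
    p = patient(
        prescriptions=[rx("r1", "OMEP20", 20)], allergies=["PPI-ALRG"]
    )
    alerts = engine.check_allergy(p)
    assert len(alerts) == 1
    a = alerts[0]
    assert a.hard_stop and a.severity == Severity.NOT_ALLOWED and a.colour == "red"


def test_ingredient_allergy_does_not_expand_upward(engine):
    """Allergy to omeprazole alone does not implicate pantoprazole."""
    p = patient(
        prescriptions=[rx("r1", "PANTO40", 40)], allergies=["OMEP-ALRG"]
    )
    assert engine.check_allergy(p) == []


def test_no_allergy_history_no_alert(engine):
    p = patient(prescriptions=[rx("r1", "OMEP20", 20)])
    assert engine.check_allergy(p) == []


def test_allergy_fires_even_for_prn(engine):
    p = patient(
        prescriptions=[rx("r1", "OMEP20", 20, prn=True)], allergies=["PPI-ALRG"]
    )
    assert len(engine.check_allergy(p)) == 1


# --- evaluate: ordering, suppression, decisions -----------------------------------


def overdose_interaction_allergy_patient():
    return patient(
        prescriptions=[
            rx("r1", "ATORVA40", 80, freq="Q12H"),
            rx("r2", "PHENEL15", 15, freq="Q12H"),
            rx("r3", "CLOPER10", 10, freq="Q8H"),
            rx("r4", "OMEP20", 20),
        ],
        allergies=["PPI-ALRG"],
    )


def test_evaluate_orders_hard_stops_first_then_severity(engine):
    result = engine.evaluate(overdose_interaction_allergy_patient())
    assert alert_rules(result) == ["allergy", "interaction", "max_dose"]
    ranks = [SEVERITY_RANK[a.severity] for a in result.alerts]
    assert result.alerts[0].hard_stop
    assert ranks[1:] == sorted(ranks[1:], reverse=True)


def test_colour_is_a_pure_function_of_severity(engine):
    result = engine.evaluate(overdose_interaction_allergy_patient())
    for a in result.alerts:
        assert a.colour == SEVERITY_COLOUR[a.severity]


def test_clean_patient_yields_no_alerts(engine):
    result = engine.evaluate(
        patient(prescriptions=[rx("r1", "ATORVA40", 40)], labs=[gfr(90)])
    )
    assert result.alerts == [] and result.skipped == []


def test_ignored_soft_alert_is_suppressed_on_reevaluation(engine):
    ledger = OverrideLedger()
    p = patient(prescriptions=[rx("r1", "ATORVA40", 80, freq="Q12H")])
    first = engine.evaluate(p, ledger)
    assert alert_rules(first) == ["max_dose"]
    record_decision(ledger, p.patient_id, first.alerts[0].suppression_key, "ignored")
    second = engine.evaluate(p, ledger)
    assert second.alerts == []


def test_suppression_survives_dose_changes(engine):
    ledger = OverrideLedger()
    p = patient(prescriptions=[rx("r1", "ATORVA40", 80, freq="Q12H")])
    first = engine.evaluate(p, ledger)
    record_decision(ledger, p.patient_id, first.alerts[0].suppression_key, "ignored")
    worse = patient(prescriptions=[rx("r1", "ATORVA40", 120, freq="Q8H")])
    assert engine.evaluate(worse, ledger).alerts == []


def test_suppression_is_per_patient(engine):
    ledger = OverrideLedger()
    p = patient(pid="A", prescriptions=[rx("r1", "ATORVA40", 80, freq="Q12H")])
    first = engine.evaluate(p, ledger)
    record_decision(ledger, "A", first.alerts[0].suppression_key, "ignored")
    other = patient(pid="B", prescriptions=[rx("r1", "ATORVA40", 80, freq="Q12H")])
    assert len(engine.evaluate(other, ledger).alerts) == 1


def test_allergy_alert_cannot_be_ignored_and_always_reappears(engine):
    ledger = OverrideLedger()
    p = patient(prescriptions=[rx("r1", "OMEP20", 20)], allergies=["PPI-ALRG"])
    first = engine.evaluate(p, ledger)
    key = first.alerts[0].suppression_key
    with pytest.raises(DecisionError, match="hard-stop"):
        record_decision(ledger, p.patient_id, key, "ignored")
    second = engine.evaluate(p, ledger)
    assert len(second.alerts) == 1 and second.alerts[0].hard_stop


def test_accepting_interaction_requires_choosing_a_drug(engine):
    ledger = OverrideLedger()
    p = patient(
        prescriptions=[rx("r1", "PHENEL15", 15), rx("r2", "CLOPER10", 10)]
    )
    first = engine.evaluate(p, ledger)
    key = first.alerts[0].suppression_key
    with pytest.raises(DecisionError, match="choosing"):
        record_decision(ledger, p.patient_id, key, "accepted")
    record_decision(ledger, p.patient_id, key, "accepted", chosen_prescription="r2")
    assert ledger.decisions[-1]["chosen_prescription"] == "r2"
    # accepted (not ignored): the alert still shows next round
    assert len(engine.evaluate(p, ledger).alerts) == 1


def test_unknown_suppression_key_rejected(engine):
    with pytest.raises(UnknownAlertError):
        record_decision(OverrideLedger(), "P1", "deadbeef", "ignored")


def test_episode_clear_resets_suppression(engine):
    ledger = OverrideLedger()
    p = patient(prescriptions=[rx("r1", "ATORVA40", 80, freq="Q12H")])
    first = engine.evaluate(p, ledger)
    record_decision(ledger, p.patient_id, first.alerts[0].suppression_key, "ignored")
    ledger.clear_episode(p.patient_id)
    assert len(engine.evaluate(p, ledger).alerts) == 1


# --- property tests over random fixture-formulary patients -------------------------

_FORMULARY = [
    ("ATORVA40", "PO"),
    ("PARA500PO", "PO"),
    ("PARA1000IV", "IV"),
    ("DALBA500", "IV"),
    ("PHENEL15", "PO"),
    ("CLOPER10", "PO"),
    ("OMEP20", "PO"),
    ("PANTO40", "PO"),
]

_rx_strategy = st.builds(
    lambda k, dose, per_day, day, days, prn: (k, dose, per_day, day, days, prn),
    k=st.integers(0, len(_FORMULARY) - 1),
    dose=st.sampled_from([10.0, 40.0, 80.0, 500.0, 1000.0, 2000.0]),
    per_day=st.sampled_from(["Q24H", "Q12H", "Q8H"]),
    day=st.integers(0, 6),
    days=st.integers(1, 7),
    prn=st.booleans(),
)


def _build_patient(spec, age, gfr_value, allergies, prn_override=None):
    prescriptions = []
    for i, (k, dose, per_day, day, days, prn) in enumerate(spec):
        code, route = _FORMULARY[k]
        prescriptions.append(
            rx(
                f"r{i}", code, dose, freq=per_day, route=route, day=day,
                days=days, prn=prn if prn_override is None else prn_override,
            )
        )
    return patient(
        pid="H1",
        age=age,
        prescriptions=prescriptions,
        labs=[gfr(gfr_value)],
        allergies=allergies,
    )


_patient_strategy = st.builds(
    _build_patient,
    spec=st.lists(_rx_strategy, min_size=0, max_size=6),
    age=st.integers(18, 99),
    gfr_value=st.sampled_from([25.0, 45.0, 90.0, 140.0]),
    allergies=st.sampled_from([[], ["PPI-ALRG"], ["OMEP-ALRG"]]),
)


@settings(max_examples=120, deadline=None)
@given(p=_patient_strategy)
def test_engine_matches_brute_force_reference(engine, fixture_kb, fixture_mappings, p):
    """evaluate() equals the plain in-memory enumeration, alert for alert."""
    assert engine_alert_set(engine.evaluate(p)) == brute_force_alerts(
        fixture_kb, fixture_mappings, p
    )


@settings(max_examples=60, deadline=None)
@given(p=_patient_strategy)
def test_prn_everywhere_silences_all_but_allergy(engine, p):
    all_prn = _build_patient(
        [
            (
                next(k for k, (c, _) in enumerate(_FORMULARY) if c == rx_.drug_code),
                rx_.dose, rx_.frequency, 0, 7, True,
            )
            for rx_ in p.prescriptions
        ],
        p.age_years,
        p.labs[0].value,
        p.allergies,
        prn_override=True,
    )
    rules = set(alert_rules(engine.evaluate(all_prn)))
    assert rules <= {"allergy"}


@settings(max_examples=60, deadline=None)
@given(p=_patient_strategy)
def test_doubling_doses_never_reduces_max_dose_alerts(engine, p):
    before = len(engine.check_max_dose(p))
    for rx_ in p.prescriptions:
        rx_.dose *= 2
    after = len(engine.check_max_dose(p))
    assert after >= before


@settings(max_examples=40, deadline=None)
@given(p=_patient_strategy)
def test_suppression_soundness(engine, p):
    """Ignoring every soft alert removes them all; hard alerts persist."""
    ledger = OverrideLedger()
    first = engine.evaluate(p, ledger)
    soft = [a for a in first.alerts if not a.hard_stop]
    hard = [a for a in first.alerts if a.hard_stop]
    for a in soft:
        record_decision(ledger, p.patient_id, a.suppression_key, "ignored")
    second = engine.evaluate(p, ledger)
    assert [a for a in second.alerts if not a.hard_stop] == []
    assert {a.suppression_key for a in second.alerts} == {
        a.suppression_key for a in hard
    }
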