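"""JSON evaluation service with an append-only audit trail.

The order-entry system publishes a JSON request whenever a clinician
adds a medication, modifies one, or asks for decision support on
demand; the service answers with the fired alerts.  The service layer
adds no alert logic of its own — response alerts are exactly the rule
engine's output, serialised — and every request/response pair is
appended to a JSON Lines audit log before the response is returned, so
the full exchange is traceable.
"""

from __future__ import annotations

import json
import time
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional, Union

from pydantic import BaseModel, Field, ValidationError

from .engine import (
    DecisionError,
    FiredAlert,
    LabResult,
    OverrideLedger,
    PatientRecord,
    Prescription,
    RuleEngine,
    UnknownAlertError,
    record_decision,
)


class ServiceError(Exception):
    """Structured service failure (maps onto an HTTP-style status)."""

    def __init__(self, status: int, code: str, detail: str):
        self.status = status
        self.code = code
        self.detail = detail
        super().__init__(f"{status} {code}: {detail}")

    def to_json(self) -> dict:
        return {"error": self.code, "status": self.status, "detail": self.detail}


# --- request / response schema (published, versioned) -------------------------

SCHEMA_VERSION = "1.0"


class DoseIn(BaseModel):
    value: float = Field(gt=0)
    unit: str


class PrescriptionIn(BaseModel):
    id: str
    drug_code: str
    dose: DoseIn
    frequency: Union[str, float]
    route: str
    start: datetime
    end: datetime
    prn: bool = False


class LabIn(BaseModel):
    test_code: str
    value: float
    unit: str
    taken_at: datetime


class PatientIn(BaseModel):
    patient_id: str = Field(min_length=1)
    age_years: int = Field(ge=0)
    sex: Optional[str] = None
    prescriptions: list[PrescriptionIn] = Field(default_factory=list)
    labs: list[LabIn] = Field(default_factory=list)
    allergies: list[str] = Field(default_factory=list)


class EvaluationRequest(BaseModel):
    request_id: str = Field(min_length=1)
    timestamp: datetime
    trigger: Literal["new_prescription", "modification", "on_demand"]
    patient: PatientIn


class AlertOut(BaseModel):
    rule: str
    severity: str
    colour: str
    hard_stop: bool
    drugs: list[str]
    criterion_iri: str
    description: str
    recommendation: str
    suppression_key: str


class SkippedOut(BaseModel):
    prescription_id: str
    reason: str


class EvaluationResponse(BaseModel):
    request_id: str
    schema_version: str = SCHEMA_VERSION
    alerts: list[AlertOut]
    skipped: list[SkippedOut]
    kb_version: str
    elapsed_ms: float


class DecisionRequest(BaseModel):
    request_id: str = Field(min_length=1)
    patient_id: str
    suppression_key: str
    decision: Literal["accepted", "ignored"]
    chosen_prescription: Optional[str] = None


def _to_patient(p: PatientIn) -> PatientRecord:
    return PatientRecord(
        patient_id=p.patient_id,
        age_years=p.age_years,
        sex=p.sex,
        prescriptions=[
            Prescription(
                id=rx.id,
                drug_code=rx.drug_code,
                dose=rx.dose.value,
                dose_unit=rx.dose.unit,
                frequency=rx.frequency,
                route=rx.route,
                start=rx.start,
                end=rx.end,
                prn=rx.prn,
            )
            for rx in p.prescriptions
        ],
        labs=[
            LabResult(
                test_code=lab.test_code,
                value=lab.value,
                unit=lab.unit,
                taken_at=lab.taken_at,
            )
            for lab in p.labs
        ],
        allergies=list(p.allergies),
    )


def alert_to_out(alert: FiredAlert) -> AlertOut:
    return AlertOut(
        rule=alert.rule,
        severity=alert.severity.value,
        colour=alert.colour,
        hard_stop=alert.hard_stop,
        drugs=list(alert.drugs),
        criterion_iri=alert.criterion.iri,
        description=alert.description,
        recommendation=alert.recommendation,
        suppression_key=alert.suppression_key,
    )


class AlertService:
    """Synchronous evaluation/decision endpoint pair over one engine."""

    def __init__(
        self,
        engine: RuleEngine,
        kb_version: str = "unversioned",
        audit_path: Optional[Union[str, Path]] = None,
        ledger: Optional[OverrideLedger] = None,
    ):
        self.engine = engine
        self.kb_version = kb_version
        self.audit_path = Path(audit_path) if audit_path else None
        self.ledger = ledger or OverrideLedger()
        self._seen_request_ids: set[str] = set()

    # --- audit -------------------------------------------------------------

    def _audit(self, kind: str, request: dict, response: dict) -> None:
        if self.audit_path is None:
            return
        record = {
            "kind": kind,
            "request": request,
            "response": response,
            "logged_at": datetime.now(timezone.utc).isoformat(),
        }
        with self.audit_path.open("a") as fh:
            fh.write(json.dumps(record, default=str) + "\n")

    # --- endpoints -----------------------------------------------------------

    def handle_evaluation(self, payload: Union[dict, EvaluationRequest]) -> EvaluationResponse:
        """POST /evaluate: validate, evaluate, audit, respond."""
        t0 = time.perf_counter()
        try:
            request = (
                payload
                if isinstance(payload, EvaluationRequest)
                else EvaluationRequest.model_validate(payload)
            )
        except ValidationError as exc:
            fields = ", ".join(
                ".".join(str(p) for p in err["loc"]) for err in exc.errors()
            )
            raise ServiceError(422, "schema_violation", f"invalid fields: {fields}")
        if request.request_id in self._seen_request_ids:
            raise ServiceError(
                409, "duplicate_request", f"request_id {request.request_id!r} reused"
            )
        self._seen_request_ids.add(request.request_id)
        try:
            patient = _to_patient(request.patient)
        except ValueError as exc:
            raise ServiceError(422, "schema_violation", str(exc))
        result = self.engine.evaluate(patient, self.ledger)
        response = EvaluationResponse(
            request_id=request.request_id,
            alerts=[alert_to_out(a) for a in result.alerts],
            skipped=[SkippedOut(**note) for note in result.skipped],
            kb_version=self.kb_version,
            elapsed_ms=(time.perf_counter() - t0) * 1000.0,
        )
        self._audit(
            "evaluation", request.model_dump(mode="json"),
            response.model_dump(mode="json"),
        )
        return response

    def handle_decision(self, payload: Union[dict, DecisionRequest]) -> dict:
        """POST /decision: record accept/ignore on an emitted alert."""
        try:
            req = (
                payload
                if isinstance(payload, DecisionRequest)
                else DecisionRequest.model_validate(payload)
            )
        except ValidationError as exc:
            raise ServiceError(422, "schema_violation", str(exc))
        try:
            record_decision(
                self.ledger,
                req.patient_id,
                req.suppression_key,
                req.decision,
                req.chosen_prescription,
            )
        except UnknownAlertError as exc:
            raise ServiceError(404, "unknown_alert", str(exc))
        except DecisionError as exc:
            raise ServiceError(403, "forbidden_decision", str(exc))
        ack = {
            "request_id": req.request_id,
            "status": "recorded",
            "decision": req.decision,
            "suppression_key": req.suppression_key,
        }
        self._audit("decision", req.model_dump(mode="json"), ack)
        return ack

    def health(self) -> dict:
        """GET /health."""
        return {"status": "ok", "kb_version": self.kb_version}


# --- audit reporting ------------------------------------------------------------


def audit_report(log_path: Union[str, Path]) -> dict:
    """Aggregate the audit log into a traffic summary.

    Acceptance rate counts decided soft alerts (accepted / decided) and
    treats hard-stop alerts as accepted by construction — they cannot
    be ignored.  Corrupt lines are skipped and counted.
    """
    path = Path(log_path)
    requests = 0
    alerts_by_rule: dict[str, int] = {}
    alerts_by_severity: dict[str, int] = {}
    hard_alerts = 0
    accepted = 0
    ignored = 0
    corrupt = 0
    if path.exists():
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                try:
                    record = json.loads(line)
                    kind = record["kind"]
                except (json.JSONDecodeError, KeyError, TypeError):
                    corrupt += 1
                    continue
                if kind == "evaluation":
                    requests += 1
                    for alert in record["response"].get("alerts", []):
                        alerts_by_rule[alert["rule"]] = (
                            alerts_by_rule.get(alert["rule"], 0) + 1
                        )
                        alerts_by_severity[alert["severity"]] = (
                            alerts_by_severity.get(alert["severity"], 0) + 1
                        )
                        if alert.get("hard_stop"):
                            hard_alerts += 1
                elif kind == "decision":
                    decision = record["request"].get("decision")
                    if decision == "accepted":
                        accepted += 1
                    elif decision == "ignored":
                        ignored += 1
                else:
                    corrupt += 1
    total_alerts = sum(alerts_by_rule.values())
    decided = accepted + ignored + hard_alerts
    rate = (accepted + hard_alerts) / decided if decided else None
    return {
        "requests": requests,
        "alerts_total": total_alerts,
        "alerts_by_rule": alerts_by_rule,
        "alerts_by_severity": alerts_by_severity,
        "decisions": {"accepted": accepted, "ignored": ignored},
        "acceptance_rate": rate,
        "corrupt_lines": corrupt,
    }
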