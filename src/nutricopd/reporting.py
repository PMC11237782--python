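"""Readers, writers, report generation, triple export and agreement
statistics.

The patient interchange schema is the flat :class:`~nutricopd.model.PatientInput`
field set, as CSV (comma-separated, UTF-8, header row, decimal point) or
JSON (a list of records). Reports serialize deterministically and annotate
every value with the rule ids and provenance from the trace. The optional
triple export renders the patient, their health condition and their
recommendation in Turtle using the ``copd:`` vocabulary, so the output can
be loaded next to the ontology the rule base mirrors.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from .model import (
    NutritionalRecommendation,
    PatientClassification,
    PatientInput,
    PatientValidationError,
    RuleTrace,
    validate_patient,
)

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = list(PatientInput.model_fields)

#: Columns that may be left blank in input files.
_OPTIONAL = {"usual_weight", "pco2", "has_t2dm", "has_hypercholesterolemia"}


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# patient IO

def _records_to_patients(records: list[dict], origin: str) -> list[PatientInput]:
    patients = []
    for i, rec in enumerate(records):
        clean = {k: v for k, v in rec.items()
                 if v is not None and not (isinstance(v, float) and np.isnan(v))}
        try:
            patients.append(validate_patient(clean))
        except PatientValidationError as exc:
            raise PatientValidationError(
                f"{origin}, record {i + 1} (id={rec.get('id', '?')}): {exc}",
                fields=exc.fields) from exc
    return patients


def read_patients(path: str | Path, format: Optional[str] = None) -> list[PatientInput]:
    """Read and validate patients from CSV or JSON.

    ``format`` defaults to the file suffix. Unknown columns raise
    :class:`SchemaError`; invalid values raise
    :class:`~nutricopd.model.PatientValidationError` carrying the record
    number. An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        text = path.read_text(encoding="utf-8")
        if not text.strip():
            logger.warning("%s is empty; returning an empty cohort", path)
            return []
        df = pd.read_csv(io.StringIO(text), float_precision="round_trip")
        unknown = set(df.columns) - set(PATIENT_COLUMNS)
        if unknown:
            raise SchemaError(f"{path}: unknown columns {sorted(unknown)}")
        missing = set(PATIENT_COLUMNS) - set(df.columns) - _OPTIONAL
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        records = df.to_dict(orient="records")
    elif fmt == "json":
        text = path.read_text(encoding="utf-8")
        if not text.strip():
            logger.warning("%s is empty; returning an empty cohort", path)
            return []
        data = json.loads(text)
        if not isinstance(data, list):
            raise SchemaError(f"{path}: expected a JSON list of patient records")
        for rec in data:
            unknown = set(rec) - set(PATIENT_COLUMNS)
            if unknown:
                raise SchemaError(f"{path}: unknown fields {sorted(unknown)}")
        records = data
    else:
        raise SchemaError(f"unsupported format {fmt!r} (use csv or json)")
    return _records_to_patients(records, str(path))


def write_patients(patients: Sequence[PatientInput], path: str | Path,
                   format: Optional[str] = None) -> None:
    """Write a cohort in the same schema :func:`read_patients` consumes."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    records = [p.model_dump(mode="json") for p in patients]
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=PATIENT_COLUMNS)
            writer.writeheader()
            for rec in records:
                writer.writerow({k: ("" if rec[k] is None else rec[k])
                                 for k in PATIENT_COLUMNS})
    elif fmt == "json":
        path.write_text(json.dumps(records, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
    else:
        raise SchemaError(f"unsupported format {fmt!r} (use csv or json)")


# ---------------------------------------------------------------------------
# reports

def _annotate(value, field: str, trace: RuleTrace):
    return {
        "value": value,
        "rules": trace.rules_for(field),
        "provenance": trace.provenance_of(field).value,
    }


def report_dict(classification: PatientClassification,
                recommendation: NutritionalRecommendation,
                trace: RuleTrace) -> dict:
    """The report as a plain dict (the JSON document's object form).

    Three sections mirror the assessment workflow: the health condition
    (classification), the nutritional recommendation, and the rule trace.
    """
    cls = classification.model_dump(mode="json")
    rec = recommendation.model_dump(mode="json")
    return {
        "patient_id": classification.patient_id,
        "health_condition": {
            k: _annotate(round(v, 2) if isinstance(v, float) else v, k, trace)
            for k, v in cls.items() if k != "patient_id"
        },
        "nutritional_recommendation": {
            k: _annotate(round(v, 1) if isinstance(v, float) else v, k, trace)
            for k, v in rec.items()
        },
        "rule_trace": [e.model_dump(mode="json") for e in trace.entries],
    }


def write_report(classification: PatientClassification,
                 recommendation: NutritionalRecommendation,
                 trace: RuleTrace, format: str = "json") -> str:
    """Serialize one patient's report deterministically as JSON or Markdown."""
    doc = report_dict(classification, recommendation, trace)
    if format == "json":
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    if format != "markdown":
        raise ValueError(f"unsupported report format {format!r}")
    lines = [f"# Patient {doc['patient_id']}", "", "## Health condition", ""]
    for key, cell in doc["health_condition"].items():
        lines.append(f"- **{key}**: {cell['value']} "
                     f"({cell['provenance']}; rules: {', '.join(cell['rules'])})")
    lines += ["", "## Nutritional recommendation", ""]
    for key, cell in doc["nutritional_recommendation"].items():
        lines.append(f"- **{key}**: {cell['value']} "
                     f"({cell['provenance']}; rules: {', '.join(cell['rules'])})")
    lines += ["", "## Fired rules", ""]
    for entry in doc["rule_trace"]:
        lines.append(f"1. `{entry['rule_id']}` — {entry['description']} "
                     f"[{entry['provenance']}]")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# triple export

COPD_NS = "http://www.example.org/copd#"


def export_triples(patient: PatientInput,
                   classification: PatientClassification,
                   recommendation: NutritionalRecommendation) -> str:
    """Serialize one patient as Turtle triples in the ``copd:`` vocabulary.

    Each patient has exactly one ``copd:isInHealthCondition`` link and one
    ``copd:hasRecommendation`` link; asserted and inferred quantities are
    datatype properties of the health condition and recommendation nodes.
    """
    from rdflib import RDF, Graph, Literal, Namespace, URIRef

    copd = Namespace(COPD_NS)
    g = Graph()
    g.bind("copd", copd)
    pat = URIRef(COPD_NS + f"Patient_{patient.id}")
    hc = URIRef(COPD_NS + f"Health_Condition_{patient.id}")
    rec = URIRef(COPD_NS + f"Nutritional_Recommendation_{patient.id}")

    g.add((pat, RDF.type, copd.Patient))
    g.add((hc, RDF.type, copd.Health_Condition))
    g.add((rec, RDF.type, copd.Nutritional_Recommendation))
    g.add((pat, copd.isInHealthCondition, hc))
    g.add((pat, copd.hasRecommendation, rec))
    g.add((pat, copd.patientID, Literal(patient.id)))

    asserted = {
        "age": patient.age,
        "currentWeight": patient.current_weight,
        "usualWeight": patient.usual_weight,
        "height_meters": patient.height,
        "FEV1": patient.fev1_percent,
        "handGrip": patient.hand_grip,
        "gaitSpeed": patient.gait_speed,
        "resistance": patient.resistance,
        "reactance": patient.reactance,
        "albuminemia": patient.albumin,
        "PCR": patient.crp,
        "ironTransport": patient.transferrin,
    }
    if patient.pco2 is not None:
        asserted["pCO2"] = patient.pco2
    inferred = {
        "nutritionalRiskIndex": round(classification.nri_value, 2),
        "resistiveIndex": round(classification.resistive_index, 2),
        "appendicularSkeletalMuscleMass": round(classification.asmm, 2),
        "BMI": round(classification.bmi, 2),
    }
    for name, value in {**asserted, **inferred}.items():
        g.add((hc, copd[name], Literal(value)))

    rec_props = {
        "regularRecommendedCaloricIntake": recommendation.bmr_kcal,
        "correctedRecommendedCaloricIntake": recommendation.energy_kcal,
        "proteinsGrams": round(recommendation.protein_g, 1),
        "proteinShare": round(recommendation.protein_share, 1),
        "carbohydratesMINshare": recommendation.carb_share_min,
        "carbohydratesMAXshare": recommendation.carb_share_max,
        "lipidsMINshare": round(recommendation.fat_share_min, 1),
        "lipidsMAXshare": round(recommendation.fat_share_max, 1),
        "sugarsMAXshare": recommendation.sugar_share_max,
        "saturatedFatsMAXshare": recommendation.satfat_share_max,
        "cholesterolMAXamount": recommendation.cholesterol_max_mg,
        "fiberMINamount": recommendation.fiber_min_g,
        "fiberMAXamount": recommendation.fiber_max_g,
        "sodiumMAXamount": recommendation.sodium_max_mg,
        "calciumAmount": recommendation.calcium_mg,
        "mealsPerDay": recommendation.meals_per_day,
        "BCAAsupplementation": recommendation.bcaa_supplement,
        "energyProteinSupplementation": recommendation.energy_protein_supplement,
    }
    for name, value in rec_props.items():
        g.add((rec, copd[name], Literal(value)))
    return g.serialize(format="turtle")


# ---------------------------------------------------------------------------
# agreement statistics

class AgreementTable(BaseModel):
    """Per-item Likert scores (items × raters), all integers in 1..5."""

    model_config = ConfigDict(frozen=True)

    item_labels: tuple[str, ...]
    per_rater_scores: tuple[tuple[int, ...], ...]

    @field_validator("per_rater_scores")
    @classmethod
    def _scores_in_range(cls, v):
        if not v:
            raise ValueError("score matrix must be non-empty")
        for row in v:
            if not row or any(s < 1 or s > 5 for s in row):
                raise ValueError("scores must be non-empty and within 1..5")
        return v


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_agreement(table: AgreementTable) -> dict:
    """Per-item (mean, sample SD) and the overall (mean, SD) of item means.

    Means and SDs are rounded half-up to two decimals; SDs use the n−1
    (sample) convention. The overall row summarizes the unrounded item
    means.
    """
    if len(table.item_labels) != len(table.per_rater_scores):
        raise ValueError("labels and score rows differ in length")
    per_item = {}
    means = []
    for label, row in zip(table.item_labels, table.per_rater_scores):
        arr = np.asarray(row, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        per_item[label] = {"mean": _round2(mean), "sd": _round2(sd)}
        means.append(mean)
    marr = np.asarray(means)
    overall_sd = float(marr.std(ddof=1)) if marr.size > 1 else 0.0
    return {
        "per_item": per_item,
        "overall": {"mean": _round2(float(marr.mean())), "sd": _round2(overall_sd)},
    }


def load_validation_agreement() -> AgreementTable:
    """The packaged expert-panel agreement scores (five patient profiles,
    seven raters) from the system's clinical validation study."""
    text = resources.files("nutricopd.data").joinpath(
        "validation_agreement.csv").read_text()
    rows = list(csv.reader(io.StringIO(text)))
    labels = tuple(r[0] for r in rows[1:] if r)
    scores = tuple(tuple(int(x) for x in r[1:]) for r in rows[1:] if r)
    return AgreementTable(item_labels=labels, per_rater_scores=scores)
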